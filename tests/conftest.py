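"""Shared fixtures: a small synthetic study reused across test modules."""

import numpy as np
import pytest

from casnano import nanoenv, pipeline, structures, synthetic

SMALL = synthetic.SyntheticConfig(
    n_trajectories=8,
    n_snapshots_per_trajectory=8,
    n_residues=30,
    n_proximal_residues=12,
    n_descriptors=10,
    n_informative_features=5,
    seed=11,
)


@pytest.fixture(scope="session")
def small_data() -> synthetic.SyntheticDataset:
    return synthetic.simulate(SMALL)


@pytest.fixture(scope="session")
def small_dataset(small_data) -> nanoenv.NanoenvDataset:
    frames = {t: sorted(fr, key=lambda s: s.snapshot_id)
              for t, fr in small_data.snapshots.items()}
    training = [s for fr in frames.values() for s in fr[:-4]]
    hpr = structures.compute_hpr_set(training)
    return nanoenv.assemble_matrix(
        small_data.table, hpr, dict(small_data.activities),
        trajectory_meta=small_data.metadata, annotate=True,
    )


@pytest.fixture(scope="session")
def small_model(small_dataset):
    """A deterministic fitted model on the small study (ridge -> extra trees)."""
    split = pipeline.make_split(small_dataset, n_holdout=4, cv_seed=0)
    model = pipeline.train_final(
        "ridge", "extra_trees", 5,
        small_dataset.X.loc[split.train_rows], small_dataset.y.loc[split.train_rows],
        seed=0,
    )
    return model, split


def make_snapshot(
    ca, nucleotides=None, snapshot_id="C001", trajectory_id="C0", residue_start=1
):
    """Snapshot from raw coordinates: ``ca`` is (n, 3); ``nucleotides`` maps
    (strand, position) -> coordinate (defaults to one sgRNA C4' at origin)."""
    ca = np.asarray(ca, dtype=float).reshape(-1, 3)
    residues = [("A", residue_start + i, "ALA") for i in range(len(ca))]
    if nucleotides is None:
        nucleotides = {(structures.SGRNA, 1): (0.0, 0.0, 0.0)}
    index = [(s, p, "A" if s == structures.SGRNA else "T")
             for (s, p) in nucleotides]
    c4 = np.array([nucleotides[k] for k in nucleotides], dtype=float).reshape(-1, 3)
    return structures.Snapshot(snapshot_id, trajectory_id, residues, ca, index, c4)
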