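"""Synthetic sgRNA-dsDNA-Cas9 snapshot sets with planted predictive signal.

The generator emulates the shape of the real study data -- 28 trajectories of
24 snapshots each, a 20-bp heteroduplex represented by C4' pseudo-atoms, a
protein residue cloud with a controlled number of residues inside the 3-7
Angstrom proximity shell, a long-format descriptor table, and per-trajectory
cleavage-activity labels in [0, 1] -- while planting a known set of
activity-informative (residue, descriptor) features so that feature
selection, model training and interpretation can be validated against ground
truth.

Generative model
----------------
Each trajectory t draws one latent signal ``z_t ~ N(0, 1)``.  Every planted
informative feature takes value ``z_t + N(0, noise_sd)`` in each snapshot of
trajectory t (so the per-feature, per-snapshot signal-to-noise ratio is
``1 / noise_sd``); every other (residue, descriptor) pair is pure ``N(0, 1)``
noise.  The activity label of trajectory t is the affine-clipped map

    a_t = clip( intercept + gain * (sum_j w_j z_t) / (sum_j |w_j|)
                + N(0, label_noise_sd), 0, 1 )

shared by all snapshots of the trajectory.  Geometry: the heteroduplex
template is two parallel straight strands of C4' pseudo-atoms 6 Angstrom
apart with a 5 Angstrom rise; snapshots are the template plus isotropic
Gaussian jitter.

All randomness flows from the single ``seed`` through named
``numpy.random.SeedSequence`` substreams (geometry, truth, latents, jitter,
descriptors, labels, metadata in that order), so each generation stage is
independently reproducible.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError
from .nanoenv import DescriptorTable, Mismatch, feature_name
from .structures import SGRNA, TSDNA, ChainMap, Snapshot, snapshot_to_pdb_text

_STREAMS = ("geometry", "truth", "latents", "jitter", "descriptors", "labels", "metadata")
_MUTATION_ALPHABET = string.digits + string.ascii_uppercase

#: deterministic descriptor-slug pool following the feature-name schema
_BASE_SLUGS = (
    "density", "entropy_density", "cross_presence_order", "side_chain_angle",
    "electrostatic_potential", "sponge", "contact_energy_density", "curvature",
    "cross_link_order", "unused_contacts", "weighted_contact_number", "solvation",
    "graph_descriptor", "residue_contacts",
)
_PLAIN_SLUGS = ("accessibility", "dssp", "hydrophobicity", "stride")
_AGGS = ("GN", "SW", "WNA", "VD")
_DISTANCES = (3, 5, 12)


def default_descriptor_names(n: int) -> list[str]:
    """First ``n`` names from a deterministic pool of schema-conformant
    descriptor slugs (aggregated neighbour descriptors plus the four plain
    parent-class descriptors)."""
    pool: list[str] = list(_PLAIN_SLUGS)
    for dist in _DISTANCES:
        for slug in _BASE_SLUGS:
            for agg in _AGGS:
                pool.append(f"neighbours_{slug}_{dist}_{agg}")
    if n > len(pool):
        raise ConfigurationError(f"at most {len(pool)} distinct descriptor names available")
    return pool[:n]


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic generator.

    Defaults reproduce the benchmark conditions used throughout the test
    suite: 28 trajectories x 24 snapshots, 40 heteroduplex-proximal residues
    x 50 descriptors = 2000 feature columns, 20 planted informative features
    with equal weights and per-feature signal-to-noise ratio 3.
    """

    n_trajectories: int = 28
    n_snapshots_per_trajectory: int = 24
    n_residues: int = 80
    n_proximal_residues: int = 40
    n_descriptors: int = 50
    n_informative_features: int = 20
    informative_weights: tuple[float, ...] | None = None
    noise_sd: float = 1.0 / 3.0
    label_noise_sd: float = 0.0
    jitter_sd: float = 0.25
    activity_intercept: float = 0.5
    activity_gain: float = 0.3
    seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_trajectories": self.n_trajectories,
            "n_snapshots_per_trajectory": self.n_snapshots_per_trajectory,
            "n_residues": self.n_residues,
            "n_proximal_residues": self.n_proximal_residues,
            "n_descriptors": self.n_descriptors,
            "n_informative_features": self.n_informative_features,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ConfigurationError(f"{name} must be a positive integer, got {value!r}")
        if self.n_proximal_residues > self.n_residues:
            raise ConfigurationError("n_proximal_residues cannot exceed n_residues")
        if self.n_informative_features > self.n_proximal_residues * self.n_descriptors:
            raise ConfigurationError(
                "n_informative_features cannot exceed n_proximal_residues * n_descriptors"
            )
        if self.n_trajectories > len(_MUTATION_ALPHABET):
            raise ConfigurationError("the mutation alphabet supports at most 36 trajectories")
        if self.n_snapshots_per_trajectory > 99:
            raise ConfigurationError("snapshot numbers are two digits (max 99 per trajectory)")
        for name in ("noise_sd", "label_noise_sd", "jitter_sd"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")
        if self.informative_weights is not None and (
            len(self.informative_weights) != self.n_informative_features
        ):
            raise ConfigurationError("informative_weights length must equal n_informative_features")

    def weights(self) -> np.ndarray:
        if self.informative_weights is None:
            return np.ones(self.n_informative_features)
        return np.asarray(self.informative_weights, dtype=float)

    def rng(self, stream: str) -> np.random.Generator:
        """Named substream generator; all streams derive from ``seed``."""
        index = _STREAMS.index(stream)
        children = np.random.SeedSequence(self.seed).spawn(len(_STREAMS))
        return np.random.default_rng(children[index])

    def trajectory_ids(self) -> list[str]:
        return [f"C{_MUTATION_ALPHABET[i]}" for i in range(self.n_trajectories)]

    def snapshot_ids(self, trajectory: str) -> list[str]:
        return [f"{trajectory}{k:02d}" for k in range(1, self.n_snapshots_per_trajectory + 1)]


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of the planted signal: which (residue, descriptor)
    features are informative, their weights, and the per-trajectory latents
    driving both feature values and activities."""

    informative_feature_ids: tuple[tuple[int, str], ...]
    weights: tuple[float, ...]
    latents: Mapping[str, float]
    activity_function: str = "affine-clipped"

    def __post_init__(self) -> None:
        if len(self.weights) != len(self.informative_feature_ids):
            raise ConfigurationError("weights and informative_feature_ids must align")

    def feature_names(self) -> list[str]:
        return [feature_name(res, desc) for res, desc in self.informative_feature_ids]


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

def _heteroduplex_template() -> tuple[list[tuple[str, int, str]], np.ndarray]:
    """Two parallel straight strands 6 A apart, 5 A rise per position."""
    guide = "ACGU" * 5
    index: list[tuple[str, int, str]] = []
    coords = []
    for p in range(1, 21):
        index.append((SGRNA, p, guide[p - 1]))
        coords.append((5.0 * (p - 1), 0.0, 0.0))
    complement = {"A": "T", "C": "G", "G": "C", "U": "A"}
    for p in range(1, 21):
        index.append((TSDNA, p, complement[guide[p - 1]]))
        coords.append((5.0 * (p - 1), 6.0, 0.0))
    return index, np.asarray(coords)


_RESNAMES = ("ALA", "GLY", "SER", "VAL", "LEU", "THR", "ASP", "LYS")


def _template_snapshot(config: SyntheticConfig) -> Snapshot:
    """Jitter-free template with exactly ``n_proximal_residues`` residues in
    the [3, 7] A shell (with margin so modest jitter keeps them there) and the
    remainder strictly beyond 9 A."""
    rng = config.rng("geometry")
    nuc_index, c4 = _heteroduplex_template()
    margin = min(3.0 * config.jitter_sd, 0.45)
    lo, hi = 3.0 + max(margin, 0.2), 7.0 - max(margin, 0.2)
    residues: list[tuple[str, int, str]] = []
    coords: list[np.ndarray] = []

    def random_unit() -> np.ndarray:
        v = rng.normal(size=3)
        return v / np.linalg.norm(v)

    num = 1
    while len(coords) < config.n_proximal_residues:
        anchor = c4[rng.integers(len(c4))]
        candidate = anchor + rng.uniform(lo, hi) * random_unit()
        d = np.linalg.norm(c4 - candidate, axis=1).min()
        if lo <= d <= hi:
            residues.append(("A", num, _RESNAMES[(num - 1) % len(_RESNAMES)]))
            coords.append(candidate)
            num += 1
    span_lo = c4.min(axis=0) - 25.0
    span_hi = c4.max(axis=0) + 25.0
    far = 9.0 + max(3.0 * config.jitter_sd, 0.5)
    while len(coords) < config.n_residues:
        candidate = rng.uniform(span_lo, span_hi)
        if np.linalg.norm(c4 - candidate, axis=1).min() > far:
            residues.append(("A", num, _RESNAMES[(num - 1) % len(_RESNAMES)]))
            coords.append(candidate)
            num += 1
    return Snapshot(
        snapshot_id="template",
        trajectory_id="template",
        residue_index=residues,
        ca_coords=np.asarray(coords),
        nucleotide_index=nuc_index,
        c4_coords=c4,
    )


def generate_snapshots(config: SyntheticConfig) -> dict[str, list[Snapshot]]:
    """Snapshots for every trajectory: the shared template plus per-snapshot
    Gaussian coordinate jitter of sd ``jitter_sd`` (Angstrom)."""
    config.validate()
    template = _template_snapshot(config)
    rng = config.rng("jitter")
    out: dict[str, list[Snapshot]] = {}
    for traj in config.trajectory_ids():
        frames = []
        for sid in config.snapshot_ids(traj):
            if config.jitter_sd > 0:
                ca = template.ca_coords + rng.normal(0, config.jitter_sd,
                                                     template.ca_coords.shape)
                c4 = template.c4_coords + rng.normal(0, config.jitter_sd,
                                                     template.c4_coords.shape)
            else:
                ca = template.ca_coords.copy()
                c4 = template.c4_coords.copy()
            frames.append(
                Snapshot(sid, traj, list(template.residue_index), ca,
                         list(template.nucleotide_index), c4)
            )
        out[traj] = frames
    return out


# ---------------------------------------------------------------------------
# planted truth, descriptor tables, activities
# ---------------------------------------------------------------------------

def make_planted_truth(config: SyntheticConfig) -> PlantedTruth:
    """Choose the planted (residue, descriptor) features (always on proximal
    residues, so they survive HPR filtering) and draw trajectory latents."""
    config.validate()
    rng = config.rng("truth")
    descriptors = default_descriptor_names(config.n_descriptors)
    n_cells = config.n_proximal_residues * config.n_descriptors
    flat = rng.choice(n_cells, size=config.n_informative_features, replace=False)
    ids = tuple(
        (int(i // config.n_descriptors) + 1, descriptors[int(i % config.n_descriptors)])
        for i in sorted(flat)
    )
    latent_rng = config.rng("latents")
    latents = {traj: float(latent_rng.normal()) for traj in config.trajectory_ids()}
    return PlantedTruth(ids, tuple(config.weights()), latents)


def generate_descriptor_table(
    snapshots: Mapping[str, Sequence[Snapshot]],
    truth: PlantedTruth,
    config: SyntheticConfig,
) -> DescriptorTable:
    """One record per (snapshot, residue, descriptor): planted features carry
    the trajectory latent plus N(0, noise_sd); all others are N(0, 1) noise."""
    if not snapshots:
        raise ConfigurationError("generate_descriptor_table requires snapshots")
    rng = config.rng("descriptors")
    descriptors = default_descriptor_names(config.n_descriptors)
    informative = set(truth.informative_feature_ids)

    snapshot_ids: list[str] = []
    latent_per_snapshot: list[float] = []
    for traj, frames in snapshots.items():
        for snap in frames:
            snapshot_ids.append(snap.snapshot_id)
            latent_per_snapshot.append(truth.latents[traj])
    n_snap, n_res, n_desc = len(snapshot_ids), config.n_residues, config.n_descriptors

    values = rng.normal(0.0, 1.0, size=(n_snap, n_res, n_desc))
    mask = np.zeros((n_res, n_desc), dtype=bool)
    for res, desc in informative:
        mask[res - 1, descriptors.index(desc)] = True
    latent = np.asarray(latent_per_snapshot)[:, None]
    noise = rng.normal(0.0, 1.0, size=(n_snap, int(mask.sum())))
    values[:, mask] = latent + config.noise_sd * noise

    frame = pd.DataFrame(
        {
            "snapshot": np.repeat(snapshot_ids, n_res * n_desc),
            "residue": np.tile(np.repeat(np.arange(1, n_res + 1), n_desc), n_snap),
            "descriptor": np.tile(descriptors, n_snap * n_res),
            "value": values.reshape(-1),
        }
    )
    return DescriptorTable(frame)


def activity_from_latent(latent: float, weights: np.ndarray, config: SyntheticConfig) -> float:
    """Noise-free affine-clipped activity for one trajectory latent."""
    weights = np.asarray(weights, dtype=float)
    scale = np.abs(weights).sum()
    signal = float(weights.sum() * latent / scale) if scale > 0 else 0.0
    return float(np.clip(config.activity_intercept + config.activity_gain * signal, 0.0, 1.0))


def generate_activities(truth: PlantedTruth, config: SyntheticConfig) -> pd.Series:
    """Per-trajectory activity labels in [0, 1] (one label per trajectory,
    shared by all its snapshots)."""
    config.validate()
    rng = config.rng("labels")
    weights = np.asarray(truth.weights, dtype=float)
    scale = np.abs(weights).sum()
    out = {}
    for traj in config.trajectory_ids():
        latent = truth.latents[traj]
        signal = float(weights.sum() * latent / scale) if scale > 0 else 0.0
        noise = rng.normal(0.0, config.label_noise_sd) if config.label_noise_sd > 0 else 0.0
        out[traj] = float(
            np.clip(config.activity_intercept + config.activity_gain * signal + noise, 0.0, 1.0)
        )
    return pd.Series(out, name="activity")


def trajectory_metadata(config: SyntheticConfig) -> pd.DataFrame:
    """On-target flag and mismatch metadata per trajectory.

    The first trajectory is the on-target reference; every other trajectory
    receives a random single PAM-distal target-strand substitution (position
    11-20), from which the guide:DNA interface type is derived.
    """
    rng = config.rng("metadata")
    rows = []
    for i, traj in enumerate(config.trajectory_ids()):
        if i == 0:
            rows.append((traj, True, None, None, None))
            continue
        position = int(rng.integers(11, 21))
        original, mutated = rng.choice(list("ACGT"), size=2, replace=False)
        mm = Mismatch(position, str(original), str(mutated))
        rows.append((traj, False, mm.position, mm.interface, mm.code))
    return pd.DataFrame(
        rows,
        columns=["trajectory_id", "on_target", "mismatch_position", "mismatch_type",
                 "mismatch_code"],
    ).set_index("trajectory_id")


# ---------------------------------------------------------------------------
# one-call bundle and writers
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    config: SyntheticConfig
    snapshots: dict[str, list[Snapshot]]
    table: DescriptorTable
    activities: pd.Series
    truth: PlantedTruth
    metadata: pd.DataFrame


def simulate(config: SyntheticConfig | None = None) -> SyntheticDataset:
    """Generate the full synthetic study: snapshots, descriptor table,
    activities, planted truth and trajectory metadata."""
    config = config or SyntheticConfig()
    config.validate()
    snapshots = generate_snapshots(config)
    truth = make_planted_truth(config)
    table = generate_descriptor_table(snapshots, truth, config)
    activities = generate_activities(truth, config)
    metadata = trajectory_metadata(config)
    return SyntheticDataset(config, snapshots, table, activities, truth, metadata)


def write_snapshots(
    snapshots: Mapping[str, Sequence[Snapshot]],
    directory: str | Path,
    chain_map: ChainMap | None = None,
) -> list[Path]:
    """One minimal PDB file per snapshot, named ``<snapshot_id>.pdb``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for frames in snapshots.values():
        for snap in frames:
            path = directory / f"{snap.snapshot_id}.pdb"
            path.write_text(snapshot_to_pdb_text(snap, chain_map))
            paths.append(path)
    return paths


def write_activities(activities: pd.Series, path: str | Path) -> None:
    frame = activities.rename_axis("trajectory").reset_index()
    frame.columns = ["trajectory", "activity"]
    frame.to_csv(path, sep="\t", index=False)


def read_activities(path: str | Path) -> pd.Series:
    frame = pd.read_csv(path, sep="\t")
    return pd.Series(frame["activity"].values, index=frame["trajectory"].values,
                     name="activity")
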