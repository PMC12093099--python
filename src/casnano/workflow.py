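"""End-to-end orchestration: simulate/load -> geometry -> assemble -> train
-> evaluate -> interpret -> stability, with provenance-stamped artifacts.

Every run is driven by a :class:`RunConfig` (single structured config,
loadable from YAML).  All stages are recomputed deterministically from the
config seeds, so invoking a later stage never depends on hidden state; the
``stages`` argument only controls which artifact groups are written.  A
manifest records the config hash and every output file.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import interpret, nanoenv, pipeline, stability, structures, synthetic
from .errors import ConfigurationError

logger = logging.getLogger(__name__)

ALL_STAGES = ("simulate", "geometry", "assemble", "train", "evaluate",
              "interpret", "stability")


@dataclass
class RunConfig:
    """Configuration of a full analysis run."""

    output_dir: str = "casnano_run"
    simulate: bool = True
    synthetic: synthetic.SyntheticConfig = field(default_factory=synthetic.SyntheticConfig)
    # input paths, used when simulate is False
    snapshots_dir: str | None = None
    descriptor_tsv: str | None = None
    labels_tsv: str | None = None
    # geometry
    d_min: float = structures.D_MIN_DEFAULT
    d_max: float = structures.D_MAX_DEFAULT
    cluster_cutoff: float = structures.CLUSTER_CUTOFF_DEFAULT
    # pipeline
    n_holdout: int = pipeline.N_HOLDOUT_DEFAULT
    cv_seed: int = 0
    model_seed: int = 0
    surrogates: tuple[str, ...] = pipeline.SURROGATE_FAMILIES
    finals: tuple[str, ...] = pipeline.FINAL_FAMILIES
    feature_sizes: tuple[int, ...] = pipeline.FEATURE_SIZES
    delta_rho: float = pipeline.DELTA_RHO_DEFAULT
    # interpretation
    shap_permutations: int = 256
    shap_seed: int = 0
    # stability
    atom_selection: str = "calpha"
    kl_threshold: float = stability.KL_THRESHOLD_DEFAULT
    domain_map_path: str | None = None

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        syn = synthetic.SyntheticConfig(**data.pop("synthetic", {}))
        for key in ("surrogates", "finals", "feature_sizes"):
            if key in data:
                data[key] = tuple(data[key])
        return RunConfig(synthetic=syn, **data)

    def to_dict(self) -> dict:
        data = asdict(self)
        data["synthetic"] = asdict(self.synthetic)
        return data

    def config_hash(self) -> str:
        canonical = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]


def _write_json(path: Path, payload: dict) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_jsonable) + "\n")


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return str(obj)


def _load_inputs(config: RunConfig):
    """Either simulate the study or load snapshots / descriptors / labels
    from the configured paths."""
    if config.simulate:
        data = synthetic.simulate(config.synthetic)
        return data.snapshots, data.table, data.activities, data.metadata
    for name in ("snapshots_dir", "descriptor_tsv", "labels_tsv"):
        value = getattr(config, name)
        if value is None or not Path(value).exists():
            raise ConfigurationError(f"{name} missing or not found: {value!r}")
    snapshots: dict[str, list[structures.Snapshot]] = {}
    for path in sorted(Path(config.snapshots_dir).glob("*.pdb")):
        sid = path.stem
        traj = structures.parse_snapshot_id(sid).trajectory_id
        snap = structures.parse_snapshot(path.read_text(), snapshot_id=sid,
                                         trajectory_id=traj)
        snapshots.setdefault(traj, []).append(snap)
    for frames in snapshots.values():
        frames.sort(key=lambda s: s.snapshot_id)
    table = nanoenv.parse_descriptor_tsv(Path(config.descriptor_tsv))
    activities = synthetic.read_activities(config.labels_tsv)
    metadata = None
    return snapshots, table, activities, metadata


def planted_recovery_experiment(
    seeds: Sequence[int],
    noise_sd: float = 1.0 / 3.0,
    m1: str = "xgboost",
    m2: str = "extra_trees",
    f: int = 30,
    base_config: synthetic.SyntheticConfig | None = None,
) -> pd.DataFrame:
    """Planted-feature recovery benchmark under the default study conditions.

    For each seed: simulate the synthetic study (28 trajectories x 24
    snapshots, 2000 feature columns, 20 planted informative features) at the
    given feature noise level, train the fixed (m1, m2, f) pipeline on the
    training partition, and report the fraction of planted features among the
    selected ones plus the held-out test Spearman correlation.
    """
    base = base_config or synthetic.SyntheticConfig()
    rows = []
    for seed in seeds:
        config = replace(base, seed=int(seed), noise_sd=noise_sd)
        data = synthetic.simulate(config)
        frames = {t: sorted(fr, key=lambda s: s.snapshot_id)
                  for t, fr in data.snapshots.items()}
        training = [s for fr in frames.values() for s in fr[:-pipeline.N_HOLDOUT_DEFAULT]]
        hpr = structures.compute_hpr_set(training)
        dataset = nanoenv.assemble_matrix(
            data.table, hpr, dict(data.activities), trajectory_meta=data.metadata
        )
        split = pipeline.make_split(dataset)
        fitted = pipeline.fit_pipeline(
            m1, m2, f, dataset.X.loc[split.train_rows], dataset.y.loc[split.train_rows],
            seed=int(seed),
        )
        planted = set(data.truth.feature_names())
        recovery = len(planted & set(fitted.selected_features)) / len(planted)
        pred = fitted.predict(dataset.X.loc[split.test_rows])
        rho, _, _, _ = pipeline.compute_metrics(
            dataset.y.loc[split.test_rows].to_numpy(), pred
        )
        rows.append((int(seed), noise_sd, recovery, rho,
                     len(split.train_rows), len(split.test_rows)))
    return pd.DataFrame(
        rows, columns=["seed", "noise_sd", "recovery", "test_spearman",
                       "n_train", "n_test"],
    )


@dataclass
class RunResult:
    """In-memory results of a full run (artifacts are also on disk)."""

    config: RunConfig
    hpr: structures.HPRSet
    dataset: nanoenv.NanoenvDataset
    split: pipeline.SplitPlan
    cv: pipeline.CVResult | None
    model: pipeline.StingCrisprModel
    metrics: pipeline.Metrics
    shap_report: interpret.ShapReport | None
    clustering: structures.ResidueClustering | None
    hotspots: dict[str, pd.DataFrame] | None
    stability: pd.DataFrame | None
    artifacts: list[Path]


def run_full(config: RunConfig, stages: Sequence[str] = ALL_STAGES) -> RunResult:
    """Execute the pipeline end to end, writing artifacts for the requested
    stages into ``config.output_dir``."""
    unknown = set(stages) - set(ALL_STAGES)
    if unknown:
        raise ConfigurationError(f"unknown stages {sorted(unknown)}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    artifacts: list[Path] = []

    def emit(name: str, writer) -> None:
        path = outdir / name
        writer(path)
        artifacts.append(path)

    snapshots, table, activities, metadata = _load_inputs(config)
    all_frames = [s for frames in snapshots.values() for s in frames]
    trajectory_of = {s.snapshot_id: s.trajectory_id for s in all_frames}

    if config.simulate and "simulate" in stages:
        data_dir = outdir / "data"
        paths = synthetic.write_snapshots(snapshots, data_dir / "snapshots")
        artifacts.extend(paths)
        emit("data/descriptors.tsv", lambda p: table.write_tsv(p))
        emit("data/activities.tsv", lambda p: synthetic.write_activities(activities, p))
        if metadata is not None:
            emit("data/trajectories.tsv", lambda p: metadata.to_csv(p, sep="\t"))

    # --- geometry: training-only HPR set and heteroduplex plasticity -------
    training_frames = []
    for frames in snapshots.values():
        ordered = sorted(frames, key=lambda s: nanoenv._snapshot_number(s.snapshot_id))
        training_frames.extend(ordered[: len(ordered) - config.n_holdout])
    hpr = structures.compute_hpr_set(training_frames, config.d_min, config.d_max)
    sums = {traj: structures.plasticity_sum(frames) for traj, frames in snapshots.items()}
    on_target = (
        metadata["on_target"].reindex(list(sums)).fillna(False).tolist()
        if metadata is not None else None
    )
    association = structures.plasticity_activity_association(
        [sums[t] for t in sums], [float(activities[t]) for t in sums], on_target
    )
    if "geometry" in stages:
        emit("hpr.tsv", lambda p: hpr.to_frame().to_csv(p, sep="\t", index=False))
        emit("plasticity.tsv", lambda p: pd.DataFrame(
            {"trajectory": list(sums), "plasticity_sum": list(sums.values()),
             "activity": [float(activities[t]) for t in sums]}
        ).to_csv(p, sep="\t", index=False))
        emit("plasticity_association.json", lambda p: _write_json(
            p, {"spearman": association.spearman, "pearson": association.pearson,
                "defined": association.defined}))

    # --- assemble ----------------------------------------------------------
    dataset = nanoenv.assemble_matrix(
        table, hpr, dict(activities), trajectory_of=trajectory_of,
        trajectory_meta=metadata, annotate=True,
    )
    if "assemble" in stages:
        emit("dataset_shape.json", lambda p: _write_json(
            p, {"rows": dataset.n_rows, "features": dataset.n_features,
                "dropped_columns": len(dataset.dropped_columns)}))

    # --- train -------------------------------------------------------------
    split = pipeline.make_split(dataset, config.n_holdout, config.cv_seed)
    X_train = dataset.X.loc[split.train_rows]
    y_train = dataset.y.loc[split.train_rows]
    cv = pipeline.grid_search(
        X_train, y_train, split, config.surrogates, config.finals,
        config.feature_sizes, seed=config.model_seed,
    )
    m1, m2 = pipeline.select_model_pair(cv)
    f_star = pipeline.select_feature_size(cv.rho_curve(m1, m2), config.delta_rho)
    model = pipeline.train_final(
        m1, m2, f_star, X_train, y_train, seed=config.model_seed,
        provenance={"config_hash": config.config_hash(), "hpr_size": len(hpr),
                    "cv_seed": config.cv_seed},
    )
    if "train" in stages:
        emit("cv_results.tsv", lambda p: cv.table.to_csv(p, sep="\t", index=False))
        emit("selection.json", lambda p: _write_json(
            p, {"m1": m1, "m2": m2, "f_star": f_star,
                "pair_mean_spearman": cv.pair_mean(m1, m2),
                "rho_curve": {str(k): v for k, v in cv.rho_curve(m1, m2).items()}}))
        emit("model.joblib", lambda p: model.save(p))

    # --- evaluate ----------------------------------------------------------
    metrics = pipeline.evaluate(
        model, dataset.X.loc[split.test_rows], dataset.y.loc[split.test_rows],
        dataset.row_meta,
    )
    if "evaluate" in stages:
        emit("metrics.json", lambda p: _write_json(p, metrics.to_dict()))

    # --- interpret ---------------------------------------------------------
    shap_report = clustering = hotspots = None
    if "interpret" in stages:
        shap_report = interpret.shap_values(
            model, dataset.X, n_permutations=config.shap_permutations,
            seed=config.shap_seed,
        )
        annotations = {name: dataset.annotations[name] for name in model.feature_names}
        selected_residues = sorted({a.residue_number for a in annotations.values()})
        if len(selected_residues) >= 2:
            mean_d = structures.mean_pairwise_residue_distances(all_frames, selected_residues)
            clustering = structures.cluster_residues(mean_d, config.cluster_cutoff)
            emit("mean_residue_distances.tsv", lambda p: mean_d.to_csv(p, sep="\t"))
            emit("clusters.json", lambda p: p.write_text(clustering.to_json() + "\n"))
        hotspots = interpret.hotspot_report(shap_report, annotations, clustering)
        emit("shap_values.tsv", lambda p: shap_report.phi.to_csv(p, sep="\t"))
        for prop, frame in hotspots.items():
            emit(f"importance_{prop}.tsv",
                 lambda p, fr=frame: fr.to_csv(p, sep="\t"))
        contact = structures.contact_count_heatmap(
            all_frames, selected_residues, d_min=config.d_min, d_max=config.d_max
        )
        emit("contact_counts.tsv", lambda p: contact.to_csv(p, sep="\t"))

    # --- stability ---------------------------------------------------------
    stability_frame = None
    if "stability" in stages:
        reference_id = None
        if metadata is not None and metadata["on_target"].any():
            reference_id = metadata.index[metadata["on_target"]][0]
        if reference_id is None:
            reference_id = next(iter(snapshots))
        chain = all_frames[0].residue_index[0][0]
        sites = [
            (chain, residue)
            for residue in sorted({
                nanoenv.parse_feature_name(name).residue_number
                for name in model.feature_names
            })
        ]
        stability_frame = stability.stability_table(
            snapshots, reference_id, sites, config.atom_selection,
            kl_threshold=config.kl_threshold,
        )
        emit("stability.tsv",
             lambda p: stability_frame.to_csv(p, sep="\t", index=False))

    manifest = {
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "artifacts": sorted(str(p.relative_to(outdir)) for p in artifacts),
    }
    _write_json(outdir / "manifest.json", manifest)
    artifacts.append(outdir / "manifest.json")

    return RunResult(config, hpr, dataset, split, cv, model, metrics,
                     shap_report, clustering, hotspots, stability_frame, artifacts)
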