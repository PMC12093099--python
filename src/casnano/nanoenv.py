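"""Descriptor tables, feature annotation, and nanoenvironment assembly.

The *nanoenvironment dataset* is the row-per-snapshot feature matrix fed to
the prediction pipeline: one column per (heteroduplex-proximal residue,
descriptor) pair, one row per structure snapshot, each row labelled with the
cleavage activity of its trajectory.  Feature names follow the schema

    Cas9_<residue>_<descriptor slug>[_<GN|SW|WNA|VD>]

and each feature carries six interpretive properties: the Cas9 residue, its
domain and contiguous domain, the parent descriptor class, the (neighbour)
descriptor class, and the neighbour aggregation method.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import DataError, ParseError
from .structures import HPRSet, parse_snapshot_id

logger = logging.getLogger(__name__)

AGGREGATIONS = ("GN", "SW", "WNA", "VD")
CANONICAL_COLUMNS = ("snapshot", "residue", "descriptor", "value")


# ---------------------------------------------------------------------------
# descriptor tables
# ---------------------------------------------------------------------------

@dataclass
class DescriptorTable:
    """Long-format (snapshot, residue, descriptor, value) records."""

    records: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in CANONICAL_COLUMNS if c not in self.records.columns]
        if missing:
            raise DataError(f"descriptor table lacks columns {missing}")
        dup = self.records.duplicated(subset=["snapshot", "residue", "descriptor"])
        if dup.any():
            first = self.records.loc[dup.idxmax(), ["snapshot", "residue", "descriptor"]]
            raise DataError(
                "duplicate descriptor record for "
                f"({first['snapshot']}, {first['residue']}, {first['descriptor']})"
            )

    def __len__(self) -> int:
        return len(self.records)

    @property
    def snapshots(self) -> list[str]:
        return sorted(self.records["snapshot"].unique())

    @property
    def residues(self) -> list[int]:
        return sorted(int(r) for r in self.records["residue"].unique())

    @property
    def descriptors(self) -> list[str]:
        return sorted(self.records["descriptor"].unique())

    def write_tsv(self, path: str | Path) -> None:
        self.records.to_csv(path, sep="\t", index=False,
                            columns=list(CANONICAL_COLUMNS))


def parse_descriptor_tsv(
    source: str | Path,
    columns: Sequence[str] | None = None,
) -> DescriptorTable:
    """Read a long-format descriptor TSV.

    ``source`` may be a path or the TSV text itself.  The canonical header is
    ``snapshot  residue  descriptor  value``; ``columns`` adapts files whose
    columns are named or ordered differently (give the source's column names
    in canonical order).  Duplicated keys and non-numeric values are errors.
    """
    if isinstance(source, Path) or (isinstance(source, str) and "\n" not in source
                                    and "\t" not in source):
        handle: object = source
    else:
        handle = io.StringIO(source)
    frame = pd.read_csv(handle, sep="\t", dtype=str)
    if columns is not None:
        if len(columns) != 4:
            raise ParseError("column adapter must name exactly four columns")
        try:
            frame = frame[list(columns)]
        except KeyError as exc:
            raise ParseError(f"adapter columns not found in file: {exc}") from exc
        frame.columns = list(CANONICAL_COLUMNS)
    missing = [c for c in CANONICAL_COLUMNS if c not in frame.columns]
    if missing:
        raise ParseError(f"descriptor TSV lacks columns {missing}")
    frame = frame[list(CANONICAL_COLUMNS)]
    values = pd.to_numeric(frame["value"], errors="coerce")
    bad = values.isna() & frame["value"].notna()
    if bad.any():
        line = int(bad.idxmax()) + 2  # header + 1-based
        raise ParseError(
            f"non-numeric descriptor value {frame['value'][bad.idxmax()]!r} on line {line}"
        )
    # pd.to_numeric is not correctly rounded; reconvert for exact round-trips
    exact = np.array(
        [float(v) if isinstance(v, str) else np.nan for v in frame["value"]],
        dtype=float,
    )
    frame = frame.assign(
        residue=pd.to_numeric(frame["residue"]).astype(int), value=exact
    )
    return DescriptorTable(frame.reset_index(drop=True))


# ---------------------------------------------------------------------------
# feature names and their six interpretive properties
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FeatureAnnotation:
    """The six interpretive properties of a nanoenvironment feature."""

    feature_name: str
    residue_number: int
    descriptor_class: str
    parent_descriptor_class: str
    aggregation: str  # one of GN / SW / WNA / VD / "none"
    cas9_domain: str
    contiguous_domain: str


def _load_yaml_resource(name: str) -> dict:
    with resources.files("casnano.data").joinpath(name).open() as fh:
        return yaml.safe_load(fh)


def load_descriptor_keywords(path: str | Path | None = None) -> dict[str, str]:
    data = yaml.safe_load(Path(path).read_text()) if path else _load_yaml_resource(
        "descriptor_classes.yaml")
    return dict(data["keywords"])


def load_domain_map(path: str | Path | None = None) -> list[dict]:
    data = yaml.safe_load(Path(path).read_text()) if path else _load_yaml_resource(
        "cas9_domains.yaml")
    return list(data["segments"])


def domain_of(residue_number: int, domain_map: list[dict] | None = None) -> tuple[str, str]:
    """(domain, contiguous domain) of a Cas9 residue per the domain map."""
    segments = domain_map if domain_map is not None else load_domain_map()
    for seg in segments:
        if seg["start"] <= residue_number <= seg["end"]:
            return str(seg["domain"]), str(seg["contiguous"])
    return "unknown", "unknown"


_FEATURE_RE = re.compile(r"^Cas9_(\d+)_(.+)$")


def parent_class_of(slug: str, keywords: Mapping[str, str] | None = None) -> str:
    """Parent descriptor class for a descriptor slug, by longest keyword match."""
    table = keywords if keywords is not None else load_descriptor_keywords()
    best, best_len = None, -1
    for keyword, cls in table.items():
        if keyword in slug and len(keyword) > best_len:
            best, best_len = cls, len(keyword)
    if best is None:
        logger.warning("descriptor slug %r matches no known parent class", slug)
        return "unknown"
    return best


def parse_feature_name(
    name: str,
    keywords: Mapping[str, str] | None = None,
    domain_map: list[dict] | None = None,
) -> FeatureAnnotation:
    """Decode a feature name into its six interpretive properties.

    Example: ``Cas9_733_neighbours_side_chain_angle_3_VD`` annotates Cas9
    residue 733 (RuvC domain, contiguous RuvC-II segment), parent descriptor
    class SCO, descriptor class SCO-VD, aggregation VD.
    """
    match = _FEATURE_RE.match(name)
    if not match:
        raise ParseError(f"malformed feature name {name!r} (expected Cas9_<residue>_<slug>)")
    residue = int(match.group(1))
    slug = match.group(2)
    tokens = slug.split("_")
    aggregation = tokens[-1] if tokens[-1] in AGGREGATIONS else "none"
    bare = "_".join(tokens[:-1]) if aggregation != "none" else slug
    if not bare:
        raise ParseError(f"feature name {name!r} has an empty descriptor slug")
    parent = parent_class_of(bare, keywords)
    descriptor_class = f"{parent}-{aggregation}" if aggregation != "none" else parent
    domain, contiguous = domain_of(residue, domain_map)
    return FeatureAnnotation(
        feature_name=name,
        residue_number=residue,
        descriptor_class=descriptor_class,
        parent_descriptor_class=parent,
        aggregation=aggregation,
        cas9_domain=domain,
        contiguous_domain=contiguous,
    )


def feature_name(residue_number: int, descriptor: str) -> str:
    return f"Cas9_{int(residue_number)}_{descriptor}"


# ---------------------------------------------------------------------------
# mismatch metadata
# ---------------------------------------------------------------------------

_RNA_COMPLEMENT = {"A": "U", "T": "A", "G": "C", "C": "G"}
_MISMATCH_RE = re.compile(r"^([ACGT])(\d{1,2})([ACGT])$")


@dataclass(frozen=True)
class Mismatch:
    """A single target-strand DNA base substitution, e.g. ``T14G``.

    ``interface`` is the resulting guide-RNA : DNA base apposition in the
    conventional ``rX:dY`` notation (written ``X:dY``), where the guide base
    is the RNA complement of the original target-strand base.
    """

    position: int
    original_base: str
    mutated_base: str

    @property
    def guide_base(self) -> str:
        return _RNA_COMPLEMENT[self.original_base]

    @property
    def interface(self) -> str:
        return f"{self.guide_base}:d{self.mutated_base}"

    @property
    def code(self) -> str:
        return f"{self.original_base}{self.position}{self.mutated_base}"


def parse_mismatch_code(code: str) -> Mismatch:
    """Parse a mutation label like ``"T14G"`` (original base, heteroduplex
    position 1-20, substituted base on the target DNA strand)."""
    match = _MISMATCH_RE.match(code.strip().upper())
    if not match:
        raise ParseError(f"malformed mismatch code {code!r} (expected e.g. 'T14G')")
    original, position, mutated = match.group(1), int(match.group(2)), match.group(3)
    if not 1 <= position <= 20:
        raise ParseError(f"mismatch position must be 1-20, got {position}")
    if original == mutated:
        raise ParseError(f"mismatch code {code!r} does not change the base")
    return Mismatch(position, original, mutated)


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------

@dataclass
class NanoenvDataset:
    """Row-per-snapshot nanoenvironment feature matrix with labels.

    ``X`` is indexed by snapshot id with one column per retained feature;
    ``y`` holds the per-row activity label (identical within a trajectory);
    ``row_meta`` carries trajectory id, snapshot number, on-target flag and
    mismatch metadata; ``dropped_columns`` lists (residue, descriptor) columns
    removed for missing values.
    """

    X: pd.DataFrame
    y: pd.Series
    row_meta: pd.DataFrame
    annotations: dict[str, FeatureAnnotation] = field(default_factory=dict)
    dropped_columns: list[str] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return len(self.X)

    @property
    def n_features(self) -> int:
        return self.X.shape[1]

    def trajectory_ids(self) -> list[str]:
        return list(dict.fromkeys(self.row_meta["trajectory_id"]))

    def trajectory_activities(self) -> pd.Series:
        return self.y.groupby(self.row_meta["trajectory_id"], sort=False).first()

    def annotate(self, keywords=None, domain_map=None) -> None:
        """(Re)compute the six-property annotation of every feature column."""
        table = keywords if keywords is not None else load_descriptor_keywords()
        segs = domain_map if domain_map is not None else load_domain_map()
        self.annotations = {
            name: parse_feature_name(name, table, segs) for name in self.X.columns
        }


def _snapshot_number(snapshot_id: str) -> int:
    try:
        return parse_snapshot_id(snapshot_id).snapshot_number
    except ParseError:
        match = re.search(r"(\d+)$", snapshot_id)
        if not match:
            raise ParseError(
                f"cannot derive a snapshot number from id {snapshot_id!r}"
            ) from None
        return int(match.group(1))


def _trajectory_of(snapshot_id: str) -> str:
    try:
        return parse_snapshot_id(snapshot_id).trajectory_id
    except ParseError:
        match = re.search(r"(\d+)$", snapshot_id)
        if not match:
            raise ParseError(
                f"cannot derive a trajectory id from snapshot id {snapshot_id!r}"
            ) from None
        return snapshot_id[: match.start()]


def assemble_matrix(
    table: DescriptorTable,
    hpr: HPRSet,
    activities: Mapping[str, float],
    trajectory_of: Mapping[str, str] | None = None,
    trajectory_meta: pd.DataFrame | None = None,
    annotate: bool = False,
) -> NanoenvDataset:
    """Pivot a descriptor table over an HPR set into the labelled matrix.

    Columns are the (HPR residue x descriptor) pairs present in the table;
    any column with a missing value in at least one snapshot is dropped (and
    logged) rather than imputed.  Rows are ordered by (trajectory, snapshot
    number).  ``activities`` maps trajectory ids to cleavage activities;
    ``trajectory_of`` overrides the snapshot-id derived trajectory
    assignment; ``trajectory_meta`` (indexed by trajectory id) may supply
    ``on_target`` / ``mismatch_position`` / ``mismatch_type`` columns.
    """
    hpr_numbers = set(hpr.residue_numbers())
    records = table.records
    subset = records[records["residue"].isin(hpr_numbers)]
    if subset.empty:
        raise DataError("no descriptor record matches the HPR set")

    wide = subset.pivot_table(
        index="snapshot",
        columns=["residue", "descriptor"],
        values="value",
        aggfunc="first",
    )
    wide.columns = [feature_name(res, desc) for res, desc in wide.columns]
    dropped = sorted(wide.columns[wide.isna().any(axis=0)])
    if dropped:
        logger.info("dropping %d incomplete feature columns", len(dropped))
        wide = wide.drop(columns=dropped)

    snapshot_ids = list(wide.index)
    traj = {
        sid: (trajectory_of[sid] if trajectory_of is not None else _trajectory_of(sid))
        for sid in snapshot_ids
    }
    unlabelled = sorted({t for t in traj.values() if t not in activities})
    if unlabelled:
        raise DataError(f"no activity label for trajectories {unlabelled}")

    meta = pd.DataFrame(
        {
            "trajectory_id": [traj[sid] for sid in snapshot_ids],
            "snapshot_number": [_snapshot_number(sid) for sid in snapshot_ids],
        },
        index=pd.Index(snapshot_ids, name="snapshot"),
    )
    if trajectory_meta is not None:
        for col in ("on_target", "mismatch_position", "mismatch_type", "mismatch_code"):
            if col in trajectory_meta.columns:
                meta[col] = [trajectory_meta.loc[traj[sid], col] for sid in snapshot_ids]
    if "on_target" not in meta.columns:
        meta["on_target"] = False

    order = meta.sort_values(["trajectory_id", "snapshot_number"], kind="stable").index
    wide = wide.loc[order]
    meta = meta.loc[order]
    labels = pd.Series(
        [float(activities[traj[sid]]) for sid in order], index=order, name="activity"
    )
    dataset = NanoenvDataset(X=wide, y=labels, row_meta=meta, dropped_columns=dropped)
    if annotate:
        dataset.annotate()
    return dataset
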