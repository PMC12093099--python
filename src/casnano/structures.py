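"""Structure snapshots and the geometry of the sgRNA-tsDNA heteroduplex.

A *snapshot* is one conformation of an sgRNA-dsDNA-Cas9 complex: protein
residues reduced to their C-alpha atoms plus the 20 heteroduplex base pairs
reduced to their C4' pseudo-atoms.  Heteroduplex positions are numbered +1
(PAM-proximal) to +20 (PAM-distal).  From collections of snapshots this
module derives

* the heteroduplex-proximal residue (HPR) set -- residues whose C-alpha lies
  within 3-7 Angstrom (inclusive) of any heteroduplex C4' atom in at least
  one snapshot,
* per-snapshot C4'-C4' base-pair distances and per-trajectory plasticity
  sums,
* snapshot-averaged pairwise residue distance matrices,
* complete-linkage residue clusters (spatial hotspots) at a 12 Angstrom
  cutoff, and
* residue-base contact count matrices.

PDB input/output goes through :mod:`biotite`; only ATOM/HETATM records with
C-alpha / C4' atoms are interpreted.
"""

from __future__ import annotations

import io
import json
import logging
import re
import string
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, squareform
from scipy.stats import pearsonr, spearmanr

from .errors import ParseError, StructureError

logger = logging.getLogger(__name__)

SGRNA = "sgRNA"
TSDNA = "tsDNA"

#: default distance shell (Angstrom, inclusive) defining heteroduplex proximity
D_MIN_DEFAULT = 3.0
D_MAX_DEFAULT = 7.0

#: default complete-linkage cutoff (Angstrom) for residue hotspot clustering
CLUSTER_CUTOFF_DEFAULT = 12.0

_PURINES = {"A", "G", "DA", "DG"}
_PYRIMIDINES = {"C", "U", "T", "DC", "DT", "DU"}


# ---------------------------------------------------------------------------
# chain mapping and snapshot container
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChainMap:
    """Assignment of PDB chain identifiers to molecular roles.

    The default follows the convention protein = chain A, sgRNA = chain B,
    tsDNA = chain C.  ``sgrna_positions`` / ``tsdna_positions`` map author
    residue numbers to heteroduplex positions +1..+20; when ``None`` the
    residue number is taken as the position directly.
    """

    protein_chains: tuple[str, ...] = ("A",)
    sgrna_chain: str = "B"
    tsdna_chain: str = "C"
    sgrna_positions: Mapping[int, int] | None = None
    tsdna_positions: Mapping[int, int] | None = None
    ignore_chains: tuple[str, ...] = ()

    def role_of(self, chain_id: str) -> str | None:
        if chain_id in self.protein_chains:
            return "protein"
        if chain_id == self.sgrna_chain:
            return SGRNA
        if chain_id == self.tsdna_chain:
            return TSDNA
        if chain_id in self.ignore_chains:
            return "ignore"
        return None

    def position_of(self, strand: str, res_id: int) -> int:
        table = self.sgrna_positions if strand == SGRNA else self.tsdna_positions
        if table is None:
            return int(res_id)
        try:
            return int(table[res_id])
        except KeyError as exc:
            raise ParseError(
                f"residue number {res_id} of {strand} chain has no "
                f"heteroduplex position in the chain map"
            ) from exc


@dataclass
class Snapshot:
    """One structure frame: residue C-alphas plus heteroduplex C4' atoms.

    ``residue_index`` holds ``(chain, residue_number, residue_name)`` in the
    same order as the rows of ``ca_coords``; ``nucleotide_index`` holds
    ``(strand, position, base)`` aligned with ``c4_coords``.  ``atoms`` is an
    optional full-atom table (chain, res_id, res_name, atom_name, x, y, z)
    retained for atom-selection analyses such as RMSD series.
    """

    snapshot_id: str
    trajectory_id: str
    residue_index: list[tuple[str, int, str]]
    ca_coords: np.ndarray
    nucleotide_index: list[tuple[str, int, str]]
    c4_coords: np.ndarray
    atoms: pd.DataFrame | None = None

    def __post_init__(self) -> None:
        self.ca_coords = np.asarray(self.ca_coords, dtype=float)
        self.c4_coords = np.asarray(self.c4_coords, dtype=float)
        if not (np.isfinite(self.ca_coords).all() and np.isfinite(self.c4_coords).all()):
            raise StructureError(f"snapshot {self.snapshot_id}: non-finite coordinates")
        for strand in (SGRNA, TSDNA):
            positions = [p for s, p, _ in self.nucleotide_index if s == strand]
            if len(positions) != len(set(positions)):
                raise StructureError(
                    f"snapshot {self.snapshot_id}: duplicate {strand} positions"
                )

    # -- lookup helpers ----------------------------------------------------
    def residue_keys(self) -> list[tuple[str, int]]:
        return [(chain, num) for chain, num, _ in self.residue_index]

    def ca_of(self, chain: str, residue_number: int) -> np.ndarray:
        for i, (c, n, _) in enumerate(self.residue_index):
            if c == chain and n == residue_number:
                return self.ca_coords[i]
        raise StructureError(
            f"snapshot {self.snapshot_id}: residue {chain}{residue_number} absent"
        )

    def c4_of(self, strand: str, position: int) -> np.ndarray:
        for i, (s, p, _) in enumerate(self.nucleotide_index):
            if s == strand and p == position:
                return self.c4_coords[i]
        raise StructureError(
            f"snapshot {self.snapshot_id}: {strand} position {position:+d} absent"
        )

    def translated(self, vector: Sequence[float]) -> "Snapshot":
        """Rigidly translated copy (convenience for invariance checks)."""
        v = np.asarray(vector, dtype=float)
        return Snapshot(
            self.snapshot_id,
            self.trajectory_id,
            list(self.residue_index),
            self.ca_coords + v,
            list(self.nucleotide_index),
            self.c4_coords + v,
            atoms=None if self.atoms is None else self.atoms.assign(
                x=self.atoms["x"] + v[0], y=self.atoms["y"] + v[1], z=self.atoms["z"] + v[2]
            ),
        )


# ---------------------------------------------------------------------------
# snapshot identifiers
# ---------------------------------------------------------------------------

_MUTATION_ALPHABET = string.digits + string.ascii_uppercase


@dataclass(frozen=True)
class SnapshotID:
    """Four-character snapshot identifier.

    First character encodes the starting structure (C = cryo-derived,
    X = x-ray), the second the mutation (0-9 then A-Z in order), the last
    two digits the snapshot number along the trajectory.
    """

    start_structure: str
    mutation_code: str
    snapshot_number: int

    def __post_init__(self) -> None:
        if self.start_structure not in ("C", "X"):
            raise ParseError(f"start structure must be C or X, got {self.start_structure!r}")
        if self.mutation_code not in _MUTATION_ALPHABET:
            raise ParseError(f"mutation code must be 0-9 or A-Z, got {self.mutation_code!r}")
        if not 0 <= self.snapshot_number <= 99:
            raise ParseError(f"snapshot number must be two digits, got {self.snapshot_number}")

    def __str__(self) -> str:
        return f"{self.start_structure}{self.mutation_code}{self.snapshot_number:02d}"

    @property
    def trajectory_id(self) -> str:
        return f"{self.start_structure}{self.mutation_code}"


def parse_snapshot_id(s: str) -> SnapshotID:
    """Decode a four-character snapshot identifier such as ``"C101"``."""
    if len(s) != 4:
        raise ParseError(f"snapshot identifier must have 4 characters, got {s!r}")
    if s[0] not in ("C", "X"):
        raise ParseError(f"snapshot identifier must start with C or X, got {s!r}")
    if s[1] not in _MUTATION_ALPHABET:
        raise ParseError(f"invalid mutation code in snapshot identifier {s!r}")
    if not s[2:].isdigit():
        raise ParseError(f"snapshot number must be two digits in {s!r}")
    return SnapshotID(s[0], s[1], int(s[2:]))


# ---------------------------------------------------------------------------
# PDB parsing / writing
# ---------------------------------------------------------------------------

def _base_letter(res_name: str) -> str:
    name = res_name.strip().upper()
    return name[1:] if name.startswith("D") and len(name) == 2 else name


def parse_snapshot(
    pdb_text: str,
    chain_map: ChainMap | None = None,
    snapshot_id: str = "",
    trajectory_id: str = "",
    keep_atoms: bool = False,
) -> Snapshot:
    """Parse ATOM records of a PDB file into a :class:`Snapshot`.

    C-alpha atoms are taken from protein chains, C4' atoms from the sgRNA and
    tsDNA chains declared in ``chain_map``.  A declared residue lacking its
    required atom, or a chain absent from the chain map, raises
    :class:`~casnano.errors.ParseError`.  Alternate locations other than the
    first are discarded.
    """
    chain_map = chain_map or ChainMap()
    try:
        pdb = PDBFile.read(io.StringIO(pdb_text))
        atoms = pdb.get_structure(model=1, altloc="first")
    except Exception as exc:  # malformed records
        raise ParseError(f"cannot read PDB text: {exc}") from exc
    if atoms.array_length() == 0:
        raise ParseError("PDB text contains no ATOM records")

    residue_index: list[tuple[str, int, str]] = []
    ca: list[np.ndarray] = []
    nucleotide_index: list[tuple[str, int, str]] = []
    c4: list[np.ndarray] = []

    for chain_id in np.unique(atoms.chain_id):
        role = chain_map.role_of(str(chain_id))
        if role is None:
            raise ParseError(f"chain {chain_id!r} not declared in chain map")
        if role == "ignore":
            continue
        chain = atoms[atoms.chain_id == chain_id]
        for res_id in np.unique(chain.res_id):
            res = chain[chain.res_id == res_id]
            res_name = str(res.res_name[0]).strip()
            if role == "protein":
                sel = res.atom_name == "CA"
                if not sel.any():
                    raise ParseError(
                        f"protein residue {chain_id}{int(res_id)} ({res_name}) lacks a CA atom"
                    )
                residue_index.append((str(chain_id), int(res_id), res_name))
                ca.append(res.coord[sel][0])
            else:
                sel = res.atom_name == "C4'"
                if not sel.any():
                    raise ParseError(
                        f"nucleotide {chain_id}{int(res_id)} ({res_name}) lacks a C4' atom"
                    )
                position = chain_map.position_of(role, int(res_id))
                nucleotide_index.append((role, position, _base_letter(res_name)))
                c4.append(res.coord[sel][0])

    # stable (chain, residue number) ordering
    res_order = sorted(range(len(residue_index)), key=lambda i: residue_index[i][:2])
    nuc_order = sorted(range(len(nucleotide_index)), key=lambda i: nucleotide_index[i][:2])

    table = None
    if keep_atoms:
        table = pd.DataFrame(
            {
                "chain": atoms.chain_id.astype(str),
                "res_id": atoms.res_id.astype(int),
                "res_name": np.char.strip(atoms.res_name.astype(str)),
                "atom_name": np.char.strip(atoms.atom_name.astype(str)),
                "x": atoms.coord[:, 0],
                "y": atoms.coord[:, 1],
                "z": atoms.coord[:, 2],
            }
        )

    return Snapshot(
        snapshot_id=snapshot_id,
        trajectory_id=trajectory_id,
        residue_index=[residue_index[i] for i in res_order],
        ca_coords=np.array([ca[i] for i in res_order], dtype=float).reshape(-1, 3),
        nucleotide_index=[nucleotide_index[i] for i in nuc_order],
        c4_coords=np.array([c4[i] for i in nuc_order], dtype=float).reshape(-1, 3),
        atoms=table,
    )


_NUC_RES_NAME = {("sgRNA", "A"): "A", ("sgRNA", "C"): "C", ("sgRNA", "G"): "G",
                 ("sgRNA", "U"): "U", ("tsDNA", "A"): "DA", ("tsDNA", "C"): "DC",
                 ("tsDNA", "G"): "DG", ("tsDNA", "T"): "DT"}


def snapshot_to_pdb_text(snapshot: Snapshot, chain_map: ChainMap | None = None) -> str:
    """Serialize a snapshot to minimal PDB text (ATOM records only)."""
    chain_map = chain_map or ChainMap()
    n = len(snapshot.residue_index) + len(snapshot.nucleotide_index)
    arr = struc.AtomArray(n)
    i = 0
    for (chain, num, name), coord in zip(snapshot.residue_index, snapshot.ca_coords):
        arr.chain_id[i] = chain
        arr.res_id[i] = num
        arr.res_name[i] = name
        arr.atom_name[i] = "CA"
        arr.element[i] = "C"
        arr.coord[i] = coord
        i += 1
    for (strand, position, base), coord in zip(snapshot.nucleotide_index, snapshot.c4_coords):
        arr.chain_id[i] = chain_map.sgrna_chain if strand == SGRNA else chain_map.tsdna_chain
        arr.res_id[i] = position
        arr.res_name[i] = _NUC_RES_NAME.get((strand, base), base)
        arr.atom_name[i] = "C4'"
        arr.element[i] = "C"
        arr.coord[i] = coord
        i += 1
    arr.hetero[:] = False
    pdb = PDBFile()
    pdb.set_structure(arr)
    buf = io.StringIO()
    pdb.write(buf)
    return buf.getvalue()


# ---------------------------------------------------------------------------
# heteroduplex-proximal residues
# ---------------------------------------------------------------------------

@dataclass
class HPRSet:
    """Set of heteroduplex-proximal residues, sorted by residue number."""

    residues: tuple[tuple[str, int], ...]
    d_min: float = D_MIN_DEFAULT
    d_max: float = D_MAX_DEFAULT
    source_snapshot_ids: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.residues)

    def __contains__(self, key: object) -> bool:
        return key in self.residues

    def residue_numbers(self) -> list[int]:
        return [num for _, num in self.residues]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.residues, columns=["chain", "residue_number"])


def compute_hpr_set(
    snapshots: Iterable[Snapshot],
    d_min: float = D_MIN_DEFAULT,
    d_max: float = D_MAX_DEFAULT,
) -> HPRSet:
    """Residues whose C-alpha falls in [d_min, d_max] of any C4' atom in at
    least one of the given snapshots (bounds inclusive).

    Only training-partition snapshots should be passed here: the proximity
    shell is part of the learned representation and deriving it from test
    snapshots would leak information.
    """
    snapshots = list(snapshots)
    if not snapshots:
        raise StructureError("compute_hpr_set requires at least one snapshot")
    found: set[tuple[str, int]] = set()
    ids = []
    for snap in snapshots:
        ids.append(snap.snapshot_id)
        if len(snap.ca_coords) == 0 or len(snap.c4_coords) == 0:
            continue
        dists = cdist(snap.ca_coords, snap.c4_coords)
        in_shell = ((dists >= d_min) & (dists <= d_max)).any(axis=1)
        for idx in np.flatnonzero(in_shell):
            chain, num, _ = snap.residue_index[idx]
            found.add((chain, num))
    residues = tuple(sorted(found, key=lambda key: (key[1], key[0])))
    return HPRSet(residues, d_min, d_max, tuple(ids))


# ---------------------------------------------------------------------------
# base-pair geometry and plasticity
# ---------------------------------------------------------------------------

def basepair_distances(
    snapshot: Snapshot, positions: Sequence[int] = tuple(range(1, 20))
) -> np.ndarray:
    """C4'-C4' distance of each requested base pair (default +1..+19).

    Position +20 (the PAM-distal terminus) is excluded by default, matching
    the 19 PAM-proximal base pairs used in the plasticity analysis.
    """
    sg = {p: coord for (s, p, _), coord in zip(snapshot.nucleotide_index, snapshot.c4_coords)
          if s == SGRNA}
    ts = {p: coord for (s, p, _), coord in zip(snapshot.nucleotide_index, snapshot.c4_coords)
          if s == TSDNA}
    out = np.empty(len(positions), dtype=float)
    for i, p in enumerate(positions):
        if p not in sg or p not in ts:
            raise StructureError(
                f"snapshot {snapshot.snapshot_id}: base pair {p:+d} missing from one strand"
            )
        out[i] = float(np.linalg.norm(sg[p] - ts[p]))
    return out


def plasticity_sum(
    snapshots: Iterable[Snapshot], positions: Sequence[int] = tuple(range(1, 20))
) -> float:
    """Sum of the base-pair distances over all snapshots of a trajectory."""
    snapshots = list(snapshots)
    if not snapshots:
        raise StructureError("plasticity_sum requires at least one snapshot")
    return float(sum(basepair_distances(s, positions).sum() for s in snapshots))


def activity_group(activity: float, on_target: bool = False) -> str:
    """Bin a cleavage activity into on-target / low (<0.01) / medium
    (0.01-0.1) / high (>0.1)."""
    if on_target:
        return "on-target"
    if activity < 0.01:
        return "low"
    if activity <= 0.1:
        return "medium"
    return "high"


@dataclass
class Association:
    """Rank and linear association between plasticity sums and activity."""

    spearman: float
    pearson: float
    groups: list[str]
    defined: bool = True


def plasticity_activity_association(
    sums: Sequence[float],
    activities: Sequence[float],
    on_target: Sequence[bool] | None = None,
) -> Association:
    """Spearman (average ranks) and Pearson correlation between per-trajectory
    plasticity sums and cleavage activities, plus activity-group labels."""
    sums = np.asarray(sums, dtype=float)
    activities = np.asarray(activities, dtype=float)
    if len(sums) != len(activities) or len(sums) < 3:
        raise StructureError("association requires equal-length vectors of length >= 3")
    if on_target is None:
        on_target = [False] * len(sums)
    groups = [activity_group(a, flag) for a, flag in zip(activities, on_target)]
    if np.ptp(sums) == 0 or np.ptp(activities) == 0:
        logger.warning("constant input vector: correlation undefined")
        return Association(float("nan"), float("nan"), groups, defined=False)
    rho = float(spearmanr(sums, activities).statistic)
    r = float(pearsonr(sums, activities).statistic)
    return Association(rho, r, groups)


# ---------------------------------------------------------------------------
# residue distance matrices, clustering, contacts
# ---------------------------------------------------------------------------

def _normalize_residue_list(
    snapshots: Sequence[Snapshot], residue_list: Sequence
) -> list[tuple[str, int]]:
    default_chain = None
    for snap in snapshots:
        if snap.residue_index:
            default_chain = snap.residue_index[0][0]
            break
    out = []
    for item in residue_list:
        if isinstance(item, tuple):
            out.append((str(item[0]), int(item[1])))
        else:
            out.append((default_chain, int(item)))
    return out


def mean_pairwise_residue_distances(
    snapshots: Sequence[Snapshot], residue_list: Sequence
) -> pd.DataFrame:
    """C-alpha distance between every residue pair, averaged over snapshots.

    ``residue_list`` may contain residue numbers (first protein chain assumed)
    or ``(chain, residue_number)`` tuples.  Every residue must be present in
    every snapshot.
    """
    snapshots = list(snapshots)
    if not snapshots:
        raise StructureError("mean_pairwise_residue_distances requires snapshots")
    keys = _normalize_residue_list(snapshots, residue_list)
    acc = np.zeros((len(keys), len(keys)), dtype=float)
    for snap in snapshots:
        coords = np.array([snap.ca_of(chain, num) for chain, num in keys])
        acc += cdist(coords, coords)
    acc /= len(snapshots)
    labels = [num for _, num in keys]
    return pd.DataFrame(acc, index=labels, columns=labels)


@dataclass
class ResidueClustering:
    """Complete-linkage clusters of residues under a hard distance cutoff.

    ``clusters`` holds the multi-residue groups (ordered by smallest member);
    residues in no multi-residue group fall into ``singletons`` (the "other"
    group).  Within any cluster every pairwise mean distance is <= cutoff.
    """

    clusters: list[tuple[int, ...]]
    singletons: tuple[int, ...]
    cutoff: float
    mean_distance_matrix: pd.DataFrame

    def group_of(self, residue_number: int) -> str:
        for i, members in enumerate(self.clusters, start=1):
            if residue_number in members:
                return f"Group {i}"
        return "other"

    def groups(self) -> dict[str, tuple[int, ...]]:
        out = {f"Group {i}": members for i, members in enumerate(self.clusters, start=1)}
        if self.singletons:
            out["other"] = self.singletons
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "cutoff": self.cutoff,
                "clusters": [list(c) for c in self.clusters],
                "other": list(self.singletons),
            },
            indent=2,
            sort_keys=True,
        )


def cluster_residues(
    mean_distance_matrix: pd.DataFrame,
    cutoff: float = CLUSTER_CUTOFF_DEFAULT,
) -> ResidueClustering:
    """Agglomerative complete-linkage clustering cut at ``cutoff``.

    Complete linkage is used because the clustering constraint is a hard
    ceiling on the distance between *any* two residues sharing a cluster,
    which is exactly the complete-linkage merge criterion.
    """
    mat = np.asarray(mean_distance_matrix, dtype=float)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise StructureError("distance matrix must be square")
    if not np.allclose(mat, mat.T, atol=1e-8):
        raise StructureError("distance matrix must be symmetric")
    if not np.allclose(np.diag(mat), 0.0, atol=1e-8):
        raise StructureError("distance matrix must have a zero diagonal")
    labels = [int(x) for x in mean_distance_matrix.index]
    if len(labels) == 1:
        return ResidueClustering([], (labels[0],), cutoff, mean_distance_matrix)
    condensed = squareform(mat, checks=False)
    tree = linkage(condensed, method="complete")
    assignment = fcluster(tree, t=cutoff, criterion="distance")
    by_cluster: dict[int, list[int]] = {}
    for label, cid in zip(labels, assignment):
        by_cluster.setdefault(int(cid), []).append(label)
    multi = [tuple(sorted(m)) for m in by_cluster.values() if len(m) >= 2]
    multi.sort(key=lambda members: members[0])
    singles = tuple(sorted(m[0] for m in by_cluster.values() if len(m) == 1))
    return ResidueClustering(multi, singles, cutoff, mean_distance_matrix)


def contact_count_heatmap(
    snapshots: Sequence[Snapshot],
    residue_list: Sequence,
    base_list: Sequence[tuple[str, int]] | None = None,
    d_min: float = D_MIN_DEFAULT,
    d_max: float = D_MAX_DEFAULT,
) -> pd.DataFrame:
    """Count, per residue-base pair, the snapshots where the C-alpha lies in
    the [d_min, d_max] shell of the base's C4' atom.

    Rows are residue numbers; columns are ``(strand, position)`` pairs.
    """
    snapshots = list(snapshots)
    if not snapshots:
        raise StructureError("contact_count_heatmap requires snapshots")
    keys = _normalize_residue_list(snapshots, residue_list)
    if base_list is None:
        base_list = [(s, p) for s, p, _ in snapshots[0].nucleotide_index]
    counts = np.zeros((len(keys), len(base_list)), dtype=int)
    for snap in snapshots:
        res_coords = np.array([snap.ca_of(chain, num) for chain, num in keys])
        base_coords = np.array([snap.c4_of(strand, pos) for strand, pos in base_list])
        dists = cdist(res_coords, base_coords)
        counts += ((dists >= d_min) & (dists <= d_max)).astype(int)
    columns = pd.MultiIndex.from_tuples(base_list, names=["strand", "position"])
    return pd.DataFrame(counts, index=[num for _, num in keys], columns=columns)
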