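"""Per-site RMSD series along trajectories and mutant-vs-reference
stability comparison.

For each site of interest (a Cas9 residue or a heteroduplex base) the RMSD
of a configurable atom selection is computed against the first frame of the
trajectory, optionally after least-squares superposition of every frame onto
frame 1 using all protein C-alpha atoms.  The RMSD distributions of a mutant
trajectory and a reference (on-target) trajectory are then compared under a
normality assumption via the Kullback-Leibler divergence

    KL(N(mu1, sd1) || N(mu0, sd0))
        = ln(sd0/sd1) + (sd1^2 + (mu1 - mu0)^2) / (2 sd0^2) - 1/2,

and sites whose divergence exceeds a threshold are classified as more mobile
(mutant sd above reference sd) or more stable (below).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .errors import StructureError
from .structures import SGRNA, TSDNA, Snapshot, _PURINES

KL_THRESHOLD_DEFAULT = 0.25

#: atom-name selections per site kind; richer selections need a snapshot
#: parsed with ``keep_atoms=True`` so the full atom table is available
PROTEIN_SELECTIONS = {
    "calpha": ("CA",),
    "backbone": ("N", "CA", "C", "O"),
}
NUCLEIC_SELECTIONS = {
    "c4": ("C4'",),
    # nucleic backbone plus the ring anchors C4/N9 (purines), C6/N1 (pyrimidines)
    "backbone_ring": ("P", "O5'", "C5'", "C4'", "C3'", "O3'"),
    "p_anchor": ("P",),
}
_PURINE_ANCHORS = ("C4", "N9")
_PYRIMIDINE_ANCHORS = ("C6", "N1")


@dataclass
class RmsdSeries:
    """Per-frame RMSD (Angstrom) of one site versus the trajectory's first
    frame."""

    site: tuple
    atom_selection: str
    values: np.ndarray
    superposed: bool

    @property
    def mean(self) -> float:
        return float(np.mean(self.values))

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else 0.0


@dataclass
class StabilityComparison:
    """Mutant-versus-reference verdict for one site."""

    site: tuple
    kl_divergence: float
    delta_mean: float
    delta_sd: float
    verdict: str  # more_mobile | more_stable | similar


# ---------------------------------------------------------------------------
# coordinate extraction and superposition
# ---------------------------------------------------------------------------

def _site_coords(snap: Snapshot, site: tuple, atom_selection: str) -> np.ndarray:
    """Coordinates of the selected atoms of one site in one frame."""
    kind = site[0]
    if kind in (SGRNA, TSDNA):
        strand, position = site
        if atom_selection == "c4":
            return snap.c4_of(strand, position).reshape(1, 3)
        if snap.atoms is None:
            raise StructureError(
                f"selection {atom_selection!r} needs the full atom table "
                f"(parse with keep_atoms=True)"
            )
        base = next(
            (b for s, p, b in snap.nucleotide_index if s == strand and p == position), None
        )
        if base is None:
            raise StructureError(f"{strand} position {position:+d} absent "
                                 f"in frame {snap.snapshot_id}")
        anchors = _PURINE_ANCHORS if base in _PURINES else _PYRIMIDINE_ANCHORS
        if atom_selection == "backbone_ring":
            names = NUCLEIC_SELECTIONS["backbone_ring"] + anchors
        elif atom_selection == "p_anchor":
            names = ("P", anchors[1])  # phosphorus plus N9 / N1
        else:
            raise StructureError(f"unknown nucleic atom selection {atom_selection!r}")
        table = snap.atoms
        rows = table[(table["res_id"] == position) & (table["atom_name"].isin(names))]
        if rows.empty:
            raise StructureError(
                f"frame {snap.snapshot_id}: no atoms {names} for {strand} "
                f"position {position:+d}"
            )
        return rows[["x", "y", "z"]].to_numpy(dtype=float)
    # protein site: (chain, residue_number)
    chain, residue = site
    if atom_selection == "calpha":
        return snap.ca_of(chain, residue).reshape(1, 3)
    if atom_selection not in PROTEIN_SELECTIONS:
        raise StructureError(f"unknown protein atom selection {atom_selection!r}")
    if snap.atoms is None:
        raise StructureError(
            f"selection {atom_selection!r} needs the full atom table "
            f"(parse with keep_atoms=True)"
        )
    names = PROTEIN_SELECTIONS[atom_selection]
    table = snap.atoms
    rows = table[(table["chain"] == chain) & (table["res_id"] == residue)
                 & (table["atom_name"].isin(names))]
    missing = set(names) - set(rows["atom_name"])
    if missing:
        raise StructureError(
            f"frame {snap.snapshot_id}: residue {chain}{residue} lacks atoms {sorted(missing)}"
        )
    return rows[["x", "y", "z"]].to_numpy(dtype=float)


def _superposition(mobile: np.ndarray, target: np.ndarray):
    """Least-squares rigid transform (rotation + translation) taking
    ``mobile`` onto ``target``; both are all-protein C-alpha sets."""
    mob_center = mobile.mean(axis=0)
    tgt_center = target.mean(axis=0)
    rotation, _ = Rotation.align_vectors(target - tgt_center, mobile - mob_center)
    return rotation, mob_center, tgt_center


def rmsd_series(
    frames: Sequence[Snapshot],
    site: tuple,
    atom_selection: str = "calpha",
    superpose: bool = True,
) -> RmsdSeries:
    """RMSD of a site's selected atoms in every frame versus frame 1.

    With ``superpose=True`` each frame is first rigidly superposed onto the
    first frame by least squares over all protein C-alpha atoms, so the
    series reflects internal motion rather than global drift.
    """
    frames = list(frames)
    if not frames:
        raise StructureError("rmsd_series requires at least one frame")
    ref_site = _site_coords(frames[0], site, atom_selection)
    ref_ca = frames[0].ca_coords
    values = np.zeros(len(frames))
    for i, snap in enumerate(frames):
        coords = _site_coords(snap, site, atom_selection)
        if coords.shape != ref_site.shape:
            raise StructureError(
                f"frame {snap.snapshot_id}: atom count changed for site {site}"
            )
        if superpose and i > 0:
            if snap.ca_coords.shape != ref_ca.shape:
                raise StructureError(
                    f"frame {snap.snapshot_id}: protein C-alpha count differs from frame 1"
                )
            rotation, mob_center, tgt_center = _superposition(snap.ca_coords, ref_ca)
            coords = rotation.apply(coords - mob_center) + tgt_center
        values[i] = math.sqrt(float(np.mean(np.sum((coords - ref_site) ** 2, axis=1))))
    return RmsdSeries(site, atom_selection, values, superpose)


# ---------------------------------------------------------------------------
# Gaussian KL and mobility classification
# ---------------------------------------------------------------------------

def gaussian_kl(mu1: float, sd1: float, mu0: float, sd0: float) -> float:
    """KL(N(mu1, sd1) || N(mu0, sd0)) in closed form; note the asymmetry."""
    if sd1 <= 0 or sd0 <= 0:
        raise StructureError("gaussian_kl requires strictly positive standard deviations")
    return float(
        math.log(sd0 / sd1) + (sd1**2 + (mu1 - mu0) ** 2) / (2 * sd0**2) - 0.5
    )


def classify_mobility(
    mutant: RmsdSeries,
    reference: RmsdSeries,
    kl_threshold: float = KL_THRESHOLD_DEFAULT,
) -> StabilityComparison:
    """Compare a mutant site's RMSD distribution against the reference.

    The divergence is computed from the sample means and sds (n-1
    denominator) under normality.  Below ``kl_threshold`` the site is
    ``similar``; otherwise the sd comparison decides ``more_mobile`` (mutant
    sd larger) versus ``more_stable``.
    """
    if len(mutant.values) < 3 or len(reference.values) < 3:
        raise StructureError("classify_mobility requires series of length >= 3")
    if mutant.sd == 0 or reference.sd == 0:
        raise StructureError("degenerate (zero-variance) RMSD distribution")
    kl = gaussian_kl(mutant.mean, mutant.sd, reference.mean, reference.sd)
    if kl < kl_threshold:
        verdict = "similar"
    elif mutant.sd > reference.sd:
        verdict = "more_mobile"
    else:
        verdict = "more_stable"
    return StabilityComparison(
        mutant.site, kl, mutant.mean - reference.mean, mutant.sd - reference.sd, verdict
    )


def stability_table(
    trajectories: Mapping[str, Sequence[Snapshot]],
    reference_id: str,
    sites: Sequence[tuple],
    atom_selection: str = "calpha",
    superpose: bool = True,
    kl_threshold: float = KL_THRESHOLD_DEFAULT,
) -> pd.DataFrame:
    """Per-(trajectory, site) stability comparison against the reference
    trajectory; one row per mutant trajectory and site."""
    if reference_id not in trajectories:
        raise StructureError(f"reference trajectory {reference_id!r} not supplied")
    reference_series = {
        site: rmsd_series(trajectories[reference_id], site, atom_selection, superpose)
        for site in sites
    }
    rows = []
    for traj_id, frames in trajectories.items():
        if traj_id == reference_id:
            continue
        for site in sites:
            mutant = rmsd_series(frames, site, atom_selection, superpose)
            comparison = classify_mobility(mutant, reference_series[site], kl_threshold)
            rows.append(
                (traj_id, str(site), mutant.mean, mutant.sd,
                 comparison.kl_divergence, comparison.delta_mean,
                 comparison.delta_sd, comparison.verdict)
            )
    return pd.DataFrame(
        rows,
        columns=["trajectory", "site", "rmsd_mean", "rmsd_sd", "kl_divergence",
                 "delta_mean", "delta_sd", "verdict"],
    )
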