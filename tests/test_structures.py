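"""Geometry: parsing, proximity shells, plasticity, clustering, contacts."""

import numpy as np
import pandas as pd
import pytest

from casnano import structures
from casnano.errors import ParseError, StructureError
from casnano.structures import (
    SGRNA,
    TSDNA,
    Snapshot,
    basepair_distances,
    cluster_residues,
    compute_hpr_set,
    contact_count_heatmap,
    mean_pairwise_residue_distances,
    parse_snapshot,
    parse_snapshot_id,
    plasticity_activity_association,
    plasticity_sum,
    snapshot_to_pdb_text,
)

from conftest import make_snapshot


# ---------------------------------------------------------------------------
# PDB parsing
# ---------------------------------------------------------------------------

HAND_PDB = "\n".join([
    "ATOM      1  CA  ALA A   1      11.000  22.000  33.000  1.00  0.00           C  ",
    "ATOM      2  CA  GLY A   2       1.500  -2.250   0.125  1.00  0.00           C  ",
    "ATOM      3  CA  SER A   3       0.000   0.000   9.000  1.00  0.00           C  ",
    "ATOM      4  C4'   U B   1       4.000   5.000   6.000  1.00  0.00           C  ",
    "ATOM      5  C4'  DA C   1       7.000   8.000   9.000  1.00  0.00           C  ",
]) + "\n"


def test_hand_written_pdb_fields_are_extracted_literally():
    snap = parse_snapshot(HAND_PDB, snapshot_id="C001", trajectory_id="C0")
    assert snap.residue_index == [("A", 1, "ALA"), ("A", 2, "GLY"), ("A", 3, "SER")]
    np.testing.assert_allclose(snap.ca_coords[0], [11.0, 22.0, 33.0])
    np.testing.assert_allclose(snap.ca_coords[1], [1.5, -2.25, 0.125])
    assert snap.nucleotide_index == [(SGRNA, 1, "U"), (TSDNA, 1, "A")]
    np.testing.assert_allclose(snap.c4_of(SGRNA, 1), [4.0, 5.0, 6.0])
    np.testing.assert_allclose(snap.c4_of(TSDNA, 1), [7.0, 8.0, 9.0])


def test_writer_reader_round_trip(small_data):
    snap = next(iter(small_data.snapshots.values()))[0]
    back = parse_snapshot(snapshot_to_pdb_text(snap), snapshot_id=snap.snapshot_id)
    # PDB coordinate fields carry three decimals
    np.testing.assert_allclose(back.ca_coords, snap.ca_coords, atol=1e-3)
    np.testing.assert_allclose(back.c4_coords, snap.c4_coords, atol=1e-3)
    assert back.residue_index == snap.residue_index
    assert back.nucleotide_index == snap.nucleotide_index


def test_protein_residue_without_ca_names_the_residue():
    text = "ATOM      1  CB  ALA A   7      1.000   2.000   3.000  1.00  0.00           C  \n"
    with pytest.raises(ParseError, match="A7"):
        parse_snapshot(text)


def test_unknown_chain_is_a_parse_error():
    text = "ATOM      1  CA  ALA Z   1      1.000   2.000   3.000  1.00  0.00           C  \n"
    with pytest.raises(ParseError, match="chain"):
        parse_snapshot(text)


# ---------------------------------------------------------------------------
# snapshot identifiers
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "text,start,code,number",
    [("C101", "C", "1", 1), ("XA23", "X", "A", 23), ("C024", "C", "0", 24)],
)
def test_snapshot_id_round_trip(text, start, code, number):
    sid = parse_snapshot_id(text)
    assert (sid.start_structure, sid.mutation_code, sid.snapshot_number) == (
        start, code, number)
    assert str(sid) == text


@pytest.mark.parametrize("bad", ["5F9R", "C1", "Ca01", "C1XX", "c101"])
def test_snapshot_id_rejects_malformed_codes(bad):
    with pytest.raises(ParseError):
        parse_snapshot_id(bad)


# ---------------------------------------------------------------------------
# HPR extraction
# ---------------------------------------------------------------------------

def test_hpr_selects_only_the_shell_residue():
    snap = make_snapshot([(2.5, 0, 0), (5.0, 0, 0), (8.0, 0, 0)])
    hpr = compute_hpr_set([snap])
    assert hpr.residues == (("A", 2),)  # only the residue at 5.0 A


@pytest.mark.parametrize("distance,included", [(3.0, True), (7.0, True),
                                               (2.999, False), (7.001, False)])
def test_hpr_shell_bounds_are_inclusive(distance, included):
    snap = make_snapshot([(distance, 0, 0)])
    hpr = compute_hpr_set([snap])
    assert (("A", 1) in hpr) is included


def _brute_force_hpr(snapshots, d_min=3.0, d_max=7.0):
    found = set()
    for snap in snapshots:
        for i, (chain, num, _) in enumerate(snap.residue_index):
            for j in range(len(snap.c4_coords)):
                d = float(np.linalg.norm(snap.ca_coords[i] - snap.c4_coords[j]))
                if d_min <= d <= d_max:
                    found.add((chain, num))
    return tuple(sorted(found, key=lambda k: (k[1], k[0])))


@pytest.mark.parametrize("seed", [0, 1, 2, 3])
def test_hpr_agrees_with_brute_force_double_loop(seed):
    rng = np.random.default_rng(seed)
    snaps = []
    for k in range(3):
        nucs = {(SGRNA, p): rng.uniform(-5, 5, 3) for p in range(1, 4)}
        snaps.append(make_snapshot(rng.uniform(-12, 12, (25, 3)), nucs,
                                   snapshot_id=f"C0{k:02d}"))
    assert compute_hpr_set(snaps).residues == _brute_force_hpr(snaps)


def test_hpr_is_monotone_in_snapshots():
    rng = np.random.default_rng(7)
    snaps = [make_snapshot(rng.uniform(-10, 10, (15, 3))) for _ in range(4)]
    small = set(compute_hpr_set(snaps[:2]).residues)
    large = set(compute_hpr_set(snaps).residues)
    assert small <= large


def test_hpr_requires_snapshots():
    with pytest.raises(StructureError):
        compute_hpr_set([])


# ---------------------------------------------------------------------------
# base-pair distances and plasticity
# ---------------------------------------------------------------------------

def _ladder_snapshot(separation=5.0, n=19, sid="C001"):
    nucs = {}
    for p in range(1, n + 1):
        nucs[(SGRNA, p)] = (5.0 * p, 0.0, 0.0)
        nucs[(TSDNA, p)] = (5.0 * p, separation, 0.0)
    return make_snapshot([(0, 50, 0)], nucs, snapshot_id=sid)


def test_basepair_distance_pythagoras():
    nucs = {(SGRNA, 1): (0, 0, 0), (TSDNA, 1): (3, 4, 0)}
    snap = make_snapshot([(0, 50, 0)], nucs)
    np.testing.assert_allclose(basepair_distances(snap, positions=[1]), [5.0])


def test_basepair_distance_coincident_atoms_is_zero():
    nucs = {(SGRNA, 1): (1, 2, 3), (TSDNA, 1): (1, 2, 3)}
    snap = make_snapshot([(0, 50, 0)], nucs)
    np.testing.assert_allclose(basepair_distances(snap, positions=[1]), [0.0])


def test_basepair_distances_invariant_under_translation():
    snap = _ladder_snapshot()
    moved = snap.translated([3.0, -7.0, 11.0])
    np.testing.assert_allclose(basepair_distances(moved), basepair_distances(snap))


def test_basepair_distance_missing_position_names_it():
    snap = _ladder_snapshot(n=5)
    with pytest.raises(StructureError, match=r"\+9"):
        basepair_distances(snap, positions=[9])


def test_plasticity_sum_two_uniform_snapshots():
    snaps = [_ladder_snapshot(sid="C001"), _ladder_snapshot(sid="C002")]
    assert plasticity_sum(snaps) == pytest.approx(2 * 19 * 5.0)


def test_plasticity_sum_single_snapshot_equals_own_sum():
    snap = _ladder_snapshot(separation=3.5)
    assert plasticity_sum([snap]) == pytest.approx(basepair_distances(snap).sum())


def _rank(values):
    values = np.asarray(values, dtype=float)
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    i = 0
    sorted_vals = values[order]
    while i < len(values):
        j = i
        while j < len(values) and sorted_vals[j] == sorted_vals[i]:
            j += 1
        ranks[order[i:j]] = (i + j + 1) / 2  # average rank, 1-based
        i = j
    return ranks


def test_association_identity_and_reverse():
    sums = [1.0, 2.0, 3.0, 4.0]
    assert plasticity_activity_association(sums, sums).spearman == pytest.approx(1.0)
    rev = plasticity_activity_association(sums, sums[::-1])
    assert rev.spearman == pytest.approx(-1.0)


def test_association_matches_rank_formula_oracle():
    sums = [12.0, 7.0, 31.0, 18.0, 18.0]
    acts = [0.02, 0.005, 0.4, 0.09, 0.11]
    out = plasticity_activity_association(sums, acts)
    rx, ry = _rank(sums), _rank(acts)
    oracle = np.corrcoef(rx, ry)[0, 1]
    assert out.spearman == pytest.approx(oracle, abs=1e-12)
    assert out.pearson == pytest.approx(np.corrcoef(sums, acts)[0, 1], abs=1e-12)
    assert out.groups == ["medium", "low", "high", "medium", "high"]


def test_association_constant_vector_is_undefined():
    out = plasticity_activity_association([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])
    assert not out.defined and np.isnan(out.spearman)


# ---------------------------------------------------------------------------
# residue distance matrices and clustering
# ---------------------------------------------------------------------------

def test_mean_pairwise_distances_average_and_symmetry():
    s1 = make_snapshot([(0, 0, 0), (4, 0, 0)])
    s2 = make_snapshot([(0, 0, 0), (6, 0, 0)], snapshot_id="C002")
    mat = mean_pairwise_residue_distances([s1, s2], [1, 2])
    assert mat.loc[1, 2] == pytest.approx(5.0)
    assert mat.loc[2, 1] == pytest.approx(5.0)
    assert mat.loc[1, 1] == 0.0


def test_mean_pairwise_distance_single_snapshot_is_plain_matrix():
    s1 = make_snapshot([(0, 0, 0), (3, 4, 0)])
    mat = mean_pairwise_residue_distances([s1], [1, 2])
    assert mat.loc[1, 2] == pytest.approx(5.0)


def test_mean_pairwise_distance_missing_residue_errors():
    s1 = make_snapshot([(0, 0, 0)])
    with pytest.raises(StructureError):
        mean_pairwise_residue_distances([s1], [1, 99])


def test_cluster_two_close_residues_merge():
    mat = pd.DataFrame([[0.0, 5.0], [5.0, 0.0]], index=[10, 11], columns=[10, 11])
    out = cluster_residues(mat)
    assert out.clusters == [(10, 11)] and out.singletons == ()


def test_cluster_complete_linkage_hand_trace():
    # AB=10, BC=10, AC=13: complete linkage refuses the 13 A pair at cutoff 12
    mat = pd.DataFrame(
        [[0, 10, 13], [10, 0, 10], [13, 10, 0]],
        index=[1, 2, 3], columns=[1, 2, 3], dtype=float,
    )
    out = cluster_residues(mat, cutoff=12.0)
    assert out.clusters == [(1, 2)]
    assert out.singletons == (3,)


@pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
def test_cluster_invariant_no_intra_pair_exceeds_cutoff(seed):
    rng = np.random.default_rng(seed)
    points = rng.uniform(0, 40, (12, 3))
    mat = np.linalg.norm(points[:, None] - points[None, :], axis=2)
    frame = pd.DataFrame(mat, index=range(1, 13), columns=range(1, 13))
    out = cluster_residues(frame, cutoff=12.0)
    members = list(out.clusters) + [(s,) for s in out.singletons]
    flattened = sorted(r for m in members for r in m)
    assert flattened == list(range(1, 13))  # partition
    for cluster in out.clusters:
        for a in cluster:
            for b in cluster:
                assert frame.loc[a, b] <= 12.0


def test_cluster_rejects_asymmetric_matrix():
    mat = pd.DataFrame([[0.0, 1.0], [2.0, 0.0]], index=[1, 2], columns=[1, 2])
    with pytest.raises(StructureError):
        cluster_residues(mat)


# ---------------------------------------------------------------------------
# contact counts
# ---------------------------------------------------------------------------

def test_contact_counts_zero_when_all_far():
    snaps = [make_snapshot([(20, 0, 0), (0, 30, 0)], snapshot_id=f"C0{k:02d}")
             for k in range(3)]
    mat = contact_count_heatmap(snaps, [1, 2])
    assert (mat.to_numpy() == 0).all()


def test_contact_counts_fixed_contact_counts_all_snapshots():
    snaps = [make_snapshot([(5, 0, 0)], snapshot_id=f"C0{k:02d}") for k in range(10)]
    mat = contact_count_heatmap(snaps, [1])
    assert mat.loc[1, (SGRNA, 1)] == 10


def test_contact_counts_bounded_by_snapshot_count(small_data):
    frames = next(iter(small_data.snapshots.values()))
    residues = [num for _, num, _ in frames[0].residue_index][:6]
    mat = contact_count_heatmap(frames, residues)
    assert mat.to_numpy().max() <= len(frames)
    assert mat.to_numpy().min() >= 0
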