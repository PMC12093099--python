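"""Descriptor tables, feature-name annotation, matrix assembly."""

import numpy as np
import pandas as pd
import pytest

from casnano import nanoenv
from casnano.errors import DataError, ParseError
from casnano.nanoenv import (
    DescriptorTable,
    assemble_matrix,
    feature_name,
    parse_descriptor_tsv,
    parse_feature_name,
    parse_mismatch_code,
)
from casnano.structures import HPRSet

TSV = (
    "snapshot\tresidue\tdescriptor\tvalue\n"
    "C001\t10\tdensity_3_SW\t1.25\n"
    "C001\t11\tdensity_3_SW\t-0.5\n"
    "C002\t10\tdensity_3_SW\t2.0\n"
    "C002\t11\tdensity_3_SW\t0.75\n"
)


def _table(n_res=2, n_desc=3, snapshots=("C001", "C002", "C003", "C004")):
    rows = []
    for sid in snapshots:
        for res in range(10, 10 + n_res):
            for d in range(n_desc):
                rows.append((sid, res, f"density_{d}_SW", float(res * 10 + d)))
    return DescriptorTable(
        pd.DataFrame(rows, columns=["snapshot", "residue", "descriptor", "value"])
    )


def _hpr(residues):
    return HPRSet(tuple(("A", r) for r in sorted(residues)))


# ---------------------------------------------------------------------------
# TSV parsing
# ---------------------------------------------------------------------------

def test_parse_tsv_exact_values():
    table = parse_descriptor_tsv(TSV)
    assert len(table) == 4
    assert table.records["value"].tolist() == [1.25, -0.5, 2.0, 0.75]
    assert table.residues == [10, 11]


def test_parse_tsv_duplicate_record_names_the_key():
    bad = TSV + "C002\t11\tdensity_3_SW\t9.0\n"
    with pytest.raises(DataError, match="C002.*11.*density_3_SW"):
        parse_descriptor_tsv(bad)


def test_parse_tsv_non_numeric_value_reports_line_number():
    bad = TSV.replace("2.0", "oops")
    with pytest.raises(ParseError, match="line 4"):
        parse_descriptor_tsv(bad)


def test_parse_tsv_column_adapter_reorders():
    shuffled = (
        "val\tres\tsnap\tdesc\n"
        "1.5\t10\tC001\tdensity_3_SW\n"
    )
    table = parse_descriptor_tsv(shuffled, columns=("snap", "res", "desc", "val"))
    assert table.records.iloc[0]["value"] == 1.5
    assert table.records.iloc[0]["snapshot"] == "C001"


# ---------------------------------------------------------------------------
# feature names
# ---------------------------------------------------------------------------

def test_feature_annotation_of_the_flagship_side_chain_feature():
    ann = parse_feature_name("Cas9_733_neighbours_side_chain_angle_3_VD")
    assert ann.residue_number == 733
    assert ann.aggregation == "VD"
    assert ann.parent_descriptor_class == "SCO"
    assert ann.descriptor_class == "SCO-VD"
    assert ann.cas9_domain == "RuvC"
    assert ann.contiguous_domain == "RuvC-II"


def test_feature_annotation_of_a_plain_parent_class_feature():
    ann = parse_feature_name("Cas9_100_accessibility")
    assert ann.residue_number == 100
    assert ann.aggregation == "none"
    assert ann.parent_descriptor_class == "Accessibility"
    assert ann.descriptor_class == "Accessibility"
    assert ann.cas9_domain == "REC"


@pytest.mark.parametrize("residue,domain,contiguous", [
    (837, "HNH", "HNH"), (1016, "RuvC", "RuvC-III"), (136, "REC", "REC-I"),
    (402, "REC", "REC-I"), (250, "REC", "REC-II"), (1200, "PI", "PI"),
])
def test_domain_map_covers_the_hotspot_residues(residue, domain, contiguous):
    ann = parse_feature_name(feature_name(residue, "density_3_SW"))
    assert (ann.cas9_domain, ann.contiguous_domain) == (domain, contiguous)


def test_malformed_feature_name_is_rejected():
    with pytest.raises(ParseError):
        parse_feature_name("733_foo")


def test_unknown_slug_annotates_as_unknown_class():
    ann = parse_feature_name("Cas9_5_mystery_metric")
    assert ann.parent_descriptor_class == "unknown"


# ---------------------------------------------------------------------------
# mismatch metadata
# ---------------------------------------------------------------------------

def test_mismatch_code_parses_and_derives_interface():
    mm = parse_mismatch_code("T14G")
    assert (mm.position, mm.original_base, mm.mutated_base) == (14, "T", "G")
    assert mm.guide_base == "A"
    assert mm.interface == "A:dG"
    assert mm.code == "T14G"


@pytest.mark.parametrize("bad", ["T14T", "X14G", "T99G", "14G", "T0G"])
def test_mismatch_code_rejects_malformed(bad):
    with pytest.raises(ParseError):
        parse_mismatch_code(bad)


# ---------------------------------------------------------------------------
# matrix assembly
# ---------------------------------------------------------------------------

LABELS = {"C0": 0.3}


def test_assembly_cardinality_product():
    ds = assemble_matrix(_table(), _hpr([10, 11]), LABELS)
    assert ds.X.shape == (4, 6)
    assert (ds.y == 0.3).all()


def test_assembly_drops_the_incomplete_column():
    table = _table()
    records = table.records
    mask = ~((records["snapshot"] == "C002") & (records["residue"] == 10)
             & (records["descriptor"] == "density_1_SW"))
    ds = assemble_matrix(DescriptorTable(records[mask]), _hpr([10, 11]), LABELS)
    assert ds.X.shape == (4, 5)
    assert ds.dropped_columns == ["Cas9_10_density_1_SW"]


def test_assembly_restricts_columns_to_the_hpr_set():
    ds = assemble_matrix(_table(), _hpr([10]), LABELS)
    assert ds.X.shape == (4, 3)
    assert all(name.startswith("Cas9_10_") for name in ds.X.columns)


def test_assembly_without_label_is_an_error():
    with pytest.raises(DataError, match="C0"):
        assemble_matrix(_table(), _hpr([10, 11]), {"WRONG": 1.0})


def test_assembly_empty_hpr_intersection_is_an_error():
    with pytest.raises(DataError):
        assemble_matrix(_table(), _hpr([999]), LABELS)


def test_assembly_is_permutation_invariant_in_record_order():
    table = _table()
    shuffled = DescriptorTable(
        table.records.sample(frac=1.0, random_state=3).reset_index(drop=True)
    )
    a = assemble_matrix(table, _hpr([10, 11]), LABELS)
    b = assemble_matrix(shuffled, _hpr([10, 11]), LABELS)
    pd.testing.assert_frame_equal(a.X, b.X)


def test_assembly_orders_rows_by_trajectory_then_snapshot(small_dataset):
    meta = small_dataset.row_meta
    for _, group in meta.groupby("trajectory_id", sort=False):
        assert group["snapshot_number"].is_monotonic_increasing
    trajectories = meta["trajectory_id"].tolist()
    assert trajectories == sorted(trajectories)


def test_every_assembled_feature_name_round_trips(small_dataset):
    for name in small_dataset.X.columns:
        ann = parse_feature_name(name)
        assert feature_name(ann.residue_number, name.split(f"Cas9_{ann.residue_number}_")[1]) == name
        assert name in small_dataset.annotations
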