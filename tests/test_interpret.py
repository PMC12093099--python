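"""Shapley attributions: oracles, additivity, grouped importances."""

import numpy as np
import pandas as pd
import pytest
from lightgbm import LGBMRegressor
from sklearn.ensemble import ExtraTreesRegressor
from sklearn.linear_model import LinearRegression
from xgboost import XGBRegressor

from casnano import interpret
from casnano.errors import DataError
from casnano.interpret import (
    ShapReport,
    brute_force_shap,
    group_importance,
    hotspot_report,
    shap_values,
    singleton_importance,
)
from casnano.nanoenv import parse_feature_name
from casnano.pipeline import StingCrisprModel
from casnano.structures import ResidueClustering


def _wrap(regressor, n_features, names=None):
    names = names or [f"Cas9_{i+1}_density_3_SW" for i in range(n_features)]
    return StingCrisprModel(names, np.zeros(n_features), np.ones(n_features),
                            regressor, type(regressor).__name__)


def _frame(Z, names):
    return pd.DataFrame(Z, columns=names)


# ---------------------------------------------------------------------------
# back-ends versus the subset-enumeration oracle
# ---------------------------------------------------------------------------

def test_linear_closed_form_matches_brute_force():
    rng = np.random.default_rng(0)
    Z = rng.normal(size=(16, 3))
    y = Z @ np.array([1.5, -2.0, 0.5]) + 0.3
    reg = LinearRegression().fit(Z, y)
    model = _wrap(reg, 3)
    report = shap_values(model, _frame(Z, model.feature_names))
    assert report.method == "linear"
    for i in range(4):
        phi, base = brute_force_shap(reg.predict, Z[i], np.zeros(3))
        np.testing.assert_allclose(report.phi.iloc[i].to_numpy(), phi, atol=1e-10)
        assert report.base_value == pytest.approx(base)


def test_permutation_estimator_is_exact_for_small_f():
    rng = np.random.default_rng(1)
    Z = rng.normal(size=(40, 3))
    y = np.sin(Z[:, 0]) + Z[:, 1] * Z[:, 2]
    reg = ExtraTreesRegressor(n_estimators=20, random_state=0).fit(Z, y)
    model = _wrap(reg, 3)
    report = shap_values(model, _frame(Z[:8], model.feature_names), seed=0)
    assert report.method == "permutation"  # 3! = 6 permutations, enumerated
    for i in range(8):
        phi, base = brute_force_shap(reg.predict, Z[i], np.zeros(3))
        np.testing.assert_allclose(report.phi.iloc[i].to_numpy(), phi, atol=1e-10)


@pytest.mark.parametrize("factory,method", [
    (lambda: XGBRegressor(n_estimators=20, max_depth=1, random_state=0,
                          base_score=0.5, n_jobs=1, verbosity=0), "tree-xgboost"),
    (lambda: LGBMRegressor(n_estimators=30, random_state=0, n_jobs=1,
                           verbose=-1, min_child_samples=5), "tree-lightgbm"),
])
def test_native_tree_contributions_single_feature(factory, method):
    """For a single-feature model, the tree Shapley value of each point must
    equal its prediction minus the cover-weighted mean prediction."""
    rng = np.random.default_rng(2)
    Z = rng.normal(size=(200, 1))
    y = np.where(Z[:, 0] > 0, 1.0, 0.0) + rng.normal(0, 0.01, 200)
    reg = factory().fit(Z, y)
    model = _wrap(reg, 1)
    report = shap_values(model, _frame(Z, model.feature_names))
    assert report.method == method
    pred = np.asarray(reg.predict(Z), dtype=float)
    np.testing.assert_allclose(report.phi.to_numpy()[:, 0],
                               pred - report.base_value, atol=1e-4)
    # the base value is the training-distribution mean prediction
    assert report.base_value == pytest.approx(pred.mean(), abs=0.05)


def test_constant_model_has_zero_attributions():
    class Constant:
        def predict(self, Z):
            return np.full(len(Z), 0.7)

    model = _wrap(Constant(), 4)
    Z = np.random.default_rng(3).normal(size=(10, 4))
    report = shap_values(model, _frame(Z, model.feature_names), seed=0)
    np.testing.assert_allclose(report.phi.to_numpy(), 0.0, atol=1e-12)
    assert report.base_value == pytest.approx(0.7)


def test_additivity_holds_on_every_row(small_model, small_dataset):
    model, _ = small_model
    report = shap_values(model, small_dataset.X, seed=0)
    assert report.additivity_error() <= 1e-6


def test_sampled_permutation_estimator_keeps_exact_additivity():
    rng = np.random.default_rng(4)
    Z = rng.normal(size=(12, 8))  # 8! >> default samples: sampled branch
    y = Z.sum(axis=1) + rng.normal(0, 0.1, 12)
    reg = ExtraTreesRegressor(n_estimators=10, random_state=0).fit(Z, y)
    model = _wrap(reg, 8)
    report = shap_values(model, _frame(Z, model.feature_names),
                         n_permutations=32, seed=0)
    assert report.additivity_error() <= 1e-10


# ---------------------------------------------------------------------------
# importances
# ---------------------------------------------------------------------------

def _phi(matrix, names):
    return pd.DataFrame(np.asarray(matrix, dtype=float), columns=names)


def test_singleton_importance_zero_and_symmetric_columns():
    phi = _phi([[0.0, 0.3], [0.0, -0.3]], ["a", "b"])
    imp = singleton_importance(phi)
    assert imp["a"] == 0.0
    assert imp["b"] == pytest.approx(0.3)


def test_singleton_importance_invariant_under_row_permutation():
    rng = np.random.default_rng(5)
    phi = _phi(rng.normal(size=(10, 3)), ["a", "b", "c"])
    shuffled = phi.sample(frac=1.0, random_state=1)
    pd.testing.assert_series_equal(singleton_importance(phi),
                                   singleton_importance(shuffled))


def test_group_importance_reduces_to_singletons():
    rng = np.random.default_rng(6)
    phi = _phi(rng.normal(size=(20, 3)), ["a", "b", "c"])
    grouped = group_importance(phi, {"a": ["a"], "b": ["b"], "c": ["c"]})
    np.testing.assert_allclose(grouped["importance"].to_numpy(),
                               singleton_importance(phi)[grouped.index].to_numpy())
    assert (grouped["count"] == 1).all()


def test_group_importance_cancellation():
    phi = _phi([[0.4, -0.4], [0.2, -0.2]], ["a", "b"])
    grouped = group_importance(phi, {"both": ["a", "b"]})
    assert grouped.loc["both", "importance"] == 0.0
    assert singleton_importance(phi)["a"] == pytest.approx(0.3)


def test_group_importance_three_feature_closed_form():
    phi = _phi([[1.0, -0.5, 0.25], [-1.0, 0.5, 0.75]], ["a", "b", "c"])
    grouped = group_importance(phi, {"ab": ["a", "b"], "c": ["c"]})
    assert grouped.loc["ab", "importance"] == pytest.approx((0.5 + 0.5) / 2)
    assert grouped.loc["c", "importance"] == pytest.approx((0.25 + 0.75) / 2)


def test_group_importance_rejects_overlap():
    phi = _phi([[1.0, 2.0]], ["a", "b"])
    with pytest.raises(DataError):
        group_importance(phi, {"g1": ["a", "b"], "g2": ["b"]})


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_group_importance_triangle_inequality(seed):
    rng = np.random.default_rng(seed)
    names = list("abcdef")
    phi = _phi(rng.normal(size=(30, 6)), names)
    grouped = group_importance(phi, {"g1": names[:3], "g2": names[3:]})
    singles = singleton_importance(phi)
    assert grouped.loc["g1", "importance"] <= singles[names[:3]].sum() + 1e-12
    assert grouped.loc["g2", "importance"] <= singles[names[3:]].sum() + 1e-12


# ---------------------------------------------------------------------------
# hotspot report
# ---------------------------------------------------------------------------

def test_hotspot_report_counts_sum_to_feature_count(small_model, small_dataset):
    model, _ = small_model
    report = shap_values(model, small_dataset.X, seed=0)
    annotations = {n: small_dataset.annotations[n] for n in model.feature_names}
    tables = hotspot_report(report, annotations)
    for table in tables.values():
        assert table["count"].sum() == len(model.feature_names)


def test_hotspot_report_requires_annotations(small_model, small_dataset):
    model, _ = small_model
    report = shap_values(model, small_dataset.X, seed=0)
    with pytest.raises(DataError):
        hotspot_report(report, {})


def test_planted_cluster_dominates_importance():
    # two informative features on residues 10 and 11 (placed < 12 A apart),
    # two inert features on distant residues
    names = ["Cas9_10_density_3_SW", "Cas9_11_density_3_SW",
             "Cas9_40_density_3_SW", "Cas9_60_density_3_SW"]
    annotations = {n: parse_feature_name(n) for n in names}
    phi = _phi(np.column_stack([
        np.full(20, 0.5), np.full(20, 0.4), np.full(20, 0.01), np.full(20, -0.02),
    ]), names)
    dist = pd.DataFrame(
        [[0, 5, 30, 50], [5, 0, 28, 48], [30, 28, 0, 40], [50, 48, 40, 0]],
        index=[10, 11, 40, 60], columns=[10, 11, 40, 60], dtype=float)
    from casnano.structures import cluster_residues

    clustering = cluster_residues(dist, cutoff=12.0)
    assert clustering.clusters == [(10, 11)]
    report = ShapReport(phi, 0.0, phi.sum(axis=1).to_numpy(), "stub")
    tables = hotspot_report(report, annotations, clustering)
    by_cluster = tables["residue_cluster"]
    assert by_cluster.index[0] == "Group 1"
    assert by_cluster.loc["Group 1", "importance"] > 10 * by_cluster.drop(
        "Group 1")["importance"].max()
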