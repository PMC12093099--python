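"""Shapley-value attribution and grouped feature importances.

For the fitted activity model this module computes per-datapoint additive
feature attributions phi (Shapley values), the per-feature importance
I_j = mean_i |phi_j^(i)|, and grouped importances
I_J = mean_i |sum_{j in J} phi_j^(i)| for feature groups induced by any of
the six interpretive feature properties (residue, domain, contiguous domain,
parent descriptor class, descriptor class, aggregation) or by spatial
residue clusters.

Attribution back-ends
---------------------
* linear / ridge regressors: the exact closed form
  ``phi_j = coef_j * (x_j - reference_j)``;
* XGBoost and LightGBM regressors: the libraries' built-in exact
  path-dependent tree Shapley contributions;
* any other regressor: a seeded permutation-sampling estimator against a
  single reference point.  Summing marginal contributions along a feature
  permutation telescopes to ``f(x) - f(reference)``, so the estimator
  satisfies the additivity contract exactly at any sample count; when the
  number of features is small enough it enumerates all permutations and is
  exact.

The additivity contract -- ``base_value + sum_j phi_j == prediction`` per
row -- is enforced for every report.

Note on the per-feature importance: the group formula's absolute value is
kept in the singleton case (mean |phi| rather than mean phi); without it,
positive and negative attributions of a feature across datapoints cancel and
importances collapse toward zero.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor
from xgboost import XGBRegressor

from .errors import DataError, PipelineError
from .nanoenv import FeatureAnnotation
from .pipeline import StingCrisprModel
from .structures import ResidueClustering

ADDITIVITY_TOL = 1e-6


@dataclass
class ShapReport:
    """Per-datapoint Shapley values for one model over one dataset."""

    phi: pd.DataFrame
    base_value: float
    predictions: np.ndarray
    method: str

    def additivity_error(self) -> float:
        recomposed = self.base_value + self.phi.to_numpy().sum(axis=1)
        return float(np.max(np.abs(recomposed - self.predictions)))

    def singleton_importance(self) -> pd.Series:
        """I_j = mean over datapoints of |phi_j|."""
        return self.phi.abs().mean(axis=0).rename("importance")

    def group_importance(self, groups: Mapping[str, Sequence[str]]) -> pd.DataFrame:
        return group_importance(self.phi, groups)


# ---------------------------------------------------------------------------
# back-ends
# ---------------------------------------------------------------------------

def _linear_shap(regressor, Z: np.ndarray, reference: np.ndarray):
    coef = np.ravel(regressor.coef_)
    phi = coef * (Z - reference)
    base = float(regressor.predict(reference.reshape(1, -1))[0])
    return phi, base


def _xgboost_shap(regressor: XGBRegressor, Z: np.ndarray):
    import xgboost

    contrib = regressor.get_booster().predict(
        xgboost.DMatrix(Z), pred_contribs=True
    )
    contrib = np.asarray(contrib, dtype=float)
    return contrib[:, :-1], float(contrib[0, -1])


def _lightgbm_shap(regressor: LGBMRegressor, Z: np.ndarray):
    contrib = np.asarray(regressor.predict(Z, pred_contrib=True), dtype=float)
    return contrib[:, :-1], float(contrib[0, -1])


def _permutation_shap(
    predict: Callable[[np.ndarray], np.ndarray],
    Z: np.ndarray,
    reference: np.ndarray,
    n_permutations: int,
    rng: np.random.Generator,
):
    n, f = Z.shape
    if f <= 20 and math.factorial(f) <= n_permutations:
        perms = list(itertools.permutations(range(f)))
    else:
        perms = [rng.permutation(f) for _ in range(n_permutations)]
    phi = np.zeros((n, f))
    base = float(predict(reference.reshape(1, -1))[0])
    for perm in perms:
        current = np.tile(reference, (n, 1))
        prev = np.full(n, base)
        for j in perm:
            current[:, j] = Z[:, j]
            cur = np.asarray(predict(current), dtype=float)
            phi[:, j] += cur - prev
            prev = cur
    phi /= len(perms)
    return phi, base


def shap_values(
    model: StingCrisprModel,
    X: pd.DataFrame,
    method: str = "auto",
    reference: np.ndarray | None = None,
    n_permutations: int = 256,
    seed: int = 0,
) -> ShapReport:
    """Shapley attributions of the activity model over the rows of ``X``.

    ``X`` is given on the original feature scale; it is standardized with the
    model's training statistics internally, and the default reference point
    is the training mean (the origin of the standardized space).  ``method``
    may force ``"permutation"``; ``"auto"`` routes linear families to the
    closed form and boosted-tree families to their native exact tree
    contributions.
    """
    Z = model.transform(X)
    regressor = model.regressor
    ref = np.zeros(Z.shape[1]) if reference is None else np.asarray(reference, dtype=float)
    if ref.shape != (Z.shape[1],):
        raise PipelineError("reference point has the wrong number of features")

    if method == "auto":
        if hasattr(regressor, "coef_"):
            method = "linear"
        elif isinstance(regressor, XGBRegressor):
            method = "tree-xgboost"
        elif isinstance(regressor, LGBMRegressor):
            method = "tree-lightgbm"
        else:
            method = "permutation"

    if method == "linear":
        phi, base = _linear_shap(regressor, Z, ref)
    elif method == "tree-xgboost":
        phi, base = _xgboost_shap(regressor, Z)
    elif method == "tree-lightgbm":
        phi, base = _lightgbm_shap(regressor, Z)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        phi, base = _permutation_shap(regressor.predict, Z, ref, n_permutations, rng)
    else:
        raise PipelineError(f"unknown attribution method {method!r}")

    predictions = np.asarray(regressor.predict(Z), dtype=float)
    report = ShapReport(
        phi=pd.DataFrame(phi, index=X.index, columns=model.feature_names),
        base_value=base,
        predictions=predictions,
        method=method,
    )
    err = report.additivity_error()
    tol = ADDITIVITY_TOL if method != "tree-xgboost" else 1e-4  # float32 contributions
    if err > tol:
        raise PipelineError(f"additivity violated by {err:.3g} (method {method})")
    return report


# ---------------------------------------------------------------------------
# exact small-f oracle
# ---------------------------------------------------------------------------

def brute_force_shap(
    predict: Callable[[np.ndarray], np.ndarray],
    x: np.ndarray,
    reference: np.ndarray,
) -> tuple[np.ndarray, float]:
    """Exact Shapley values of one point by subset enumeration.

    The coalition value of a feature subset S is the model prediction with
    features in S taken from ``x`` and the rest from ``reference``.  Cost is
    O(2^f); refuse more than 16 features.
    """
    x = np.asarray(x, dtype=float)
    reference = np.asarray(reference, dtype=float)
    f = x.shape[0]
    if f > 16:
        raise PipelineError("brute-force Shapley is limited to 16 features")
    masks = np.array(list(itertools.product((0, 1), repeat=f)), dtype=bool)
    points = np.where(masks, x, reference)
    values = np.asarray(predict(points), dtype=float)
    value_of = {tuple(m): v for m, v in zip(map(tuple, masks.astype(int)), values)}

    phi = np.zeros(f)
    for j in range(f):
        others = [k for k in range(f) if k != j]
        for size in range(f):
            weight = (
                math.factorial(size) * math.factorial(f - size - 1) / math.factorial(f)
            )
            for subset in itertools.combinations(others, size):
                mask = [0] * f
                for k in subset:
                    mask[k] = 1
                without = value_of[tuple(mask)]
                mask[j] = 1
                with_j = value_of[tuple(mask)]
                phi[j] += weight * (with_j - without)
    base = value_of[tuple([0] * f)]
    return phi, float(base)


# ---------------------------------------------------------------------------
# grouped importances
# ---------------------------------------------------------------------------

def singleton_importance(phi: pd.DataFrame) -> pd.Series:
    """Mean absolute Shapley value per feature."""
    return phi.abs().mean(axis=0).rename("importance")


def group_importance(
    phi: pd.DataFrame, groups: Mapping[str, Sequence[str]]
) -> pd.DataFrame:
    """I_J = mean over datapoints of |sum over the group's features of phi|,
    plus the feature count of each group.  Groups must be disjoint."""
    seen: dict[str, str] = {}
    for name, features in groups.items():
        for feat in features:
            if feat in seen:
                raise DataError(f"feature {feat!r} appears in groups "
                                f"{seen[feat]!r} and {name!r}")
            if feat not in phi.columns:
                raise DataError(f"feature {feat!r} not present in the phi matrix")
            seen[feat] = name
    rows = []
    for name, features in groups.items():
        summed = phi[list(features)].to_numpy().sum(axis=1)
        rows.append((name, float(np.abs(summed).mean()), len(features)))
    return pd.DataFrame(rows, columns=["group", "importance", "count"]).set_index("group")


def hotspot_report(
    report: ShapReport,
    annotations: Mapping[str, FeatureAnnotation],
    clustering: ResidueClustering | None = None,
) -> dict[str, pd.DataFrame]:
    """Feature counts and grouped Shapley importances for every interpretive
    property, plus the spatial residue-cluster grouping when provided.

    Returns a table per grouping property (``residue``, ``domain``,
    ``contiguous_domain``, ``parent_class``, ``class``, ``aggregation`` and,
    with a clustering, ``residue_cluster``), each sorted by descending
    importance.
    """
    features = list(report.phi.columns)
    missing = [f for f in features if f not in annotations]
    if missing:
        raise DataError(f"unannotated features: {missing[:5]}")

    def grouping(key: Callable[[FeatureAnnotation], str]) -> dict[str, list[str]]:
        out: dict[str, list[str]] = {}
        for feat in features:
            out.setdefault(key(annotations[feat]), []).append(feat)
        return out

    properties: dict[str, Callable[[FeatureAnnotation], str]] = {
        "residue": lambda a: str(a.residue_number),
        "domain": lambda a: a.cas9_domain,
        "contiguous_domain": lambda a: a.contiguous_domain,
        "parent_class": lambda a: a.parent_descriptor_class,
        "class": lambda a: a.descriptor_class,
        "aggregation": lambda a: a.aggregation,
    }
    tables = {}
    for name, key in properties.items():
        tables[name] = group_importance(report.phi, grouping(key)).sort_values(
            "importance", ascending=False
        )
    if clustering is not None:
        tables["residue_cluster"] = group_importance(
            report.phi,
            grouping(lambda a: clustering.group_of(a.residue_number)),
        ).sort_values("importance", ascending=False)
    return tables
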