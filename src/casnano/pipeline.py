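"""Three-step prediction pipeline: scale, surrogate-select, regress.

The pipeline standardizes the nanoenvironment matrix, fits a surrogate model
``m1`` on all features, keeps the ``f`` features with the highest surrogate
importance (|coefficient| for linear families, impurity importance for tree
ensembles), and fits a final regressor ``m2`` on the retained columns.

Hyperparameters ``m1`` (5 families), ``m2`` (6 families) and ``f`` in
F = {5, 10, ..., 50} are tuned by grid search under five-fold cross-validation
of the training partition: the model pair maximizing the mean validation
Spearman correlation averaged across F is chosen first, then the smallest
``f*`` whose increment-of-5 Spearman gain is at most delta_rho = 2e-3.
Re-fitting the winning configuration on the full training partition and
extracting ``m2`` yields the deployable activity model.

The train/test split holds out the last 4 snapshots of every trajectory, so
train and test rows are distributed similarly; generalization to entirely
unseen guide-target pairs is probed separately by trajectory-holdout
cross-validation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
from lightgbm import LGBMRegressor
from scipy.stats import pearsonr, spearmanr
from sklearn.ensemble import ExtraTreesRegressor, GradientBoostingRegressor
from sklearn.linear_model import LinearRegression, Ridge
from sklearn.metrics import mean_absolute_error, mean_squared_error
from sklearn.preprocessing import StandardScaler
from xgboost import XGBRegressor

from .errors import PipelineError
from .nanoenv import NanoenvDataset

logger = logging.getLogger(__name__)

#: surrogate (m1) families, in declaration order (used for tie-breaking)
SURROGATE_FAMILIES = ("linear", "ridge", "xgboost", "extra_trees", "lightgbm")
#: final (m2) families; the sixth is a classic gradient-boosting ensemble
FINAL_FAMILIES = SURROGATE_FAMILIES + ("gbdt",)
#: default candidate feature-set sizes
FEATURE_SIZES = tuple(range(5, 55, 5))
#: default Spearman-improvement threshold for the feature-size rule
DELTA_RHO_DEFAULT = 2e-3
N_HOLDOUT_DEFAULT = 4
N_FOLDS_DEFAULT = 5


def make_model(family: str, seed: int = 0):
    """Instantiate a model family with library-default hyperparameters and a
    fixed seed (where the family is stochastic)."""
    if family == "linear":
        return LinearRegression()
    if family == "ridge":
        return Ridge()
    if family == "xgboost":
        return XGBRegressor(random_state=seed, n_jobs=1, verbosity=0)
    if family == "extra_trees":
        return ExtraTreesRegressor(random_state=seed, n_jobs=1)
    if family == "lightgbm":
        return LGBMRegressor(random_state=seed, n_jobs=1, verbose=-1)
    if family == "gbdt":
        return GradientBoostingRegressor(random_state=seed)
    raise PipelineError(f"unknown model family {family!r}")


def feature_importance(model) -> np.ndarray:
    """Native importance of a fitted model: |coefficients| for linear
    families, impurity-based importance for tree ensembles."""
    if hasattr(model, "coef_"):
        return np.abs(np.ravel(model.coef_))
    if hasattr(model, "feature_importances_"):
        return np.asarray(model.feature_importances_, dtype=float)
    raise PipelineError(f"model {type(model).__name__} exposes no importance")


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

@dataclass
class SplitPlan:
    """Row partition: trajectory-tail holdout plus CV folds of the rest."""

    train_rows: list
    test_rows: list
    folds: list[list]
    cv_seed: int
    n_holdout: int

    def fold_split(self, k: int) -> tuple[list, list]:
        """(train, validation) row labels for fold ``k``."""
        validation = set(self.folds[k])
        train = [r for r in self.train_rows if r not in validation]
        return train, self.folds[k]


def make_split(
    dataset: NanoenvDataset,
    n_holdout: int = N_HOLDOUT_DEFAULT,
    cv_seed: int = 0,
    n_folds: int = N_FOLDS_DEFAULT,
) -> SplitPlan:
    """Hold out the last ``n_holdout`` snapshots of every trajectory for the
    test partition and split the remaining rows into ``n_folds`` random,
    near-equal cross-validation folds."""
    meta = dataset.row_meta
    test_rows: list = []
    train_rows: list = []
    for traj, group in meta.groupby("trajectory_id", sort=False):
        ordered = group.sort_values("snapshot_number", kind="stable").index.tolist()
        if len(ordered) <= n_holdout:
            raise PipelineError(
                f"trajectory {traj} has only {len(ordered)} snapshots; "
                f"cannot hold out {n_holdout}"
            )
        test_rows.extend(ordered[-n_holdout:])
        train_rows.extend(ordered[:-n_holdout])
    rng = np.random.default_rng(cv_seed)
    shuffled = list(np.array(train_rows, dtype=object)[rng.permutation(len(train_rows))])
    folds = [list(part) for part in np.array_split(np.array(shuffled, dtype=object), n_folds)]
    return SplitPlan(train_rows, test_rows, folds, cv_seed, n_holdout)


# ---------------------------------------------------------------------------
# pipeline fitting
# ---------------------------------------------------------------------------

@dataclass
class FittedPipeline:
    """A fitted scale / select / regress pipeline."""

    m1_family: str
    m2_family: str
    f: int
    scaler: StandardScaler
    feature_names: list[str]
    selected_features: list[str]
    selected_indices: np.ndarray
    surrogate: object
    regressor: object
    seed: int

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        Z = self.scaler.transform(X[self.feature_names].to_numpy())
        return Z[:, self.selected_indices]

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise PipelineError(f"input lacks {len(missing)} pipeline features: {missing[:5]}")
        return np.asarray(self.regressor.predict(self.transform(X)), dtype=float)


def fit_pipeline(
    m1_family: str,
    m2_family: str,
    f: int,
    X: pd.DataFrame,
    y: pd.Series | np.ndarray,
    seed: int = 0,
) -> FittedPipeline:
    """Standardize, rank features by surrogate importance (descending; ties
    broken by ascending column index) and fit the final regressor on the top
    ``f`` columns."""
    if X.shape[0] == 0:
        raise PipelineError("empty training matrix")
    if f > X.shape[1]:
        raise PipelineError(f"f={f} exceeds the {X.shape[1]} available features")
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        warnings.warn("degenerate labels: all training activities identical", stacklevel=2)
    scaler = StandardScaler()
    Z = scaler.fit_transform(X.to_numpy())
    surrogate = make_model(m1_family, seed)
    surrogate.fit(Z, y)
    importance = feature_importance(surrogate)
    order = np.argsort(-importance, kind="stable")  # stable: index order on ties
    selected = order[:f]
    regressor = make_model(m2_family, seed)
    regressor.fit(Z[:, selected], y)
    names = list(X.columns)
    return FittedPipeline(
        m1_family, m2_family, int(f), scaler, names,
        [names[i] for i in selected], np.asarray(selected), surrogate, regressor, seed,
    )


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

@dataclass
class CVResult:
    """Per-(m1, m2, f, fold) validation Spearman correlations."""

    table: pd.DataFrame  # columns: m1, m2, f, fold, spearman
    surrogates: tuple[str, ...]
    finals: tuple[str, ...]
    feature_sizes: tuple[int, ...]

    def rho(self, m1: str, m2: str, f: int) -> float:
        sel = self.table[
            (self.table["m1"] == m1) & (self.table["m2"] == m2) & (self.table["f"] == f)
        ]["spearman"].to_numpy()
        if len(sel) == 0 or np.isnan(sel).all():
            return float("nan")
        return float(np.nanmean(sel))

    def rho_curve(self, m1: str, m2: str) -> dict[int, float]:
        return {f: self.rho(m1, m2, f) for f in self.feature_sizes}

    def pair_mean(self, m1: str, m2: str) -> float:
        values = np.array([self.rho(m1, m2, f) for f in self.feature_sizes])
        if np.isnan(values).all():
            return float("nan")
        return float(np.nanmean(values))

    @property
    def n_cells(self) -> int:
        return len(self.surrogates) * len(self.finals) * len(self.feature_sizes)


def grid_search(
    X: pd.DataFrame,
    y: pd.Series,
    split: SplitPlan,
    surrogates: Sequence[str] = SURROGATE_FAMILIES,
    finals: Sequence[str] = FINAL_FAMILIES,
    feature_sizes: Sequence[int] = FEATURE_SIZES,
    seed: int = 0,
) -> CVResult:
    """Evaluate every (m1, m2, f) grid cell by mean validation Spearman over
    the CV folds.

    Each surrogate is fitted once per fold and its feature ranking shared
    across all (m2, f) cells, which is equivalent to refitting per cell.  A
    cell whose fit fails is recorded as missing and the run continues.
    """
    records = []
    y = pd.Series(np.asarray(y, dtype=float), index=X.index)
    for k in range(len(split.folds)):
        train_rows, val_rows = split.fold_split(k)
        X_tr, X_val = X.loc[train_rows], X.loc[val_rows]
        y_tr, y_val = y.loc[train_rows].to_numpy(), y.loc[val_rows].to_numpy()
        scaler = StandardScaler()
        Z_tr = scaler.fit_transform(X_tr.to_numpy())
        Z_val = scaler.transform(X_val.to_numpy())
        for m1 in surrogates:
            try:
                surrogate = make_model(m1, seed)
                surrogate.fit(Z_tr, y_tr)
                order = np.argsort(-feature_importance(surrogate), kind="stable")
            except Exception as exc:  # noqa: BLE001 - cell failure must not kill the run
                logger.warning("fold %d surrogate %s failed: %s", k, m1, exc)
                for m2 in finals:
                    for f in feature_sizes:
                        records.append((m1, m2, int(f), k, float("nan")))
                continue
            for f in feature_sizes:
                selected = order[:f]
                for m2 in finals:
                    try:
                        model = make_model(m2, seed)
                        model.fit(Z_tr[:, selected], y_tr)
                        pred = model.predict(Z_val[:, selected])
                        rho = float(spearmanr(y_val, pred).statistic)
                    except Exception as exc:  # noqa: BLE001
                        logger.warning("cell (%s, %s, %d) fold %d failed: %s",
                                       m1, m2, f, k, exc)
                        rho = float("nan")
                    records.append((m1, m2, int(f), k, rho))
    table = pd.DataFrame(records, columns=["m1", "m2", "f", "fold", "spearman"])
    return CVResult(table, tuple(surrogates), tuple(finals), tuple(int(f) for f in feature_sizes))


def select_model_pair(cv: CVResult) -> tuple[str, str]:
    """Model pair with the highest mean validation Spearman averaged across
    the candidate feature sizes; exact ties resolve to the earlier-declared
    pair."""
    best: tuple[str, str] | None = None
    best_score = -np.inf
    for m1 in cv.surrogates:
        for m2 in cv.finals:
            score = cv.pair_mean(m1, m2)
            if np.isnan(score):
                logger.warning("pair (%s, %s) has no evaluated cells; skipped", m1, m2)
                continue
            if score > best_score:
                best, best_score = (m1, m2), score
    if best is None:
        raise PipelineError("no model pair has any evaluated grid cell")
    logger.info("selected model pair %s (mean validation Spearman %.4f)", best, best_score)
    return best


def select_feature_size(
    rho_curve: Mapping[int, float], delta: float = DELTA_RHO_DEFAULT
) -> int:
    """Smallest ``f`` whose increment-of-5 Spearman gain is at most ``delta``.

    If every increment exceeds ``delta`` the largest candidate size is
    returned (with a log notice).
    """
    if delta <= 0:
        raise PipelineError("delta must be positive")
    sizes = sorted(int(f) for f in rho_curve)
    values = {int(f): float(v) for f, v in rho_curve.items()}
    if any(np.isnan(values[f]) for f in sizes):
        raise PipelineError("feature-size curve contains missing points")
    for f, f_next in zip(sizes, sizes[1:]):
        if values[f_next] - values[f] <= delta:
            return f
    logger.info("no increment satisfied the threshold; keeping f = %d", sizes[-1])
    return sizes[-1]


# ---------------------------------------------------------------------------
# final model
# ---------------------------------------------------------------------------

@dataclass
class StingCrisprModel:
    """Deployable activity model: selected features, their training
    standardization statistics, and the fitted final regressor."""

    feature_names: list[str]
    feature_means: np.ndarray
    feature_sds: np.ndarray
    regressor: object
    family: str
    provenance: dict = field(default_factory=dict)

    def transform(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise PipelineError(
                f"input lacks {len(missing)} selected features: {missing[:5]}"
            )
        Z = X[self.feature_names].to_numpy(dtype=float)
        return (Z - self.feature_means) / self.feature_sds

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return np.asarray(self.regressor.predict(self.transform(X)), dtype=float)

    def save(self, path: str | Path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path: str | Path) -> "StingCrisprModel":
        return joblib.load(path)


def train_final(
    m1_family: str,
    m2_family: str,
    f: int,
    X_train: pd.DataFrame,
    y_train: pd.Series,
    seed: int = 0,
    provenance: dict | None = None,
) -> StingCrisprModel:
    """Refit the winning pipeline configuration on the full training
    partition and extract the final regressor with its selected features and
    training scaling statistics."""
    pipe = fit_pipeline(m1_family, m2_family, f, X_train, y_train, seed=seed)
    means = pipe.scaler.mean_[pipe.selected_indices]
    sds = pipe.scaler.scale_[pipe.selected_indices]  # zero-variance -> 1.0
    prov = {
        "m1": m1_family, "m2": m2_family, "f": int(f), "seed": int(seed),
        "n_train_rows": int(X_train.shape[0]), "n_features_total": int(X_train.shape[1]),
    }
    prov.update(provenance or {})
    return StingCrisprModel(
        list(pipe.selected_features), means, sds, pipe.regressor, m2_family, prov
    )


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class Metrics:
    """Global regression metrics plus grouped squared-error breakdowns."""

    spearman: float
    pearson: float
    mse: float
    mae: float
    group_squared_errors: pd.DataFrame | None = None

    def to_dict(self) -> dict:
        out = {"spearman": self.spearman, "pearson": self.pearson,
               "mse": self.mse, "mae": self.mae}
        if self.group_squared_errors is not None:
            out["groups"] = self.group_squared_errors.to_dict(orient="records")
        return out


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[float, float, float, float]:
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    rho = float(spearmanr(y_true, y_pred).statistic)
    r = float(pearsonr(y_true, y_pred).statistic) if np.ptp(y_pred) > 0 else float("nan")
    return rho, r, float(mean_squared_error(y_true, y_pred)), float(
        mean_absolute_error(y_true, y_pred))


def evaluate(
    model: StingCrisprModel | FittedPipeline,
    X_test: pd.DataFrame,
    y_test: pd.Series,
    row_meta: pd.DataFrame | None = None,
) -> Metrics:
    """Test metrics plus squared-error breakdowns by on-target flag, mismatch
    position and mismatch interface type (when metadata is available)."""
    pred = model.predict(X_test)
    y = np.asarray(y_test, dtype=float)
    rho, r, mse, mae = compute_metrics(y, pred)
    groups = None
    if row_meta is not None:
        sq = (y - pred) ** 2
        rows = []
        meta = row_meta.loc[X_test.index]
        position = np.where(
            meta.get("on_target", pd.Series(False, index=meta.index)).fillna(False),
            "ON",
            meta.get("mismatch_position", pd.Series(np.nan, index=meta.index)).astype(
                "object").map(lambda p: "NA" if pd.isna(p) else str(int(p))),
        )
        for kind, labels in (
            ("position", pd.Series(position, index=meta.index)),
            ("interface", meta.get("mismatch_type", pd.Series("NA", index=meta.index))),
        ):
            frame = pd.DataFrame({"group": labels.fillna("NA").astype(str), "sq": sq})
            agg = frame.groupby("group", sort=True)["sq"].agg(["mean", "std", "count"])
            for name, row in agg.iterrows():
                rows.append((kind, name, float(row["mean"]),
                             float(row["std"]) if row["count"] > 1 else 0.0,
                             int(row["count"])))
        groups = pd.DataFrame(
            rows, columns=["kind", "group", "mean_sq_err", "sd_sq_err", "n"]
        )
    return Metrics(rho, r, mse, mae, groups)


# ---------------------------------------------------------------------------
# trajectory-holdout cross-validation
# ---------------------------------------------------------------------------

def assign_trajectory_folds(
    activities: pd.Series, n_folds: int = N_FOLDS_DEFAULT
) -> dict[str, int]:
    """Fold of each trajectory: the trajectory with the n-th lowest activity
    (0-based, ties broken by trajectory id) goes to fold ``n mod n_folds``."""
    frame = activities.rename("activity").rename_axis("trajectory").reset_index()
    if frame["activity"].duplicated().any():
        logger.info("duplicate activities: fold assignment ties broken by trajectory id")
    frame = frame.sort_values(["activity", "trajectory"], kind="stable").reset_index(drop=True)
    return {row["trajectory"]: int(i % n_folds) for i, row in frame.iterrows()}


def holdout_trajectory_cv(
    dataset: NanoenvDataset,
    families: Sequence[str] = SURROGATE_FAMILIES,
    n_folds: int = N_FOLDS_DEFAULT,
    seed: int = 0,
) -> pd.DataFrame:
    """Generalization probe: hold out whole trajectories per fold (assigned
    by activity rank) and fit each model family on all features without
    feature selection; returns per-(fold, family) Spearman and Pearson."""
    activities = dataset.trajectory_activities()
    if len(activities) < n_folds:
        raise PipelineError(f"need at least {n_folds} trajectories")
    fold_of = assign_trajectory_folds(activities, n_folds)
    meta = dataset.row_meta
    records = []
    for k in range(n_folds):
        test_traj = {t for t, fk in fold_of.items() if fk == k}
        test_rows = meta.index[meta["trajectory_id"].isin(test_traj)]
        train_rows = meta.index[~meta["trajectory_id"].isin(test_traj)]
        scaler = StandardScaler()
        Z_tr = scaler.fit_transform(dataset.X.loc[train_rows].to_numpy())
        Z_te = scaler.transform(dataset.X.loc[test_rows].to_numpy())
        y_tr = dataset.y.loc[train_rows].to_numpy()
        y_te = dataset.y.loc[test_rows].to_numpy()
        for family in families:
            model = make_model(family, seed)
            model.fit(Z_tr, y_tr)
            pred = model.predict(Z_te)
            rho, r, mse, mae = compute_metrics(y_te, pred)
            records.append((k, family, rho, r, mse, mae, sorted(test_traj)))
    return pd.DataFrame(
        records,
        columns=["fold", "family", "spearman", "pearson", "mse", "mae", "test_trajectories"],
    )
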