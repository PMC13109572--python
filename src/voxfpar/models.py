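"""Regressor fitting, evaluation and voxel-level fPAR prediction.

Four algorithms are supported with the published final hyperparameters as
defaults: random forest (300 trees, 6 features per split), XGBoost
(eta 0.01, 500 trees, depth 6), an RBF support vector machine (C 10,
gamma 0.1) and PLS regression (10 components). SVM and PLSR consume
standardized predictors (statistics learned on the calibration split only,
inside a sklearn pipeline); the tree ensembles take raw vegetation indices.

All data splitting — the 80/20 calibration/validation split and the
repeated 10-fold cross-validation — is grouped by tree so that no tree
contributes rows to both sides of any split.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.cross_decomposition import PLSRegression
from sklearn.ensemble import RandomForestRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from xgboost import XGBRegressor

from .errors import ConfigurationError, InsufficientDataError
from .indices import INDEX_NAMES

ALGORITHMS = ("RF", "XGBoost", "SVM", "PLSR")

DEFAULT_HYPERPARAMETERS = {
    "RF": {"n_estimators": 300, "max_features": 6},
    "XGBoost": {"learning_rate": 0.01, "n_estimators": 500, "max_depth": 6},
    "SVM": {"C": 10.0, "gamma": 0.1, "epsilon": 0.01},
    "PLSR": {"n_components": 10},
}

#: small grids centered on the default values, used when search is enabled
DEFAULT_GRIDS = {
    "RF": {"max_features": [4, 6, 8]},
    "XGBoost": {"max_depth": [4, 6, 8]},
    "SVM": {"C": [1.0, 10.0, 100.0], "gamma": [0.01, 0.1, 1.0]},
    "PLSR": {"n_components": [4, 7, 10, 14]},
}


class _PLSWrapper(BaseEstimator, RegressorMixin):
    """PLS regression with 1-D predictions and an n_components guard."""

    def __init__(self, n_components=10):
        self.n_components = n_components

    def fit(self, X, y):
        n_comp = int(min(self.n_components, X.shape[1], max(X.shape[0] - 1, 1)))
        self.pls_ = PLSRegression(n_components=n_comp)
        self.pls_.fit(X, y)
        return self

    def predict(self, X):
        return np.asarray(self.pls_.predict(X)).ravel()


@dataclass(frozen=True)
class ModelSpec:
    algorithm: str = "RF"
    hyperparameters: dict = field(default_factory=dict)
    grid: Optional[dict] = None
    seed: int = 0

    def __post_init__(self):
        if self.algorithm not in ALGORITHMS:
            raise ConfigurationError(
                f"unknown algorithm {self.algorithm!r}; choose from {ALGORITHMS}")

    def resolved_hyperparameters(self) -> dict:
        params = dict(DEFAULT_HYPERPARAMETERS[self.algorithm])
        params.update(self.hyperparameters)
        return params

    def resolved_grid(self) -> dict:
        return self.grid if self.grid is not None \
            else DEFAULT_GRIDS[self.algorithm]


def make_estimator(spec: ModelSpec, **overrides):
    params = spec.resolved_hyperparameters()
    params.update(overrides)
    if spec.algorithm == "RF":
        return RandomForestRegressor(random_state=spec.seed, n_jobs=1, **params)
    if spec.algorithm == "XGBoost":
        return XGBRegressor(random_state=spec.seed, n_jobs=1, verbosity=0,
                            **params)
    if spec.algorithm == "SVM":
        return Pipeline([("scale", StandardScaler()),
                         ("svr", SVR(kernel="rbf", **params))])
    return Pipeline([("scale", StandardScaler()),
                     ("pls", _PLSWrapper(**params))])


def evaluate(observed, predicted):
    """R^2 and RMSE of predictions.

    R^2 = 1 - SSE/SST; RMSE = sqrt(mean squared error). With zero total
    variance R^2 is undefined (NaN) while RMSE is still returned.
    """
    y = np.asarray(observed, dtype=float)
    yhat = np.asarray(predicted, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("observed and predicted lengths differ")
    if y.size < 2:
        raise InsufficientDataError("need n >= 2 for evaluation")
    sse = float(np.sum((y - yhat) ** 2))
    sst = float(np.sum((y - y.mean()) ** 2))
    rmse = float(np.sqrt(sse / y.size))
    r2 = np.nan if sst == 0 else 1.0 - sse / sst
    return r2, rmse


def split_data(table: pd.DataFrame, fraction: float = 0.8,
               unit: str = "tree_id", seed: int = 0):
    """Grouped calibration/validation split: all rows of a unit stay together."""
    if not 0 < fraction < 1:
        raise ConfigurationError("fraction must be in (0, 1)")
    units = np.sort(table[unit].unique())
    if units.size < 5:
        raise InsufficientDataError(
            f"need >= 5 grouping units, got {units.size}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(units)
    n_cal = int(round(fraction * units.size))
    n_cal = min(max(n_cal, 1), units.size - 1)
    cal_units = set(perm[:n_cal].tolist())
    mask = table[unit].isin(cal_units)
    return (table[mask].reset_index(drop=True),
            table[~mask].reset_index(drop=True))


def grouped_cv_folds(groups, n_splits: int = 10, n_repeats: int = 5,
                     seed: int = 0):
    """Yield (train_idx, test_idx) for repeated group k-fold CV.

    Groups are shuffled independently per repeat and partitioned into
    ``n_splits`` contiguous chunks, so every group is held out exactly once
    per repeat and never straddles a fold boundary.
    """
    groups = np.asarray(groups)
    uniq = np.sort(np.unique(groups))
    if uniq.size < n_splits:
        raise InsufficientDataError(
            f"{uniq.size} groups cannot form {n_splits} folds")
    rng = np.random.default_rng(seed)
    for _ in range(n_repeats):
        perm = rng.permutation(uniq)
        for chunk in np.array_split(perm, n_splits):
            test = np.isin(groups, chunk)
            yield np.where(~test)[0], np.where(test)[0]


@dataclass
class FitResult:
    spec: ModelSpec
    model: object
    predictors: list
    target: str
    best_params: dict
    cv_results: pd.DataFrame     # one row per repeat x fold
    cv_rmse_mean: float
    cv_r2_mean: float
    calibration_r2: float
    calibration_rmse: float
    seed: int
    groups: np.ndarray
    n_rows: int
    dropped_rows: int


def train_model(calibration: pd.DataFrame, spec: ModelSpec,
                predictors: list = INDEX_NAMES, target: str = "fpar_label",
                group: str = "tree_id", n_splits: int = 10,
                n_repeats: int = 5, grid_search: bool = False) -> FitResult:
    """Fit one regressor under grouped repeated k-fold CV.

    Rows with any missing predictor or target are dropped (count reported
    on the result). When ``grid_search`` is on, the grid point minimizing
    mean CV RMSE wins (ties go to the first grid point in iteration order);
    the final model is refit on the full calibration set either way.
    """
    cols = [*predictors, target, group]
    data = calibration[cols].copy()
    complete = data.notna().all(axis=1)
    dropped = int((~complete).sum())
    if dropped:
        warnings.warn(f"dropping {dropped} incomplete training rows")
    data = data[complete]
    if len(data) == 0:
        raise InsufficientDataError("all training rows were incomplete")
    if len(data) < 20:
        raise InsufficientDataError(
            f"need >= 20 training rows, got {len(data)}")
    X = data[list(predictors)].to_numpy(dtype=float)
    y = data[target].to_numpy(dtype=float)
    groups = data[group].to_numpy()

    candidates = [{}]
    if grid_search:
        grid = spec.resolved_grid()
        keys = list(grid)
        candidates = [dict(zip(keys, vals))
                      for vals in itertools.product(*(grid[k] for k in keys))]

    best = None
    for cand in candidates:
        rows = []
        for fold, (tr, te) in enumerate(grouped_cv_folds(
                groups, n_splits, n_repeats, seed=spec.seed)):
            est = clone(make_estimator(spec, **cand))
            est.fit(X[tr], y[tr])
            r2, rmse = evaluate(y[te], est.predict(X[te]))
            rows.append((fold // n_splits, fold % n_splits, r2, rmse))
        cv = pd.DataFrame(rows, columns=["repeat", "fold", "r2", "rmse"])
        mean_rmse = float(cv["rmse"].mean())
        if best is None or mean_rmse < best[0]:
            best = (mean_rmse, cand, cv)

    _, best_params, cv = best
    model = make_estimator(spec, **best_params)
    model.fit(X, y)
    cal_r2, cal_rmse = evaluate(y, model.predict(X))
    return FitResult(
        spec=spec, model=model, predictors=list(predictors), target=target,
        best_params=best_params, cv_results=cv,
        cv_rmse_mean=float(cv["rmse"].mean()),
        cv_r2_mean=float(cv["r2"].mean()),
        calibration_r2=cal_r2, calibration_rmse=cal_rmse,
        seed=spec.seed, groups=np.unique(groups), n_rows=len(data),
        dropped_rows=dropped)


def validate_model(fit: FitResult, validation: pd.DataFrame):
    """Held-out R^2 and RMSE on complete rows of the validation table."""
    data = validation[[*fit.predictors, fit.target]].dropna()
    y = data[fit.target].to_numpy(dtype=float)
    yhat = fit.model.predict(data[fit.predictors].to_numpy(dtype=float))
    return evaluate(y, yhat)


def permutation_importance(fit: FitResult, table: pd.DataFrame,
                           n_repeats: int = 10, seed: int = 0) -> pd.DataFrame:
    """Mean increase in RMSE when one predictor column is shuffled.

    The standard permutation measure of accuracy decrease: for each
    predictor, its values are permuted ``n_repeats`` times and the mean
    RMSE increase over the intact baseline is recorded. Returns a table
    sorted by descending importance with a 1-based rank column.
    """
    data = table[[*fit.predictors, fit.target]].dropna()
    X = data[fit.predictors].to_numpy(dtype=float)
    y = data[fit.target].to_numpy(dtype=float)
    _, base_rmse = evaluate(y, fit.model.predict(X))
    rng = np.random.default_rng(seed)
    rows = []
    for pos, name in enumerate(fit.predictors):
        increases = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, pos] = Xp[rng.permutation(len(Xp)), pos]
            _, rmse = evaluate(y, fit.model.predict(Xp))
            increases.append(rmse - base_rmse)
        rows.append((name, float(np.mean(increases)), float(np.std(increases))))
    out = pd.DataFrame(rows, columns=["predictor", "importance", "importance_sd"])
    out = out.sort_values(["importance", "predictor"],
                          ascending=[False, True], ignore_index=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


def predict_voxels(fit: FitResult, table: pd.DataFrame,
                   out_column: str = "fpar_pred") -> pd.DataFrame:
    """Voxel-level predictions clipped to [0, 1].

    Rows with missing predictors get missing predictions and
    ``pred_missing = True``; out-of-range raw predictions are capped with
    ``pred_clipped = True``.
    """
    out = table.copy()
    X = out[fit.predictors].to_numpy(dtype=float)
    complete = np.isfinite(X).all(axis=1)
    pred = np.full(len(out), np.nan)
    clipped = np.zeros(len(out), dtype=bool)
    if complete.any():
        raw = np.asarray(fit.model.predict(X[complete]), dtype=float)
        clip = np.clip(raw, 0.0, 1.0)
        pred[complete] = clip
        clipped[complete] = raw != clip
    out[out_column] = pred
    out["pred_clipped"] = clipped
    out["pred_missing"] = ~complete
    return out
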