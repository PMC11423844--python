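"""Random-forest determinants analysis of bias-corrected efficiency.

A random-forest regressor (500 trees, 5 candidate variables per split by
default) predicts the bias-corrected efficiency score from seven
contextual covariates plus the calendar year.  Fit quality is measured on
held-out predictions from repeated k-fold cross-validation (10 folds, 3
repeats), variable importance by the perturbation method (permute one
variable within each of 50 bootstrap subsamples and record the RMSE
increase), and variable effects by partial dependence over a sample of
500 observations.  The same analysis can be refit independently within
each socio-economic region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

logger = logging.getLogger(__name__)

#: default feature set: seven contextual variables + year
FEATURE_COLS = [
    "marginalization",
    "phc_coverage",
    "indigenous_pct",
    "demand",
    "gini",
    "gov_support",
    "employment",
    "year",
]


@dataclass
class RFConfig:
    n_trees: int = 500
    vars_per_split: int = 5
    cv_folds: int = 10
    cv_repeats: int = 3
    n_importance_subsamples: int = 50
    n_pd_observations: int = 500
    n_pd_grid: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_trees", "vars_per_split", "cv_folds", "cv_repeats",
                     "n_importance_subsamples", "n_pd_observations"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")


@dataclass
class FitMetrics:
    """Cross-validated error metrics, pooled over folds and repeats.

    ``mad`` is the median absolute error of the held-out residuals;
    ``mad_residuals`` is the median absolute deviation of the residuals
    from their own median (reported alongside, not contract-bearing).
    """

    mse: float
    rmse: float
    r_squared: float
    mad: float
    mad_residuals: float

    def as_dict(self) -> dict[str, float]:
        return {
            "mse": self.mse,
            "rmse": self.rmse,
            "r_squared": self.r_squared,
            "mad": self.mad,
            "mad_residuals": self.mad_residuals,
        }


def _make_forest(config: RFConfig, n_features: int, seed: int) -> RandomForestRegressor:
    # min_samples_leaf=5 is the standard regression-forest node size
    return RandomForestRegressor(
        n_estimators=config.n_trees,
        max_features=min(config.vars_per_split, n_features),
        min_samples_leaf=5,
        random_state=seed,
        n_jobs=1,
    )


def fit_rf(
    features: pd.DataFrame,
    target: np.ndarray | pd.Series,
    config: RFConfig,
) -> tuple[RandomForestRegressor, FitMetrics]:
    """Train the forest and score it on repeated-CV held-out predictions.

    Returns the model refit on all rows plus the pooled CV metrics.
    """
    X = features.to_numpy(float)
    y = np.asarray(target, dtype=float)
    if X.shape[0] != y.shape[0]:
        raise ValueError("features and target lengths differ")
    if np.isnan(X).any() or np.isnan(y).any():
        raise ValueError("missing values are not allowed")
    if X.shape[0] < config.cv_folds:
        raise ValueError(
            f"{X.shape[0]} rows is fewer than cv_folds={config.cv_folds}"
        )
    if np.ptp(y) == 0:
        raise ValueError("constant target: nothing to model")
    if config.vars_per_split > X.shape[1]:
        raise ValueError("vars_per_split exceeds the number of predictors")

    y_true_pool: list[np.ndarray] = []
    y_pred_pool: list[np.ndarray] = []
    fold_models: list[RandomForestRegressor] = []
    fold_of = np.empty(X.shape[0], dtype=int)
    for rep in range(config.cv_repeats):
        kf = KFold(n_splits=config.cv_folds, shuffle=True,
                   random_state=config.seed + 1000 * rep)
        for fold, (tr, te) in enumerate(kf.split(X)):
            model = _make_forest(config, X.shape[1],
                                 config.seed + 1000 * rep + fold)
            model.fit(X[tr], y[tr])
            y_true_pool.append(y[te])
            y_pred_pool.append(model.predict(X[te]))
            if rep == 0:  # keep first-repeat folds for out-of-fold scoring
                fold_models.append(model)
                fold_of[te] = fold
    yt = np.concatenate(y_true_pool)
    yp = np.concatenate(y_pred_pool)
    resid = yt - yp
    mse = float(np.mean(resid**2))
    metrics = FitMetrics(
        mse=mse,
        rmse=float(np.sqrt(mse)),
        r_squared=float(1.0 - mse / np.var(yt)),
        mad=float(np.median(np.abs(resid))),
        mad_residuals=float(np.median(np.abs(resid - np.median(resid)))),
    )
    final = _make_forest(config, X.shape[1], config.seed)
    final.fit(X, y)
    final.feature_names_ = list(features.columns)
    final.cv_models_ = fold_models
    final.cv_fold_of_ = fold_of
    return final, metrics


def perturbation_importance(
    model: RandomForestRegressor,
    features: pd.DataFrame,
    target: np.ndarray | pd.Series,
    config: RFConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Mean RMSE increase when one variable is permuted, over bootstrap subsamples.

    For each variable and each of ``n_importance_subsamples`` subsamples
    (drawn with replacement, size n): permute the variable's values within
    the subsample, and record

        delta_rmse = RMSE(permuted subsample) - RMSE(intact subsample).

    Variables are ranked by mean delta_rmse, descending.

    When the model carries cross-validation fold models (as models from
    :func:`fit_rf` do), every row is scored by the fold model that never
    saw it during training.  This out-of-fold evaluation is what makes an
    irrelevant variable's importance converge to zero: scoring training
    rows with the final model would instead charge part of the forest's
    memorized noise to whichever variable is permuted.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    names = getattr(model, "feature_names_", list(features.columns))
    if list(features.columns) != names:
        raise ValueError(
            f"feature mismatch: model was fit on {names}, got "
            f"{list(features.columns)}"
        )
    X = features.to_numpy(float)
    y = np.asarray(target, dtype=float)
    n = X.shape[0]

    cv_models = getattr(model, "cv_models_", None)
    fold_of = getattr(model, "cv_fold_of_", None)
    use_oof = cv_models is not None and fold_of is not None and len(fold_of) == n

    def predict_rows(X_rows: np.ndarray, row_ids: np.ndarray) -> np.ndarray:
        if not use_oof:
            return model.predict(X_rows)
        out = np.empty(len(row_ids))
        folds = fold_of[row_ids]
        for f, m in enumerate(cv_models):
            mask = folds == f
            if mask.any():
                out[mask] = m.predict(X_rows[mask])
        return out

    # one shared set of subsamples: the intact-subsample RMSE is computed
    # once per subsample and reused as the baseline for every variable
    idx_sets = [rng.integers(0, n, size=n)
                for _ in range(config.n_importance_subsamples)]
    base = np.array(
        [
            np.sqrt(np.mean((predict_rows(X[idx], idx) - y[idx]) ** 2))
            for idx in idx_sets
        ]
    )
    rows = []
    for k, name in enumerate(names):
        deltas = np.empty(config.n_importance_subsamples)
        for s, idx in enumerate(idx_sets):
            Xp = X[idx].copy()
            Xp[:, k] = rng.permutation(Xp[:, k])
            pert = float(np.sqrt(np.mean((predict_rows(Xp, idx) - y[idx]) ** 2)))
            deltas[s] = pert - base[s]
        rows.append(
            {"variable": name, "mean_delta_rmse": deltas.mean(),
             "sd_delta_rmse": deltas.std(ddof=1)}
        )
    table = pd.DataFrame(rows).sort_values(
        "mean_delta_rmse", ascending=False, ignore_index=True
    )
    table["rank"] = np.arange(1, len(table) + 1)
    return table


def partial_dependence(
    model: RandomForestRegressor,
    features: pd.DataFrame,
    variable: str,
    config: RFConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Average prediction as ``variable`` sweeps its observed 1st-99th pct range.

    Uses min(n_pd_observations, n) rows sampled without replacement; all
    other variables keep their observed values.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    names = getattr(model, "feature_names_", list(features.columns))
    if variable not in names:
        raise ValueError(f"{variable!r} is not a model feature")
    col = features[variable]
    if not np.issubdtype(col.dtype, np.number):
        raise ValueError(f"{variable!r} is not numeric")
    n = len(features)
    take = min(config.n_pd_observations, n)
    idx = rng.choice(n, size=take, replace=False)
    X = features.to_numpy(float)[idx]
    lo, hi = np.percentile(col.to_numpy(float), [1, 99])
    grid = np.linspace(lo, hi, config.n_pd_grid)
    k = names.index(variable)
    means = np.empty_like(grid)
    for g, val in enumerate(grid):
        Xg = X.copy()
        Xg[:, k] = val
        means[g] = model.predict(Xg).mean()
    return pd.DataFrame(
        {"variable": variable, "grid": grid, "mean_prediction": means}
    )


def fit_regional(
    features: pd.DataFrame,
    target: np.ndarray | pd.Series,
    region: np.ndarray | pd.Series,
    config: RFConfig,
) -> tuple[dict[int, tuple[FitMetrics, pd.DataFrame]], list[int]]:
    """Independent refits per region; under-populated regions are skipped.

    Returns ({region: (metrics, importance_table)}, skipped_regions).
    """
    region = np.asarray(region)
    y = np.asarray(target, dtype=float)
    results: dict[int, tuple[FitMetrics, pd.DataFrame]] = {}
    skipped: list[int] = []
    for reg in sorted(np.unique(region)):
        mask = region == reg
        if mask.sum() < config.cv_folds:
            logger.warning(
                "region %s has %d rows < cv_folds=%d; skipped",
                reg, int(mask.sum()), config.cv_folds,
            )
            skipped.append(int(reg))
            continue
        sub = features.loc[mask].reset_index(drop=True)
        model, metrics = fit_rf(sub, y[mask], config)
        imp = perturbation_importance(
            model, sub, y[mask], config,
            rng=np.random.default_rng([config.seed, int(reg)]),
        )
        results[int(reg)] = (metrics, imp)
    return results, skipped
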