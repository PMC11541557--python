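"""Gradient-boosted identification of bleaching drivers.

The workflow mirrors the standard boosted-regression-tree protocol in
ecology: a hyperparameter grid (learning rate 0.01-0.001, tree complexity
3-5, bag fraction 0.5) evaluated by 10-fold cross-validation with at least
1000 trees under squared-error loss; a global model over all candidate
metrics; model simplification under pairwise-correlation and
variance-inflation constraints plus a cross-validated drop rule; and
reporting of relative influence, partial-dependence curves with bootstrap
bands, pairwise interaction H statistics, and residuals.

LightGBM supplies the tree ensembles (tree complexity c maps to trees with
c splits: ``num_leaves = c + 1``, ``max_depth = c``); everything around the
ensembles - selection, screening, simplification, influence, diagnostics -
lives here.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict

import lightgbm as lgb
import numpy as np
import pandas as pd
from sklearn.model_selection import KFold

from .robust import (
    PDCurve,
    collinearity_screen,
    friedman_h,
    partial_dependence,
    partial_dependence_ci,
    vif_screen,
)

__all__ = [
    "ModelConfig",
    "GBMFit",
    "DriverModelResult",
    "fit_gbm",
    "relative_influence",
    "simplify_model",
    "predict_bleaching",
]


@dataclass
class ModelConfig:
    """Hyperparameters and protocol settings for the boosted-tree workflow."""

    learning_rates: tuple[float, ...] = (0.01, 0.005, 0.001)
    tree_complexities: tuple[int, ...] = (3, 4, 5)
    bag_fraction: float = 0.5
    min_trees: int = 1000
    max_trees: int = 2500
    k_folds: int = 10
    min_node: int = 10
    drop_tolerance: float = 0.005
    r_max: float = 0.6
    vif_max: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.bag_fraction <= 1.0:
            raise ValueError("bag_fraction must lie in (0, 1]")
        if self.min_trees < 1:
            raise ValueError("min_trees must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.max_trees < self.min_trees:
            raise ValueError(
                f"max_trees={self.max_trees} < min_trees={self.min_trees}: no "
                f"grid point can reach the minimum tree count; lower the "
                f"learning rate or raise max_trees"
            )


def _lgb_params(config: ModelConfig, lr: float, complexity: int) -> dict:
    return {
        "objective": "regression",
        "metric": "l2",
        "learning_rate": lr,
        "num_leaves": complexity + 1,
        "max_depth": complexity,
        "bagging_fraction": config.bag_fraction,
        "bagging_freq": 1,
        "feature_fraction": 1.0,
        "min_data_in_leaf": config.min_node,
        "verbosity": -1,
        "num_threads": 1,
        "deterministic": True,
        "force_row_wise": True,
        "seed": config.seed,
    }


def _early_stop_after_min(min_trees: int, patience: int = 120):
    """Stop a CV fold once past ``min_trees`` with no recent improvement.

    Unlike stock early stopping this never halts before the protocol's
    minimum tree count, so the CV deviance curve always covers the selection
    range [min_trees, max_trees].
    """
    best = [np.inf, 0]

    def cb(env):
        value = env.evaluation_result_list[0][2]
        if value < best[0] - 1e-12:
            best[0], best[1] = value, env.iteration
        if env.iteration >= min_trees and env.iteration - best[1] >= patience:
            raise lgb.callback.EarlyStopException(
                env.iteration, env.evaluation_result_list
            )

    cb.order = 30
    return cb


def _cv_curve(
    X: pd.DataFrame, y: np.ndarray, config: ModelConfig, lr: float, complexity: int
) -> tuple[np.ndarray, float]:
    """Mean validation squared error per boosting iteration, plus null deviance."""
    params = _lgb_params(config, lr, complexity)
    kf = KFold(n_splits=config.k_folds, shuffle=True, random_state=config.seed)
    curves = []
    null = []
    for train_idx, val_idx in kf.split(X):
        Xt, Xv = X.iloc[train_idx], X.iloc[val_idx]
        yt, yv = y[train_idx], y[val_idx]
        dtrain = lgb.Dataset(Xt, yt)
        dval = lgb.Dataset(Xv, yv, reference=dtrain)
        record: dict = {}
        lgb.train(
            params,
            dtrain,
            num_boost_round=config.max_trees,
            valid_sets=[dval],
            valid_names=["val"],
            callbacks=[
                lgb.record_evaluation(record),
                _early_stop_after_min(config.min_trees),
            ],
        )
        curves.append(np.asarray(record["val"]["l2"], dtype=float))
        null.append(np.mean((yv - yt.mean()) ** 2))
    # folds stop at different iterations; extend each flat past its stop point
    length = max(len(c) for c in curves)
    padded = [
        np.concatenate([c, np.full(length - len(c), c[-1])]) if len(c) < length else c
        for c in curves
    ]
    return np.mean(padded, axis=0), float(np.mean(null))


@dataclass
class GBMFit:
    """A fitted ensemble plus the cross-validation evidence that selected it."""

    booster: lgb.Booster
    feature_names: list[str]
    learning_rate: float
    complexity: int
    n_trees: int
    cv_deviance: float
    cv_null_deviance: float
    cv_r2: float
    config: ModelConfig

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in X.columns]
        if missing:
            raise KeyError(f"missing predictor(s): {missing}")
        return np.asarray(self.booster.predict(X[self.feature_names]))


def _fit_final(
    X: pd.DataFrame, y: np.ndarray, config: ModelConfig, lr: float, complexity: int, n_trees: int
) -> lgb.Booster:
    params = _lgb_params(config, lr, complexity)
    return lgb.train(params, lgb.Dataset(X, y), num_boost_round=n_trees)


def fit_gbm(
    X: pd.DataFrame,
    y: np.ndarray,
    config: ModelConfig | None = None,
    hyperparams: tuple[float, int] | None = None,
) -> GBMFit:
    """Fit a boosted ensemble with CV-based grid and tree-count selection.

    For every (learning rate, tree complexity) grid point the 10-fold CV
    deviance curve is computed; the grid point and iteration minimizing CV
    deviance subject to the tree count being at least ``min_trees`` is
    selected, and the final ensemble is refit on all rows. Deterministic
    given the config seed. ``hyperparams=(lr, complexity)`` restricts the
    grid to one point (used during model simplification so every refit
    reuses the globally selected hyperparameters).
    """
    config = config or ModelConfig()
    y = np.asarray(y, dtype=float)
    if X.isna().to_numpy().any() or np.isnan(y).any():
        raise ValueError("missing values in features or response")
    if len(X) < 5 * config.k_folds:
        raise ValueError(
            f"only {len(X)} rows for {config.k_folds}-fold cross-validation"
        )
    grid = (
        [hyperparams]
        if hyperparams is not None
        else [(lr, c) for lr in config.learning_rates for c in config.tree_complexities]
    )
    best = None
    for lr, complexity in grid:
        curve, null_dev = _cv_curve(X, y, config, lr, complexity)
        segment = curve[config.min_trees - 1 :]
        offset = int(np.argmin(segment))
        n_trees = config.min_trees + offset
        deviance = float(segment[offset])
        if best is None or deviance < best[0]:
            best = (deviance, null_dev, lr, complexity, n_trees)
    deviance, null_dev, lr, complexity, n_trees = best
    booster = _fit_final(X, y, config, lr, complexity, n_trees)
    return GBMFit(
        booster=booster,
        feature_names=list(X.columns),
        learning_rate=lr,
        complexity=complexity,
        n_trees=n_trees,
        cv_deviance=deviance,
        cv_null_deviance=null_dev,
        cv_r2=1.0 - deviance / null_dev,
        config=config,
    )


def relative_influence(fit: GBMFit) -> pd.Series:
    """Split-improvement relative influence per predictor, summing to 100."""
    gains = np.asarray(
        fit.booster.feature_importance(importance_type="gain"), dtype=float
    )
    total = gains.sum()
    if total <= 0:
        warnings.warn("model has no splits; influence undefined (all zeros)", stacklevel=2)
        return pd.Series(np.zeros(len(gains)), index=fit.feature_names)
    return pd.Series(100.0 * gains / total, index=fit.feature_names).sort_values(
        ascending=False
    )


@dataclass
class DriverModelResult:
    """Final simplified driver model and its diagnostics."""

    selected_predictors: list[str]
    relative_influence: pd.Series
    cv_r2: float
    n_trees: int
    learning_rate: float
    complexity: int
    fit: GBMFit
    pd_curves: dict[str, PDCurve]
    h_matrix: pd.DataFrame | None
    residuals: np.ndarray
    dropped_correlated: list[tuple[str, str, float]]
    dropped_vif: list[tuple[str, float]]
    dropped_cv: list[str]
    global_influence: pd.Series

    def report(self) -> dict:
        """JSON-serializable summary of the fitted driver model."""
        return {
            "selected_predictors": self.selected_predictors,
            "relative_influence": {
                k: round(float(v), 4) for k, v in self.relative_influence.items()
            },
            "cv_r2": round(float(self.cv_r2), 4),
            "n_trees": int(self.n_trees),
            "learning_rate": self.learning_rate,
            "tree_complexity": self.complexity,
            "h_matrix": (
                None
                if self.h_matrix is None
                else {
                    f"{a}:{b}": round(float(self.h_matrix.loc[a, b]), 4)
                    for a in self.h_matrix.index
                    for b in self.h_matrix.columns
                    if a < b
                }
            ),
            "dropped_correlated": [
                [a, b, round(r, 3)] for a, b, r in self.dropped_correlated
            ],
            "dropped_vif": [[a, round(v, 2)] for a, v in self.dropped_vif],
            "dropped_cv": self.dropped_cv,
        }


def simplify_model(
    X: pd.DataFrame,
    y: np.ndarray,
    config: ModelConfig | None = None,
    compute_h: bool = True,
    pd_n_boot: int = 0,
    pd_grid_points: int = 25,
) -> DriverModelResult:
    """Global fit, collinearity/VIF screening, and CV-guided simplification.

    Steps: (1) fit the global model on all candidate metrics; (2) rank
    predictors by relative influence; (3) apply the greedy correlation
    screen (|r| < r_max, influence-ranked) then the VIF screen (VIF <
    vif_max); (4) iteratively drop predictors whose removal costs at most
    ``drop_tolerance`` of CV-R2, trying candidates in ascending influence
    order and refitting after each drop; (5) refit the final model and
    attach partial-dependence curves (bootstrap bands when ``pd_n_boot`` >=
    100), the pairwise H matrix (unless disabled), and residuals.
    """
    config = config or ModelConfig()
    y = np.asarray(y, dtype=float)
    if X.shape[1] < 2:
        raise ValueError("need at least 2 candidate predictors")

    global_fit = fit_gbm(X, y, config)
    global_infl = relative_influence(global_fit)
    ranking = list(global_infl.index)

    kept, dropped_corr = collinearity_screen(X, config.r_max, ranking)
    kept, dropped_vif = vif_screen(X[kept], config.vif_max)
    if not kept:
        raise ValueError("all predictors eliminated by the screens")
    hp = (global_fit.learning_rate, global_fit.complexity)

    current = list(kept)
    fit = fit_gbm(X[current], y, config, hyperparams=hp)
    dropped_cv: list[str] = []
    while len(current) > 1:
        order = list(relative_influence(fit).index)[::-1]  # ascending influence
        dropped_this_round = False
        for cand in order:
            reduced = [c for c in current if c != cand]
            trial = fit_gbm(X[reduced], y, config, hyperparams=hp)
            if fit.cv_r2 - trial.cv_r2 <= config.drop_tolerance:
                current, fit = reduced, trial
                dropped_cv.append(cand)
                dropped_this_round = True
                break
        if not dropped_this_round:
            break

    infl = relative_influence(fit)
    selected = list(infl.index)
    residuals = y - fit.predict(X)

    pd_curves: dict[str, PDCurve] = {}
    for name in selected:
        if pd_n_boot >= 100:
            def refitter(Xb, yb, _hp=hp):
                return fit_gbm(Xb, np.asarray(yb), config, hyperparams=_hp).predict
            pd_curves[name] = partial_dependence_ci(
                refitter,
                X[selected],
                y,
                name,
                n_boot=pd_n_boot,
                seed=config.seed,
                grid_points=pd_grid_points,
                base_predict=fit.predict,
            )
        else:
            grid, est = partial_dependence(fit.predict, X[selected], name, pd_grid_points)
            pd_curves[name] = PDCurve(
                predictor=name,
                grid=grid,
                estimate=est,
                lower=None,
                upper=None,
                rug=X[name].to_numpy(dtype=float),
            )

    h_matrix = None
    if compute_h and len(selected) >= 2:
        h_matrix = pd.DataFrame(0.0, index=selected, columns=selected)
        for i, a in enumerate(selected):
            for b in selected[i + 1 :]:
                h = friedman_h(fit.predict, X[selected], (a, b), seed=config.seed)
                h_matrix.loc[a, b] = h_matrix.loc[b, a] = h

    return DriverModelResult(
        selected_predictors=selected,
        relative_influence=infl,
        cv_r2=fit.cv_r2,
        n_trees=fit.n_trees,
        learning_rate=fit.learning_rate,
        complexity=fit.complexity,
        fit=fit,
        pd_curves=pd_curves,
        h_matrix=h_matrix,
        residuals=residuals,
        dropped_correlated=dropped_corr,
        dropped_vif=dropped_vif,
        dropped_cv=dropped_cv,
        global_influence=global_infl,
    )


def predict_bleaching(
    model: GBMFit | DriverModelResult, metrics: pd.DataFrame
) -> tuple[np.ndarray, np.ndarray]:
    """Predict bleaching severity for new metric rows.

    Returns ``(clipped, raw)``: the ensemble prediction clipped to the
    reporting scale [0, 100], and the raw value. Column order of the input
    is irrelevant; a missing predictor raises a KeyError naming it.
    """
    fit = model.fit if isinstance(model, DriverModelResult) else model
    raw = fit.predict(metrics)
    return np.clip(raw, 0.0, 100.0), raw
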