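"""Gradient-boosted benefit regression with Boruta-SHAP feature selection.

The regression task maps pre-randomization features to the individualized
log HR labels produced by :mod:`phenoadapt.effects`.  Labels are 95%
winsorized before fitting.  Feature selection follows the Boruta-SHAP
scheme: each feature is permuted into a "shadow" copy, a boosted model is
fitted on the combined matrix, and a feature scores a hit whenever its
mean absolute SHAP importance exceeds the best shadow importance; after
20 iterations, features whose hit count is significantly above the
Binomial(20, 1/2) null (two-sided 0.05) are retained.  SHAP importances
use xgboost's exact tree-path attribution (``pred_contribs``).

Hyperparameters are tuned by sampling 25 configurations (without
replacement) from a fixed grid, each trained with early stopping
(patience 20, at most 1000 rounds) against validation RMSE on an inner
80/20 split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import xgboost as xgb
from scipy import stats

from .core import SchemaError, ValidationError
from .effects import BenefitLabels

LABEL_WINSOR_LIMITS = (2.5, 97.5)

#: the hyperparameter grid searched (25 random draws)
PARAM_GRID = {
    "learning_rate": [0.01, 0.05, 0.10, 0.15],
    "max_depth": [3, 5, 6, 10, 15, 20],
    "subsample": [round(v, 1) for v in np.arange(0.5, 1.01, 0.1)],
    "colsample_bytree": [round(v, 1) for v in np.arange(0.4, 1.01, 0.1)],
    "colsample_bylevel": [round(v, 1) for v in np.arange(0.4, 1.01, 0.1)],
    "n_estimators": [100, 500, 1000],
}

N_GRID_DRAWS = 25
N_BORUTA_ITERATIONS = 20
EARLY_STOPPING_ROUNDS = 20
MAX_BOOST_ROUNDS = 1000
#: boosting rounds of the selection-probe model (a shallow probe suffices
#: for comparing real vs shadow importances)
N_SELECTION_ROUNDS = 50


def winsorize_labels(labels: BenefitLabels) -> tuple[BenefitLabels, tuple[float, float]]:
    """Clip labels at their 2.5th/97.5th percentiles; returns clipped + bounds."""
    valid = labels.valid()
    if len(valid) < 20:
        raise ValidationError("need >=20 labels to winsorize")
    lo, hi = np.percentile(valid.to_numpy(float), LABEL_WINSOR_LIMITS)
    clipped = labels.loghr.clip(lower=lo, upper=hi)
    return BenefitLabels(loghr=clipped, n_dropped=labels.n_dropped), (float(lo), float(hi))


@dataclass
class SelectionReport:
    selected: list[str]
    n_iterations: int
    shadow_max_importance: list[float]
    hit_counts: dict


def _hit_threshold(n_iter: int, alpha: float = 0.05) -> int:
    """Smallest hit count rejecting Binomial(n, 1/2) two-sided at alpha."""
    for h in range(n_iter // 2 + 1, n_iter + 1):
        if 2.0 * stats.binom.sf(h - 1, n_iter, 0.5) < alpha:
            return h
    return n_iter + 1


def _mean_abs_shap(booster: xgb.Booster, dmat: xgb.DMatrix) -> np.ndarray:
    contribs = booster.predict(dmat, pred_contribs=True)
    return np.abs(contribs[:, :-1]).mean(axis=0)  # last column is the bias term


_SELECTION_PARAMS = {
    "objective": "reg:squarederror",
    "learning_rate": 0.1,
    "max_depth": 3,
    "tree_method": "hist",
    "nthread": 1,
    "verbosity": 0,
}


def boruta_shap_select(X: pd.DataFrame, y, seed: int, n_iterations: int = N_BORUTA_ITERATIONS) -> SelectionReport:
    """All-relevant feature selection against permuted shadow features."""
    if X.shape[1] < 2:
        raise ValidationError("need >=2 candidate features")
    if len(X) < 50:
        raise ValidationError("need >=50 rows for selection")
    y = np.asarray(y, float)
    feats = list(X.columns)
    hits = {f: 0 for f in feats}
    shadow_max = []
    rng = np.random.default_rng(seed)
    Xv = X.to_numpy(float)
    for it in range(n_iterations):
        shadow = Xv[rng.permutation(len(Xv))[:, None], np.arange(Xv.shape[1])]
        combined = np.hstack([Xv, shadow])
        dmat = xgb.DMatrix(combined, label=y)
        params = dict(_SELECTION_PARAMS, seed=int(rng.integers(2**31 - 1)))
        booster = xgb.train(params, dmat, num_boost_round=N_SELECTION_ROUNDS)
        imp = _mean_abs_shap(booster, dmat)
        orig, shad = imp[: len(feats)], imp[len(feats):]
        thr = float(shad.max())
        shadow_max.append(thr)
        for f, v in zip(feats, orig):
            if v > thr:
                hits[f] += 1
    cutoff = _hit_threshold(n_iterations)
    selected = [f for f in feats if hits[f] >= cutoff]
    return SelectionReport(
        selected=selected,
        n_iterations=n_iterations,
        shadow_max_importance=shadow_max,
        hit_counts=hits,
    )


@dataclass
class BenefitModel:
    """Fitted feature-selection + boosted-regressor bundle."""

    selection: SelectionReport | None
    booster: xgb.Booster | None
    best_params: dict
    train_rmse: float
    valid_rmse: float
    label_bounds: tuple[float, float] | None
    feature_names: list[str]
    best_iteration: int = 0
    constant_value: float | None = None  # set for degenerate (zero-variance) labels


def _sample_grid(rng: np.random.Generator, n_draws: int) -> list[dict]:
    keys = list(PARAM_GRID)
    sizes = [len(PARAM_GRID[k]) for k in keys]
    total = int(np.prod(sizes))
    idx = rng.choice(total, size=min(n_draws, total), replace=False)
    combos = []
    for flat in idx:
        combo = {}
        for k, s in zip(keys, sizes):
            combo[k] = PARAM_GRID[k][flat % s]
            flat //= s
    # note: unravel order is fixed by the key order above
        combos.append(combo)
    return combos


def fit_benefit_model(
    X: pd.DataFrame,
    y,
    seed: int,
    selection: SelectionReport | None = None,
    label_bounds: tuple[float, float] | None = None,
    n_grid: int = N_GRID_DRAWS,
) -> BenefitModel:
    """Tune and fit the boosted benefit regressor on selected features."""
    y = np.asarray(y, float)
    if len(X) < 50:
        raise ValidationError("need >=50 rows to fit the benefit model")
    feats = selection.selected if selection is not None else list(X.columns)
    if not feats:
        raise ValidationError("empty feature selection")
    Xs = X[feats]

    if np.std(y) == 0.0:
        warnings.warn("degenerate labels (zero variance); returning constant predictor")
        return BenefitModel(
            selection=selection,
            booster=None,
            best_params={},
            train_rmse=0.0,
            valid_rmse=0.0,
            label_bounds=label_bounds,
            feature_names=feats,
            constant_value=float(y[0]),
        )

    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(Xs))
    n_valid = max(1, int(round(0.2 * len(Xs))))
    valid_idx, train_idx = perm[:n_valid], perm[n_valid:]
    dtrain = xgb.DMatrix(Xs.iloc[train_idx].to_numpy(float), label=y[train_idx])
    dvalid = xgb.DMatrix(Xs.iloc[valid_idx].to_numpy(float), label=y[valid_idx])

    best = None
    for combo in _sample_grid(rng, n_grid):
        params = {
            "objective": "reg:squarederror",
            "eval_metric": "rmse",
            "tree_method": "hist",
            "nthread": 1,
            "verbosity": 0,
            "seed": seed,
            **{k: v for k, v in combo.items() if k != "n_estimators"},
        }
        rounds = min(combo["n_estimators"], MAX_BOOST_ROUNDS)
        evals_result: dict = {}
        booster = xgb.train(
            params,
            dtrain,
            num_boost_round=rounds,
            evals=[(dtrain, "train"), (dvalid, "valid")],
            early_stopping_rounds=EARLY_STOPPING_ROUNDS,
            evals_result=evals_result,
            verbose_eval=False,
        )
        best_it = booster.best_iteration
        vrmse = evals_result["valid"]["rmse"][best_it]
        trmse = evals_result["train"]["rmse"][best_it]
        if best is None or vrmse < best[0]:
            best = (vrmse, trmse, combo, booster, best_it)

    vrmse, trmse, combo, booster, best_it = best
    return BenefitModel(
        selection=selection,
        booster=booster,
        best_params=combo,
        train_rmse=float(trmse),
        valid_rmse=float(vrmse),
        label_bounds=label_bounds,
        feature_names=feats,
        best_iteration=int(best_it),
    )


def predict_benefit(model: BenefitModel, X_new: pd.DataFrame) -> np.ndarray:
    """Predicted individualized log HR per row (name-based feature binding)."""
    missing = [f for f in model.feature_names if f not in X_new.columns]
    if missing:
        raise SchemaError(f"missing selected features: {missing}")
    if model.constant_value is not None:
        return np.full(len(X_new), model.constant_value)
    dmat = xgb.DMatrix(X_new[model.feature_names].to_numpy(float))
    pred = model.booster.predict(dmat, iteration_range=(0, model.best_iteration + 1))
    if not np.isfinite(pred).all():
        raise ValidationError("non-finite predictions")
    return pred
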