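"""Leakage-free baseline-covariate preprocessing.

The pipeline is fitted on a training subset only and then applied,
frozen, to any conforming dataset.  Fitted steps, in order:

1. drop covariates with more than 10% missingness;
2. among continuous pairs with \\|Pearson r\\| > 0.9, iteratively drop the
   member with the largest mean absolute correlation against all other
   remaining continuous covariates (pairs scanned in descending \\|r\\|,
   correlations recomputed after each drop);
3. 95% winsorization of continuous covariates (clip at the 2.5th/97.5th
   percentiles, linear-interpolation percentile convention);
4. drop zero-variance factor (binary/categorical) covariates;
5. iterative random-forest imputation, at most five rounds, seeded;
6. one-hot encoding of categoricals (full encoding, one indicator per
   level seen at fit; unseen levels at transform map to all-zero rows).

Transforms expose two views: the fully numeric one-hot matrix consumed by
the boosted-tree stages, and a mixed-type "Gower frame" (winsorized,
imputed, original category levels) consumed by the phenomap, which
compares categoricals on their original levels rather than indicator
columns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.experimental import enable_iterative_imputer  # noqa: F401
from sklearn.impute import IterativeImputer

from .core import BINARY, CATEGORICAL, CONTINUOUS, Covariate, SchemaError, TrialDataset

MISSING_DROP_THRESHOLD = 0.10
COLLINEARITY_THRESHOLD = 0.9
WINSOR_LIMITS = (2.5, 97.5)


class PipelineError(RuntimeError):
    pass


@dataclass
class TransformedData:
    """Output of :func:`apply_preprocess` for one dataset."""

    ids: np.ndarray
    X: pd.DataFrame  # one-hot encoded, fully numeric, no missing
    gower_frame: pd.DataFrame  # winsorized + imputed, original category levels
    kinds: dict  # gower-frame column -> covariate kind


@dataclass
class PreprocessFit:
    """Frozen state of the fitted pipeline."""

    schema: tuple[Covariate, ...]
    kept_features: list[str]
    dropped_missing: list[str]
    dropped_collinear: list[str]
    dropped_zero_var: list[str]
    winsor_bounds: dict  # continuous name -> (lower, upper)
    encoder_map: dict  # categorical name -> level list seen at fit
    level_codes: dict = field(default_factory=dict)  # categorical name -> level -> code
    imputer: IterativeImputer | None = None
    seed: int = 0


def _collinear_drops(cont: pd.DataFrame) -> list[str]:
    """Iteratively drop one member of each |r| > 0.9 continuous pair."""
    dropped: list[str] = []
    cols = [c for c in cont.columns]
    while len(cols) >= 2:
        corr = cont[cols].corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        i, j = np.unravel_index(np.nanargmax(corr.values), corr.shape)
        if not corr.values[i, j] > COLLINEARITY_THRESHOLD:
            break
        a, b = corr.index[i], corr.columns[j]
        # drop the member with the larger mean |r| against all others
        mean_r = corr.mean(axis=1)  # zero diagonal; constant scale, ranks unchanged
        victim = a if mean_r[a] >= mean_r[b] else b
        dropped.append(victim)
        cols.remove(victim)
    return dropped


def _encode_numeric(fit: PreprocessFit, cov: pd.DataFrame) -> np.ndarray:
    """Kept covariates as a numeric matrix (categoricals ordinal-coded)."""
    cols = []
    for name in fit.kept_features:
        kind = _kind(fit, name)
        if kind == CATEGORICAL:
            codes = fit.level_codes[name]
            cols.append(cov[name].map(codes).to_numpy(float))
        else:
            vals = cov[name].to_numpy(float)
            if kind == CONTINUOUS:
                lo, hi = fit.winsor_bounds[name]
                vals = np.clip(vals, lo, hi)
            cols.append(vals)
    return np.column_stack(cols)


def _kind(fit: PreprocessFit, name: str) -> str:
    for c in fit.schema:
        if c.name == name:
            return c.kind
    raise SchemaError(f"unknown covariate {name!r}")


def fit_preprocess(train: TrialDataset, seed: int = 0) -> PreprocessFit:
    """Fit the pipeline on the training subset only."""
    if train.n < 20:
        raise PipelineError("need >=20 participants to fit preprocessing")
    cov = train.covariates()
    by_kind = {c.name: c for c in train.schema}

    miss = cov.isna().mean()
    dropped_missing = [c for c in cov.columns if miss[c] > MISSING_DROP_THRESHOLD]
    keep = [c for c in cov.columns if c not in dropped_missing]

    cont = [c for c in keep if by_kind[c].kind == CONTINUOUS]
    dropped_collinear = _collinear_drops(cov[cont]) if len(cont) >= 2 else []
    keep = [c for c in keep if c not in dropped_collinear]

    winsor_bounds = {}
    for c in keep:
        if by_kind[c].kind == CONTINUOUS:
            vals = cov[c].dropna().to_numpy(float)
            lo, hi = np.percentile(vals, WINSOR_LIMITS)  # linear interpolation
            winsor_bounds[c] = (float(lo), float(hi))

    dropped_zero_var = []
    for c in keep:
        if by_kind[c].kind in (BINARY, CATEGORICAL):
            if cov[c].dropna().nunique() < 2:
                dropped_zero_var.append(c)
    keep = [c for c in keep if c not in dropped_zero_var]
    if not keep:
        raise PipelineError("all covariates dropped during preprocessing")

    encoder_map, level_codes = {}, {}
    for c in keep:
        if by_kind[c].kind == CATEGORICAL:
            seen = [lv for lv in by_kind[c].levels if lv in set(cov[c].dropna())]
            encoder_map[c] = seen
            level_codes[c] = {lv: float(i) for i, lv in enumerate(seen)}

    fit = PreprocessFit(
        schema=train.schema,
        kept_features=keep,
        dropped_missing=dropped_missing,
        dropped_collinear=dropped_collinear,
        dropped_zero_var=dropped_zero_var,
        winsor_bounds=winsor_bounds,
        encoder_map=encoder_map,
        level_codes=level_codes,
        seed=seed,
    )

    base = RandomForestRegressor(n_estimators=10, max_depth=8, random_state=seed, n_jobs=1)
    imputer = IterativeImputer(
        estimator=base,
        max_iter=5,
        random_state=seed,
        sample_posterior=False,
        keep_empty_features=True,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # <=5 rounds rarely meets sklearn's tol
        imputer.fit(_encode_numeric(fit, cov))
    fit.imputer = imputer
    return fit


def apply_preprocess(fit: PreprocessFit, ds: TrialDataset) -> TransformedData:
    """Apply the frozen pipeline; deterministic given fit and data."""
    cov = ds.covariates()
    for name in fit.kept_features:
        if name not in cov.columns:
            raise SchemaError(f"covariate {name!r} present at fit but absent now")
    M = _encode_numeric(fit, cov)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        M = fit.imputer.transform(M)

    gower = {}
    kinds = {}
    X_cols = {}
    for j, name in enumerate(fit.kept_features):
        kind = _kind(fit, name)
        kinds[name] = kind
        col = M[:, j]
        if kind == CONTINUOUS:
            lo, hi = fit.winsor_bounds[name]
            col = np.clip(col, lo, hi)  # imputed values honor the train bounds
            gower[name] = col
            X_cols[name] = col
        elif kind == BINARY:
            col = np.clip(np.round(col), 0.0, 1.0)
            gower[name] = col
            X_cols[name] = col
        else:
            levels = fit.encoder_map[name]
            codes = np.clip(np.round(col), 0, len(levels) - 1).astype(int)
            labels = np.asarray(levels, dtype=object)[codes]
            # rows whose raw level was unseen at fit stay unseen in X
            raw = cov[name].to_numpy(object)
            seen = pd.Series(raw).isin(levels).to_numpy() | pd.isna(raw)
            gower[name] = labels
            for i, lv in enumerate(levels):
                X_cols[f"{name}={lv}"] = ((labels == lv) & seen).astype(float)

    gower_frame = pd.DataFrame(gower, index=cov.index)
    X = pd.DataFrame(X_cols, index=cov.index)
    if X.isna().any().any():
        raise PipelineError("missing values survived imputation")
    return TransformedData(ids=cov.index.to_numpy(), X=X, gower_frame=gower_frame, kinds=kinds)
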