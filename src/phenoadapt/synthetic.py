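"""Synthetic two-arm RCT generator with known ground-truth treatment effects.

The generator emulates a large cardiovascular-outcomes trial: 1:1
randomization, uniform accrual over a multi-year window, exponential
(constant-hazard) event times with administrative censoring at a fixed
per-participant follow-up horizon plus optional random censoring, mixed
continuous/binary/categorical baseline covariates, and a configurable
covariate-dependent treatment-effect term.  Because the individual log
hazard ratio is known by construction, every downstream stage has a
parameter-recovery oracle (:func:`true_individual_loghr`).

The hazard model for participant *i* in arm :math:`a_i \\in \\{0, 1\\}` is

.. math:: \\lambda_i = \\lambda_0 \\exp\\{a_i (\\beta_{ATE} + \\sum_k \\gamma_k x_{ik})\\}

with :math:`\\lambda_0` calibrated in closed form so that the control-arm
event proportion at the follow-up horizon equals ``control_rate``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import (
    ARM_CONTROL,
    ARM_INTERVENTION,
    BINARY,
    CATEGORICAL,
    CONTINUOUS,
    Covariate,
    TrialDataset,
    ValidationError,
)


@dataclass
class SyntheticConfig:
    """Generating conditions for one synthetic trial.

    ``hte_coeffs`` are per-feature interaction log-HR coefficients: a
    negative coefficient on a binary feature means carriers benefit more
    from the intervention.  ``censor_rate`` is the random-censoring hazard
    as a fraction of the control event hazard.
    """

    n_total: int = 4000
    accrual_days: float = 2899.0  # multi-year enrollment window
    followup_days: float = 1825.0  # 5-year administrative horizon
    n_continuous: int = 6
    n_binary: int = 4
    n_categorical: int = 2
    n_levels: int = 3
    control_rate: float = 0.118
    ate_loghr: float = float(np.log(0.76))
    hte_features: tuple[str, ...] = ()
    hte_coeffs: tuple[float, ...] = ()
    censor_rate: float = 0.15
    missing_frac: float = 0.0
    binary_prevalence: tuple[float, ...] | None = None  # default: U(0.2, 0.5) per feature
    corr: float = 0.0  # pairwise Gaussian-copula correlation of continuous covariates
    n_safety_tiers: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.control_rate < 1.0:
            raise ValidationError("control_rate must be in (0, 1)")
        if not 0.0 <= self.missing_frac <= 0.5:
            raise ValidationError("missing_frac must be in [0, 0.5]")
        if len(self.hte_features) != len(self.hte_coeffs):
            raise ValidationError("hte_features and hte_coeffs must align")
        names = {c.name for c in self.schema()}
        unknown = set(self.hte_features) - names
        if unknown:
            raise ValidationError(f"unknown hte features {sorted(unknown)}")

    def schema(self) -> tuple[Covariate, ...]:
        levels = tuple(f"L{j}" for j in range(self.n_levels))
        out = [Covariate(f"x{k}", CONTINUOUS) for k in range(self.n_continuous)]
        out += [Covariate(f"b{k}", BINARY) for k in range(self.n_binary)]
        out += [Covariate(f"c{k}", CATEGORICAL, levels) for k in range(self.n_categorical)]
        return tuple(out)


def _control_hazard(cfg: SyntheticConfig) -> float:
    # With random-censoring hazard c = censor_rate * lam, the event
    # proportion by horizon H is (1 - exp(-lam (1+cr) H)) / (1 + cr);
    # invert for lam in closed form.
    cr, p, H = cfg.censor_rate, cfg.control_rate, cfg.followup_days
    x = p * (1.0 + cr)
    if x >= 1.0:
        raise ValidationError("control_rate too high for the given censor_rate")
    return -np.log1p(-x) / ((1.0 + cr) * H)


def _hte_values(cfg: SyntheticConfig, cov: pd.DataFrame) -> np.ndarray:
    """Numeric value of each HTE feature per participant (n x k)."""
    kinds = {c.name: c for c in cfg.schema()}
    cols = []
    for name in cfg.hte_features:
        c = kinds[name]
        if c.kind == CATEGORICAL:
            # indicator of the last level carries the interaction
            cols.append((cov[name] == c.levels[-1]).to_numpy(float))
        else:
            cols.append(cov[name].to_numpy(float))
    if not cols:
        return np.zeros((len(cov), 0))
    return np.column_stack(cols)


def generate_trial(cfg: SyntheticConfig) -> TrialDataset:
    """Simulate one trial under ``cfg``; deterministic for a fixed seed."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_total
    schema = cfg.schema()

    # baseline covariates
    cov = {}
    if cfg.n_continuous:
        if cfg.corr:
            S = np.full((cfg.n_continuous, cfg.n_continuous), cfg.corr)
            np.fill_diagonal(S, 1.0)
            Z = rng.multivariate_normal(np.zeros(cfg.n_continuous), S, size=n, method="cholesky")
        else:
            Z = rng.standard_normal((n, cfg.n_continuous))
        for k in range(cfg.n_continuous):
            cov[f"x{k}"] = Z[:, k]
    if cfg.binary_prevalence is not None:
        bin_p = np.asarray(cfg.binary_prevalence, float)
        if len(bin_p) != cfg.n_binary:
            raise ValidationError("binary_prevalence must match n_binary")
    else:
        bin_p = rng.uniform(0.2, 0.5, size=cfg.n_binary)
    for k in range(cfg.n_binary):
        cov[f"b{k}"] = (rng.random(n) < bin_p[k]).astype(float)
    levels = [f"L{j}" for j in range(cfg.n_levels)]
    for k in range(cfg.n_categorical):
        cov[f"c{k}"] = rng.choice(levels, size=n)
    cov = pd.DataFrame(cov)

    arm = (rng.random(n) < 0.5).astype(int)  # 1:1 randomization
    lam0 = _control_hazard(cfg)
    eta = arm * (cfg.ate_loghr + _hte_values(cfg, cov) @ np.asarray(cfg.hte_coeffs, float))
    lam = lam0 * np.exp(eta)

    T = rng.exponential(1.0 / lam)
    if cfg.censor_rate > 0:
        C = rng.exponential(1.0 / (cfg.censor_rate * lam0), size=n)
    else:
        C = np.full(n, np.inf)
    H = cfg.followup_days
    time = np.minimum.reduce([T, C, np.full(n, H)])
    event = (T <= np.minimum(C, H)).astype(int)
    time = np.maximum(time, 1e-6)

    t = pd.DataFrame(
        {
            "id": [f"P{i:06d}" for i in range(n)],
            "arm": np.where(arm == 1, ARM_INTERVENTION, ARM_CONTROL),
            "accrual_time": rng.uniform(0.0, cfg.accrual_days, size=n),
            "primary_time": time,
            "primary_event": event,
        }
    )

    # hierarchical safety tiers: arm-neutral exponential processes
    # (tier 0 = all-cause mortality, later tiers = non-fatal events)
    tier_props = np.linspace(0.05, 0.12, max(cfg.n_safety_tiers, 1))
    for k in range(cfg.n_safety_tiers):
        lam_k = -np.log1p(-tier_props[k]) / H
        Tk = rng.exponential(1.0 / lam_k, size=n)
        t[f"safety_{k}_time"] = np.maximum(np.minimum(Tk, H), 1e-6)
        t[f"safety_{k}_event"] = (Tk <= H).astype(int)

    # MCAR missingness per covariate
    if cfg.missing_frac > 0:
        for c in schema:
            mask = rng.random(n) < cfg.missing_frac
            cov.loc[mask, c.name] = np.nan if c.kind != CATEGORICAL else None

    for c in schema:
        t[c.name] = cov[c.name].to_numpy()

    return TrialDataset(t, schema, cfg.n_safety_tiers)


def true_individual_loghr(cfg: SyntheticConfig, ds: TrialDataset) -> pd.Series:
    """Ground-truth individual log HR (intervention vs control) per participant.

    Computed from the dataset's covariates as
    ``ate_loghr + sum_k hte_coeffs[k] * x_k``; raises if any HTE feature is
    missing (the oracle needs pre-missingness values).
    """
    cov = ds.covariates()
    for name in cfg.hte_features:
        if cov[name].isna().any():
            raise ValidationError(f"hte feature {name!r} has missing values; oracle undefined")
    vals = _hte_values(cfg, cov.reset_index(drop=True))
    lhr = cfg.ate_loghr + vals @ np.asarray(cfg.hte_coeffs, float)
    return pd.Series(lhr, index=cov.index, name="true_loghr")


def shuffle_covariates(ds: TrialDataset, seed: int) -> TrialDataset:
    """Negative control: permute whole covariate rows across participants.

    Arms, accrual and outcomes are untouched, so the average treatment
    effect is preserved while covariate-outcome links are destroyed.
    """
    if ds.n == 0:
        raise ValidationError("empty dataset")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ds.n)
    t = ds.table.copy()
    names = ds.covariate_names
    t[names] = ds.table[names].to_numpy()[perm]
    return TrialDataset(t, ds.schema, ds.n_safety_tiers)
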