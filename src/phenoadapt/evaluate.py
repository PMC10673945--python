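"""Outcome analyses, run summaries, and rank-stability machinery.

Outcome side: unadjusted arm-only Cox hazard ratios, two-sample log-rank
comparisons by enrollment period, arm-balance chi-square checks, final
population composition, and the unmatched win ratio over a prioritized
hierarchy of safety outcomes (all-cause mortality first).

Stability side: the predicted-benefit *rank concordance* across repeated
random splits.  For a pair of participants (A, B), let C>= count the
iterations ranking A as the stronger responder and C'>= the iterations
ranking B higher (only iterations with both in the test set count).  The
pair concordance is 1 when the counts are equal and max/min of the two
counts otherwise; pairs always ordered the same way (a zero minority
count) get a +0.5 continuity correction to both counts, and pairs never
jointly observed are excluded.  The average concordance odds is the mean
of the defined upper-triangle entries, with a participant-level
percentile bootstrap CI.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines.statistics import logrank_test
from scipy import stats

from .core import ARM_CONTROL, ARM_INTERVENTION, TrialDataset, ValidationError
from .effects import weighted_cox


# -- primary outcome -------------------------------------------------------


def primary_cox_hr(ds: TrialDataset, cut: float | None = None) -> tuple[float, float]:
    """Unweighted arm-only Cox fit; returns (HR, Wald p)."""
    d = ds.censored_at(cut) if cut is not None else ds
    t = d.table["primary_time"].to_numpy(float)
    e = d.table["primary_event"].to_numpy(int)
    x = d.arm_indicator()
    res = weighted_cox(t, e, x, np.ones_like(t, float))
    if not res.converged:
        raise ValidationError("primary Cox fit did not converge")
    z = res.loghr / res.se
    return float(np.exp(res.loghr)), float(2.0 * stats.norm.sf(abs(z)))


# -- win ratio -------------------------------------------------------------


@dataclass(frozen=True)
class WinRatioResult:
    wins: int
    losses: int
    ties: int
    wr: float
    ci_low: float
    ci_high: float
    flagged: bool  # CI undefined (zero losses) or all ties


def win_ratio(ds: TrialDataset, cut: float | None = None) -> WinRatioResult:
    """Unmatched pairwise win ratio over the safety-outcome hierarchy.

    Every intervention-control pair descends the tiers: on a tier the
    intervention member wins if the control member has the earlier
    observed event, loses in the mirror case, and passes to the next tier
    otherwise.  CI by the log-scale normal approximation.
    """
    if ds.n_safety_tiers < 1:
        raise ValidationError("win ratio needs >=1 safety tier")
    d = ds.censored_at(cut) if cut is not None else ds
    arm = d.arm_indicator()
    if arm.sum() == 0 or arm.sum() == len(arm):
        raise ValidationError("both arms must be nonempty")
    i_idx, j_idx = np.flatnonzero(arm == 1), np.flatnonzero(arm == 0)
    wins = np.zeros((len(i_idx), len(j_idx)), dtype=bool)
    losses = np.zeros_like(wins)
    undecided = np.ones_like(wins)
    for t_arr, e_arr in d.safety_outcomes():
        ti, ei = t_arr[i_idx][:, None], e_arr[i_idx][:, None].astype(bool)
        tj, ej = t_arr[j_idx][None, :], e_arr[j_idx][None, :].astype(bool)
        w = undecided & ej & (tj < ti)
        l = undecided & ei & (ti < tj)
        wins |= w
        losses |= l
        undecided &= ~(w | l)
    n_w, n_l = int(wins.sum()), int(losses.sum())
    n_t = int(undecided.sum())
    if n_l == 0 or n_w == 0:
        wr = np.inf if (n_w > 0 and n_l == 0) else (0.0 if n_w == 0 and n_l > 0 else 1.0)
        return WinRatioResult(n_w, n_l, n_t, wr, np.nan, np.nan, True)
    wr = n_w / n_l
    # log-scale normal CI with the first-order two-sample U-statistic
    # (projection) variance — pairs sharing a participant are correlated
    m, n = wins.shape
    tw, tl = n_w / (m * n), n_l / (m * n)
    rw, cw = wins.mean(axis=1), wins.mean(axis=0)
    rl, cl = losses.mean(axis=1), losses.mean(axis=0)
    var_w = np.var(rw, ddof=1) / m + np.var(cw, ddof=1) / n
    var_l = np.var(rl, ddof=1) / m + np.var(cl, ddof=1) / n
    cov_wl = (
        np.cov(rw, rl, ddof=1)[0, 1] / m + np.cov(cw, cl, ddof=1)[0, 1] / n
    )
    se_log = np.sqrt(max(var_w / tw**2 + var_l / tl**2 - 2 * cov_wl / (tw * tl), 0.0))
    z = 1.959963984540054
    lo = wr * np.exp(-z * se_log)
    hi = wr * np.exp(z * se_log)
    return WinRatioResult(n_w, n_l, n_t, float(wr), float(lo), float(hi), False)


# -- balance & composition -------------------------------------------------


def balance_and_composition(
    ds_final: TrialDataset, ds_original: TrialDataset, strata: list[str] | None = None
) -> tuple[float, pd.DataFrame]:
    """Arm-balance chi-square p and demographic-stratum shares final vs original.

    ``strata`` are binary covariate names (share = mean of the indicator);
    defaults to every binary covariate in the schema.
    """
    if ds_final.n == 0 or ds_original.n == 0:
        raise ValidationError("empty dataset")
    table = np.array(
        [
            [(ds_final.table["arm"] == a).sum() for a in (ARM_INTERVENTION, ARM_CONTROL)],
            [(ds_original.table["arm"] == a).sum() for a in (ARM_INTERVENTION, ARM_CONTROL)],
        ]
    )
    _, p, _, _ = stats.chi2_contingency(table)
    if strata is None:
        strata = [c.name for c in ds_final.schema if c.kind == "binary"]
    rows = {}
    for name in strata:
        rows[name] = {
            "final_share": float(ds_final.table[name].mean()),
            "original_share": float(ds_original.table[name].mean()),
        }
    return float(p), pd.DataFrame.from_dict(rows, orient="index")


# -- concordance -----------------------------------------------------------


def pair_concordance(counts_ge_ij: int, counts_ge_ji: int) -> float | None:
    """Concordance ratio for one pair; None when the pair was never observed.

    Equal counts give 1; otherwise the majority/minority count ratio, with
    a +0.5 continuity correction to both counts when the minority count is
    zero (the raw ratio is undefined there).
    """
    a, b = counts_ge_ij, counts_ge_ji
    if a < 0 or b < 0:
        raise ValidationError("counts must be nonnegative")
    if a == 0 and b == 0:
        return None
    if a == b:
        return 1.0
    hi, lo = max(a, b), min(a, b)
    if lo == 0:
        hi, lo = hi + 0.5, lo + 0.5
    return hi / lo


@dataclass
class ConcordanceMatrix:
    """Accumulated pairwise rank-order counts across stability iterations."""

    ids: np.ndarray
    counts_ge: np.ndarray  # counts_ge[i, j] = iterations ranking i above j

    def ratio_matrix(self) -> np.ndarray:
        n = len(self.ids)
        M = np.full((n, n), np.nan)
        for i in range(n):
            for j in range(i + 1, n):
                v = pair_concordance(int(self.counts_ge[i, j]), int(self.counts_ge[j, i]))
                if v is not None:
                    M[i, j] = M[j, i] = v
        return M


def average_concordance_odds(
    cmat: ConcordanceMatrix, n_boot: int = 1000, seed: int = 0
) -> tuple[float, tuple[float, float]]:
    """Mean upper-triangle concordance ratio + participant-bootstrap 95% CI."""
    M = cmat.ratio_matrix()
    n = len(cmat.ids)
    iu = np.triu_indices(n, k=1)
    vals = M[iu]
    vals = vals[~np.isnan(vals)]
    if len(vals) == 0:
        raise ValidationError("no defined pairs")
    mean = float(vals.mean())
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        idx = rng.choice(n, size=n, replace=True)
        sub = M[np.ix_(idx, idx)]
        pick = sub[np.triu_indices(n, k=1)]
        same = idx[iu[0]] == idx[iu[1]]  # resampled self-pairs are undefined
        pick = pick[~same]
        pick = pick[~np.isnan(pick)]
        if len(pick):
            boots.append(pick.mean())
    lo, hi = np.percentile(boots, [2.5, 97.5])
    return mean, (float(lo), float(hi))


# -- stability loop --------------------------------------------------------


@dataclass
class StabilityResult:
    concordance: ConcordanceMatrix
    feature_frequency: pd.Series  # selection frequency per candidate feature
    n_failed: int


def stability_run(
    ds: TrialDataset,
    interim_cut: float,
    n_iter: int = 100,
    seed: int = 0,
    n_grid: int = 25,
) -> StabilityResult:
    """Repeat split/phenomap/label/fit/predict and accumulate rank stability.

    Pairs contribute to the concordance counts only in iterations where
    both members land in the test set; per-iteration failures are skipped
    and counted.
    """
    from .pipeline import fit_interim_model  # local import: avoids a cycle

    from .core import split_half

    cens = ds.censored_at(interim_cut)
    ids = cens.ids
    pos = {pid: k for k, pid in enumerate(ids)}
    n = len(ids)
    counts = np.zeros((n, n), dtype=np.int32)
    freq: dict = {}
    n_failed = 0
    rng = np.random.default_rng(seed)
    for _ in range(n_iter):
        it_seed = int(rng.integers(2**31 - 1))
        try:
            split = split_half(cens, it_seed)
            fitted = fit_interim_model(cens, split, seed=it_seed, n_grid=n_grid)
        except Exception:
            n_failed += 1
            continue
        for base in {f.split("=")[0] for f in fitted.selection.selected}:
            freq[base] = freq.get(base, 0) + 1
        if fitted.model is None:
            continue  # empty selection: no ranks this iteration
        test_ids = fitted.test_ids
        pred = fitted.test_predictions
        order = np.asarray(pred, float)
        k_idx = np.array([pos[pid] for pid in test_ids])
        # i above j when predicted log HR of i is lower (stronger responder)
        below = order[:, None] < order[None, :]
        np.add.at(counts, (k_idx[:, None], k_idx[None, :]), below)
    frequency = pd.Series({k: v / n_iter for k, v in freq.items()}, dtype=float)
    return StabilityResult(
        concordance=ConcordanceMatrix(ids=ids, counts_ge=counts),
        feature_frequency=frequency.sort_values(ascending=False),
        n_failed=n_failed,
    )


# -- run summaries ---------------------------------------------------------


@dataclass(frozen=True)
class MetricSummary:
    mean: float
    sem: float
    t: float
    p: float
    flagged: bool  # zero-variance runs: t/p undefined


def summarize_metric(values, reference: float, one_sided: bool = False) -> MetricSummary:
    """Mean +/- SEM and one-sample t of run-level values against a reference.

    One-sided tests (used for final-N counts, alpha 0.025) test for a
    reduction below the reference; otherwise two-sided.
    """
    v = np.asarray(values, float)
    if len(v) < 2:
        raise ValidationError("need >=2 runs to summarize")
    mean = float(v.mean())
    sem = float(v.std(ddof=1) / np.sqrt(len(v)))
    if sem == 0.0:
        return MetricSummary(mean, 0.0, np.nan, 1.0 if mean == reference else np.nan, True)
    res = stats.ttest_1samp(v, reference, alternative="less" if one_sided else "two-sided")
    return MetricSummary(mean, sem, float(res.statistic), float(res.pvalue), False)


def period_logrank(ds_adaptive: TrialDataset, ds_original: TrialDataset, period: tuple[float, float]) -> float:
    """Two-sample log-rank p for the primary outcome among a period's enrollees."""
    lo, hi = period
    def grab(ds):
        acc = ds.table["accrual_time"].to_numpy(float)
        m = (acc >= lo) & (acc < hi)
        return ds.table.loc[m, "primary_time"].to_numpy(float), ds.table.loc[m, "primary_event"].to_numpy(int)
    ta, ea = grab(ds_adaptive)
    tb, eb = grab(ds_original)
    if len(ta) == 0 or len(tb) == 0 or (ea.sum() + eb.sum()) == 0:
        raise ValidationError("empty subset or no events in the period")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = logrank_test(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.p_value)
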