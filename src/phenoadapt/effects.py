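"""Individualized treatment-effect estimation via weighted Cox regression.

For each index participant, every other participant is weighted by
phenotypic proximity (see :mod:`phenoadapt.phenomap`) and a Cox
proportional-hazards model with the randomized arm as the sole covariate
is fitted by maximizing the weight-incorporated partial likelihood

.. math::

   \\ell(\\beta) = \\sum_i w_i \\delta_i \\Big[\\beta x_i -
       \\log \\sum_{j: t_j \\ge t_i} w_j e^{\\beta x_j}\\Big]

(Breslow tie handling).  The fitted coefficient is the individualized log
hazard ratio of intervention vs control seen "from the phenotypic angle"
of the index participant.  Because the weights encode proximity rather
than replication, the reported standard error is the robust (sandwich)
one.

A dedicated Newton solver is used instead of a general-purpose fitter:
with a single binary covariate the score and information reduce to O(n)
array expressions, which matters when the model is refitted once per
training participant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import TrialDataset, ValidationError
from .phenomap import PhenoMap, similarity_weights

_MAX_ABS_BETA = 15.0


@dataclass(frozen=True)
class WeightedCoxResult:
    loghr: float
    se: float  # robust (sandwich) standard error
    converged: bool
    n_effective: float  # sum of weights


def _prepare(times, events, arm, weights):
    t = np.asarray(times, float)
    d = np.asarray(events, int)
    x = np.asarray(arm, int)
    w = np.asarray(weights, float)
    if not (len(t) == len(d) == len(x) == len(w)):
        raise ValidationError("input arrays must align")
    if (w < 0).any():
        raise ValidationError("negative weights")
    if w.sum() <= 0:
        raise ValidationError("all-zero weights")
    order = np.argsort(t, kind="stable")
    return t[order], d[order], x[order], w[order]


def _score_info(beta, t, d, x, w, tie_first):
    exb = w * np.exp(beta * x)
    s0 = np.cumsum(exb[::-1])[::-1]  # suffix sums: risk set = times >= t_i
    s1 = np.cumsum((exb * x)[::-1])[::-1]
    ev = d == 1
    S0 = s0[tie_first][ev]
    m = s1[tie_first][ev] / S0  # S1/S0; S2 == S1 for binary x
    wd = w[ev]
    U = np.sum(wd * (x[ev] - m))
    I = np.sum(wd * (m - m * m))
    ll = np.sum(wd * (beta * x[ev] - np.log(S0)))
    return U, I, ll, s0, s1


def weighted_cox(times, events, arm, weights) -> WeightedCoxResult:
    """Arm-only Cox fit under observation weights (Breslow ties, robust SE).

    ``arm`` is 1 for intervention, 0 for control.  Monotone likelihood
    (no weighted events in one arm) is flagged as non-convergence rather
    than an error; all-zero weights raise.
    """
    t, d, x, w = _prepare(times, events, arm, weights)
    n_eff = float(w.sum())
    if w[x == 1].sum() <= 0 or w[x == 0].sum() <= 0:
        raise ValidationError("both arms need positive total weight")
    wd = w * d
    if wd.sum() <= 0:
        raise ValidationError("no weighted events")
    if wd[x == 1].sum() == 0 or wd[x == 0].sum() == 0:
        # monotone partial likelihood: no finite maximizer
        return WeightedCoxResult(np.nan, np.nan, False, n_eff)

    tie_first = np.searchsorted(t, t, side="left")
    beta = 0.0
    converged = False
    for _ in range(60):
        U, I, _, _, _ = _score_info(beta, t, d, x, w, tie_first)
        if I <= 1e-12:
            break
        step = U / I
        step = float(np.clip(step, -2.0, 2.0))  # damp early overshoot
        beta += step
        if abs(beta) > _MAX_ABS_BETA:
            break
        if abs(U) < 1e-10 or abs(step) < 1e-12:
            converged = True
            break
    if not converged or abs(beta) > _MAX_ABS_BETA:
        return WeightedCoxResult(np.nan, np.nan, False, n_eff)

    U, I, _, s0, s1 = _score_info(beta, t, d, x, w, tie_first)
    se = _robust_se(beta, t, d, x, w, tie_first, s0, s1, I)
    return WeightedCoxResult(float(beta), float(se), True, n_eff)


def _robust_se(beta, t, d, x, w, tie_first, s0, s1, info):
    """Lin-Wei sandwich SE from weighted score residuals."""
    ev = d == 1
    S0_all = s0[tie_first]
    m_all = s1[tie_first] / S0_all
    contrib = np.where(ev, w / S0_all, 0.0)  # event mass w_k / S0(t_k)
    cum_a = np.cumsum(contrib)
    cum_b = np.cumsum(contrib * m_all)
    tie_last = np.searchsorted(t, t, side="right") - 1
    a = cum_a[tie_last]
    b = cum_b[tie_last]
    exb = np.exp(beta * x)
    resid = d * (x - m_all) - exb * (x * a - b)
    B = np.sum((w * resid) ** 2)
    if info <= 0:
        return np.nan
    return np.sqrt(B) / info


@dataclass
class BenefitLabels:
    """Per-participant individualized log HR labels for the ML stage.

    ``loghr`` is indexed by participant id; NaN marks indices whose
    weighted fit did not converge or had too few weighted events — those
    labels are excluded downstream rather than imputed.
    """

    loghr: pd.Series
    n_dropped: int

    def valid(self) -> pd.Series:
        return self.loghr.dropna()


def individualized_loghr(
    ds_train: TrialDataset,
    pmap: PhenoMap,
    min_weighted_events: float = 5.0,
    weight_cutoff: float = 0.0,
) -> BenefitLabels:
    """Individualized log HR for every index participant of the phenomap.

    ``ds_train`` must already be censored at the interim cut (follow-up
    truncated at ``cut - accrual_time``).  ``weight_cutoff`` optionally
    zeroes weights below a threshold purely for speed; it is 0 (off) by
    default.
    """
    id_pos = {pid: i for i, pid in enumerate(ds_train.ids)}
    missing = [pid for pid in pmap.ids if pid not in id_pos]
    if missing:
        raise ValidationError(f"phenomap ids not in training data: {missing[:3]}")
    rows = [id_pos[pid] for pid in pmap.ids]
    t = ds_train.table["primary_time"].to_numpy(float)[rows]
    d = ds_train.table["primary_event"].to_numpy(int)[rows]
    x = ds_train.arm_indicator()[rows]

    out = {}
    n_dropped = 0
    for pid in pmap.ids:
        w = similarity_weights(pmap, pid).w
        if weight_cutoff > 0:
            w = np.where(w < weight_cutoff, 0.0, w)
        if float((w * d).sum()) < min_weighted_events:
            out[pid] = np.nan
            n_dropped += 1
            continue
        res = weighted_cox(t, d, x, w)
        if res.converged:
            out[pid] = res.loghr
        else:
            out[pid] = np.nan
            n_dropped += 1
    return BenefitLabels(loghr=pd.Series(out, name="loghr"), n_dropped=n_dropped)
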