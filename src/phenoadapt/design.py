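"""Group-sequential scaffolding for the adaptive trial.

Covers four concerns: (1) locating interim analysis calendar times from
cumulative primary-event counts; (2) efficacy boundaries from one-sided
alpha-spending functions (O'Brien-Fleming-type and Pocock-type), solved
by recursive numerical integration of the canonical joint normal law of
sequential test statistics; (3) the treatment-effect heterogeneity gate,
a Cox arm-by-subgroup interaction test on the held-out half at a
screening threshold of p < 0.2; and (4) Schoenfeld-formula sample-size
revision under candidate predictive-enrichment levels q in
{0.50, 0.55, ..., 0.95}.

The projected effect size under enrichment level q blends, on the log-HR
scale and weighted by expected event counts, the hazard ratio observed in
the already-enrolled cohort with the test-set hazard ratio among the
top-q predicted responders (taken as the composition of future
enrollment).  A level is accepted only if its required sample size is
within the originally planned one *and* strictly below the projection
without enrichment, so a q-invariant projection never triggers
enrichment.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from scipy import special, stats

_SQRT2PI = np.sqrt(2.0 * np.pi)


def _npdf(z):
    return np.exp(-0.5 * z * z) / _SQRT2PI


def _simpson_weights(u: np.ndarray) -> np.ndarray:
    # composite Simpson quadrature weights for an odd-length uniform grid
    h = u[1] - u[0]
    w = np.full(len(u), 2.0)
    w[1::2] = 4.0
    w[0] = w[-1] = 1.0
    return w * h / 3.0

from .core import TrialDataset, ValidationError

Q_GRID = tuple(np.round(np.arange(0.50, 0.951, 0.05), 2))

OBRIEN_FLEMING = "obrien_fleming"
POCOCK = "pocock"


@dataclass
class DesignSpec:
    """Fixed design parameters of the group-sequential trial."""

    n_planned: int
    control_rate: float
    intervention_rate: float
    power: float = 0.80
    alpha_one_sided: float = 0.025
    interim_event_triggers: tuple[int, ...] = (50, 100, 150)
    spending: str = OBRIEN_FLEMING

    def __post_init__(self) -> None:
        trig = self.interim_event_triggers
        if any(b <= a for a, b in zip(trig, trig[1:])):
            raise ValidationError("interim triggers must be strictly increasing")
        if not 0 < self.alpha_one_sided < 0.5:
            raise ValidationError("alpha must be in (0, 0.5)")
        for r in (self.control_rate, self.intervention_rate):
            if not 0 < r < 1:
                raise ValidationError("event rates must be in (0, 1)")
        if self.spending not in (OBRIEN_FLEMING, POCOCK):
            raise ValidationError(f"unknown spending function {self.spending!r}")

    @property
    def n_looks(self) -> int:
        return len(self.interim_event_triggers) + 1

    @property
    def assumed_hr(self) -> float:
        # exponential-model relation between event proportions and HR
        return float(np.log1p(-self.intervention_rate) / np.log1p(-self.control_rate))


@dataclass
class InterimDecision:
    """Record of one interim look."""

    look_index: int
    calendar_time: float
    boundary_z: float
    interaction_p: float | None
    gate_passed: bool
    q_chosen: float | None
    n_revised: int | None
    enrich: bool

    def __post_init__(self) -> None:
        if self.enrich and not self.gate_passed:
            raise ValidationError("enrichment requires a passed heterogeneity gate")


# -- interim timing --------------------------------------------------------


def interim_calendar_times(ds: TrialDataset, triggers) -> list[float]:
    """Calendar day of the k-th trigger-count primary event, per trigger."""
    t = ds.table
    ev = t[t["primary_event"] == 1]
    dates = np.sort(ev["accrual_time"].to_numpy(float) + ev["primary_time"].to_numpy(float))
    if len(dates) < max(triggers):
        raise ValidationError(
            f"only {len(dates)} events; cannot reach trigger {max(triggers)}"
        )
    return [float(dates[k - 1]) for k in triggers]


# -- alpha spending --------------------------------------------------------


def spending_function(name: str, alpha: float, t: np.ndarray) -> np.ndarray:
    t = np.asarray(t, float)
    if name == OBRIEN_FLEMING:
        return 2.0 - 2.0 * stats.norm.cdf(stats.norm.ppf(1.0 - alpha / 2.0) / np.sqrt(t))
    if name == POCOCK:
        return alpha * np.log1p((np.e - 1.0) * t)
    raise ValidationError(f"unknown spending function {name!r}")


def spending_boundaries(spec: DesignSpec, information_fractions) -> np.ndarray:
    """Per-look one-sided efficacy z-boundaries for the given spending plan.

    Solved on the Brownian scale: with S_k the partial-sum process at
    information t_k, boundaries c_k satisfy
    P(S_1 < c_1, ..., S_{k-1} < c_{k-1}, S_k >= c_k) = alpha_k, computed
    by propagating the sub-density of the non-stopped process on a grid.
    """
    t = np.asarray(information_fractions, float)
    if np.any(np.diff(t) <= 0) or np.any(t <= 0) or np.any(t > 1.0 + 1e-12):
        raise ValidationError("information fractions must be increasing in (0, 1]")
    cum = spending_function(spec.spending, spec.alpha_one_sided, t)
    alpha_inc = np.diff(np.concatenate([[0.0], cum]))

    n_grid = 801
    z_span = 8.5
    boundaries = []
    grid = None  # (points, density) of the surviving Brownian mass
    for k, (tk, ak) in enumerate(zip(t, alpha_inc)):
        sd_k = np.sqrt(tk)
        if k == 0:
            c = sd_k * stats.norm.ppf(1.0 - ak)
        else:
            u, f, du = grid
            dt = tk - t[k - 1]
            sdt = np.sqrt(dt)

            def exceed(c_try):
                tail = special.ndtr((u - c_try) / sdt)  # P(increment >= c - u)
                return np.sum(f * tail * du) - ak

            c = _brentq(exceed, -z_span * sd_k, z_span * sd_k)
        boundaries.append(c / sd_k)
        # propagate the sub-density below the boundary
        new_u = np.linspace(-z_span * sd_k, c, n_grid)
        new_du = _simpson_weights(new_u)
        if k == 0:
            new_f = _npdf(new_u / sd_k) / sd_k
        else:
            u, f, du = grid
            dt = t[k] - t[k - 1]
            kern = _npdf((new_u[:, None] - u[None, :]) / np.sqrt(dt)) / np.sqrt(dt)
            new_f = kern @ (f * du)
        grid = (new_u, new_f, new_du)
    return np.asarray(boundaries)


def _brentq(fn, lo, hi):
    from scipy.optimize import brentq

    return brentq(fn, lo, hi, xtol=1e-10)


# -- heterogeneity gate ----------------------------------------------------


@dataclass
class GateResult:
    interaction_p: float | None
    passed: bool
    cut: float | None
    benefit_group: np.ndarray | None  # 1 = predicted stronger responder


def heterogeneity_gate(
    test_ds: TrialDataset,
    predictions,
    interim_cut: float | None = None,
    cut_strategy: str = "median",
    min_group_frac: float = 0.20,
) -> GateResult:
    """Arm-by-predicted-subgroup interaction screen on the held-out half.

    Dichotomizes predicted log HR (default: median split; ``"scan"`` tries
    deciles between the 20th and 80th percentiles and keeps the cut
    minimizing the interaction p, a more aggressive variant that inflates
    the screen's type-I rate).  The minor group must hold at least 20% of
    the population; cuts yielding an arm-subgroup cell with no events are
    skipped.  The gate passes iff the Wald interaction p is below 0.2.
    """
    ds = test_ds.censored_at(interim_cut) if interim_cut is not None else test_ds
    pred = np.asarray(predictions, float)
    if len(pred) != ds.n:
        raise ValidationError("one prediction per test participant required")
    uniq = np.unique(pred)
    if len(uniq) < 2:
        return GateResult(interaction_p=None, passed=False, cut=None, benefit_group=None)
    mids = 0.5 * (uniq[:-1] + uniq[1:])
    if cut_strategy == "median":
        # the admissible cut closest to an even split (robust to discrete
        # or bimodal predictions, where the raw median can sit on a mass)
        shares = np.array([(pred <= c).mean() for c in mids])
        ok = (shares >= min_group_frac) & (shares <= 1.0 - min_group_frac)
        if not ok.any():
            return GateResult(interaction_p=None, passed=False, cut=None, benefit_group=None)
        cuts = [float(mids[ok][np.argmin(np.abs(shares[ok] - 0.5))])]
    elif cut_strategy == "scan":
        cuts = list(np.percentile(pred, np.arange(20, 81, 10)))
    else:
        raise ValidationError(f"unknown cut strategy {cut_strategy!r}")

    times = ds.table["primary_time"].to_numpy(float)
    events = ds.table["primary_event"].to_numpy(int)
    arm = ds.arm_indicator()

    best: tuple[float, float, np.ndarray] | None = None
    for cut in cuts:
        # responders predicted below the cut (more negative log HR = more benefit)
        g = (pred <= cut).astype(int)
        share = g.mean()
        if not (min_group_frac <= share <= 1.0 - min_group_frac):
            continue
        ok = True
        for a in (0, 1):
            for gg in (0, 1):
                if events[(arm == a) & (g == gg)].sum() == 0:
                    ok = False
        if not ok:
            continue
        frame = pd.DataFrame(
            {"T": times, "E": events, "arm": arm, "grp": g, "arm_grp": arm * g}
        )
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter()
                cph.fit(frame, duration_col="T", event_col="E")
            p = float(cph.summary.loc["arm_grp", "p"])
        except Exception:
            continue
        if best is None or p < best[0]:
            best = (p, cut, g)
    if best is None:
        return GateResult(interaction_p=None, passed=False, cut=None, benefit_group=None)
    p, cut, g = best
    return GateResult(interaction_p=p, passed=p < 0.2, cut=cut, benefit_group=g)


# -- sample size -----------------------------------------------------------


def required_events(spec: DesignSpec, hr_assumed: float) -> float:
    """Schoenfeld event count D = 4 (z_{1-a} + z_{1-b})^2 / ln(HR)^2."""
    if not 0 < hr_assumed:
        raise ValidationError("hr must be positive")
    if hr_assumed == 1.0:
        return float("inf")
    za = stats.norm.ppf(1.0 - spec.alpha_one_sided)
    zb = stats.norm.ppf(spec.power)
    return 4.0 * (za + zb) ** 2 / np.log(hr_assumed) ** 2


def required_sample(spec: DesignSpec, hr_assumed: float, event_rate_control: float | None = None) -> float:
    """Total N from the Schoenfeld event count and average event probability."""
    D = required_events(spec, hr_assumed)
    if not np.isfinite(D):
        return float("inf")
    p_ctl = spec.control_rate if event_rate_control is None else event_rate_control
    p_int = 1.0 - (1.0 - p_ctl) ** hr_assumed  # exponential-model conversion
    p_bar = 0.5 * (p_ctl + p_int)
    return D / p_bar


# -- enrichment-level revision --------------------------------------------


def _arm_only_hr(ds: TrialDataset, mask=None, min_events_per_arm: int = 0) -> float | None:
    """Point-estimate HR of intervention vs control on a (sub)dataset.

    Subgroups with fewer than ``min_events_per_arm`` events in either arm
    yield None: their hazard-ratio estimates are too unstable to project a
    sample size from.
    """
    from .effects import weighted_cox

    t = ds.table["primary_time"].to_numpy(float)
    e = ds.table["primary_event"].to_numpy(int)
    x = ds.arm_indicator()
    if mask is not None:
        t, e, x = t[mask], e[mask], x[mask]
    if len(t) == 0 or e.sum() == 0 or len(np.unique(x)) < 2:
        return None
    if min(e[x == 1].sum(), e[x == 0].sum()) < min_events_per_arm:
        return None
    res = weighted_cox(t, e, x, np.ones_like(t, float))
    if not res.converged:
        return None
    return float(np.exp(res.loghr))


def revise_under_enrichment(
    spec: DesignSpec,
    n_enrolled: int,
    hr_enrolled: float,
    test_ds: TrialDataset,
    predictions,
    q_grid=Q_GRID,
    min_events_per_arm: int = 3,
) -> tuple[float, int] | None:
    """Pick the enrichment level minimizing the revised required sample.

    Returns ``(q_chosen, n_revised)`` or None when no level is both
    adequately powered within the planned size and an actual improvement
    over continuing without enrichment.  Candidate subgroups whose HR
    rests on fewer than ``min_events_per_arm`` events in either arm are
    not considered.
    """
    pred = np.asarray(predictions, float)
    if len(pred) != test_ds.n:
        raise ValidationError("one prediction per test participant required")
    n_future = max(spec.n_planned - n_enrolled, 0)
    if n_future == 0 or hr_enrolled is None:
        return None
    p_bar_w = 1.0  # event weights proportional to cohort sizes under a shared rate

    hr_all = _arm_only_hr(test_ds)
    if hr_all is None:
        return None

    def projected_n(hr_future: float) -> float:
        lhr = (
            n_enrolled * np.log(hr_enrolled) + n_future * np.log(hr_future)
        ) / ((n_enrolled + n_future) * p_bar_w)
        return required_sample(spec, float(np.exp(lhr)))

    n_no_enrich = projected_n(hr_all)
    accepted = []
    order = np.argsort(pred, kind="stable")  # strongest predicted responders first
    for q in q_grid:
        k = max(1, int(np.ceil(q * len(pred))))
        mask = np.zeros(len(pred), dtype=bool)
        mask[order[:k]] = True  # top-q by rank (robust to tied predictions)
        hr_q = _arm_only_hr(test_ds, mask, min_events_per_arm=min_events_per_arm)
        if hr_q is None:
            continue
        n_q = projected_n(hr_q)
        if np.isfinite(n_q) and n_q <= spec.n_planned and n_q < n_no_enrich:
            accepted.append((int(np.ceil(n_q)), float(q)))
    if not accepted:
        return None
    n_best, q_best = min(accepted)
    return q_best, max(n_best, n_enrolled)
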