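"""End-to-end group-sequential adaptive enrichment simulation.

One run replays a candidate pool through the adaptive design: everyone
arriving before the first interim is enrolled; at each interim the
enrolled data are censored at the interim calendar time, split 50:50,
and the phenomapping/benefit-model chain is fitted on the training half.
If the held-out half shows evidence of treatment-effect heterogeneity
(interaction p < 0.2) and some enrichment level q keeps the revised
required sample within the planned one, arrivals of the next period are
enrolled by benefit-weighted sampling at level q; otherwise enrollment
continues unrestricted.  Treatment assignment is never modified.  The
final analysis happens at the calendar time of the pool's last primary
event.

A fresh model is trained at every interim (no warm start), and the
run-level seed fans out to per-stage seeds through a fixed counter
scheme so every stage is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import TrialDataset, ValidationError, split_half
from .preprocess import PipelineError
from .design import (
    DesignSpec,
    GateResult,
    InterimDecision,
    heterogeneity_gate,
    interim_calendar_times,
    revise_under_enrichment,
    spending_boundaries,
)
from .enrichment import (
    benefit_to_x,
    enrollment_probability,
    responder_ratio,
    sample_period_candidates,
)
from .evaluate import (
    MetricSummary,
    WinRatioResult,
    balance_and_composition,
    primary_cox_hr,
    summarize_metric,
    win_ratio,
)
from .pipeline import fit_interim_model
from .synthetic import shuffle_covariates


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage identifier."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class SimulationResult:
    """Outputs of one adaptive run."""

    run_seed: int
    decisions: list[InterimDecision]
    final_n: int
    final_hr: float
    final_p: float
    event_counts: list[int]  # cumulative primary events at each look
    win_ratios: list[WinRatioResult]
    arm_balance_p: float
    demographics: pd.DataFrame
    enrichment_active_periods: list[int]
    enrolled_ids: tuple


def _stage_seed(run_seed: int, look: int, stage: int) -> int:
    # fixed counter scheme; keeps every derived seed below 2**31
    return int(np.random.default_rng([run_seed, look, stage]).integers(2**31 - 1))


def run_adaptive_trial(
    ds_candidates: TrialDataset,
    spec: DesignSpec,
    seed: int,
    cut_strategy: str = "median",
    n_grid: int = 25,
    enrich_enabled: bool = True,
    compute_win_ratio: bool = True,
) -> SimulationResult:
    """Simulate one adaptive run over the candidate pool."""
    interim_times = interim_calendar_times(ds_candidates, spec.interim_event_triggers)
    event_dates = (
        ds_candidates.table.loc[ds_candidates.table["primary_event"] == 1, "accrual_time"]
        + ds_candidates.table.loc[ds_candidates.table["primary_event"] == 1, "primary_time"]
    )
    final_time = float(event_dates.max())
    d_total = int(ds_candidates.table["primary_event"].sum())
    fractions = [k / d_total for k in spec.interim_event_triggers] + [1.0]
    boundaries = spending_boundaries(spec, fractions)

    acc = ds_candidates.table["accrual_time"].to_numpy(float)
    ids = ds_candidates.ids
    enrolled = list(ids[acc < interim_times[0]])  # period 1: enroll everyone
    decisions: list[InterimDecision] = []
    active_periods: list[int] = []

    for look, t_cut in enumerate(interim_times, start=1):
        analysis = ds_candidates.subset(enrolled).censored_at(t_cut)
        fitted = None
        try:
            split = split_half(analysis, _stage_seed(seed, look, 0))
            fitted = fit_interim_model(
                analysis, split, seed=_stage_seed(seed, look, 1), n_grid=n_grid
            )
        except (PipelineError, ValidationError):
            # too little accrued data to model this look: the trial simply
            # continues standard enrollment (no evidence of heterogeneity)
            fitted = None
        except Exception as exc:  # noqa: BLE001 - stage identity matters downstream
            raise StageError(f"interim_{look}_model", exc) from exc

        gate = GateResult(None, False, None, None)
        revision = None
        if fitted is not None and fitted.model is not None:
            test_cens = analysis.subset(split.test_ids)
            gate = heterogeneity_gate(
                test_cens, fitted.test_predictions, cut_strategy=cut_strategy
            )
            if gate.passed and enrich_enabled:
                hr_enr, _ = primary_cox_hr(analysis)
                revision = revise_under_enrichment(
                    spec, len(enrolled), hr_enr, test_cens, fitted.test_predictions
                )

        enrich = revision is not None
        decisions.append(
            InterimDecision(
                look_index=look,
                calendar_time=t_cut,
                boundary_z=float(boundaries[look - 1]),
                interaction_p=gate.interaction_p,
                gate_passed=gate.passed,
                q_chosen=revision[0] if enrich else None,
                n_revised=revision[1] if enrich else None,
                enrich=enrich,
            )
        )

        t_next = interim_times[look] if look < len(interim_times) else np.inf
        arrival_mask = (acc >= t_cut) & (acc < t_next)
        arrival_ids = ids[arrival_mask]
        if len(arrival_ids) == 0:
            continue
        if enrich:
            arrivals = ds_candidates.subset(arrival_ids)
            pred = fitted.predict(arrivals)
            z = responder_ratio(fitted.test_predictions)
            if z <= 0:
                enrolled.extend(arrival_ids)  # no predicted responders: no enrichment
                continue
            x = benefit_to_x(pred)
            p = enrollment_probability(x, z)
            chosen = sample_period_candidates(
                arrivals.ids, p, revision[0], _stage_seed(seed, look, 2)
            )
            enrolled.extend(chosen)
            active_periods.append(look + 1)
        else:
            enrolled.extend(arrival_ids)

    final_ds = ds_candidates.subset(enrolled)
    final_cens = final_ds.censored_at(final_time)
    final_hr, final_p = primary_cox_hr(final_cens)
    look_times = interim_times + [final_time]
    event_counts = [
        int(final_ds.censored_at(t).table["primary_event"].sum()) for t in look_times
    ]
    wrs = []
    if compute_win_ratio and final_ds.n_safety_tiers:
        wrs = [win_ratio(final_ds, cut=t) for t in look_times]
    bal_p, demo = balance_and_composition(final_cens, ds_candidates)
    return SimulationResult(
        run_seed=seed,
        decisions=decisions,
        final_n=final_cens.n,
        final_hr=final_hr,
        final_p=final_p,
        event_counts=event_counts,
        win_ratios=wrs,
        arm_balance_p=bal_p,
        demographics=demo,
        enrichment_active_periods=active_periods,
        enrolled_ids=tuple(enrolled),
    )


@dataclass
class ExperimentSummary:
    """r adaptive runs + r negative-control runs against the all-comers reference."""

    adaptive: list[SimulationResult]
    negative_control: list[SimulationResult]
    reference_n: int
    reference_hr: float
    reference_p: float
    final_n_summary: MetricSummary
    final_hr_summary: MetricSummary
    control_n_summary: MetricSummary

    @property
    def mean_reduction_pct(self) -> float:
        return 100.0 * (self.final_n_summary.mean - self.reference_n) / self.reference_n

    @property
    def control_reduction_pct(self) -> float:
        return 100.0 * (self.control_n_summary.mean - self.reference_n) / self.reference_n


def run_experiment(
    ds: TrialDataset,
    spec: DesignSpec,
    r: int = 10,
    seed: int = 0,
    cut_strategy: str = "median",
    n_grid: int = 25,
    compute_win_ratio: bool = True,
) -> ExperimentSummary:
    """Repeat the adaptive simulation r times plus shuffled negative controls."""
    if r < 1:
        raise ValueError("r must be >= 1")
    root = np.random.default_rng(seed)
    run_seeds = [int(root.integers(2**31 - 1)) for _ in range(2 * r)]
    adaptive = [
        run_adaptive_trial(
            ds, spec, s, cut_strategy=cut_strategy, n_grid=n_grid,
            compute_win_ratio=compute_win_ratio,
        )
        for s in run_seeds[:r]
    ]
    control = []
    for s in run_seeds[r:]:
        shuffled = shuffle_covariates(ds, s)
        control.append(
            run_adaptive_trial(
                shuffled, spec, s, cut_strategy=cut_strategy, n_grid=n_grid,
                compute_win_ratio=compute_win_ratio,
            )
        )

    # all-comers reference: identical pool, no enrichment
    event_dates = (
        ds.table.loc[ds.table["primary_event"] == 1, "accrual_time"]
        + ds.table.loc[ds.table["primary_event"] == 1, "primary_time"]
    )
    final_time = float(event_dates.max())
    ref = ds.censored_at(final_time)
    ref_hr, ref_p = primary_cox_hr(ref)

    n_summary = summarize_metric([x.final_n for x in adaptive], ref.n, one_sided=True)
    hr_summary = summarize_metric([x.final_hr for x in adaptive], ref_hr)
    c_summary = summarize_metric([x.final_n for x in control], ref.n, one_sided=True)
    return ExperimentSummary(
        adaptive=adaptive,
        negative_control=control,
        reference_n=ref.n,
        reference_hr=ref_hr,
        reference_p=ref_p,
        final_n_summary=n_summary,
        final_hr_summary=hr_summary,
        control_n_summary=c_summary,
    )
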