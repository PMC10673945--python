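# Methods

`phenoadapt` simulates a two-arm randomized clinical trial whose enrollment
is adaptively *predictively enriched*: at pre-planned interim analyses the
accumulated data are used to learn a signature of individualized treatment
benefit, and — when the evidence supports it — the probability that a future
screening candidate is enrolled is conditioned on their predicted benefit.
Treatment assignment itself is never touched; enrichment acts strictly as a
gatekeeper before randomization.

This note records the model, the estimators, the tunable parameters, and the
design decisions taken where the procedure was genuinely open.

## 1. The trial model

The synthetic generator (`phenoadapt.synthetic`) draws a candidate pool of
`n_total` participants with

- uniform accrual over `accrual_days` (calendar day 0 = first randomization);
- 1:1 Bernoulli randomization to intervention vs control;
- mixed baseline covariates: standard-normal continuous (optionally
  equicorrelated through a Gaussian copula), Bernoulli binaries (prevalence
  per feature either fixed or drawn uniformly from [0.2, 0.5]), and uniform
  categoricals;
- exponential primary-event times with individual hazard
  `lambda_i = lambda_0 * exp(a_i * (beta_ATE + sum_k gamma_k x_ik))`, where
  `a_i` is the arm indicator and the `gamma_k` are interaction log-HR
  coefficients on a chosen covariate subset (the planted heterogeneous
  treatment effect, HTE);
- administrative censoring at a fixed per-participant follow-up horizon
  (default 1825 days) plus exponential random censoring with hazard
  `censor_rate * lambda_0`;
- optional MCAR missingness per covariate;
- an ordered hierarchy of arm-neutral safety outcomes (tier 0 plays the role
  of all-cause mortality).

`lambda_0` is calibrated in closed form so that the control-arm event
proportion at the horizon equals `control_rate` (default 0.118, a
control-arm proportion typical of large cardiovascular outcome trials) after
accounting for random censoring. Exponential (constant-hazard) event times
were chosen over Weibull because they satisfy proportional hazards exactly —
the assumption the weighted Cox stage relies on — and admit that closed-form
calibration. Because the individual log HR is known by construction,
`true_individual_loghr` provides a parameter-recovery oracle for every
downstream stage.

What the generator deliberately does *not* emulate: competing risks,
informative censoring, site/cluster structure, covariate-dependent (MAR/MNAR)
missingness, non-proportional hazards, and realistic covariate correlation
structure (a single equicorrelation knob stands in for it). Tests passing on
this generator show that the machinery recovers planted signal under the
model's own assumptions; they do not certify behavior under violations of
those assumptions.

## 2. Preprocessing

Fitted on the training half only, then frozen (`fit_preprocess` /
`apply_preprocess`):

1. drop covariates with >10% missingness;
2. among continuous pairs with |Pearson r| > 0.9, iteratively drop the member
   with the largest mean absolute correlation against the other remaining
   continuous covariates (descending-|r| scan, correlations recomputed after
   each drop — this makes the tiebreak deterministic);
3. 95% winsorization of continuous covariates (clip at the 2.5th/97.5th
   percentiles; linear-interpolation percentile convention, so bounds are
   reproducible — e.g. the values 1..100 give bounds (3.475, 97.525));
4. drop zero-variance factors;
5. iterative forest imputation: scikit-learn's `IterativeImputer` with a
   10-tree random-forest base learner, at most 5 rounds, seeded. Categoricals
   are ordinal-coded for imputation and rounded back to levels. Any seeded
   iterative forest imputer satisfies the contract here (deterministic given
   seed; no missing values out);
6. full one-hot encoding of categoricals (one indicator per level seen at
   fit, no reference level — downstream learners are trees, so the dummy
   trap does not apply). Unseen levels at transform map to all-zero rows.

The collinearity screen applies to continuous covariates only; correlation
between raw categorical codes is not meaningful before encoding. The order
(missingness screen, collinearity, winsorize, zero-variance, impute, encode)
is fixed; whether the collinearity screen should precede winsorization is
not determined by the procedure's description, and the chosen order is
exposed by the pipeline structure itself.

## 3. Phenomap and individualized effects

**Gower distance.** Computed on the winsorized, imputed, *pre-one-hot* data:
continuous features contribute `|x_i - x_j| / range` (range observed in the
analysis subset at that interim, not globally), categorical and binary
features contribute a 0/1 mismatch indicator, and the distance is the
unweighted mean of the contributions. Comparing categoricals on their
original levels is the canonical Gower treatment; comparing one-hot columns
instead would double-weight categorical mismatches. Zero-range continuous
features are excluded from the mean with a warning. Note the distance
convention: identical values contribute 0 (a *dissimilarity*), so identical
participants are at distance 0.

**Proximity weights.** For an index participant, every participant receives
weight `w_j = ReLU((1 - d_ij)^3)`: a cubic decay of similarity. The ReLU is
mathematically redundant for distances in [0, 1] and is kept purely as a
guard against floating-point noise. The self-weight is exactly 1.

**Weighted Cox.** For each index participant, an arm-only Cox model is
fitted by maximizing the weight-incorporated partial likelihood (Breslow
ties; ties are measure-zero under the generator anyway), yielding that
participant's individualized log HR. A dedicated Newton solver is used
because the model is refitted once per training participant: with one binary
covariate the score and information are O(n) array expressions. The reported
standard error is the robust (Lin–Wei sandwich) one, since proximity weights
encode similarity, not replication. Non-convergence (monotone likelihood in
sparse neighborhoods — e.g. no weighted events in one arm) and neighborhoods
with fewer than `min_weighted_events = 5` weighted events produce a *missing*
label, excluded downstream; fabricating a clipped value would bias the
regressor. No neighborhood truncation is applied by default; a weight cutoff
exists purely as a speed knob and is off in tests.

## 4. Benefit model

Labels (individualized log HRs) are 95%-winsorized before fitting.

**Feature selection** follows the Boruta-SHAP scheme: in each of 20
iterations, every feature is permuted into a shadow copy, a gradient-boosted
probe (50 rounds, depth 3, learning rate 0.1) is fitted on the combined
matrix, and a feature scores a *hit* when its mean absolute SHAP importance
exceeds the best shadow importance. SHAP values use xgboost's exact
tree-path attribution (`pred_contribs=True`), which is the TreeSHAP
algorithm. Features whose hit count is significantly above the
Binomial(20, 1/2) null at two-sided 0.05 (i.e. >= 15/20) are selected — the
standard Boruta decision rule. With phenomap-derived labels, selection tends
to be inclusive: the labels are genuine smooth functions of the full
covariate vector, so many features legitimately beat their shadows. Under
pure-noise labels the per-feature hit probability is roughly 1/(p+1), far
below 1/2, and selection is rare.

**Regression.** An xgboost regressor tuned by sampling 25 configurations
without replacement from the grid {learning rate 0.01/0.05/0.10/0.15; max
depth 3/5/6/10/15/20; subsample 0.5–1.0 by 0.1; feature fraction per tree
0.4–1.0 by 0.1; per level 0.4–1.0 by 0.1; trees 100/500/1000} — the full
grid has 21,168 points, so "25 iterations" is read as 25 random draws. Each
draw trains on an inner 80/20 split with early stopping (patience 20, at
most 1000 rounds) on validation RMSE; the best configuration's booster is
returned (the tuning fit *is* the refit — both are deterministic given the
seed). Zero-variance labels yield a constant predictor with a warning.
Predictions bind by feature name, not column position.

## 5. Group-sequential design

**Interim timing.** Look k happens at the calendar day of the
`trigger_k`-th primary event in the original pool (defaults 50/100/150),
with the final analysis at the calendar time of the pool's last primary
event.

**Boundaries.** One-sided alpha-spending boundaries (O'Brien-Fleming-type
`f(t) = 2 - 2*Phi(z_{1-alpha/2}/sqrt(t))` or Pocock-type
`f(t) = alpha*ln(1+(e-1)t)`), solved by recursive numerical integration of
the sub-density of the non-stopped Brownian partial-sum process on an
801-point grid with composite Simpson quadrature. Information fractions are
event fractions `D_k / D_total`, the standard choice for survival designs.
The four-look equal-fraction O'Brien-Fleming boundaries agree with published
values to 5e-5. Boundaries are computed and logged per look; stopping for
efficacy is configurable and off by default (all simulated runs proceed to
the final analysis, and there is no futility assessment).

**Heterogeneity gate.** On the held-out test half, predicted log HRs are
dichotomized and a Cox model with arm, group, and arm-by-group terms is
fitted; the gate passes when the Wald interaction p is below 0.2 (a lenient
screen, reflecting that only half the interim data are available). The
default dichotomy is the admissible cut closest to an even split (computed
over midpoints of adjacent distinct predictions, so bimodal or discrete
predictions behave sensibly), subject to a 20% minor-group floor. A
min-p scan over the 20th–80th percentile deciles is available via
`cut_strategy="scan"` but is *not* the default: taking the minimum over ~7
nested cutpoints inflates the screen's null pass rate to roughly 0.5,
destroying the 0.2 calibration that the rest of the design assumes. Cuts
producing an arm-subgroup cell with zero events are skipped; constant
predictions admit no valid dichotomy and fail the gate.

**Sample-size revision.** Required events follow Schoenfeld,
`D = 4 (z_{1-alpha} + z_{1-beta})^2 / ln(HR)^2`, converted to a total N via
the average event probability across arms (the intervention rate is derived
from the control rate and the HR under the exponential model). For each
enrichment level q in {0.50, ..., 0.95}, the projected effect size blends, on
the log-HR scale and weighted by cohort sizes (expected events under a
shared event probability), (a) the observed HR of the already-enrolled
cohort with (b) the test-set HR among the top-q predicted responders (by
rank), taken as the composition of future enrollment. A level is accepted
only if its required N is within the originally planned sample *and*
strictly below the no-enrichment projection; the accepted level minimizing N
wins. Subgroup HRs resting on fewer than 3 events per arm are not
projected — sample-size arithmetic from such counts is numerically
meaningless, and left unchecked it lets a single extreme noise estimate
trigger enrichment. This blend is an explicit modeling choice: the
underlying procedure ("revising the expected effect size under the
assumption of predictive enrichment") is not fully specified, and point
estimates are used without propagating subgroup-HR uncertainty.

**Enrollment.** Predicted log HRs of the next period's candidates are
sign-flipped and min-max scaled to x in [0, 1] (all-equal predictions map
to 0.5), and the enrollment weight is `p = sigmoid(10*(x - (1 - z)))^2`,
where z is the responder:non-responder ratio (predicted log HR < 0 vs >= 0)
in the test set the model was validated on; z is capped at the responder
count when there are no non-responders. The period's enrollees are then a
weighted without-replacement sample of exactly `ceil(q * n_candidates)` ids —
the probabilistic weights decide *who*, the revision's q decides *how many*,
which keeps the sample-size arithmetic deterministic. Min-max normalization
uses the period's candidate batch retrospectively (a simulation-context
choice, not a streaming rule).

## 6. Harness and evaluation

Each run enrolls everyone arriving before look 1; at each look the enrolled
data are censored at the interim calendar time, split 50:50, and the full
chain (preprocess, phenomap, labels, selection, model) is refitted from
scratch — no warm starts. Insufficient accumulated data to fit the chain
(too few usable labels, an empty selection) is treated as "no evidence of
heterogeneity" for that look, not as a failure: the trial continues standard
enrollment. The run-level seed fans out to per-stage seeds through a fixed
counter scheme so each stage is independently reproducible. With enrichment
disabled the pipeline reproduces the all-comers analysis exactly.

Outcome analyses: unadjusted arm-only Cox HR and Wald p; arm-balance
chi-square against the original pool; demographic stratum shares;
hierarchical safety win ratio (unmatched pairwise comparison descending the
tier hierarchy; the intervention member of a pair wins a tier if the control
member has the strictly earlier observed event). The win-ratio CI uses a
log-scale normal approximation with the first-order two-sample U-statistic
(projection) variance — pairs sharing a participant are correlated, so the
naive `1/W + 1/L` variance would be far too small. Zero losses (or zero
wins) flag the CI as undefined; all ties yield a flagged point value of 1.

Run summaries: per-metric mean, SEM, and one-sample t against the all-comers
reference, one-sided at alpha 0.025 for final-N counts (a directional claim)
and two-sided at 0.05 otherwise.

**Stability.** The split/fit/predict loop is repeated (100 iterations in the
methodology; reduced counts in examples) and two things are accumulated:
per-feature selection frequency, and pairwise rank-concordance counts over
iterations where both pair members are in the test set. The pair concordance
is 1 for equal counts, otherwise majority/minority; a zero minority count
gets +0.5 added to both counts (the printed ratio is undefined there — this
continuity rule is a documented choice, and the raw-count variant is a
one-line change); never-jointly-observed pairs are excluded. The average
concordance odds is the mean of the defined upper-triangle entries with a
participant-level percentile bootstrap CI (1000 replicates, seeded);
bootstrapping over participants rather than pairs is a choice the CI width
is sensitive to.

**Negative control.** `shuffle_covariates` permutes whole covariate rows
across participants, preserving arms, accrual and outcomes — hence the
average treatment effect — while destroying covariate-outcome links.
Adaptive runs on shuffled data are the specificity check: enrichment should
then be rare and small.

## 7. Desk-scale study conditions

The canonical planted-HTE scenario (`phenoadapt.scenarios`) uses n = 2500
candidates, control rate 0.118, average treatment log HR ln(0.84), and a
-0.5 interaction log HR on a binary feature of prevalence 0.35 — an overall
population HR of about 0.70. The matching design assumes event rates
consistent with that overall effect (11.8% vs 8.52%, assumed HR 0.712), so
the planned sample of 2500 sits marginally *below* the Schoenfeld-required
one (~2680). That geometry matters for specificity: when a spurious gate
pass occurs under the null, the revised sample size is anchored near (above)
the planned one, so noise alone rarely justifies enrichment. Accrual is slow
(5000 days) so that the 50/100/150-event interims fall at roughly 38%, 67%
and 86% of accrual and a substantial candidate tail remains enrichable —
the regime of the long-running cardiovascular trials this emulates. Repeated
experiments use r = 10 adaptive plus r = 10 negative-control runs, 6
hyperparameter draws per interim instead of the full 25, and skip per-look
win ratios; these reductions keep a full experiment in the minutes range and
leave the scientific behavior unchanged. The larger parameter-recovery
checks (rank recovery of the planted signal, selection frequency of the
driving feature) run at n = 4000.

## 8. Known limitations

- The heterogeneity screen at 0.2 admits, by construction, spurious
  enrichment in roughly a fifth of null interim looks; the sample-size
  revision filters most but not all of these, so negative-control runs show
  small, statistically non-significant size reductions rather than exactly
  zero.
- Interaction power at 50–150-event interims is modest even for a -0.5
  planted interaction; enrichment therefore activates in a fraction of runs,
  and mean size reductions are correspondingly smaller than what a larger
  trial with the same geometry would show.
- The individualized-label stage assumes proportional hazards within
  phenotypic neighborhoods and produces labels whose sampling noise at early
  interims is large; the label-winsorization and dropped-label policies tame
  but do not remove this.
- Sample-size projections use point estimates of subgroup HRs; no
  uncertainty propagation or shrinkage is applied.
- The win-ratio CI is a first-order approximation; a bootstrap variant would
  be preferable for very small arms.
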