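# Methods

This note documents the statistical procedure `ccw` implements, the
conventions it pins where several reasonable choices exist, what the
synthetic-data generator does and does not emulate, and known limitations.

## Estimand and identification

The package targets **per-protocol effects** of sustained treatment
strategies: the contrast in counterfactual outcome risk had everyone
followed strategy A versus strategy B from a common time zero. With
observational data this is identified under the usual conditions —
consistency, measured (time-varying) confounding of adherence, and
positivity — by the clone–censor–weight construction:

* cloning every eligible patient into every arm at time zero removes
  confounding *at baseline* by construction and aligns eligibility,
  assignment, and the start of follow-up (no immortal time, no
  prevalent-user selection);
* artificial censoring converts "deviation from protocol" into a censoring
  process whose timing is fully determined by the observed data and the
  strategy definition;
* inverse-probability weighting removes the selection bias that this
  censoring introduces, because deviation is driven by prognostic
  covariates.

The headline estimands are absolute: risk difference and survival
difference at a horizon, and the difference in restricted mean survival
time (RMST, the area under the survival step function). Hazard ratios are
deliberately not a headline output; `per_interval_risk_check` warns when
weighted per-interval event risk reaches 10%, above which discrete-time
(pooled logistic) coefficients stop approximating hazard ratios.

## Time conventions

Time is integer units (default days) since each patient's own time zero.
The follow-up grid divides `(0, horizon]` into intervals of
`interval_length`; a final short interval is allowed and flagged. Day `t`
belongs to interval `(k·L, (k+1)·L]` with `k = (t−1)//L`.

Protocol windows are **closed on both ends**: a component on day
`window_end` is inside the window. An unmet *require* rule deviates **at**
`window_end` (the earliest time the deviation is visible in the data), not
the day after; this convention is applied consistently in the adherence
engine, the censoring step, and the weight-model risk sets. Death or classic
censoring at or before `window_end` preempts the deadline (the clone ends as
an event or classic censoring). A *forbid* rule deviates on the day the
forbidden component occurs; if that day is also the patient's event day, the
event wins (tie order **event > classic censoring > artificial censoring**,
which maximizes event capture — the day-112 death in the worked example is
an event in both arms precisely because of this rule).

Excusal conditions (e.g., incident cancer during a screening protocol)
suspend all requirements from their onset onward: violations dated at or
after the excusal time are discarded.

Recurring schedule rules ("repeat within 14 months of the last occurrence")
treat time zero and every occurrence as anchors; the deviation is dated
`last_anchor + window_end`. Trigger-anchored rules (dynamic strategies)
are dormant until the named covariate first becomes truthy; a companion
forbid rule can be `lift_on_trigger`-ed so that, e.g., therapy is forbidden
*until* progression and required *within 3 months after* it. For deferred
strategies with an additional absolute deadline ("or at least 2 years after
baseline"), the config encodes the precedence explicitly as the forbid
window's end; the engine does not guess.

Day-0 treatment events are post-baseline. Exclusions like "surgery in the
month before diagnosis" must be encoded as baseline flags and filtered by
eligibility criteria, which are baseline-only by contract (permuting
post-baseline records can never change the eligible set).

## Weight estimation

Let `p_j` be the probability of remaining free of artificial censoring in
interval `j` given covariates and time. The row weight is the cumulative
product `w_k = ∏_{j≤k} num_j / p_j`, with the censored clone's final row set
to weight 0.

**Risk sets.** The censoring model's risk set is *time-window based*: all
clones of an arm during the window in which the strategy can still censor
someone, regardless of whether the individual clone has already satisfied
its requirement. In an initiation arm during the grace period, clones that
already initiated stay in the risk set as "uncensored" outcomes — they are
exactly the mass that must be upweighted when the non-initiators are
censored at the window end. Rows after the window (or after a trigger-lifted
forbid window closes) have structurally zero censoring hazard and contribute
probability 1. For sequential strategies the chained window depends on the
prior component's completion day; the at-risk flag is conservative there
(treated as open until the horizon).

**Estimators.** Two are provided per arm: exact empirical proportions per
(covariate-stratum × interval) cell — the saturated/nonparametric choice,
which enables exact conservation checks — and pooled logistic regression on
the interval-level rows with a flexible time term. Time enters as
categorical interval when the grid has ≤ 20 intervals, else as a cubic
B-spline with 4 df (knots at quantiles); polynomial time is also available.
Design matrices are built directly (numeric columns as-is, categorical
columns expanded to indicators), so no formula library is involved.

**Stabilization** replaces the numerator 1 with a model conditioning on a
baseline-covariate subset plus time. When the denominator itself uses only
baseline covariates, stabilizing on the same set reproduces weights ≡ 1
(self-stabilization), so the default is unstabilized; stabilization is the
right tool when time-varying covariates enter the denominator, and the
worked example's reference weights (5/4 and 4) are unstabilized.

**Truncation** caps weights at a sample percentile of the positive row
weights. The percentile is the inverted-CDF definition (the smallest
observed weight with cumulative frequency ≥ p), so the cap is always an
observed weight value: for weights {1,1,1,1,100} the 80th percentile is 1
and the outlier is capped to 1. The number of capped rows is reported.

**IPTW implementation.** For single-component initiation/abstention pairs
the weights can equivalently be computed from a treatment-initiation model
fitted in the *original* (uncloned) cohort person-time: per-interval
non-initiation factors for the abstention arm and the probability of
initiation within the grace window, applied at the window-end interval, for
the initiation arm. With empirical (saturated) models both implementations
reduce to the same within-stratum proportions and coincide to machine
precision; with smooth models they agree only up to modeling error. Other
strategy kinds raise `NotImplementedError` and should use IPCW.

**Classic censoring.** Informative loss to follow-up is handled by a second
discrete-time model predicting remaining free of loss (`end_reason ==
"lost"`; administrative end of study is treated as non-informative), whose
inverse-probability weight multiplies the artificial-censoring weight
row-wise.

**Positivity.** Any fitted uncensored-probability below 1e-6 triggers a
`PositivityWarning` naming the stratum/interval cells; a probability of 0
attached to person-time that survives censoring raises `PositivityError`
(e.g., an abstention arm in which everyone initiates immediately).

## Risk-set conservation (what is exact and what is not)

With unstabilized stratum-empirical weights, reweighting restores — exactly,
in every (arm, interval, stratum) cell — the at-risk mass present
immediately before that interval's artificial censoring:

```
Σ_{rows uncensored through j} w_j  =  Σ_{all rows at j} w_{j−1}
```

since `w_j = w_{j−1} · n/(n−c)` for the `n−c` uncensored of `n` at risk.
`check_risk_set_conservation` verifies this identity per cell.

Two caveats are worth stating precisely. First, the identity cannot be
strengthened to "equals the at-risk count of the *fully uncensored* clone
table at every interval": a patient may die after their clone was
artificially censored (the worked example's patient 1 dies on day 300, long
after its abstention-arm clone was censored on day 90), and from that
moment the uncensored table's risk set contains deaths the weighted table
cannot see; the finite-sample identity necessarily breaks there. Second, a
cell in which *every* at-risk clone is censored in the same interval (a
structural positivity failure) loses its weight mass entirely; such cells
are flagged `exhausted` in the conservation report and have already raised
a positivity warning during weighting.

## Outcome estimation

The weighted Kaplan–Meier estimator uses, per interval, the weighted event
mass `dw` and the weighted risk set `nw` = total weight of the interval's
positive-weight rows; events are processed before same-interval censorings.
RMST integrates the resulting step function exactly (no smoothing). The
weighted pooled-logistic outcome model (arm + time + arm×time) predicts
cumulative incidence as `1 − ∏(1 − hazard)`; with categorical interval time
and no covariates the model is saturated, its maximum-likelihood hazards are
the weighted per-cell event proportions (computed in closed form rather than
by iterative fitting), and the predictions equal `1 − KM` identically —
a property the test suite asserts at 1e-12.

## Uncertainty

Clones of one patient are correlated, so naive variance estimates are
invalid. `bootstrap_ci` resamples **patients** with replacement (B = 500 by
default; percentile intervals) and re-runs cloning, censoring, weight
estimation, and estimation inside every replicate. Replicates that fail —
typically an arm emptying in a small resample — are excluded and counted,
and the count is reported alongside the interval. For the common two-arm
design with empirical weights on discrete baseline strata, an aggregated
count-based engine (`ccw._fast`) evaluates the identical algebra from
bincounted per-interval totals; a dedicated test asserts it matches the
row-level pipeline to float precision, and the bootstrap dispatches to it
automatically when applicable. A robust (sandwich) variance is deliberately
not implemented; the bootstrap is the reference method here.

## Balance diagnostics

`weighted_smd` reports, per covariate, the standardized mean difference
between two arms among clones at risk at a reference time (default: the
latest grace-period end): `SMD = (m_A − m_B) / sqrt((v_A + v_B)/2)`, with
proportion variance `p(1−p)` for binary covariates and indicator expansion
for categorical ones. At time 0 every SMD is exactly 0 (the cloning
identity). The at-risk snapshot necessarily omits clones whose event
preceded the reference time; the report carries that caveat in its `note`.
`weight_summary` reports per-arm mean/median/tails/max of the positive row
weights (stabilized weights should average ≈ 1).

## The synthetic-data generator

`simulate_cohort` draws, per subject: a binary frailty `Z` (P(Z=1) = 0.5),
then a day-by-day loop over the horizon (365 days) with Bernoulli hazards —
initiation first (while untreated), then the outcome event, then dropout.
Initiation on day `t` switches the event hazard to the treated value from
day `t` on. Defaults: daily initiation probability 0.010 (Z=0) vs 0.004
(Z=1); daily event probability 0.0008 vs 0.0030; grace period 182 days.
These give one-year mortality of ~25% vs ~66% and within-grace initiation of
~84% vs ~52% — the frail die more and initiate less, so a naive
ever-treated analysis is biased in favor of treatment by both confounding
and immortal person-time, while positivity remains comfortable in both
arms. The effect scenario multiplies the treated daily odds by
`exp(−0.6)`, calibrated once against the counterfactual oracle so the true
one-year risk difference is ≈ −0.10.

`oracle_truth` computes the truth by forced-adherence Monte Carlo on a
large population (default 10⁶) from the same generative law: arm A
initiates at the natural day, forced at the grace end if later; arm B never
initiates. Dropout is missingness, not outcome, and is ignored in the
counterfactual. Under the null the two potential outcomes coincide subject
by subject, so the reported risk difference is exactly 0. The oracle's
Monte Carlo standard error is reported.

Two deliberate design points. (1) The generator's clock is the pipeline's
discrete grid, so oracle and estimator target the same discrete-time law
with no continuous-time approximation error. (2) The validation strategy
pair is "initiate within the grace window" vs **"never initiate during
follow-up"** (`simulation_strategies`), because that is the oracle's arm B.
A grace-window-only abstention arm (as in the worked example) tolerates
late initiation, and under a protective effect its observational survival
exceeds the never-initiate counterfactual — an estimand difference, not an
estimator bias. The worked example keeps the within-window abstention arm,
whose reference trace requires it.

What the generator does **not** emulate: time-varying confounders beyond
the optional progression trigger (hence no treatment–confounder feedback in
the default scenarios), measurement error, calendar-time trends, competing
risks, or re-eligibility. Passing tests therefore demonstrate correctness
of the machinery under a known law with a single measured confounder — not
robustness to the richer failure modes of real registry data, where weight
models must be specified with care.

## Problem sizes used in validation

The shipped checks use: the 5-patient worked example (exact, hand-derived);
n = 500 for exact conservation; n = 2000 for the null bias demonstration
and balance diagnostics; n = 5000 against a 10⁶-subject oracle for effect
recovery (tolerance ±0.03, several oracle SEs wide); 100 cohorts × B = 200
patient-bootstraps (n = 500) for CI coverage, asserted ≥ 0.88 against a
nominal 0.95. These sizes make the full suite run in a few minutes on one
CPU while keeping Monte Carlo error well inside every asserted tolerance.

## Known limitations

* IPTW covers single-window initiation/abstention designs only.
* The censoring-risk flag for sequential strategies is conservative; weight
  models there may include structurally risk-free rows late in follow-up.
* The SMD-at-grace-end snapshot is the only balance diagnostic; it excludes
  early events by construction and has no time-resolved alternative here.
* One enrollment per patient per run; repeated/multi-cohort enrollment is
  handled by invoking the pipeline once per cohort.
* Competing risks, M-estimation/sandwich variance, g-computation, and
  doubly robust weight estimators are out of scope.

## Run configuration schema

```yaml
inputs: {patients: p.csv, treatments: t.csv, covariates: c.csv}  # covariates optional
grid: {unit: day, horizon: 365, interval_length: 1}
eligibility:
  - {covariate: age, op: between, value: [70, 89]}   # ops: between, ==, !=, <=, >=, in
strategies:
  - id: surgery
    kind: initiation          # initiation | abstention | sequential | schedule | dynamic
    components:
      - {component: surgery, mode: require, window: [0, 182], anchor: time-zero}
    excusals: []              # e.g. [{condition: incident_cancer}]
  - id: no_surgery
    kind: abstention
    components:
      - {component: surgery, mode: forbid, window: [0, 182]}
weights:
  implementation: ipcw        # ipcw | iptw | nonparametric
  estimator: pooled-logistic  # pooled-logistic | empirical
  denominator: [z]
  numerator: []               # non-empty (or stabilized: true) => stabilized
  time_form: default          # categorical | spline:4 | polynomial:2
  truncation_percentile: null
  classic: false              # loss-to-follow-up weights
estimation:
  arms: [surgery, no_surgery]
  estimands: [survival_difference, risk_difference, rmst_difference]
  horizon: 365
  bootstrap: {B: 500, seed: 7}   # B: 0 => point estimates only
output: out/
```
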