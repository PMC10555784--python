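# Methods

## Measurement-error model

All corrections in this package assume the **classical additive error
model**: an observation of variable `v` at occasion `o ∈ {1, 2}` is

```
X_o = T + δ·1[o = 2] + e_o,    e_o ~ N(0, σe²),
```

with the errors independent of the truth `T`, independent across
occasions, and homoscedastic. `δ` is a constant systematic shift at the
repeat occasion (an instrument or protocol change); the reliability is
`R = var(T) / (var(T) + σe²)`. Under this model the two-occasion
single-measurement ICC estimates `R`, the regression coefficient of an
outcome on `X₁` converges to `R·β` (regression dilution), and both
correction routes below are consistent. Berkson-type error, error
correlated with the truth or with the outcome, and differential error
all violate these assumptions; results under them may be biased in
either direction and the package makes no attempt to detect them
beyond the accuracy coefficient's check on location/scale shifts.

## Agreement metrics

**ICC.** From the balanced two-way (subjects × occasions) ANOVA with
mean squares MSR (rows/subjects), MSC (columns/occasions) and MSE
(residual), the single-measurement forms are

- consistency: `(MSR − MSE) / (MSR + (k−1)·MSE)`
- absolute agreement: `(MSR − MSE) / (MSR + (k−1)·MSE + k(MSC − MSE)/n)`

with `k = 2` occasions. **Absolute agreement is the default** — for
test–retest data the occasion effect (e.g. drift between visits) is a
real disagreement, not noise to be conditioned away. Confidence
intervals use the exact F-bound transformation for the consistency form
and the Satterthwaite-degrees-of-freedom approximation for absolute
agreement; both are validated against pingouin's independent
implementation in the test suite. Degenerate zero-residual tables
return a point interval; negative ICC estimates are reported as-is but
flagged, and no correction factor is emitted for ICC ≤ 0.

**Accuracy coefficient.** Lin's bias-correction component with
population (divide-by-n) moments, `Cb = 2σ₁σ₂/(σ₁² + σ₂² + (μ₁−μ₂)²)`;
a sample-moments variant is available by flag. Under a pure location
shift of `u = δ/σ` standard deviations, `Cb → 2/(2 + u²)`.

**Variance of the ICC.** Estimated by a seeded nonparametric bootstrap
over participants (default B = 1000). An asymptotic formula would also
work; the bootstrap was chosen because it is assumption-light and the
derived quantities are tied together by exact delta-method identities
regardless of the estimator: `var(1/λ̂) = var(ICĈ)` and
`var(λ̂) = var(ICĈ)/ICĈ⁴`, so `var(1/λ̂) = var(λ̂)/λ̂⁴` always holds.

## Dilution correction of a fitted estimate

`β* = λ̂·β̂` with `λ̂ = 1/ICĈ`. The interval solves the quadratic in the
Frost–Thompson construction (`f0/f1/f2` as in the README); the
covariance `cov(β̂, 1/λ̂)` defaults to 0, appropriate when the repeat
subsample is disjoint from — or a small fraction of — the main analysis
sample; a nonzero value is accepted for sensitivity analyses. When
`f2 ≤ 0` (correction factor too imprecise) or the discriminant is
negative (possible only with a nonzero covariance term), the operation
raises rather than clamping: a clamped interval would fabricate
coverage. Ratio measures (hazard/odds ratios) are corrected on the log
scale with `var(β̂) = ((ln U − ln L)/(2z))²` recovered from the Wald
interval, then exponentiated.

This route corrects the exposure only; random error in confounders is
out of its reach by construction and is handled by regression
calibration.

## Regression calibration

First stage: OLS of the error-prone covariable's occasion-2 value on
its occasion-1 value plus the occasion-1 values of every other
covariable in the outcome model (categoricals as indicator contrasts,
reference = first observed level), complete-case within the repeat
subsample. When several covariables are error-prone, each first-stage
model uses the *observed* values of the others (simultaneous, not
iterated). Predictions are made for the whole cohort, including the
repeat subsample. Second stage: the outcome model refitted on the
predicted values; linear and logistic through statsmodels, Cox through
the lifelines partial likelihood.

**Bootstrap.** Because first-stage estimation error invalidates
model-based second-stage standard errors, intervals come from
resampling participants with replacement from the full cohort and
refitting both stages within each replicate (default 10 000 replicates;
percentile 2.5/97.5 limits; a normal-approximation interval is
available). Repeat-subsample membership travels with the resampled
rows, so both stages' sampling variability is captured jointly.
Replicates with an empty or rank-deficient repeat subsample are skipped
and counted; more than 10% skipped aborts with an error. For the linear
and Cox families the per-replicate refits run through a vectorised
least-squares / Newton path (the Cox solver maximises the Breslow
partial likelihood; it is tested against lifelines at 1e-5 on tie-free
data — resampled replicates contain tied times, where Breslow and
Efron weighting differ negligibly). The logistic family refits through
statsmodels per replicate.

## Synthetic cohort generator

The generator emulates a biobank-style design: a baseline measurement
for everyone, a retest for a seeded simple-random subsample of exactly
`round(n·repeat_fraction)` participants (default 10%), correlated
multivariate-normal true covariables, classical error at configurable
per-variable reliability, an optional occasion-2 shift, error-free
categorical confounders, and survival outcomes with exponential event
times under exact proportional hazards, administratively censored at a
follow-up horizon (default 12 years). When a target event fraction is
given, the baseline hazard is solved by bisection on the realised
uniform draws, which hits the target exactly in distribution while
keeping proportional hazards and the known true log-hazards intact —
chosen over thinning by extra random censoring because it leaves the
generator's effect parameters directly interpretable as the Cox
estimands. All randomness derives from one integer seed; outputs are
bit-identical across calls.

What the generator does **not** emulate: non-Gaussian or skewed true
values, heteroscedastic or truth-correlated error, informative
missingness in the repeat subsample, non-proportional hazards,
competing risks, and misclassification of categorical covariables.
Passing tests therefore demonstrate correctness of the estimators under
the classical model, not robustness to its violations in real data.

## Variable screening

Eligibility rules, applied in fixed precedence so reason counts are
deterministic: (1) a repeat measurement must exist; (2) the variable
must be continuous — integer-coded measures qualify only with more than
20 distinct values; (3) no single value may be shared by more than 20%
of participants; (4) at least 100 complete repeat pairs. Boundaries are
strict as stated: a 20% share and 100 pairs pass; 20 distinct integer
values fail. The tie share and continuity class are assessed on
occasion-1 values, the measure actually analysed. Threshold-coded
strings such as "≤1" substitute their boundary value by default (a
map-to-missing policy is available); multiple readings within a visit
collapse to the mean of valid readings (first-valid available).
Study-specific ineligibility (derived/data-processing fields) is the
caller's responsibility via an allowlist; no heuristic is attempted.

## Problem sizes and defaults

Defaults reflect the design the package emulates: 10% repeat fraction,
two-sided 95% intervals (`z = 1.96`, configurable), 10 000 bootstrap
replicates for reported analyses, B = 1000 for the ICC-variance
bootstrap. The test suite exercises the same estimators at reduced
sizes chosen to keep Monte-Carlo error well inside the asserted
tolerances: reliability recovery at n = 20 000 pairs (±0.02), linear
recovery at n = 50 000 (slope ±0.05), Cox recovery at n = 20 000 with
~30% events (log-hazard ±0.05), and bootstrap coverage at 200 cohorts
of n = 2000 with 500 replicates each (coverage 95% ± 4%).

## Known limitations

- The ICC route cannot correct confounder error; the calibration route
  corrects only continuously measured covariables with repeats.
  Misclassified categorical covariables are out of scope.
- Regression calibration is exactly unbiased for linear models and only
  approximately so for Cox and logistic models; the approximation is
  good for modest effects and event fractions but degrades for large
  log-hazards.
- Percentile bootstrap intervals can be asymmetric around the point
  estimate and, in tiny cohorts, may fail to contain it.
- A corrected estimate inherits every other bias of the uncorrected
  analysis (confounding, selection, systematic error); correction for
  random error alone can move an estimate away from the true value when
  other biases act in the opposite direction.
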