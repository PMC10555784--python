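# regdilute

Tools to quantify and correct **regression dilution bias** — the
attenuation of a regression coefficient toward the null caused by
random measurement error in a continuous covariable — using repeat
measurements collected on a subsample of a cohort. It is aimed at
epidemiologists working with prospective cohorts (large biobank-style
studies that re-measure ~10% of participants at a retest visit) who
want to screen which variables are usable, estimate each variable's
reliability, and report exposure–outcome associations corrected for
measurement error in the exposure and in continuously measured
confounders.

## The statistics

Under the classical error model an observation is
`X = T + e`, `e ~ N(0, σe²)` independent of the truth `T`, and the
**reliability** is `R = var(T)/var(X)`. A linear (or, approximately, a
log-hazard / log-odds) coefficient fitted on `X` converges to `R·β`
instead of `β`.

- **ICC** — with two occasions per participant, the single-measurement
  intraclass correlation from the balanced two-way mixed-effects ANOVA
  (subjects × occasions) estimates `R`. Both the absolute-agreement and
  consistency forms are available; absolute agreement is the default
  for test–retest data.
- **Accuracy coefficient** — Lin's bias-correction component
  `Cb = 2σ₁σ₂ / (σ₁² + σ₂² + (μ₁−μ₂)²)` flags *systematic* differences
  between occasions (`Cb = 1` means none).
- **Correction factor** — `λ̂ = 1/ICC` multiplies the uncorrected
  coefficient: `β* = λ̂·β̂`. The confidence interval propagates the
  uncertainty in both `β̂` and `λ̂` through the Frost–Thompson
  quadratic: with `f0 = β̂² − z²·var(β̂)`,
  `f1 = β̂/λ̂ − z²·cov(β̂, 1/λ̂)`, `f2 = 1/λ̂² − z²·var(1/λ̂)`, the 95% CI
  for `β*` is `[f1 ± √(f1² − f0·f2)] / f2`.
- **Regression calibration** — to correct the exposure *and*
  error-prone confounders together: each error-prone covariable's
  repeat measurement is regressed on its baseline measurement plus all
  other covariables (first stage, fitted on the repeat subsample);
  the fitted values, predicted for the whole cohort, replace the
  observed values in the outcome model (second stage: linear, logistic
  or Cox). Confidence intervals come from bootstrapping the whole
  two-stage process.

A synthetic cohort generator with configurable reliabilities, occasion-2
systematic shifts, correlated true covariables and proportional-hazards
survival outcomes makes every stage testable end to end with known truth.

## Worked example

```python
from regdilute import correct_ratio_measure

hr, (lo, hi) = correct_ratio_measure(
    ratio=1.203, ci=(1.194, 1.212),   # uncorrected hazard ratio
    lam=1.9356,                        # correction factor 1/ICC (ICC = 0.52)
    var_inv_lam=0.000029,              # variance of 1/lambda
)
print(f"{hr:.3f} ({lo:.3f}, {hi:.3f})")
```

prints

```
1.430 (1.407, 1.454)
```

— a hazard ratio of 1.203 per unit of an exposure whose test–retest ICC
is 0.52 strengthens to 1.430 once the attenuation from random
measurement error is undone; the interval is wider than the uncorrected
one because the correction factor is itself estimated.

The `examples/` directory holds one short script per capability
(simulation, screening, the agreement catalogue, Frost correction,
regression calibration, and the four-model comparison report), each
printing the numbers it computes and what they mean. The same stages
are available from the shell via the `regdilute` command
(`simulate`, `screen`, `scan`, `correct`, `calibrate`, `report`).

## Layout

- `src/regdilute/simulate.py` — synthetic cohort generator
- `src/regdilute/screening.py` — variable eligibility rules
- `src/regdilute/agreement.py` — ICC, accuracy coefficient, correction factor
- `src/regdilute/correction.py` — Frost-interval dilution correction
- `src/regdilute/calibration.py` — two-stage regression calibration + bootstrap
- `src/regdilute/pipeline.py`, `cli.py` — orchestration and shell interface
- `docs/methods.md` — models, assumptions, numerical choices, limitations
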