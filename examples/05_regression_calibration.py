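"""Two-stage regression calibration of a survival association.

A sole exposure with reliability 0.5 and true log-hazard 0.3: the
uncorrected Cox coefficient attenuates toward 0.15; calibrating the
exposure (regressing its repeat measurement on the baseline one and
predicting for everybody) restores the truth, and the whole-process
bootstrap gives an interval that carries first-stage uncertainty.
"""

import numpy as np

from regdilute import (
    CovariableRole, OutcomeSpec, SimulationConfig, VariableSpec,
    bootstrap_calibration, fit_second_stage, simulate_cohort,
)

config = SimulationConfig(
    n_participants=20_000,
    variables=[VariableSpec("x", reliability=0.5, role="exposure")],
    repeat_fraction=0.10,
    outcome=OutcomeSpec(log_hazards={"x": 0.3}, horizon=12.0,
                        target_event_fraction=0.30),
    seed=7,
)
cohort = simulate_cohort(config)
roles = [CovariableRole("x", "exposure", error_prone=True)]

uncorrected = fit_second_stage(cohort, roles, "cox")
est = bootstrap_calibration(cohort, roles, "cox", reps=500, seed=1)

b_u = uncorrected.coefficients["x__i1"]
b_c = est.coefficients["x__i1"]
lo, hi = est.bootstrap_ci["x__i1"]
print(f"true log-hazard:        0.300  (HR {np.exp(0.3):.3f})")
print(f"uncorrected estimate:   {b_u:.3f}  (HR {np.exp(b_u):.3f})")
print(f"calibrated estimate:    {b_c:.3f}  (HR {np.exp(b_c):.3f})")
print(f"bootstrap 95% CI (log): ({lo:.3f}, {hi:.3f})")
# The uncorrected estimate sits near reliability * truth = 0.15; the
# calibrated one recovers ~0.3, and the percentile interval is wider
# than the naive Wald interval because both stages are resampled.
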