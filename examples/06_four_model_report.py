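"""The four-model comparison for one exposure-outcome association.

(i) uncorrected Cox model; (ii) exposure corrected by the reciprocal-ICC
factor with the Frost interval; (iii) exposure corrected by regression
calibration; (iv) exposure and error-prone confounders calibrated
together. With an error-prone exposure and a nearly error-free
confounder, rows (ii)-(iv) move away from the null and rows (iii) and
(iv) nearly coincide.
"""

import numpy as np

from regdilute import (
    AnalysisConfig, CovariableRole, OutcomeSpec, SimulationConfig,
    VariableSpec, person_years_rate, run_corrected_analysis, simulate_cohort,
)

config = SimulationConfig(
    n_participants=10_000,
    variables=[
        VariableSpec("x", reliability=0.5, role="exposure"),
        VariableSpec("c", reliability=0.93, role="confounder"),
    ],
    true_correlation=np.array([[1.0, 0.3], [0.3, 1.0]]),
    repeat_fraction=0.20,
    outcome=OutcomeSpec(log_hazards={"x": 0.4, "c": 0.2}, horizon=12.0,
                        target_event_fraction=0.3),
    seed=5,
)
cohort = simulate_cohort(config)

rate = person_years_rate(cohort["time"], cohort["event"])
print(f"deaths: {rate['deaths']}, person-years: {rate['person_years']:.0f}, "
      f"rate {rate['rate_per_1000']:.2f}/1000 py "
      f"({rate['ci'][0]:.2f}, {rate['ci'][1]:.2f})")

analysis = AnalysisConfig(
    roles=[CovariableRole("x", "exposure", error_prone=True),
           CovariableRole("c", "confounder", error_prone=True)],
    family="cox", bootstrap_reps=1000, seed=1,
)
table = run_corrected_analysis(cohort, analysis)
print()
print(table.frame().round(3).to_string(index=False))
# Row (i) is attenuated by the exposure's reliability of 0.5; every
# corrected row sits farther from HR = 1. Because the confounder is
# nearly error-free, calibrating it too (row iv) barely changes row iii.
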