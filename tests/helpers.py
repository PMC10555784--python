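import numpy as np

from regdilute import (
    SimulationConfig,
    VariableSpec,
    attach_linear_outcome,
    simulate_cohort,
)


def make_linear_cohort(n, reliability, beta, seed, repeat_fraction=0.10,
                       noise_sd=1.0):
    """Cohort with one error-prone exposure and a linear outcome on the truth."""
    cfg = SimulationConfig(
        n_participants=n,
        variables=[VariableSpec("x", 0.0, 1.0, reliability=reliability,
                                role="exposure")],
        repeat_fraction=repeat_fraction,
        seed=seed,
    )
    cohort, truth = simulate_cohort(cfg, return_truth=True)
    return attach_linear_outcome(cohort, truth, {"x": beta}, noise_sd=noise_sd,
                                 seed=seed + 100_000)
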