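import numpy as np
import pandas as pd
import pytest

from regdilute import CovariableRole, OutcomeSpec, SimulationConfig, VariableSpec


@pytest.fixture
def toy_pairs():
    """The 4x2 hand-ANOVA table: occasion 2 is occasion 1 plus one."""
    from regdilute import PairedMeasures

    return PairedMeasures([0, 1, 2, 3], [1, 3, 5, 7], [2, 4, 6, 8])


@pytest.fixture
def sole_exposure_config():
    """One error-prone exposure at reliability 0.5, survival outcome with
    ~30% events: the canonical attenuation scenario."""
    return SimulationConfig(
        n_participants=20_000,
        variables=[VariableSpec("x", 0.0, 1.0, reliability=0.5, role="exposure")],
        repeat_fraction=0.10,
        outcome=OutcomeSpec(log_hazards={"x": 0.3}, horizon=12.0,
                            target_event_fraction=0.30),
        seed=7,
    )


@pytest.fixture
def exposure_role():
    return [CovariableRole("x", "exposure", error_prone=True)]
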