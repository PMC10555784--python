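"""Configuration objects for the synthetic cohort generator.

The generator emulates the structure of a large prospective cohort in
which every participant is measured once at baseline and a random
subsample (typically ~10%) returns for a second, repeat measurement.
Continuous covariables are observed under the classical additive error
model at a configurable reliability R = var(truth)/var(observed), with
an optional constant systematic shift at the repeat occasion, and the
outcome is a censored survival time generated from a proportional
hazards model on the latent true values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Literal

import numpy as np
import yaml

Role = Literal["exposure", "confounder", "noise"]


@dataclass
class VariableSpec:
    """One continuous covariable observed with classical error.

    Parameters
    ----------
    name
        Column stem; occasion columns are ``<name>__i1`` / ``<name>__i2``.
    true_mean, true_sd
        Moments of the latent (error-free) value.
    reliability
        R in (0, 1]: the fraction of observed variance that is true
        variance. The measurement-error variance is
        ``true_sd**2 * (1 - R) / R`` so that var(truth)/var(observed) = R.
    shift
        Constant additive systematic difference applied at occasion 2
        only (e.g. an instrument change between visits). Default 0.
    role
        How the variable enters the outcome analysis.
    """

    name: str
    true_mean: float = 0.0
    true_sd: float = 1.0
    reliability: float = 1.0
    shift: float = 0.0
    role: Role = "noise"

    def __post_init__(self) -> None:
        if not (0.0 < self.reliability <= 1.0):
            raise ValueError(
                f"reliability for {self.name!r} must be in (0, 1], got {self.reliability}"
            )
        if self.true_sd < 0:
            raise ValueError(f"true_sd for {self.name!r} must be >= 0")


@dataclass
class CategoricalConfounderSpec:
    """An error-free categorical confounder with per-level log-hazards."""

    name: str
    levels: list[str]
    level_probabilities: list[float]
    log_hazards: list[float]

    def __post_init__(self) -> None:
        if len(self.levels) != len(self.level_probabilities) or len(self.levels) != len(
            self.log_hazards
        ):
            raise ValueError(f"level lists for {self.name!r} must have equal length")
        if abs(sum(self.level_probabilities) - 1.0) > 1e-8:
            raise ValueError(f"level_probabilities for {self.name!r} must sum to 1")


@dataclass
class OutcomeSpec:
    """Proportional-hazards outcome: exponential event times, administrative
    censoring at ``horizon`` years, optionally calibrated to a target event
    fraction by solving for the baseline hazard."""

    log_hazards: dict[str, float] = field(default_factory=dict)
    baseline_hazard: float = 0.01
    horizon: float = 12.0
    target_event_fraction: float | None = None

    def __post_init__(self) -> None:
        if self.horizon <= 0:
            raise ValueError("follow-up horizon must be > 0")
        if self.baseline_hazard <= 0 and self.target_event_fraction is None:
            raise ValueError("baseline_hazard must be > 0 (or give target_event_fraction)")
        if self.target_event_fraction is not None and not (
            0.0 < self.target_event_fraction < 1.0
        ):
            raise ValueError("target_event_fraction must be in (0, 1)")


@dataclass
class SimulationConfig:
    """Full recipe for one synthetic cohort.

    ``true_correlation`` is the correlation matrix of the latent true
    values across ``variables`` (row/column order follows the variable
    list); it must be symmetric positive-definite with unit diagonal.
    """

    n_participants: int
    variables: list[VariableSpec]
    repeat_fraction: float = 0.10
    true_correlation: np.ndarray | None = None
    categorical_confounders: list[CategoricalConfounderSpec] = field(default_factory=list)
    outcome: OutcomeSpec = field(default_factory=OutcomeSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("n_participants must be >= 2")
        if not (0.0 <= self.repeat_fraction <= 1.0):
            raise ValueError("repeat_fraction must be in [0, 1]")
        p = len(self.variables)
        if self.true_correlation is None:
            self.true_correlation = np.eye(p)
        else:
            self.true_correlation = np.asarray(self.true_correlation, dtype=float)
        c = self.true_correlation
        if c.shape != (p, p):
            raise ValueError(f"correlation matrix must be {p}x{p}")
        if not np.allclose(c, c.T):
            raise ValueError("correlation matrix must be symmetric")
        if not np.allclose(np.diag(c), 1.0):
            raise ValueError("correlation matrix must have unit diagonal")
        if np.linalg.eigvalsh(c).min() <= 0:
            raise ValueError("correlation matrix must be positive definite")

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    def to_dict(self) -> dict:
        d = asdict(self)
        d["true_correlation"] = np.asarray(self.true_correlation).tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["variables"] = [VariableSpec(**v) for v in d.get("variables", [])]
        d["categorical_confounders"] = [
            CategoricalConfounderSpec(**c) for c in d.get("categorical_confounders", [])
        ]
        if "outcome" in d and isinstance(d["outcome"], dict):
            d["outcome"] = OutcomeSpec(**d["outcome"])
        if d.get("true_correlation") is not None:
            d["true_correlation"] = np.asarray(d["true_correlation"], dtype=float)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
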