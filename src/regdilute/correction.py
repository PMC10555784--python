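"""Regression dilution correction of a fitted effect via the ICC method.

An uncorrected coefficient beta-hat on the linear or log scale
(difference in means, log odds, logit, log hazard) is multiplied by the
correction factor lambda = 1/ICC to undo attenuation. The confidence
interval for the corrected estimate propagates the uncertainty in both
beta-hat and the correction factor through the Frost & Thompson
quadratic construction:

    f0 = beta^2 - z^2 var(beta)
    f1 = beta/lambda - z^2 cov(beta, 1/lambda)
    f2 = 1/lambda^2 - z^2 var(1/lambda)

    CI = [ f1 -/+ sqrt(f1^2 - f0 f2) ] / f2

The covariance term is 0 when the repeat-measures sample is distinct
from (or a small subset of) the main analysis sample, the default here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "CorrectionInput",
    "CorrectedEstimate",
    "correct_estimate",
    "frost_ci",
    "correct_ratio_measure",
]


@dataclass
class CorrectionInput:
    beta: float
    var_beta: float
    lam: float
    var_inv_lam: float
    cov_beta_inv_lam: float = 0.0
    z: float = 1.96

    def __post_init__(self) -> None:
        if self.var_beta < 0 or self.var_inv_lam < 0:
            raise ValueError("variances must be non-negative")
        if self.lam <= 0:
            raise ValueError("correction factor must be positive")
        if self.z <= 0:
            raise ValueError("z must be positive")


@dataclass
class CorrectedEstimate:
    beta_star: float
    ci: tuple[float, float]
    f0: float = field(repr=False, default=float("nan"))
    f1: float = field(repr=False, default=float("nan"))
    f2: float = field(repr=False, default=float("nan"))

    @property
    def discriminant(self) -> float:
        return self.f1**2 - self.f0 * self.f2


def correct_estimate(beta: float, lam: float) -> float:
    """beta* = lambda * beta; requires lambda > 0."""
    if lam <= 0:
        raise ValueError("correction factor must be positive")
    return lam * beta


def frost_ci(inp: CorrectionInput) -> CorrectedEstimate:
    """Corrected estimate with the quadratic-root confidence interval.

    Raises when f2 <= 0 (the correction factor is too imprecise for the
    interval to exist) or when the discriminant is negative (the
    interval is undefined for these inputs); clamping in either case
    would fabricate coverage.
    """
    z2 = inp.z**2
    f0 = inp.beta**2 - z2 * inp.var_beta
    f1 = inp.beta / inp.lam - z2 * inp.cov_beta_inv_lam
    f2 = 1.0 / inp.lam**2 - z2 * inp.var_inv_lam
    if f2 <= 0:
        raise ValueError("correction factor too imprecise (f2 <= 0); CI does not exist")
    disc = f1**2 - f0 * f2
    if disc < 0:
        raise ValueError("CI undefined for these inputs (negative discriminant)")
    root = np.sqrt(disc)
    lower = (f1 - root) / f2
    upper = (f1 + root) / f2
    return CorrectedEstimate(
        beta_star=correct_estimate(inp.beta, inp.lam),
        ci=(min(lower, upper), max(lower, upper)),
        f0=f0, f1=f1, f2=f2,
    )


def var_from_ci(lower: float, upper: float, z: float = 1.96, log_scale: bool = True
                ) -> float:
    """Recover a sampling variance from a symmetric Wald interval,
    ((ln U - ln L)/(2z))^2 on the log scale."""
    if log_scale:
        lower, upper = np.log(lower), np.log(upper)
    return float(((upper - lower) / (2 * z)) ** 2)


def correct_ratio_measure(
    ratio: float,
    ci: tuple[float, float],
    lam: float,
    var_inv_lam: float,
    z: float = 1.96,
    cov_beta_inv_lam: float = 0.0,
) -> tuple[float, tuple[float, float]]:
    """Correct a ratio measure (hazard ratio, odds ratio) with its CI.

    Converts to the log scale (beta = ln ratio, var(beta) from the
    interval half-width), applies the Frost correction, and
    exponentiates back.
    """
    lower, upper = ci
    if ratio <= 0 or not (0 < lower < upper):
        raise ValueError("ratio and CI must be positive with lower < upper")
    inp = CorrectionInput(
        beta=float(np.log(ratio)),
        var_beta=var_from_ci(lower, upper, z),
        lam=lam,
        var_inv_lam=var_inv_lam,
        cov_beta_inv_lam=cov_beta_inv_lam,
        z=z,
    )
    est = frost_ci(inp)
    return float(np.exp(est.beta_star)), (float(np.exp(est.ci[0])), float(np.exp(est.ci[1])))
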