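"""Agreement between repeat measurements: random and systematic error.

Random error is quantified by the intraclass correlation coefficient
(ICC) from a balanced two-way (subjects x occasions) mixed-effects
ANOVA; under the classical error model the ICC estimates the
reliability ratio var(truth)/var(observed). Systematic error is
quantified by Lin's accuracy coefficient

    Cb = 2*s1*s2 / (s1^2 + s2^2 + (m1 - m2)^2),

which is 1 exactly when the two occasions agree in mean and spread and
drops below 1 under a location or scale shift. The correction factor
for regression dilution is the reciprocal of the ICC, lambda = 1/ICC;
its sampling variance follows from the variance of the ICC by the
first-order delta method, var(lambda) = var(ICC)/ICC^4.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
import scipy.stats as st

Convention = Literal["absolute_agreement", "consistency"]

__all__ = [
    "PairedMeasures",
    "AnovaDecomposition",
    "AgreementResult",
    "anova_decompose",
    "icc_estimate",
    "accuracy_coefficient",
    "var_icc",
    "reliability_statistics",
    "assess_agreement",
    "summarize_categories",
]


@dataclass
class PairedMeasures:
    """Complete pairs of the same variable measured on two occasions."""

    ids: np.ndarray
    occasion1: np.ndarray
    occasion2: np.ndarray

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids)
        self.occasion1 = np.asarray(self.occasion1, dtype=float)
        self.occasion2 = np.asarray(self.occasion2, dtype=float)
        if not (len(self.ids) == len(self.occasion1) == len(self.occasion2)):
            raise ValueError("ids and occasions must have equal length")
        if len(self.occasion1) < 2:
            raise ValueError("need at least 2 complete pairs")
        if not (np.all(np.isfinite(self.occasion1)) and np.all(np.isfinite(self.occasion2))):
            raise ValueError("paired measures must be finite (drop incomplete pairs first)")

    @classmethod
    def from_columns(cls, v1, v2, ids=None) -> "PairedMeasures":
        """Build from two columns, keeping complete pairs only."""
        v1 = np.asarray(v1, dtype=float)
        v2 = np.asarray(v2, dtype=float)
        ids = np.arange(len(v1)) if ids is None else np.asarray(ids)
        keep = np.isfinite(v1) & np.isfinite(v2)
        return cls(ids[keep], v1[keep], v2[keep])

    @property
    def n_pairs(self) -> int:
        return len(self.occasion1)

    def matrix(self) -> np.ndarray:
        return np.column_stack([self.occasion1, self.occasion2])


@dataclass
class AnovaDecomposition:
    """Mean squares of the balanced two-way layout (one value per cell)."""

    msr: float  # between-subject (rows)
    msc: float  # between-occasion (columns)
    mse: float  # residual
    n: int      # subjects
    k: int = 2  # occasions


@dataclass
class AgreementResult:
    variable: str
    n_pairs: int
    icc: float
    icc_ci: tuple[float, float]
    ci_level: float
    convention: Convention
    accuracy: float
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    correction_factor: float | None
    var_icc: float | None
    var_correction_factor: float | None
    var_inv_correction_factor: float | None
    flags: list[str]

    @property
    def location_shift(self) -> float:
        """u = (m1 - m2)/sqrt(s1*s2), the standardized mean difference."""
        return (self.mean1 - self.mean2) / np.sqrt(self.sd1 * self.sd2)

    @property
    def scale_shift(self) -> float:
        """v = s1/s2, the ratio of spreads."""
        return self.sd1 / self.sd2


def anova_decompose(paired: PairedMeasures) -> AnovaDecomposition:
    """Exact mean squares of the subjects x occasions two-way ANOVA.

    For the balanced layout with one observation per cell:
    SSR = k * sum_i (rowmean_i - grand)^2, SSC = n * sum_j (colmean_j -
    grand)^2, SSE = total SS - SSR - SSC, with degrees of freedom n-1,
    k-1 and (n-1)(k-1).
    """
    x = paired.matrix()
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst = np.sum((x - grand) ** 2)
    sse = max(sst - ssr - ssc, 0.0)
    return AnovaDecomposition(
        msr=ssr / (n - 1), msc=ssc / (k - 1), mse=sse / ((n - 1) * (k - 1)), n=n, k=k
    )


def icc_estimate(
    decomp: AnovaDecomposition,
    convention: Convention = "absolute_agreement",
    ci_level: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """Single-measurement ICC from the two-way mixed-effects model.

    consistency:        (MSR - MSE) / (MSR + (k-1) MSE)
    absolute agreement: (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE)/n)

    Confidence intervals use the F-based closed forms: the exact bound
    transformation of F = MSR/MSE for consistency, and the
    Satterthwaite-degrees-of-freedom approximation for absolute
    agreement. Degenerate zero-residual tables (ICC = 1) return a point
    interval.
    """
    msr, msc, mse, n, k = decomp.msr, decomp.msc, decomp.mse, decomp.n, decomp.k
    alpha = 1.0 - ci_level
    if convention == "consistency":
        denom = msr + (k - 1) * mse
        if denom == 0:
            raise ZeroDivisionError("ICC undefined: zero total variance")
        icc = (msr - mse) / denom
        if mse == 0:
            return icc, (icc, icc)
        f = msr / mse
        df1, df2 = n - 1, (n - 1) * (k - 1)
        fl = f / st.f.ppf(1 - alpha / 2, df1, df2)
        fu = f * st.f.ppf(1 - alpha / 2, df2, df1)
        return icc, ((fl - 1) / (fl + k - 1), (fu - 1) / (fu + k - 1))

    if convention != "absolute_agreement":
        raise ValueError(f"unknown ICC convention {convention!r}")
    denom = msr + (k - 1) * mse + k * (msc - mse) / n
    if denom == 0:
        raise ZeroDivisionError("ICC undefined: zero total variance")
    icc = (msr - mse) / denom
    if mse == 0 and msc == 0:
        return icc, (icc, icc)
    # Satterthwaite df for the compound error term a*MSC + b*MSE
    r = min(icc, 1 - 1e-12)
    a = k * r / (n * (1 - r))
    b = 1 + k * r * (n - 1) / (n * (1 - r))
    num = (a * msc + b * mse) ** 2
    den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
    v = num / den if den > 0 else n - 1
    f_star = st.f.ppf(1 - alpha / 2, n - 1, v)
    f_star2 = st.f.ppf(1 - alpha / 2, v, n - 1)
    lower = n * (msr - f_star * mse) / (
        f_star * (k * msc + (k * n - k - n) * mse) + n * msr
    )
    upper = n * (f_star2 * msr - mse) / (
        k * msc + (k * n - k - n) * mse + n * f_star2 * msr
    )
    return icc, (lower, upper)


def accuracy_coefficient(
    paired: PairedMeasures, moments: Literal["population", "sample"] = "population"
) -> float:
    """Lin's accuracy (bias-correction) coefficient Cb in (0, 1]."""
    ddof = 0 if moments == "population" else 1
    s1 = paired.occasion1.std(ddof=ddof)
    s2 = paired.occasion2.std(ddof=ddof)
    if s1 == 0 or s2 == 0:
        raise ValueError("accuracy coefficient undefined: zero spread in an occasion")
    d = paired.occasion1.mean() - paired.occasion2.mean()
    return 2 * s1 * s2 / (s1**2 + s2**2 + d**2)


def var_icc(
    paired: PairedMeasures,
    convention: Convention = "absolute_agreement",
    n_boot: int = 1000,
    seed: int = 0,
) -> float:
    """Sampling variance of the ICC by nonparametric bootstrap.

    Participants (pairs) are resampled with replacement ``n_boot``
    times; the variance of the resampled ICC estimates is returned.
    Deterministic under ``seed``.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be >= 2")
    rng = np.random.default_rng(seed)
    x = paired.matrix()
    n = len(x)
    estimates = np.empty(n_boot)
    for b in range(n_boot):
        xb = x[rng.integers(0, n, size=n)]
        pm = PairedMeasures(np.arange(n), xb[:, 0], xb[:, 1])
        estimates[b] = icc_estimate(anova_decompose(pm), convention)[0]
    return float(np.var(estimates, ddof=1))


def reliability_statistics(icc: float, var_icc_: float) -> tuple[float, float, float]:
    """Correction factor and its variances from the ICC.

    lambda = 1/ICC; var(1/lambda) = var(ICC); var(lambda) =
    var(ICC)/ICC^4 by the first-order delta method. The pair satisfies
    the identity var(1/lambda) = var(lambda)/lambda^4.
    """
    if icc <= 0:
        raise ValueError("correction factor undefined for ICC <= 0")
    lam = 1.0 / icc
    var_inv_lam = var_icc_
    var_lam = var_icc_ / icc**4
    return lam, var_lam, var_inv_lam


def assess_agreement(
    paired: PairedMeasures,
    variable: str = "",
    convention: Convention = "absolute_agreement",
    ci_level: float = 0.95,
    n_boot: int = 1000,
    seed: int = 0,
) -> AgreementResult:
    """Full agreement work-up of one variable's repeat pairs."""
    decomp = anova_decompose(paired)
    icc, ci = icc_estimate(decomp, convention, ci_level)
    cb = accuracy_coefficient(paired)
    v_icc = var_icc(paired, convention, n_boot, seed)
    flags: list[str] = []
    if icc <= 0:
        flags.append("nonpositive_icc")
        lam = var_lam = var_inv = None
    else:
        lam, var_lam, var_inv = reliability_statistics(icc, v_icc)
    return AgreementResult(
        variable=variable,
        n_pairs=paired.n_pairs,
        icc=icc,
        icc_ci=ci,
        ci_level=ci_level,
        convention=convention,
        accuracy=cb,
        mean1=float(paired.occasion1.mean()),
        mean2=float(paired.occasion2.mean()),
        sd1=float(paired.occasion1.std()),
        sd2=float(paired.occasion2.std()),
        correction_factor=lam,
        var_icc=v_icc,
        var_correction_factor=var_lam,
        var_inv_correction_factor=var_inv,
        flags=flags,
    )


def summarize_categories(
    iccs: pd.Series | dict[str, float], categories: pd.Series | dict[str, str]
) -> pd.DataFrame:
    """Median and interquartile range of ICCs per variable category.

    Quantiles use linear interpolation between order statistics (the
    numpy default), fixed so reported IQRs are reproducible. Empty
    categories are omitted.
    """
    iccs = pd.Series(iccs, dtype=float)
    categories = pd.Series(categories)
    df = pd.DataFrame({"icc": iccs, "category": categories.reindex(iccs.index)})
    rows = []
    for cat, grp in df.dropna().groupby("category", sort=True):
        q1, med, q3 = np.quantile(grp["icc"], [0.25, 0.5, 0.75])
        rows.append({"category": cat, "n": len(grp), "median": med, "q1": q1, "q3": q3})
    return pd.DataFrame(rows)
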