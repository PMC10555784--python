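"""Two-stage regression calibration with whole-process bootstrap.

First stage: for each error-prone covariable, ordinary least squares of
its repeat (occasion-2) measurement on its initial (occasion-1)
measurement plus every other covariable in the outcome model, fitted on
the repeat subsample. Second stage: the outcome model (linear, logistic
or Cox proportional hazards) refitted with each error-prone
covariable's observed values replaced by the first-stage fitted values,
predicted for the whole cohort. Under the classical error model the
fitted values estimate E[truth | observed, covariables], so the
second-stage coefficients are (approximately, for the non-linear
families) unbiased for the true-effect parameters.

Because the first-stage coefficients are themselves estimated,
model-based standard errors from the second stage are too small;
confidence intervals come instead from bootstrapping the whole
process — resampling participants, refitting both stages within each
replicate, and taking percentile limits across replicate estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .simulate import OCC1_SUFFIX, OCC2_SUFFIX

Family = Literal["linear", "logistic", "cox"]

__all__ = [
    "CovariableRole",
    "CalibrationFit",
    "ModelEstimate",
    "fit_first_stage",
    "predict_calibrated",
    "calibrate_all",
    "fit_second_stage",
    "bootstrap_calibration",
]


@dataclass
class CovariableRole:
    """How one covariable enters the analysis.

    Continuous covariables are read from ``<name>__i1`` (and
    ``<name>__i2`` for the repeat subsample); categorical covariables
    from the plain ``name`` column and are assumed error-free.
    """

    name: str
    role: Literal["exposure", "confounder"] = "confounder"
    error_prone: bool = False
    has_repeat: bool = True
    scale: Literal["continuous", "categorical"] = "continuous"

    def __post_init__(self) -> None:
        if self.error_prone and self.scale != "continuous":
            raise ValueError(f"{self.name!r}: only continuous covariables can be error-prone")

    @property
    def column(self) -> str:
        return self.name + OCC1_SUFFIX if self.scale == "continuous" else self.name


@dataclass
class CalibrationFit:
    """First-stage OLS fit for one error-prone covariable."""

    target: str
    params: np.ndarray          # aligned with design_columns
    design_columns: list[str]   # 'const', '<target>__i1', then the others
    cat_levels: dict[str, list] # fixed category order for dummy coding
    n_used: int

    @property
    def intercept(self) -> float:
        return float(self.params[0])

    @property
    def slope(self) -> float:
        """Coefficient on the target's own occasion-1 value; converges
        to the (conditional) reliability under classical error."""
        return float(self.params[1])

    @property
    def coefficients(self) -> dict[str, float]:
        return dict(zip(self.design_columns, self.params))


@dataclass
class ModelEstimate:
    family: Family
    coefficients: dict[str, float]
    variances: dict[str, float]
    wald_ci: dict[str, tuple[float, float]]
    n: int
    bootstrap_ci: dict[str, tuple[float, float]] | None = None
    n_boot: int | None = None
    n_skipped: int = 0
    replicates: pd.DataFrame | None = field(default=None, repr=False)


def _cat_levels(cohort: pd.DataFrame, roles: Sequence[CovariableRole]) -> dict[str, list]:
    out = {}
    for r in roles:
        if r.scale == "categorical":
            out[r.name] = list(pd.unique(cohort[r.name].dropna()))
    return out


def _dummy_columns(name: str, levels: list) -> list[str]:
    return [f"{name}[{lev}]" for lev in levels[1:]]


def _build_design(
    cohort: pd.DataFrame,
    cont_columns: list[str],
    cat_levels: dict[str, list],
    const: bool = True,
) -> tuple[np.ndarray, list[str]]:
    """Design matrix with fixed column order: const, continuous columns,
    then indicator contrasts (reference = first observed level)."""
    n = len(cohort)
    cols: list[np.ndarray] = []
    names: list[str] = []
    if const:
        cols.append(np.ones(n))
        names.append("const")
    for c in cont_columns:
        if c not in cohort.columns:
            raise KeyError(f"missing covariable column {c!r}")
        cols.append(cohort[c].to_numpy(dtype=float))
        names.append(c)
    for name, levels in cat_levels.items():
        if name not in cohort.columns:
            raise KeyError(f"missing covariable column {name!r}")
        vals = cohort[name].to_numpy()
        for lev in levels[1:]:
            cols.append((vals == lev).astype(float))
            names.append(f"{name}[{lev}]")
    X = np.column_stack(cols) if cols else np.empty((n, 0))
    return X, names


def _ols(X: np.ndarray, y: np.ndarray, names: list[str]) -> np.ndarray:
    params, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if rank < X.shape[1]:
        # identify which columns are linearly dependent on the ones before them
        bad = []
        r = 0
        for j in range(X.shape[1]):
            sub_rank = np.linalg.matrix_rank(X[:, : j + 1])
            if sub_rank == r:
                bad.append(names[j])
            r = sub_rank
        raise np.linalg.LinAlgError(
            f"rank-deficient first-stage design; collinear columns: {bad}"
        )
    return params


def fit_first_stage(
    cohort: pd.DataFrame,
    target: CovariableRole | str,
    others: Sequence[CovariableRole] = (),
    cat_levels: dict[str, list] | None = None,
) -> CalibrationFit:
    """OLS of the target's occasion-2 value on its occasion-1 value and
    all other covariables, complete-case within the repeat subsample."""
    tname = target.name if isinstance(target, CovariableRole) else target
    others = [o for o in others if (o.name if isinstance(o, CovariableRole) else o) != tname]
    cat_levels = cat_levels if cat_levels is not None else _cat_levels(cohort, others)
    cont_others = [o.column for o in others if o.scale == "continuous"]
    cont_columns = [tname + OCC1_SUFFIX] + cont_others

    y = cohort[tname + OCC2_SUFFIX].to_numpy(dtype=float)
    X, names = _build_design(cohort, cont_columns, cat_levels)
    rows = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
    n_used = int(rows.sum())
    if n_used < X.shape[1] + 1:
        raise ValueError(
            f"too few complete repeat-subsample rows ({n_used}) to fit the "
            f"first-stage model for {tname!r}"
        )
    params = _ols(X[rows], y[rows], names)
    return CalibrationFit(
        target=tname, params=params, design_columns=names,
        cat_levels=cat_levels, n_used=n_used,
    )


def predict_calibrated(fit: CalibrationFit, cohort: pd.DataFrame) -> np.ndarray:
    """Fitted (calibrated) values for every participant, including those
    without a repeat measurement."""
    cont = [c for c in fit.design_columns
            if c != "const" and "[" not in c]
    X, names = _build_design(cohort, cont, fit.cat_levels)
    if names != fit.design_columns:
        raise KeyError(f"cohort design {names} does not match fit {fit.design_columns}")
    return X @ fit.params


def calibrate_all(
    cohort: pd.DataFrame, roles: Sequence[CovariableRole]
) -> tuple[pd.DataFrame, dict[str, CalibrationFit]]:
    """Replace every error-prone covariable's occasion-1 column by its
    first-stage fitted values; all other columns pass through unchanged.

    Each first-stage model is fitted against the *observed* occasion-1
    values of the other covariables (simultaneous, not iterated).
    """
    for r in roles:
        if r.error_prone and not r.has_repeat:
            raise ValueError(f"{r.name!r} is error-prone but has no repeat measurements")
    calibrated = cohort.copy()
    fits: dict[str, CalibrationFit] = {}
    cat_levels = _cat_levels(cohort, roles)
    for r in roles:
        if not r.error_prone:
            continue
        others = [o for o in roles if o.name != r.name]
        fit = fit_first_stage(
            cohort, r, others,
            cat_levels={k: v for k, v in cat_levels.items()},
        )
        fits[r.name] = fit
        calibrated[r.name + OCC1_SUFFIX] = predict_calibrated(fit, cohort)
    return calibrated, fits


def fit_second_stage(
    cohort: pd.DataFrame,
    roles: Sequence[CovariableRole],
    family: Family,
    outcome_col: str | None = None,
    time_col: str = "time",
    event_col: str = "event",
    ci_level: float = 0.95,
) -> ModelEstimate:
    """Fit the outcome model on the (calibrated) covariable columns.

    linear and logistic use statsmodels; cox uses the lifelines partial
    likelihood. Confidence intervals here are model-based Wald
    intervals; see :func:`bootstrap_calibration` for intervals that
    carry first-stage uncertainty.
    """
    import scipy.stats as st

    cat_levels = _cat_levels(cohort, roles)
    cont_columns = [r.column for r in roles if r.scale == "continuous"]
    z = st.norm.ppf(0.5 + ci_level / 2)

    if family in ("linear", "logistic"):
        import statsmodels.api as sm

        if outcome_col is None:
            raise ValueError("outcome_col is required for linear/logistic families")
        X, names = _build_design(cohort, cont_columns, cat_levels, const=True)
        y = cohort[outcome_col].to_numpy(dtype=float)
        rows = np.isfinite(y) & np.all(np.isfinite(X), axis=1)
        if family == "linear":
            res = sm.OLS(y[rows], X[rows]).fit()
        else:
            res = sm.GLM(y[rows], X[rows], family=sm.families.Binomial()).fit()
        if not np.all(np.isfinite(res.params)):
            raise RuntimeError(f"{family} second-stage fit did not converge")
        coefs = dict(zip(names, res.params))
        variances = dict(zip(names, np.diag(res.cov_params())))
        n = int(rows.sum())
    elif family == "cox":
        from lifelines import CoxPHFitter

        X, names = _build_design(cohort, cont_columns, cat_levels, const=False)
        df = pd.DataFrame(X, columns=names)
        df["__time"] = cohort[time_col].to_numpy(dtype=float)
        df["__event"] = cohort[event_col].to_numpy(dtype=float)
        df = df.dropna()
        cph = CoxPHFitter()
        cph.fit(df, duration_col="__time", event_col="__event")
        coefs = cph.params_.to_dict()
        variances = np.diag(cph.variance_matrix_.to_numpy())
        variances = dict(zip(names, variances))
        n = len(df)
    else:
        raise ValueError(f"unknown family {family!r}")

    wald = {k: (coefs[k] - z * np.sqrt(variances[k]), coefs[k] + z * np.sqrt(variances[k]))
            for k in coefs}
    return ModelEstimate(
        family=family, coefficients=coefs, variances=variances, wald_ci=wald, n=n
    )


def _cox_newton(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                max_iter: int = 30, tol: float = 1e-8) -> np.ndarray | None:
    """Cox partial-likelihood Newton solver (Breslow tie handling).

    Small-dimension solver used inside the bootstrap loop, where a full
    model object per replicate is wasteful. Returns the coefficient
    vector, or None if the iteration fails to converge.
    """
    order = np.argsort(time, kind="stable")
    X = X[order]
    time = time[order]
    event = event[order].astype(bool)
    n, p = X.shape
    # risk set of an event at t is everyone with time >= t: reverse
    # cumulative sums read at the first index of each tie group
    first_idx = np.searchsorted(time, time, side="left")
    ev_idx = np.flatnonzero(event)
    ev_first = first_idx[ev_idx]
    beta = np.zeros(p)
    for _ in range(max_iter):
        lp = X @ beta
        lp -= lp.max()  # guard overflow; S1/S0 ratios are shift-invariant
        w = np.exp(lp)
        wx = w[:, None] * X
        s0 = np.cumsum(w[::-1])[::-1]
        s1 = np.cumsum(wx[::-1], axis=0)[::-1]
        xbar = s1[ev_first] / s0[ev_first, None]
        g = X[ev_idx].sum(axis=0) - xbar.sum(axis=0)
        wxx = np.einsum("ij,ik->ijk", X, wx)
        s2 = np.cumsum(wxx[::-1], axis=0)[::-1]
        h = (s2[ev_first] / s0[ev_first, None, None]).sum(axis=0) - np.einsum(
            "ij,ik->jk", xbar, xbar
        )
        try:
            step = np.linalg.solve(h, g)
        except np.linalg.LinAlgError:
            return None
        beta = beta + step
        if not np.all(np.isfinite(beta)):
            return None
        if np.max(np.abs(step)) < tol:
            return beta
    return beta if np.max(np.abs(g)) < 1e-3 else None


def _fast_pipeline(
    idx: np.ndarray,
    occ2: dict[str, np.ndarray],
    second_X: np.ndarray,
    second_names: list[str],
    y: np.ndarray | None,
    time: np.ndarray | None,
    event: np.ndarray | None,
    error_prone: list[str],
    first_designs: dict[str, np.ndarray],
    family: Family,
) -> np.ndarray | None:
    """One calibrate-then-fit pass on a row index, all in numpy.

    ``second_X`` holds the uncalibrated second-stage design (with a
    constant column for the linear family, without one for cox); the
    columns of the error-prone covariables are overwritten by
    first-stage fitted values before the final solve. Returns the
    second-stage coefficient vector, or None when a fit is infeasible
    in this replicate.
    """
    Xs = second_X[idx].copy()
    for name in error_prone:
        Xf = first_designs[name][idx]
        yf = occ2[name][idx]
        rows = np.isfinite(yf)
        if rows.sum() < Xf.shape[1] + 1:
            return None
        params, _, rank, _ = np.linalg.lstsq(Xf[rows], yf[rows], rcond=None)
        if rank < Xf.shape[1]:
            return None
        col = second_names.index(name + OCC1_SUFFIX)
        Xs[:, col] = Xf @ params
    if family == "linear":
        params, _, rank, _ = np.linalg.lstsq(Xs, y[idx], rcond=None)
        if rank < Xs.shape[1]:
            return None
        return params
    return _cox_newton(Xs, time[idx], event[idx])


def bootstrap_calibration(
    cohort: pd.DataFrame,
    roles: Sequence[CovariableRole],
    family: Family,
    reps: int = 10_000,
    seed: int = 0,
    outcome_col: str | None = None,
    time_col: str = "time",
    event_col: str = "event",
    ci_level: float = 0.95,
    ci_type: Literal["percentile", "normal"] = "percentile",
    keep_replicates: bool = False,
) -> ModelEstimate:
    """Whole-process bootstrap of the two-stage calibration.

    Participants are resampled with replacement from the full cohort;
    within each replicate every first-stage model is refitted on the
    replicate's repeat subsample and the second-stage model on the full
    replicate, so the interval reflects sampling variability of both
    stages jointly. Percentile limits are the default; a
    normal-approximation interval (point estimate +/- z * bootstrap SD)
    is available. Replicates whose repeat subsample is empty or
    rank-deficient are skipped; more than 10% skipped is an error.
    """
    import scipy.stats as st

    if reps < 2:
        raise ValueError("reps must be >= 2")
    rng = np.random.default_rng(seed)
    n = len(cohort)

    calibrated, _ = calibrate_all(cohort, roles)
    point = fit_second_stage(
        calibrated, roles, family, outcome_col, time_col, event_col, ci_level
    )
    coef_names = list(point.coefficients)
    error_prone = [r.name for r in roles if r.error_prone]

    draws = np.full((reps, len(coef_names)), np.nan)
    if family in ("linear", "cox"):
        cat_levels = _cat_levels(cohort, roles)
        cont_columns = [r.column for r in roles if r.scale == "continuous"]
        second_X, second_names = _build_design(
            cohort, cont_columns, cat_levels, const=(family == "linear")
        )
        y = cohort[outcome_col].to_numpy(dtype=float) if family == "linear" else None
        time = cohort[time_col].to_numpy(dtype=float) if family == "cox" else None
        event = cohort[event_col].to_numpy(dtype=float) if family == "cox" else None
        occ2 = {name: cohort[name + OCC2_SUFFIX].to_numpy(dtype=float)
                for name in error_prone}
        first_designs = {}
        for r in roles:
            if not r.error_prone:
                continue
            others = [o for o in roles if o.name != r.name]
            cont = [r.column] + [o.column for o in others if o.scale == "continuous"]
            Xf, _ = _build_design(cohort, cont, _cat_levels(cohort, others), const=True)
            first_designs[r.name] = Xf
        n_skipped = 0
        # map replicate coefficient order onto the point-estimate names
        col_order = [second_names.index(k) for k in coef_names]
        for b in range(reps):
            idx = rng.integers(0, n, size=n)
            params = _fast_pipeline(
                idx, occ2, second_X, second_names, y, time, event,
                error_prone, first_designs, family,
            )
            if params is None:
                n_skipped += 1
            else:
                draws[b] = params[col_order]
    else:
        n_skipped = 0
        for b in range(reps):
            idx = rng.integers(0, n, size=n)
            boot = cohort.iloc[idx].reset_index(drop=True)
            try:
                cal, _ = calibrate_all(boot, roles)
                est = fit_second_stage(
                    cal, roles, family, outcome_col, time_col, event_col, ci_level
                )
                draws[b] = [est.coefficients[k] for k in coef_names]
            except (ValueError, KeyError, RuntimeError, np.linalg.LinAlgError):
                n_skipped += 1

    if n_skipped > 0.10 * reps:
        raise RuntimeError(
            f"{n_skipped}/{reps} bootstrap replicates failed; cohort too small "
            "or repeat subsample too sparse for a stable bootstrap"
        )
    ok = ~np.isnan(draws[:, 0])
    alpha = 1.0 - ci_level
    boot_ci: dict[str, tuple[float, float]] = {}
    for j, name in enumerate(coef_names):
        vals = draws[ok, j]
        if ci_type == "percentile":
            lo, hi = np.quantile(vals, [alpha / 2, 1 - alpha / 2])
        else:
            z = st.norm.ppf(1 - alpha / 2)
            c = point.coefficients[name]
            sd = vals.std(ddof=1)
            lo, hi = c - z * sd, c + z * sd
        boot_ci[name] = (float(lo), float(hi))

    point.bootstrap_ci = boot_ci
    point.n_boot = reps
    point.n_skipped = n_skipped
    if keep_replicates:
        point.replicates = pd.DataFrame(draws[ok], columns=coef_names)
    return point
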