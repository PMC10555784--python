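"""Two-stage regression calibration: hand-solvable first-stage fits,
attenuation-law recovery in simulation, and the whole-process bootstrap."""

import numpy as np
import pandas as pd
import pytest

from regdilute import (
    CovariableRole,
    bootstrap_calibration,
    calibrate_all,
    fit_first_stage,
    fit_second_stage,
    predict_calibrated,
)
from helpers import make_linear_cohort


def _toy_cohort():
    """Three repeat rows with exactly solvable normal equations:
    x2 = 1 + 2*x1 fits x1=(0,1,2), x2=(1,3,5) with zero residual."""
    return pd.DataFrame({
        "x__i1": [0.0, 1.0, 2.0, 3.0, 4.0],
        "x__i2": [1.0, 3.0, 5.0, np.nan, np.nan],
        "y": [0.1, 0.2, 0.3, 0.4, 0.5],
    })


def test_first_stage_identity_when_occasions_agree():
    df = pd.DataFrame({"x__i1": [1.0, 2.0, 3.0, 4.0],
                       "x__i2": [1.0, 2.0, 3.0, 4.0]})
    fit = fit_first_stage(df, "x")
    assert fit.slope == pytest.approx(1.0)
    assert fit.intercept == pytest.approx(0.0, abs=1e-12)
    assert fit.n_used == 4


def test_first_stage_toy_exact_coefficients():
    fit = fit_first_stage(_toy_cohort(), "x")
    assert fit.intercept == pytest.approx(1.0)
    assert fit.slope == pytest.approx(2.0)
    assert fit.n_used == 3


def test_first_stage_slope_estimates_reliability():
    cohort = make_linear_cohort(n=50_000, reliability=0.5, beta=1.0, seed=21,
                                repeat_fraction=1.0)
    fit = fit_first_stage(cohort, "x")
    assert abs(fit.slope - 0.5) < 0.01


def test_predictions_match_hand_linear_combination():
    cohort = _toy_cohort()
    fit = fit_first_stage(cohort, "x")
    pred = predict_calibrated(fit, cohort)
    np.testing.assert_allclose(pred, 1.0 + 2.0 * cohort["x__i1"].to_numpy())


def test_fitted_values_never_exceed_observed_variance():
    cohort = make_linear_cohort(n=3000, reliability=0.4, beta=1.0, seed=22)
    roles = [CovariableRole("x", "exposure", error_prone=True)]
    cal, _ = calibrate_all(cohort, roles)
    assert cal["x__i1"].var() <= cohort["x__i1"].var()


def test_calibrate_all_reduces_to_single_fit(exposure_role):
    cohort = make_linear_cohort(n=2000, reliability=0.6, beta=1.0, seed=23)
    cal, fits = calibrate_all(cohort, exposure_role)
    fit = fit_first_stage(cohort, "x")
    np.testing.assert_allclose(cal["x__i1"], predict_calibrated(fit, cohort))
    assert fits["x"].slope == pytest.approx(fit.slope)


def test_error_free_columns_pass_through_unchanged():
    cohort = make_linear_cohort(n=500, reliability=0.6, beta=1.0, seed=24)
    cohort["z__i1"] = np.arange(500.0)
    roles = [CovariableRole("x", "exposure", error_prone=True),
             CovariableRole("z", "confounder", error_prone=False)]
    cal, _ = calibrate_all(cohort, roles)
    np.testing.assert_array_equal(cal["z__i1"], cohort["z__i1"])
    # no error-prone covariables at all: table is unchanged
    roles_none = [CovariableRole("x", "exposure", error_prone=False)]
    cal2, fits2 = calibrate_all(cohort, roles_none)
    pd.testing.assert_frame_equal(cal2, cohort)
    assert fits2 == {}


def test_two_error_prone_covariables_match_hand_ols():
    """Each first-stage model uses the observed occasion-1 values of the
    other covariable; verify against normal equations solved directly."""
    rng = np.random.default_rng(25)
    n = 400
    t1, t2 = rng.normal(size=n), rng.normal(size=n)
    df = pd.DataFrame({
        "a__i1": t1 + rng.normal(0, 1, n), "a__i2": t1 + rng.normal(0, 1, n),
        "b__i1": t2 + rng.normal(0, 0.5, n), "b__i2": t2 + rng.normal(0, 0.5, n),
    })
    roles = [CovariableRole("a", "exposure", error_prone=True),
             CovariableRole("b", "confounder", error_prone=True)]
    cal, fits = calibrate_all(df, roles)
    for target, other in (("a", "b"), ("b", "a")):
        X = np.column_stack([np.ones(n), df[f"{target}__i1"], df[f"{other}__i1"]])
        beta = np.linalg.solve(X.T @ X, X.T @ df[f"{target}__i2"].to_numpy())
        np.testing.assert_allclose(fits[target].params, beta, rtol=1e-8)
        np.testing.assert_allclose(cal[f"{target}__i1"], X @ beta, rtol=1e-8)


def test_error_prone_without_repeats_is_rejected():
    cohort = make_linear_cohort(n=200, reliability=0.6, beta=1.0, seed=26)
    roles = [CovariableRole("x", "exposure", error_prone=True, has_repeat=False)]
    with pytest.raises(ValueError, match="repeat"):
        calibrate_all(cohort, roles)


def test_rank_deficiency_names_collinear_columns():
    cohort = make_linear_cohort(n=200, reliability=0.6, beta=1.0, seed=27)
    cohort["dup__i1"] = cohort["x__i1"] * 2.0
    roles = [CovariableRole("dup", "confounder")]
    with pytest.raises(np.linalg.LinAlgError, match="dup__i1"):
        fit_first_stage(cohort, "x", roles)


def test_second_stage_equals_uncorrected_fit_when_error_free(exposure_role):
    cohort = make_linear_cohort(n=2000, reliability=1.0, beta=0.7, seed=28)
    uncorrected = fit_second_stage(cohort, exposure_role, "linear", outcome_col="y")
    cal, _ = calibrate_all(cohort, exposure_role)
    corrected = fit_second_stage(cal, exposure_role, "linear", outcome_col="y")
    assert corrected.coefficients["x__i1"] == pytest.approx(
        uncorrected.coefficients["x__i1"], abs=1e-6
    )


def test_linear_family_recovers_true_slope(exposure_role):
    cohort = make_linear_cohort(n=50_000, reliability=0.5, beta=1.0, seed=29)
    uncorrected = fit_second_stage(cohort, exposure_role, "linear", outcome_col="y")
    cal, _ = calibrate_all(cohort, exposure_role)
    corrected = fit_second_stage(cal, exposure_role, "linear", outcome_col="y")
    assert abs(uncorrected.coefficients["x__i1"] - 0.5) < 0.02
    assert abs(corrected.coefficients["x__i1"] - 1.0) < 0.05


def test_logistic_family_runs_and_reduces_attenuation():
    rng = np.random.default_rng(30)
    n = 20_000
    t = rng.normal(size=n)
    cohort = pd.DataFrame({
        "x__i1": t + rng.normal(0, 1, n),
        "x__i2": np.where(rng.uniform(size=n) < 0.2,
                          t + rng.normal(0, 1, n), np.nan),
        "d": rng.binomial(1, 1 / (1 + np.exp(-(-1.0 + 0.5 * t)))),
    })
    roles = [CovariableRole("x", "exposure", error_prone=True)]
    u = fit_second_stage(cohort, roles, "logistic", outcome_col="d")
    cal, _ = calibrate_all(cohort, roles)
    c = fit_second_stage(cal, roles, "logistic", outcome_col="d")
    assert abs(c.coefficients["x__i1"] - 0.5) < 0.1
    assert u.coefficients["x__i1"] < c.coefficients["x__i1"]


def test_bootstrap_is_seeded_and_contains_point(exposure_role):
    cohort = make_linear_cohort(n=2000, reliability=0.5, beta=1.0, seed=31)
    est1 = bootstrap_calibration(cohort, exposure_role, "linear", reps=300,
                                 seed=5, outcome_col="y")
    est2 = bootstrap_calibration(cohort, exposure_role, "linear", reps=300,
                                 seed=5, outcome_col="y")
    assert est1.bootstrap_ci == est2.bootstrap_ci
    lo, hi = est1.bootstrap_ci["x__i1"]
    assert lo <= est1.coefficients["x__i1"] <= hi
    est3 = bootstrap_calibration(cohort, exposure_role, "linear", reps=300,
                                 seed=6, outcome_col="y")
    lo3, hi3 = est3.bootstrap_ci["x__i1"]
    assert abs(lo3 - lo) < (hi - lo) and abs(hi3 - hi) < (hi - lo)


def test_bootstrap_ci_width_scales_with_sample_size(exposure_role):
    def width(n, seed):
        cohort = make_linear_cohort(n=n, reliability=0.5, beta=1.0, seed=seed)
        est = bootstrap_calibration(cohort, exposure_role, "linear", reps=400,
                                    seed=1, outcome_col="y")
        lo, hi = est.bootstrap_ci["x__i1"]
        return hi - lo

    ratio = width(2000, 32) / width(8000, 33)
    assert 1.4 < ratio < 2.6  # expect ~2 under sqrt-n scaling


def test_internal_cox_solver_matches_lifelines(sole_exposure_config):
    """The Newton solver used inside the bootstrap loop must agree with
    the lifelines partial-likelihood fit (tie-free data, where Breslow
    and Efron tie handling coincide)."""
    from lifelines import CoxPHFitter

    from regdilute import simulate_cohort
    from regdilute.calibration import _cox_newton

    cfg = sole_exposure_config
    cfg.n_participants = 2000
    cohort = simulate_cohort(cfg)
    rng = np.random.default_rng(0)
    cohort["z"] = rng.normal(size=len(cohort))
    X = cohort[["x__i1", "z"]].to_numpy()
    beta = _cox_newton(X, cohort["time"].to_numpy(), cohort["event"].to_numpy())
    cph = CoxPHFitter().fit(cohort[["x__i1", "z", "time", "event"]],
                            "time", event_col="event")
    np.testing.assert_allclose(beta, cph.params_.to_numpy(), atol=1e-5)


def test_bootstrap_with_cox_family(exposure_role, sole_exposure_config):
    from regdilute import simulate_cohort

    cfg = sole_exposure_config
    cfg.n_participants = 3000
    cohort = simulate_cohort(cfg)
    est = bootstrap_calibration(cohort, exposure_role, "cox", reps=30, seed=2)
    lo, hi = est.bootstrap_ci["x__i1"]
    assert lo <= est.coefficients["x__i1"] <= hi
    assert est.n_skipped <= 3
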