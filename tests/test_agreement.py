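"""Agreement metrics against independent oracles: hand-computed ANOVA
fractions on toy tables, pingouin's ICC implementation on random data,
and Monte-Carlo reliability recovery on simulated repeats."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st_h

from regdilute import (
    PairedMeasures,
    SimulationConfig,
    VariableSpec,
    accuracy_coefficient,
    add_measurement_error,
    anova_decompose,
    assess_agreement,
    generate_true_covariates,
    icc_estimate,
    reliability_statistics,
    summarize_categories,
    var_icc,
)


def test_anova_toy_table_exact_fractions(toy_pairs):
    d = anova_decompose(toy_pairs)
    assert Fraction(d.msr).limit_denominator(10**6) == Fraction(40, 3)
    assert d.msc == 2.0
    assert d.mse == 0.0
    # mean squares recompose the total sum of squares of the balanced layout
    sst = ((toy_pairs.matrix() - toy_pairs.matrix().mean()) ** 2).sum()
    assert np.isclose((d.n - 1) * d.msr + d.msc + (d.n - 1) * d.mse, sst)


def test_icc_toy_closed_forms(toy_pairs):
    d = anova_decompose(toy_pairs)
    icc_c, _ = icc_estimate(d, "consistency")
    icc_a, _ = icc_estimate(d, "absolute_agreement")
    assert icc_c == 1.0
    assert Fraction(icc_a).limit_denominator(10**6) == Fraction(40, 43)


def test_identical_occasions_give_unit_icc():
    pm = PairedMeasures([0, 1, 2], [1, 2, 3], [1, 2, 3])
    d = anova_decompose(pm)
    assert icc_estimate(d, "consistency")[0] == 1.0
    assert icc_estimate(d, "absolute_agreement")[0] == 1.0


def test_anova_matches_brute_force_cell_sums():
    rng = np.random.default_rng(0)
    x = rng.normal(size=(10, 2))
    pm = PairedMeasures(np.arange(10), x[:, 0], x[:, 1])
    d = anova_decompose(pm)
    # brute force: explicit additive decomposition over all cells
    grand = x.mean()
    ssr = sum((x[i].mean() - grand) ** 2 for i in range(10)) * 2
    ssc = sum((x[:, j].mean() - grand) ** 2 for j in range(2)) * 10
    sse = sum(
        (x[i, j] - x[i].mean() - x[:, j].mean() + grand) ** 2
        for i in range(10) for j in range(2)
    )
    assert np.isclose(d.msr, ssr / 9)
    assert np.isclose(d.msc, ssc / 1)
    assert np.isclose(d.mse, sse / 9)


@pytest.mark.parametrize("convention,pg_type", [
    ("consistency", "ICC(C,1)"), ("absolute_agreement", "ICC(A,1)"),
])
def test_icc_point_and_ci_match_pingouin(convention, pg_type):
    """pingouin implements the two-way single-measurement ICCs
    independently; point estimates and F-based CIs must agree."""
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(1)
    truth = rng.normal(size=80)
    x = np.column_stack([truth + rng.normal(0, 0.7, 80),
                         truth + 0.3 + rng.normal(0, 0.7, 80)])
    pm = PairedMeasures(np.arange(80), x[:, 0], x[:, 1])
    icc, ci = icc_estimate(anova_decompose(pm), convention)
    long = pd.DataFrame({
        "subject": np.repeat(np.arange(80), 2),
        "rater": np.tile([1, 2], 80),
        "score": x.ravel(),
    })
    ref = pingouin.intraclass_corr(long, "subject", "rater", "score").set_index("Type")
    assert np.isclose(icc, ref.loc[pg_type, "ICC"], atol=1e-6)
    lo, hi = ref.loc[pg_type, "CI95"]  # pingouin rounds the CI to 2 dp
    assert np.isclose(ci[0], lo, atol=6e-3) and np.isclose(ci[1], hi, atol=6e-3)


def test_simulated_reliability_recovered():
    cfg = SimulationConfig(
        n_participants=5000,
        variables=[VariableSpec("x", reliability=0.6)],
        seed=2,
    )
    truth = generate_true_covariates(cfg)
    o1 = add_measurement_error(truth, cfg, 1)
    o2 = add_measurement_error(truth, cfg, 2)
    pm = PairedMeasures.from_columns(o1["x"], o2["x"])
    icc, _ = icc_estimate(anova_decompose(pm))
    assert abs(icc - 0.6) < 0.03


def test_shift_lowers_absolute_agreement_below_consistency():
    cfg = SimulationConfig(
        n_participants=5000,
        variables=[VariableSpec("x", reliability=0.8, shift=1.0)],
        seed=3,
    )
    truth = generate_true_covariates(cfg)
    o1 = add_measurement_error(truth, cfg, 1)
    o2 = add_measurement_error(truth, cfg, 2)
    pm = PairedMeasures.from_columns(o1["x"], o2["x"])
    d = anova_decompose(pm)
    assert icc_estimate(d, "absolute_agreement")[0] < icc_estimate(d, "consistency")[0]


def test_accuracy_coefficient_hand_oracles(toy_pairs):
    # unit mean shift with equal spreads: 2*5/(5+5+1)
    assert np.isclose(accuracy_coefficient(toy_pairs), 10 / 11)
    # doubled spread, equal means: 2*2/(1+4)
    x = np.array([-1.5, -0.5, 0.5, 1.5])
    pm = PairedMeasures(np.arange(4), x, 2 * x)
    assert np.isclose(accuracy_coefficient(pm), 0.8)
    # identical occasions: exactly 1
    pm = PairedMeasures(np.arange(4), x, x)
    assert accuracy_coefficient(pm) == 1.0


@given(
    shift=st_h.floats(-3, 3), scale=st_h.floats(0.1, 10),
    seed=st_h.integers(0, 50),
)
@settings(max_examples=30, deadline=None, derandomize=True)
def test_accuracy_invariances(shift, scale, seed):
    """Cb is symmetric in the occasions and invariant to rescaling both."""
    rng = np.random.default_rng(seed)
    a = rng.normal(size=30)
    b = a + shift + rng.normal(0, 0.5, 30)
    pm = PairedMeasures(np.arange(30), a, b)
    swapped = PairedMeasures(np.arange(30), b, a)
    scaled = PairedMeasures(np.arange(30), scale * a, scale * b)
    cb = accuracy_coefficient(pm)
    assert 0 < cb <= 1
    assert np.isclose(cb, accuracy_coefficient(swapped))
    assert np.isclose(cb, accuracy_coefficient(scaled))


def test_var_icc_zero_for_degenerate_pairs():
    pm = PairedMeasures(np.arange(5), [1, 2, 3, 4, 5], [1, 2, 3, 4, 5])
    assert var_icc(pm, n_boot=50, seed=0) < 1e-12


def test_var_icc_decreases_with_sample_size():
    def one(n, seed):
        rng = np.random.default_rng(seed)
        t = rng.normal(size=n)
        pm = PairedMeasures(np.arange(n), t + rng.normal(0, 1, n),
                            t + rng.normal(0, 1, n))
        return var_icc(pm, n_boot=200, seed=seed)

    assert one(5000, 4) < one(500, 4)


def test_var_icc_calibrated_against_monte_carlo():
    """The bootstrap variance should track the sampling variance of the
    ICC across independent datasets within a factor of two."""
    n, n_sets = 200, 200
    estimates = np.empty(n_sets)
    boot_vars = np.empty(n_sets)
    for s in range(n_sets):
        rng = np.random.default_rng(10_000 + s)
        t = rng.normal(size=n)
        pm = PairedMeasures(np.arange(n), t + rng.normal(0, 1, n),
                            t + rng.normal(0, 1, n))
        estimates[s] = icc_estimate(anova_decompose(pm))[0]
        boot_vars[s] = var_icc(pm, n_boot=200, seed=s)
    empirical = estimates.var(ddof=1)
    assert empirical / 2 < boot_vars.mean() < empirical * 2


@pytest.mark.parametrize(
    "lam,var_lam,expected_var_inv",
    [
        (1.9356, 0.000410, 0.000029),
        (3.4987, 0.007635, 0.000051),
        (1.8091, 0.000335, 0.000031),
        (1.0794, 0.000001, 0.000001),
        (1.1745, 0.000030, 0.000016),
    ],
)
def test_delta_identity_links_both_variances(lam, var_lam, expected_var_inv):
    """var(1/lambda) = var(lambda)/lambda^4 at 6-dp rounding, for the
    correction factors of five real blood/anthropometric variables."""
    icc = 1.0 / lam
    lam_out, var_lam_out, var_inv_out = reliability_statistics(
        icc, var_icc_=var_lam / lam**4
    )
    assert np.isclose(lam_out, lam)
    assert round(var_lam_out, 6) == round(var_lam, 6)
    assert round(var_inv_out, 6) == expected_var_inv
    # the identity holds exactly, not just at printed precision
    assert np.isclose(var_inv_out * lam_out**4, var_lam_out)


def test_reliability_statistics_rejects_nonpositive_icc():
    with pytest.raises(ValueError, match="ICC"):
        reliability_statistics(-0.1, 0.001)
    lam, _, _ = reliability_statistics(0.5, 0.0)
    assert lam == 2.0


def test_category_summary_quantile_rule():
    # single value: collapsed IQR
    out = summarize_categories({"a": 0.7}, {"a": "imaging"})
    assert out.iloc[0][["median", "q1", "q3"]].tolist() == [0.7, 0.7, 0.7]
    # odd n: middle order statistic
    out = summarize_categories(
        {"a": 0.1, "b": 0.2, "c": 0.3}, {"a": "x", "b": "x", "c": "x"}
    )
    assert out.iloc[0]["median"] == 0.2
    # even n: linear interpolation between order statistics
    out = summarize_categories(
        dict(zip("abcd", [0.1, 0.2, 0.3, 0.4])), {k: "x" for k in "abcd"}
    )
    assert np.isclose(out.iloc[0]["q1"], 0.175)
    assert np.isclose(out.iloc[0]["median"], 0.25)
    assert np.isclose(out.iloc[0]["q3"], 0.325)


def test_assess_agreement_bundles_consistent_statistics():
    rng = np.random.default_rng(6)
    t = rng.normal(10, 2, 400)
    pm = PairedMeasures(np.arange(400), t + rng.normal(0, 1, 400),
                        t + rng.normal(0, 1, 400))
    res = assess_agreement(pm, "v", n_boot=100, seed=1)
    assert res.correction_factor * res.icc == pytest.approx(1.0)
    assert res.var_inv_correction_factor == pytest.approx(res.var_icc)
    assert res.var_correction_factor == pytest.approx(
        res.var_inv_correction_factor * res.correction_factor**4
    )
    assert 0 < res.accuracy <= 1
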