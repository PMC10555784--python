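"""Synthetic cohort generation under classical measurement error.

Every downstream stage of the package (screening, agreement metrics,
dilution correction, regression calibration) is validated against
cohorts produced here, where the true effect sizes, reliabilities and
systematic shifts are known by construction.

Model
-----
Latent true values ``T`` are multivariate normal with configured
marginal moments and correlation. The observation at occasion ``o`` is

    X_o = T + shift * 1[o = 2] + e_o,   e_o ~ N(0, sd^2 (1 - R) / R)

with errors independent of ``T`` and across occasions, so that the
reliability ratio var(T)/var(X) equals R and the two-occasion ICC
converges to R when shift = 0. Event times are exponential given the
linear predictor on the *true* values (proportional hazards hold
exactly), administratively censored at the follow-up horizon.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import SimulationConfig

OCC1_SUFFIX = "__i1"
OCC2_SUFFIX = "__i2"

__all__ = [
    "OCC1_SUFFIX",
    "OCC2_SUFFIX",
    "generate_true_covariates",
    "add_measurement_error",
    "generate_survival",
    "assemble_cohort",
    "simulate_cohort",
    "generate_showcase_table",
    "ShowcaseFixture",
    "write_cohort",
    "read_cohort",
]


def generate_true_covariates(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Draw the latent true values, one row per participant.

    Returns a DataFrame with a ``participant_id`` column followed by one
    column per configured variable (unsuffixed: these are error-free).
    Deterministic given ``config.seed`` when ``rng`` is not supplied.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n = config.n_participants
    sds = np.array([v.true_sd for v in config.variables])
    means = np.array([v.true_mean for v in config.variables])
    cov = config.true_correlation * np.outer(sds, sds)
    z = rng.multivariate_normal(np.zeros(len(sds)), config.true_correlation, size=n,
                                method="cholesky")
    values = means + z * sds  # exact zeros where true_sd == 0
    df = pd.DataFrame(values, columns=config.variable_names)
    df.insert(0, "participant_id", np.arange(n))
    # cov retained only for documentation of the target; not used further
    del cov
    return df


def add_measurement_error(
    true_values: pd.DataFrame,
    config: SimulationConfig,
    occasion: int,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Observe the latent values under classical additive error.

    ``occasion`` is 1 or 2; the configured systematic ``shift`` is added
    only at occasion 2. Error variance for reliability R is
    ``true_sd**2 * (1 - R) / R``; R = 1 returns the truth exactly.
    """
    if occasion not in (1, 2):
        raise ValueError("occasion must be 1 or 2")
    rng = rng if rng is not None else np.random.default_rng(config.seed + occasion)
    out = pd.DataFrame({"participant_id": true_values["participant_id"].to_numpy()})
    n = len(true_values)
    for v in config.variables:
        err_sd = v.true_sd * np.sqrt((1.0 - v.reliability) / v.reliability)
        noise = rng.normal(0.0, err_sd, size=n) if err_sd > 0 else 0.0
        shift = v.shift if occasion == 2 else 0.0
        out[v.name] = true_values[v.name].to_numpy() + shift + noise
    return out


def _linear_predictor(
    true_values: pd.DataFrame,
    categorical: pd.DataFrame | None,
    config: SimulationConfig,
) -> np.ndarray:
    lp = np.zeros(len(true_values))
    for name, beta in config.outcome.log_hazards.items():
        lp += beta * true_values[name].to_numpy()
    if categorical is not None:
        for spec in config.categorical_confounders:
            hz = dict(zip(spec.levels, spec.log_hazards))
            lp += np.array([hz[lev] for lev in categorical[spec.name]])
    return lp


def generate_survival(
    true_values: pd.DataFrame,
    categorical: pd.DataFrame | None,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Exponential event times under the proportional-hazards model.

    hazard_i = h0 * exp(sum_j beta_j * truth_ij + categorical terms),
    administratively censored at the horizon. When the config sets a
    target event fraction, the baseline hazard h0 is solved by bisection
    on the realized uniform draws so the observed fraction matches it.

    Returns a DataFrame with ``time`` (years, in (0, horizon]) and
    ``event`` (1 = death observed, 0 = censored).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 7)
    out_spec = config.outcome
    lp = _linear_predictor(true_values, categorical, config)
    u = rng.uniform(size=len(true_values))
    neg_log_u = -np.log(u)

    def times_for(h0: float) -> np.ndarray:
        return neg_log_u / (h0 * np.exp(lp))

    h0 = out_spec.baseline_hazard
    if out_spec.target_event_fraction is not None:
        target = out_spec.target_event_fraction
        lo, hi = 1e-10, 1e4
        for _ in range(200):
            mid = np.sqrt(lo * hi)
            frac = np.mean(times_for(mid) < out_spec.horizon)
            if frac < target:
                lo = mid
            else:
                hi = mid
        h0 = np.sqrt(lo * hi)
    if h0 <= 0:
        raise ValueError("baseline hazard must be positive")
    t = times_for(h0)
    event = (t < out_spec.horizon).astype(int)
    time = np.minimum(t, out_spec.horizon)
    return pd.DataFrame(
        {"participant_id": true_values["participant_id"].to_numpy(),
         "time": time, "event": event}
    )


def _draw_categorical(
    config: SimulationConfig, n: int, rng: np.random.Generator
) -> pd.DataFrame | None:
    if not config.categorical_confounders:
        return None
    out = pd.DataFrame({"participant_id": np.arange(n)})
    for spec in config.categorical_confounders:
        out[spec.name] = rng.choice(spec.levels, size=n, p=spec.level_probabilities)
    return out


def assemble_cohort(
    occ1: pd.DataFrame,
    occ2: pd.DataFrame,
    survival: pd.DataFrame,
    config: SimulationConfig,
    categorical: pd.DataFrame | None = None,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Combine the parts into the wide analysis table.

    Occasion-2 values are kept only for a seeded simple random subsample
    of exactly ``round(n * repeat_fraction)`` participants; everyone
    else gets missing values in the ``__i2`` columns.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed + 13)
    ids = occ1["participant_id"].to_numpy()
    for part in (occ2, survival) + ((categorical,) if categorical is not None else ()):
        if not np.array_equal(part["participant_id"].to_numpy(), ids):
            raise ValueError("participant ids of cohort parts do not match")
    n = len(ids)
    n_repeat = int(round(n * config.repeat_fraction))
    repeat_ids = rng.choice(ids, size=n_repeat, replace=False)
    is_repeat = np.isin(ids, repeat_ids)

    cohort = pd.DataFrame({"participant_id": ids})
    for v in config.variable_names:
        cohort[v + OCC1_SUFFIX] = occ1[v].to_numpy()
        col2 = occ2[v].to_numpy().astype(float).copy()
        col2[~is_repeat] = np.nan
        cohort[v + OCC2_SUFFIX] = col2
    if categorical is not None:
        for spec in config.categorical_confounders:
            cohort[spec.name] = categorical[spec.name].to_numpy()
    cohort["time"] = survival["time"].to_numpy()
    cohort["event"] = survival["event"].to_numpy()
    return cohort


def simulate_cohort(
    config: SimulationConfig, return_truth: bool = False
) -> pd.DataFrame | tuple[pd.DataFrame, pd.DataFrame]:
    """End-to-end generation: truth -> two observation occasions ->
    survival outcome -> assembled wide table. Bit-reproducible for a
    fixed config (all randomness derives from ``config.seed``).

    With ``return_truth`` the latent true values are returned alongside
    the cohort, for simulation studies that need an oracle."""
    rng = np.random.default_rng(config.seed)
    truth = generate_true_covariates(config, rng)
    cats = _draw_categorical(config, config.n_participants, rng)
    occ1 = add_measurement_error(truth, config, 1, rng)
    occ2 = add_measurement_error(truth, config, 2, rng)
    surv = generate_survival(truth, cats, config, rng)
    cohort = assemble_cohort(occ1, occ2, surv, config, cats, rng)
    return (cohort, truth) if return_truth else cohort


def attach_linear_outcome(
    cohort: pd.DataFrame,
    truth: pd.DataFrame,
    coefficients: dict[str, float],
    noise_sd: float = 1.0,
    seed: int = 0,
    name: str = "y",
) -> pd.DataFrame:
    """Add a continuous outcome ``y = sum_j beta_j * truth_j + N(0, sd^2)``
    to a cohort, for linear-family simulation studies."""
    rng = np.random.default_rng(seed)
    y = rng.normal(0.0, noise_sd, size=len(truth))
    for var, beta in coefficients.items():
        y = y + beta * truth[var].to_numpy()
    out = cohort.copy()
    out[name] = y
    return out


def write_cohort(cohort: pd.DataFrame, config: SimulationConfig, out_dir) -> Path:
    """Write the cohort CSV (missing values as empty strings) and a JSON
    sidecar of the generating config, including the seed, for provenance."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "cohort.csv"
    cohort.to_csv(path, index=False, na_rep="")
    with open(out_dir / "cohort.config.json", "w") as fh:
        json.dump(config.to_dict(), fh, indent=2)
    return path


def read_cohort(path) -> pd.DataFrame:
    return pd.read_csv(path)


@dataclass
class ShowcaseFixture:
    """A screening fixture with known, constructed verdicts.

    ``expected_reasons`` maps each variable name to the screening reason
    its construction guarantees ('ok' for eligible variables).
    """

    table: pd.DataFrame
    expected_reasons: dict[str, str]


def generate_showcase_table(n: int = 600, seed: int = 0) -> ShowcaseFixture:
    """Build a wide table exercising every screening rule.

    Contains, by construction: an integer variable with exactly 20
    distinct values (fails the >20-distinct rule), a variable with >20%
    of participants sharing one value, a variable with only 99 repeat
    pairs, a threshold-coded string variable (values like "≤1"), a
    variable with no occasion-2 column at all, and two clean continuous
    variables.
    """
    rng = np.random.default_rng(seed)
    n_rep = max(150, int(round(n * 0.25)))
    is_rep = np.zeros(n, dtype=bool)
    is_rep[rng.choice(n, size=n_rep, replace=False)] = True

    def with_repeats(values, reliability=0.8):
        err = np.std(values) * np.sqrt((1 - reliability) / reliability)
        v2 = values + rng.normal(0, err if err > 0 else 1e-9, size=n)
        v2 = np.where(is_rep, v2, np.nan)
        return values, v2

    table = pd.DataFrame({"participant_id": np.arange(n)})

    clean1, clean1_r = with_repeats(rng.normal(50, 10, n))
    clean2, clean2_r = with_repeats(rng.normal(0, 1, n))
    table["height__i1"], table["height__i2"] = clean1, clean1_r
    table["crp__i1"], table["crp__i2"] = clean2, clean2_r

    # integer-coded with exactly 20 distinct values -> not continuous
    few = rng.integers(0, 20, size=n).astype(float)
    few[:20] = np.arange(20)  # force all 20 levels present
    table["score20__i1"], table["score20__i2"] = with_repeats(few)

    # >20% of participants share one value
    tied = rng.normal(10, 2, n)
    tied[: int(0.30 * n)] = 7.5
    table["ties__i1"], table["ties__i2"] = with_repeats(tied)

    # only 99 complete repeat pairs
    sparse1 = rng.normal(5, 1, n)
    sparse2 = np.full(n, np.nan)
    idx = np.flatnonzero(is_rep)[:99]
    sparse2[idx] = sparse1[idx] + rng.normal(0, 0.5, size=99)
    table["sparse__i1"], table["sparse__i2"] = sparse1, sparse2

    # threshold-coded strings, otherwise clean
    miles = np.round(rng.gamma(4.0, 1.5, n), 1) + 1.1
    m1 = miles.astype(str)
    m1[rng.uniform(size=n) < 0.05] = "≤1"
    m2 = np.where(is_rep, (miles + rng.normal(0, 0.8, n)).round(1).astype(str), "")
    table["miles__i1"], table["miles__i2"] = m1, m2

    # no occasion-2 column at all
    table["deprivation__i1"] = rng.normal(0, 3, n)

    expected = {
        "height": "ok",
        "crp": "ok",
        "miles": "ok",
        "score20": "not_continuous",
        "ties": "too_many_ties",
        "sparse": "too_few_repeats",
        "deprivation": "no_repeat",
    }
    return ShowcaseFixture(table=table, expected_reasons=expected)
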