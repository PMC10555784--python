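"""Variable eligibility screening for repeat-measures agreement analysis.

A candidate variable survives screening only if it behaves like a
continuous measure with enough repeat pairs to estimate agreement:

* it has an occasion-2 column at all (``no_repeat`` otherwise);
* it is real-valued, or integer-valued with more than 20 distinct
  values (``not_continuous``);
* no single value is shared by more than 20% of participants
  (``too_many_ties``);
* at least 100 participants have complete repeat pairs
  (``too_few_repeats``).

Boundary semantics are strict as stated: a 20% share passes, 21% fails;
100 repeat pairs pass, 99 fail; 21 distinct integer values pass, 20
fail. Exclusion reasons are assigned in the fixed precedence order
no_repeat -> not_continuous -> too_many_ties -> too_few_repeats so that
reason counts are deterministic.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Literal

import numpy as np
import pandas as pd

from .simulate import OCC1_SUFFIX, OCC2_SUFFIX

ThresholdPolicy = Literal["boundary", "missing"]

MAX_TIE_SHARE = 0.20
MIN_REPEAT_PAIRS = 100
MIN_DISTINCT_INTEGER = 20  # integer variables need strictly more than this

_THRESHOLD_RE = re.compile(r"^\s*(≤|<=|≥|>=|<|>)\s*([0-9.eE+-]+)\s*$")


@dataclass
class ScreeningDecision:
    variable: str
    n_repeat_pairs: int
    distinct_count: int
    max_value_share: float
    verdict: Literal["include", "exclude"]
    reason: Literal["no_repeat", "not_continuous", "too_many_ties", "too_few_repeats", "ok"]


def coerce_threshold_codes(
    values: Iterable, policy: ThresholdPolicy = "boundary"
) -> pd.Series:
    """Coerce raw (possibly string) values to floats.

    Threshold codes such as "≤1", "<5" or ">=2.5" are resolved by the
    chosen policy: ``boundary`` substitutes the stated bound, ``missing``
    drops them. Plain numeric strings pass through; anything unparseable
    becomes missing.
    """
    if policy not in ("boundary", "missing"):
        raise ValueError(f"unknown threshold policy {policy!r}")

    def one(v):
        if isinstance(v, (int, float, np.integer, np.floating)):
            return float(v)
        if v is None:
            return np.nan
        s = str(v).strip()
        if not s:
            return np.nan
        m = _THRESHOLD_RE.match(s)
        if m:
            return float(m.group(2)) if policy == "boundary" else np.nan
        try:
            return float(s)
        except ValueError:
            return np.nan

    vals = pd.Series(list(values))
    return vals.map(one).astype(float)


def collapse_visit_readings(
    readings: Iterable[float], policy: str = "mean"
) -> float:
    """Collapse multiple readings taken at one visit into a single value.

    Default is the arithmetic mean of valid (finite) readings;
    ``first`` takes the first valid reading. Returns NaN when no reading
    is valid.
    """
    arr = np.asarray(list(readings), dtype=float)
    valid = arr[np.isfinite(arr)]
    if valid.size == 0:
        return float("nan")
    if policy == "mean":
        return float(valid.mean())
    if policy == "first":
        return float(valid[0])
    raise ValueError(f"unknown collapse policy {policy!r}")


def classify_variable(values: pd.Series | np.ndarray) -> tuple[str, int]:
    """Classify a numeric variable as continuous or not.

    Real-valued variables are continuous. Integer-valued variables count
    as continuous only with more than 20 distinct observed values.
    Returns ``(class, distinct_count)`` with class in
    {'continuous', 'not_continuous'}.
    """
    arr = np.asarray(values, dtype=float)
    arr = arr[np.isfinite(arr)]
    distinct = len(np.unique(arr))
    if distinct == 0:
        return "not_continuous", 0
    integer_valued = np.all(arr == np.round(arr))
    if integer_valued and distinct <= MIN_DISTINCT_INTEGER:
        return "not_continuous", distinct
    return "continuous", distinct


def apply_eligibility(
    variable: str,
    *,
    has_repeat: bool,
    continuity_class: str,
    distinct_count: int,
    max_value_share: float,
    n_repeat_pairs: int,
) -> ScreeningDecision:
    """Apply the exclusion rules in fixed precedence order."""
    if not has_repeat:
        reason = "no_repeat"
    elif continuity_class != "continuous":
        reason = "not_continuous"
    elif max_value_share > MAX_TIE_SHARE:
        reason = "too_many_ties"
    elif n_repeat_pairs < MIN_REPEAT_PAIRS:
        reason = "too_few_repeats"
    else:
        reason = "ok"
    return ScreeningDecision(
        variable=variable,
        n_repeat_pairs=n_repeat_pairs,
        distinct_count=distinct_count,
        max_value_share=max_value_share,
        verdict="include" if reason == "ok" else "exclude",
        reason=reason,
    )


def variable_stems(table: pd.DataFrame) -> list[str]:
    """Variable name stems present in a wide cohort table (order of
    first appearance of their occasion-1 column)."""
    return [c[: -len(OCC1_SUFFIX)] for c in table.columns if c.endswith(OCC1_SUFFIX)]


def screen_table(
    table: pd.DataFrame, threshold_policy: ThresholdPolicy = "boundary"
) -> tuple[list[ScreeningDecision], dict[str, int]]:
    """Screen every ``<var>__i1`` variable in a wide table.

    The tie share and continuity class are assessed on occasion-1
    non-missing values (the analysis measure); repeat pairs require both
    occasions non-missing. Returns the per-variable decisions and a
    summary count by reason; the counts partition the variable set.
    """
    decisions: list[ScreeningDecision] = []
    for stem in variable_stems(table):
        v1 = coerce_threshold_codes(table[stem + OCC1_SUFFIX], threshold_policy)
        has_repeat = stem + OCC2_SUFFIX in table.columns
        if has_repeat:
            v2 = coerce_threshold_codes(table[stem + OCC2_SUFFIX], threshold_policy)
            n_pairs = int((v1.notna() & v2.notna()).sum())
        else:
            n_pairs = 0
        nonmiss = v1.dropna()
        share = float(nonmiss.value_counts(normalize=True).max()) if len(nonmiss) else 0.0
        cls, distinct = classify_variable(nonmiss)
        decisions.append(
            apply_eligibility(
                stem,
                has_repeat=has_repeat and n_pairs > 0,
                continuity_class=cls,
                distinct_count=distinct,
                max_value_share=share,
                n_repeat_pairs=n_pairs,
            )
        )
    counts: dict[str, int] = {}
    for d in decisions:
        counts[d.reason] = counts.get(d.reason, 0) + 1
    return decisions, counts


def decisions_frame(decisions: list[ScreeningDecision]) -> pd.DataFrame:
    return pd.DataFrame([d.__dict__ for d in decisions])
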