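"""HbA1c-dependent relative risk and adjusted complication incidence.

The risk model is threshold-linear: below its class threshold a
complication's annual incidence equals the literature baseline; above it,
risk grows additively by ``increment_per_point`` of baseline per 1
percentage point of excess HbA1c, evaluated on a 0.1-point grid
(equivalently, 1/10 of the increment per 0.1-point step).  Excess HbA1c is
rounded to the nearest 0.1 (ties upward) before scaling.

The five-year extrapolation assumes the 6-month HbA1c level persists: model
year 1 averages the adjusted incidence at the baseline level (first
half-year) and at the 6-month level (second half-year); years 2-5 use the
6-month level throughout.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import pandas as pd

from .parameters import (
    HORIZON_YEARS,
    CohortProfile,
    ComplicationClass,
    ComplicationParam,
    ModelConfig,
    RiskRule,
)

__all__ = [
    "risk_multiplier",
    "adjusted_incidence",
    "year_incidence",
    "incidence_table",
]

RuleSet = Mapping[ComplicationClass, RiskRule]


def _round_to_tenth(excess: float) -> float:
    # nearest 0.1 with ties rounded up, matching the 0.1%-increment grid;
    # the small epsilon keeps decimal inputs like 7.05 (stored just below
    # the tie in binary) on the tie-up side
    return math.floor(excess * 10 + 0.5 + 1e-9) / 10


def risk_multiplier(hba1c: float, rule: RiskRule) -> float:
    """Relative risk multiplier (>= 1) for one complication class.

    Returns ``1 + increment_per_point * excess`` where ``excess`` is the
    HbA1c above the rule threshold rounded to the nearest 0.1 point;
    exactly 1 at or below the threshold.
    """
    excess = max(0.0, hba1c - rule.threshold)
    return 1.0 + rule.increment_per_point * _round_to_tenth(excess)


def adjusted_incidence(
    comp: ComplicationParam, hba1c: float, rules: RuleSet
) -> float:
    """Annual incidence of ``comp`` at a given mean HbA1c, capped at 1."""
    try:
        rule = rules[comp.complication_class]
    except KeyError:
        raise KeyError(
            f"no risk rule for complication class {comp.complication_class.value!r}"
        ) from None
    return min(1.0, comp.baseline_incidence * risk_multiplier(hba1c, rule))


def year_incidence(
    comp: ComplicationParam, cohort: CohortProfile, year: int, rules: RuleSet
) -> float:
    """Annual incidence for a model year of the five-year horizon.

    Year 1 is the arithmetic mean of the adjusted incidence at the cohort's
    baseline HbA1c (first half-year) and at its 6-month HbA1c (second
    half-year).  Years 2-5 hold the 6-month level.
    """
    if not 1 <= year <= HORIZON_YEARS:
        raise ValueError(f"model year must be in 1..{HORIZON_YEARS}, got {year}")
    at_6mo = adjusted_incidence(comp, cohort.hba1c_6mo, rules)
    if year == 1:
        at_baseline = adjusted_incidence(comp, cohort.hba1c_baseline, rules)
        return 0.5 * (at_baseline + at_6mo)
    return at_6mo


def incidence_table(
    config: ModelConfig, cohorts: Iterable[str] | None = None
) -> pd.DataFrame:
    """Adjusted annual incidence for every complication x cohort x model year.

    Returns a tidy frame with columns ``cohort, complication, year,
    incidence`` suitable for CSV export.
    """
    rules = {rule.complication_class: rule for rule in config.risk_rules}
    keys = list(cohorts) if cohorts is not None else list(config.cohorts)
    rows = []
    for key in keys:
        cohort = config.cohorts[key]
        for comp in config.complications:
            for year in range(1, HORIZON_YEARS + 1):
                rows.append(
                    {
                        "cohort": key,
                        "complication": comp.name,
                        "year": year,
                        "incidence": year_incidence(comp, cohort, year, rules),
                    }
                )
    return pd.DataFrame(rows)
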