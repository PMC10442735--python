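"""Patient-level outcome computations for a nurse-educator diabetes cohort.

Operates on :class:`PatientRecord` collections (typically produced by
:mod:`diabia.cohort` or read back from its CSV pair) and implements the
study's outcome definitions:

* change in a monitored parameter (HbA1c by default) between baseline and a
  nominal follow-up timepoint, using nearest-measurement matching within a
  +/-6 week window;
* classification against the patient's personal target (reached/maintained,
  improved but not reached, not improved, or missing);
* care-plan adherence: performed events over planned events prorated to the
  patient's follow-up duration, capped at 100% per item;
* cohort summary statistics (mean/SD/median/IQR, HbA1c band proportions,
  target-category proportions, adherence distribution), with missing data
  excluded pairwise and counted.
"""

from __future__ import annotations

import datetime as dt
import math
import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TargetDirection",
    "OutcomeCategory",
    "Measurement",
    "CarePlanItem",
    "PatientRecord",
    "OutcomeClassification",
    "DEFAULT_TARGET_DIRECTIONS",
    "DEFAULT_HBA1C_BANDS",
    "CLINICALLY_RELEVANT_CHANGE",
    "measurement_at",
    "parameter_change",
    "hba1c_change",
    "classify_target",
    "adherence",
    "cohort_summary",
]

DAYS_PER_MONTH = 365.25 / 12
MATCH_WINDOW_DAYS = 42  # nearest measurement within +/-6 weeks of the timepoint
# HbA1c decrease considered clinically relevant (percentage points)
CLINICALLY_RELEVANT_CHANGE = -0.4
# band edges for the HbA1c distribution view: <7.0, 7.0-7.9, 8.0-8.9, >=9.0
DEFAULT_HBA1C_BANDS = (7.0, 8.0, 9.0)


class TargetDirection(str, Enum):
    AT_MOST = "at_most"  # lower is better (HbA1c, LDL, blood pressure, ...)
    AT_LEAST = "at_least"  # higher is better (HDL cholesterol)


DEFAULT_TARGET_DIRECTIONS: dict[str, TargetDirection] = {
    "hba1c": TargetDirection.AT_MOST,
    "ldl": TargetDirection.AT_MOST,
    "hdl": TargetDirection.AT_LEAST,
    "total_cholesterol": TargetDirection.AT_MOST,
    "triglycerides": TargetDirection.AT_MOST,
    "sbp": TargetDirection.AT_MOST,
    "dbp": TargetDirection.AT_MOST,
    "weight": TargetDirection.AT_MOST,
    "waist": TargetDirection.AT_MOST,
}


class OutcomeCategory(str, Enum):
    REACHED_OR_MAINTAINED = "reached_or_maintained"
    IMPROVED_NOT_REACHED = "improved_not_reached"
    NOT_IMPROVED = "not_improved"
    MISSING = "missing"


@dataclass(frozen=True)
class Measurement:
    parameter: str
    date: dt.date
    value: float
    target_value: float | None = None
    target_direction: TargetDirection | None = None


@dataclass(frozen=True)
class CarePlanItem:
    name: str
    planned_per_year: float
    performed_dates: tuple[dt.date, ...] = ()

    @property
    def performed(self) -> int:
        return len(self.performed_dates)


@dataclass(frozen=True)
class PatientRecord:
    patient_id: str
    diabetes_type: int  # 1 or 2
    enrollment_date: dt.date
    followup_months: float
    measurements: tuple[Measurement, ...] = ()
    care_plan: tuple[CarePlanItem, ...] = ()

    def __post_init__(self) -> None:
        if self.diabetes_type not in (1, 2):
            raise ValueError(f"diabetes_type must be 1 or 2, got {self.diabetes_type}")
        if self.followup_months < 6:
            raise ValueError(
                f"patient {self.patient_id}: analyzed patients need >= 6 months of "
                f"follow-up, got {self.followup_months}"
            )


@dataclass(frozen=True)
class OutcomeClassification:
    patient_id: str
    parameter: str
    category: OutcomeCategory
    baseline: float | None = None
    endpoint: float | None = None


def measurement_at(
    record: PatientRecord,
    parameter: str,
    month: float,
    window_days: float = MATCH_WINDOW_DAYS,
) -> Measurement | None:
    """Measurement of ``parameter`` nearest to ``month`` after enrollment.

    Returns ``None`` when no measurement falls within ``window_days`` of the
    nominal timepoint.  Ties (equidistant earlier/later measurements) resolve
    to the earlier one.
    """
    nominal = record.enrollment_date + dt.timedelta(days=month * DAYS_PER_MONTH)
    candidates = [m for m in record.measurements if m.parameter == parameter]
    best: Measurement | None = None
    best_dist = math.inf
    for m in sorted(candidates, key=lambda m: m.date):
        dist = abs((m.date - nominal).days)
        if dist <= window_days and dist < best_dist:
            best, best_dist = m, dist
    return best


def parameter_change(
    record: PatientRecord, parameter: str, window_months: int = 6
) -> float | None:
    """Signed change (follow-up minus baseline) in ``parameter``.

    ``None`` when either endpoint is missing; missingness is a value here,
    not an error.
    """
    if window_months not in (3, 6, 9, 12):
        raise ValueError(f"window_months must be one of 3, 6, 9, 12, got {window_months}")
    baseline = measurement_at(record, parameter, 0.0)
    endpoint = measurement_at(record, parameter, float(window_months))
    if baseline is None or endpoint is None:
        return None
    return endpoint.value - baseline.value


def hba1c_change(record: PatientRecord, window_months: int = 6) -> float | None:
    """HbA1c change in percentage points over the follow-up window."""
    return parameter_change(record, "hba1c", window_months)


def _direction_for(record: PatientRecord, parameter: str) -> TargetDirection:
    for m in record.measurements:
        if m.parameter == parameter and m.target_direction is not None:
            return m.target_direction
    if parameter in DEFAULT_TARGET_DIRECTIONS:
        return DEFAULT_TARGET_DIRECTIONS[parameter]
    raise KeyError(f"unknown parameter {parameter!r}: no target direction available")


def classify_target(
    record: PatientRecord, parameter: str, window_months: int = 6
) -> OutcomeClassification:
    """Classify a patient against their personal target for ``parameter``.

    The endpoint value alone decides target attainment: at the follow-up
    timepoint the patient has *reached or maintained* the target when the
    endpoint satisfies it (<= target for at-most parameters, >= for at-least
    parameters such as HDL), has *improved* when the endpoint is strictly
    better than baseline in the target direction, and otherwise has *not
    improved*.  Missing either endpoint yields the ``missing`` category.
    """
    direction = _direction_for(record, parameter)
    baseline = measurement_at(record, parameter, 0.0)
    endpoint = measurement_at(record, parameter, float(window_months))
    if baseline is None or endpoint is None:
        return OutcomeClassification(
            patient_id=record.patient_id,
            parameter=parameter,
            category=OutcomeCategory.MISSING,
            baseline=None if baseline is None else baseline.value,
            endpoint=None if endpoint is None else endpoint.value,
        )
    target = endpoint.target_value if endpoint.target_value is not None else baseline.target_value
    if target is None:
        raise ValueError(
            f"patient {record.patient_id}: no personal target for {parameter!r}"
        )
    if direction is TargetDirection.AT_MOST:
        reached = endpoint.value <= target
        improved = endpoint.value < baseline.value
    else:
        reached = endpoint.value >= target
        improved = endpoint.value > baseline.value
    if reached:
        category = OutcomeCategory.REACHED_OR_MAINTAINED
    elif improved:
        category = OutcomeCategory.IMPROVED_NOT_REACHED
    else:
        category = OutcomeCategory.NOT_IMPROVED
    return OutcomeClassification(
        patient_id=record.patient_id,
        parameter=parameter,
        category=category,
        baseline=baseline.value,
        endpoint=endpoint.value,
    )


def adherence(record: PatientRecord) -> tuple[float, dict[str, float]]:
    """Care-plan adherence: overall percent and per-item percents.

    Per item, the expected number of events is the planned annual frequency
    prorated to the patient's follow-up duration, floored at one event (any
    planned test falls due at least once during a >= 6-month follow-up); the
    item's adherence is performed/expected, capped at 100%.  The overall
    figure is the unweighted mean over items.  Items with a zero planned
    frequency carry no expectation and are excluded with a warning.
    """
    if not record.care_plan:
        raise ValueError(f"patient {record.patient_id} has no care-plan items")
    per_item: dict[str, float] = {}
    for item in record.care_plan:
        if item.planned_per_year <= 0:
            warnings.warn(
                f"patient {record.patient_id}: care-plan item {item.name!r} has zero "
                "planned frequency; excluded from adherence",
                stacklevel=2,
            )
            continue
        expected = item.planned_per_year * record.followup_months / 12.0
        expected = max(1.0, expected)
        per_item[item.name] = min(1.0, item.performed / expected) * 100.0
    if not per_item:
        raise ValueError(
            f"patient {record.patient_id}: no care-plan items with positive planned frequency"
        )
    overall = float(np.mean(list(per_item.values())))
    return overall, per_item


def _band_label(value: float, edges: Sequence[float]) -> str:
    if value < edges[0]:
        return f"<{edges[0]:g}"
    for low, high in zip(edges, edges[1:]):
        if low <= value < high:
            return f"{low:g}-{high:g}"
    return f">={edges[-1]:g}"


def _describe(values: Sequence[float]) -> dict[str, float]:
    arr = np.asarray(values, dtype=float)
    return {
        "n": int(arr.size),
        "mean": float(np.mean(arr)),
        "sd": float(np.std(arr, ddof=1)) if arr.size > 1 else float("nan"),
        "median": float(np.median(arr)),
        "q1": float(np.percentile(arr, 25)),
        "q3": float(np.percentile(arr, 75)),
    }


def cohort_summary(
    records: Iterable[PatientRecord],
    parameter: str = "hba1c",
    window_months: int = 6,
    bands: Sequence[float] = DEFAULT_HBA1C_BANDS,
) -> dict:
    """Cohort-level outcome summary.

    Returns a dict with:

    ``change``
        mean/SD/median/IQR of the parameter change among patients with
        paired data, the number missing, and the proportion of decreasing
        patients with a clinically relevant decrease (<= -0.4 points).
    ``bands``
        DataFrame of band proportions (columns baseline / followup) over
        the paired subset, using the configured band edges.
    ``target_categories``
        counts and proportions per outcome category over patients with
        paired data; categories partition that subset exactly.
    ``adherence``
        distribution of per-patient overall adherence, plus per-item means.
    """
    records = list(records)
    if not records:
        raise ValueError("cohort is empty")

    changes: list[float] = []
    baselines: list[float] = []
    endpoints: list[float] = []
    n_missing = 0
    for rec in records:
        b = measurement_at(rec, parameter, 0.0)
        e = measurement_at(rec, parameter, float(window_months))
        if b is None or e is None:
            n_missing += 1
            continue
        baselines.append(b.value)
        endpoints.append(e.value)
        changes.append(e.value - b.value)

    change_stats: dict = {"n_missing": n_missing}
    if changes:
        change_stats.update(_describe(changes))
        decreased = [c for c in changes if c < 0]
        change_stats["n_decreased"] = len(decreased)
        change_stats["clinically_relevant_fraction_of_decreased"] = (
            float(np.mean([c <= CLINICALLY_RELEVANT_CHANGE for c in decreased]))
            if decreased
            else float("nan")
        )

    labels = [f"<{bands[0]:g}"] + [
        f"{lo:g}-{hi:g}" for lo, hi in zip(bands, bands[1:])
    ] + [f">={bands[-1]:g}"]
    band_rows = {}
    for when, values in (("baseline", baselines), ("followup", endpoints)):
        counts = {label: 0 for label in labels}
        for v in values:
            counts[_band_label(v, bands)] += 1
        total = max(1, len(values))
        band_rows[when] = {label: counts[label] / total for label in labels}
    band_df = pd.DataFrame(band_rows)
    band_df.index.name = f"{parameter}_band"

    cat_counts = {cat.value: 0 for cat in OutcomeCategory}
    for rec in records:
        cat_counts[classify_target(rec, parameter, window_months).category.value] += 1
    n_paired = len(changes)
    cat_props = {
        cat: (count / n_paired if cat != OutcomeCategory.MISSING.value and n_paired else np.nan)
        for cat, count in cat_counts.items()
    }

    overall_adherences: list[float] = []
    item_values: dict[str, list[float]] = {}
    for rec in records:
        if not rec.care_plan:
            continue
        overall, per_item = adherence(rec)
        overall_adherences.append(overall)
        for name, value in per_item.items():
            item_values.setdefault(name, []).append(value)
    adherence_stats: dict = {}
    if overall_adherences:
        adherence_stats = _describe(overall_adherences)
        adherence_stats["fraction_above_70pct"] = float(
            np.mean([a > 70 for a in overall_adherences])
        )
        adherence_stats["per_item_mean"] = {
            name: float(np.mean(vals)) for name, vals in sorted(item_values.items())
        }

    return {
        "parameter": parameter,
        "window_months": window_months,
        "n_patients": len(records),
        "change": change_stats,
        "bands": band_df,
        "target_categories": {"counts": cat_counts, "proportions": cat_props},
        "adherence": adherence_stats,
    }
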