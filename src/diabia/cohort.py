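"""Synthetic patient-cohort generator with the structure of the nurse-educator
diabetes study.

The generator emulates the real cohort's *summary* structure — 117 patients
(8 type 1 / 109 type 2), baseline HbA1c mean 7.8 (SD 1.4), 6-month change
mean -0.6 (SD 1.3), paired baseline/6-month HbA1c available for 79/117
patients, per-patient care plans with partial completion — so that every
clinical-pipeline operation is testable without any real data.  It does not
model longitudinal glucose dynamics, treatment effects, or the joint
distribution of cardiometabolic parameters (sampled independently).

Sampling is fully deterministic given ``CohortSpec.seed``.  The default mode
applies subgroup membership (type 1, paired availability) as independent
Bernoulli draws; ``stratified=True`` pins the exact published denominators
(8 type 1 patients, 79 paired) instead.
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, model_validator

from .clinical import (
    DAYS_PER_MONTH,
    CarePlanItem,
    Measurement,
    PatientRecord,
    TargetDirection,
)

__all__ = [
    "ParameterSpec",
    "CarePlanItemSpec",
    "CohortSpec",
    "generate",
    "write_cohort",
    "read_cohort",
]


class ParameterSpec(BaseModel):
    """Sampling distribution for one monitored parameter.

    Baseline values are truncated-normal on [lower, upper]; the follow-up
    value adds an independent normal change, truncated below at ``floor``.
    ``paired_fraction`` is the probability that a patient has both a
    baseline and a 6-month measurement.
    """

    model_config = ConfigDict(frozen=True)

    baseline_mean: float
    baseline_sd: float = Field(ge=0)
    change_mean: float = 0.0
    change_sd: float = Field(default=0.0, ge=0)
    lower: float = 0.0
    upper: float = float("inf")
    floor: float = 0.0
    paired_fraction: float = Field(default=1.0, ge=0, le=1)
    target_choices: tuple[float, ...] = ()
    target_probs: tuple[float, ...] = ()
    direction: TargetDirection = TargetDirection.AT_MOST

    @model_validator(mode="after")
    def _check(self) -> "ParameterSpec":
        if self.upper <= self.lower:
            raise ValueError("upper must exceed lower")
        if self.target_probs and len(self.target_probs) != len(self.target_choices):
            raise ValueError("target_probs must match target_choices in length")
        return self


class CarePlanItemSpec(BaseModel):
    model_config = ConfigDict(frozen=True)

    planned_per_year: float = Field(gt=0)
    completion_probability: float = Field(ge=0, le=1)


def _default_parameters() -> dict[str, ParameterSpec]:
    return {
        # pooled study cohort: baseline 7.8 (1.4), 6-month change -0.6 (1.3),
        # paired data for 79/117 patients
        "hba1c": ParameterSpec(
            baseline_mean=7.8,
            baseline_sd=1.4,
            change_mean=-0.6,
            change_sd=1.3,
            lower=4.5,
            upper=15.0,
            floor=4.0,
            paired_fraction=79 / 117,
            target_choices=(6.5, 7.0, 7.5),
            target_probs=(0.15, 0.7, 0.15),
            direction=TargetDirection.AT_MOST,
        ),
        "ldl": ParameterSpec(
            baseline_mean=2.4,
            baseline_sd=0.9,
            change_mean=-0.1,
            change_sd=0.5,
            lower=0.5,
            upper=8.0,
            floor=0.3,
            paired_fraction=71 / 117,
            target_choices=(1.8, 2.5),
            target_probs=(0.6, 0.4),
            direction=TargetDirection.AT_MOST,
        ),
        "hdl": ParameterSpec(
            baseline_mean=1.2,
            baseline_sd=0.3,
            change_mean=0.0,
            change_sd=0.15,
            lower=0.4,
            upper=3.0,
            floor=0.3,
            paired_fraction=71 / 117,
            target_choices=(1.0, 1.2),
            target_probs=(0.5, 0.5),
            direction=TargetDirection.AT_LEAST,
        ),
        "sbp": ParameterSpec(
            baseline_mean=133.0,
            baseline_sd=15.0,
            change_mean=-2.0,
            change_sd=12.0,
            lower=90.0,
            upper=210.0,
            floor=80.0,
            paired_fraction=79 / 117,
            target_choices=(140.0,),
            target_probs=(1.0,),
            direction=TargetDirection.AT_MOST,
        ),
    }


def _default_care_plan() -> dict[str, CarePlanItemSpec]:
    # planned frequencies follow the program's follow-up schedule (quarterly
    # HbA1c and nurse visits, semiannual lipids and physician visits, annual
    # renal test, dietetics and eye/foot screening); completion probabilities
    # mirror the reported per-item adherence pattern (labs and consultations
    # near-complete, dietetics and screenings partial)
    return {
        "hba1c_test": CarePlanItemSpec(planned_per_year=4, completion_probability=0.99),
        "lipid_test": CarePlanItemSpec(planned_per_year=2, completion_probability=0.98),
        "mau_test": CarePlanItemSpec(planned_per_year=1, completion_probability=0.98),
        "dne_consultation": CarePlanItemSpec(planned_per_year=4, completion_probability=0.99),
        "doctor_consultation": CarePlanItemSpec(planned_per_year=2, completion_probability=0.98),
        "dietetic_consultation": CarePlanItemSpec(planned_per_year=1, completion_probability=0.59),
        "eye_examination": CarePlanItemSpec(planned_per_year=1, completion_probability=0.57),
        "foot_examination": CarePlanItemSpec(planned_per_year=1, completion_probability=0.44),
    }


class CohortSpec(BaseModel):
    """Specification of a synthetic cohort; defaults match the study cohort."""

    n_patients: int = Field(default=117, gt=0)
    type1_fraction: float = Field(default=8 / 117, ge=0, le=1)
    parameters: dict[str, ParameterSpec] = Field(default_factory=_default_parameters)
    care_plan: dict[str, CarePlanItemSpec] = Field(default_factory=_default_care_plan)
    followup_months_min: float = Field(default=6.0, ge=6)
    followup_months_max: float = 12.0
    enrollment_start: dt.date = dt.date(2019, 11, 25)
    enrollment_end: dt.date = dt.date(2020, 6, 30)
    stratified: bool = False
    # stress-test knob: couples care-plan completion to the HbA1c change
    # (0 = independent, as reported)
    adherence_change_correlation: float = Field(default=0.0, ge=-1, le=1)
    seed: int = 0

    @model_validator(mode="after")
    def _check(self) -> "CohortSpec":
        if self.followup_months_max < self.followup_months_min:
            raise ValueError("followup_months_max must be >= followup_months_min")
        if self.enrollment_end < self.enrollment_start:
            raise ValueError("enrollment_end must be >= enrollment_start")
        if "hba1c" not in self.parameters:
            raise ValueError("parameters must include 'hba1c'")
        return self


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lower: float, upper: float, size: int
) -> np.ndarray:
    if sd == 0:
        return np.full(size, float(np.clip(mean, lower, upper)))
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=size - filled)
        keep = draw[(draw >= lower) & (draw <= upper)]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def _exact_mask(rng: np.random.Generator, n: int, fraction: float) -> np.ndarray:
    k = int(round(n * fraction))
    mask = np.zeros(n, dtype=bool)
    mask[rng.permutation(n)[:k]] = True
    return mask


def generate(spec: CohortSpec) -> list[PatientRecord]:
    """Draw a synthetic cohort; deterministic given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_patients

    enroll_span = (spec.enrollment_end - spec.enrollment_start).days
    enroll_offsets = rng.integers(0, enroll_span + 1, size=n)
    followups = rng.uniform(spec.followup_months_min, spec.followup_months_max, size=n)

    if spec.stratified:
        type1 = _exact_mask(rng, n, spec.type1_fraction)
    else:
        type1 = rng.random(n) < spec.type1_fraction

    # per-parameter draws
    param_values: dict[str, dict[str, np.ndarray]] = {}
    for name, p in spec.parameters.items():
        baseline = _truncated_normal(rng, p.baseline_mean, p.baseline_sd, p.lower, p.upper, n)
        change = rng.normal(p.change_mean, p.change_sd, size=n) if p.change_sd > 0 else np.full(
            n, p.change_mean
        )
        followup_value = np.maximum(p.floor, baseline + change)
        if spec.stratified:
            paired = _exact_mask(rng, n, p.paired_fraction)
        else:
            paired = rng.random(n) < p.paired_fraction
        if p.target_choices:
            probs = np.asarray(p.target_probs) if p.target_probs else None
            targets = rng.choice(np.asarray(p.target_choices), size=n, p=probs)
        else:
            targets = np.full(n, np.nan)
        jitter = rng.integers(-14, 15, size=n)  # 6-month visit date jitter, days
        param_values[name] = {
            "baseline": baseline,
            "followup": followup_value,
            "paired": paired,
            "target": targets,
            "jitter": jitter,
        }

    # optional coupling of completion probability to the HbA1c change
    hba1c_change = (
        param_values["hba1c"]["followup"] - param_values["hba1c"]["baseline"]
    )
    sd = spec.parameters["hba1c"].change_sd or 1.0
    completion_shift = -spec.adherence_change_correlation * (hba1c_change / sd) * 0.15

    records: list[PatientRecord] = []
    for i in range(n):
        enrollment = spec.enrollment_start + dt.timedelta(days=int(enroll_offsets[i]))
        followup_months = float(followups[i])
        measurements: list[Measurement] = []
        for name, p in spec.parameters.items():
            vals = param_values[name]
            target = None if np.isnan(vals["target"][i]) else float(vals["target"][i])
            measurements.append(
                Measurement(
                    parameter=name,
                    date=enrollment,
                    value=round(float(vals["baseline"][i]), 2),
                    target_value=target,
                    target_direction=p.direction,
                )
            )
            if vals["paired"][i]:
                visit = enrollment + dt.timedelta(
                    days=int(round(6 * DAYS_PER_MONTH)) + int(vals["jitter"][i])
                )
                measurements.append(
                    Measurement(
                        parameter=name,
                        date=visit,
                        value=round(float(vals["followup"][i]), 2),
                        target_value=target,
                        target_direction=p.direction,
                    )
                )
        care_plan: list[CarePlanItem] = []
        for item_name, item in spec.care_plan.items():
            expected = max(1, int(round(item.planned_per_year * followup_months / 12.0)))
            prob = float(np.clip(item.completion_probability + completion_shift[i], 0, 1))
            performed = int(rng.binomial(expected, prob))
            step = followup_months * DAYS_PER_MONTH / max(1, performed + 1)
            dates = tuple(
                enrollment + dt.timedelta(days=int(round(step * (j + 1))))
                for j in range(performed)
            )
            care_plan.append(
                CarePlanItem(
                    name=item_name,
                    planned_per_year=item.planned_per_year,
                    performed_dates=dates,
                )
            )
        records.append(
            PatientRecord(
                patient_id=f"P{i + 1:04d}",
                diabetes_type=1 if type1[i] else 2,
                enrollment_date=enrollment,
                followup_months=round(followup_months, 2),
                measurements=tuple(measurements),
                care_plan=tuple(care_plan),
            )
        )
    return records


# ---------------------------------------------------------------------------
# CSV round trip
# ---------------------------------------------------------------------------

_PATIENT_COLUMNS = [
    "patient_id",
    "diabetes_type",
    "enrollment_date",
    "followup_months",
    "parameter",
    "date",
    "value",
    "target_value",
    "target_direction",
]
_CAREPLAN_COLUMNS = ["patient_id", "item", "planned_per_year", "performed_dates"]


def write_cohort(records: list[PatientRecord], out_dir: str | Path) -> dict[str, Path]:
    """Write the cohort as the two CSVs consumed by the clinical pipeline.

    ``patients.csv`` holds one row per patient-measurement; ``careplans.csv``
    one row per care-plan item, with performed-event dates semicolon-joined.
    ``read_cohort`` round-trips the files value-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    measurement_rows = []
    careplan_rows = []
    for rec in records:
        for m in rec.measurements:
            measurement_rows.append(
                {
                    "patient_id": rec.patient_id,
                    "diabetes_type": rec.diabetes_type,
                    "enrollment_date": rec.enrollment_date.isoformat(),
                    "followup_months": rec.followup_months,
                    "parameter": m.parameter,
                    "date": m.date.isoformat(),
                    "value": m.value,
                    "target_value": "" if m.target_value is None else m.target_value,
                    "target_direction": "" if m.target_direction is None else m.target_direction.value,
                }
            )
        for item in rec.care_plan:
            careplan_rows.append(
                {
                    "patient_id": rec.patient_id,
                    "item": item.name,
                    "planned_per_year": item.planned_per_year,
                    "performed_dates": ";".join(d.isoformat() for d in item.performed_dates),
                }
            )
    patients_path = out_dir / "patients.csv"
    careplans_path = out_dir / "careplans.csv"
    pd.DataFrame(measurement_rows, columns=_PATIENT_COLUMNS).to_csv(patients_path, index=False)
    pd.DataFrame(careplan_rows, columns=_CAREPLAN_COLUMNS).to_csv(careplans_path, index=False)
    return {"patients": patients_path, "careplans": careplans_path}


def read_cohort(patients_csv: str | Path, careplans_csv: str | Path) -> list[PatientRecord]:
    """Rebuild :class:`PatientRecord` objects from the CSV pair."""
    patients = pd.read_csv(patients_csv, dtype={"patient_id": str}, keep_default_na=False)
    careplans = pd.read_csv(careplans_csv, dtype={"patient_id": str}, keep_default_na=False)
    plans_by_patient: dict[str, list[CarePlanItem]] = {}
    for _, row in careplans.iterrows():
        dates = tuple(
            dt.date.fromisoformat(s) for s in str(row["performed_dates"]).split(";") if s
        )
        plans_by_patient.setdefault(row["patient_id"], []).append(
            CarePlanItem(
                name=row["item"],
                planned_per_year=float(row["planned_per_year"]),
                performed_dates=dates,
            )
        )
    records = []
    for patient_id, group in patients.groupby("patient_id", sort=False):
        first = group.iloc[0]
        measurements = tuple(
            Measurement(
                parameter=row["parameter"],
                date=dt.date.fromisoformat(row["date"]),
                value=float(row["value"]),
                target_value=None if row["target_value"] == "" else float(row["target_value"]),
                target_direction=None
                if row["target_direction"] == ""
                else TargetDirection(row["target_direction"]),
            )
            for _, row in group.iterrows()
        )
        records.append(
            PatientRecord(
                patient_id=patient_id,
                diabetes_type=int(first["diabetes_type"]),
                enrollment_date=dt.date.fromisoformat(first["enrollment_date"]),
                followup_months=float(first["followup_months"]),
                measurements=measurements,
                care_plan=tuple(plans_by_patient.get(patient_id, [])),
            )
        )
    return records
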