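import datetime as dt

import pytest

from diabia.clinical import CarePlanItem, Measurement, PatientRecord, TargetDirection
from diabia.parameters import ComplicationClass, default_config


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def rules(config):
    return {rule.complication_class: rule for rule in config.risk_rules}


@pytest.fixture(scope="session")
def macro_rule(rules):
    return rules[ComplicationClass.MACROVASCULAR]


@pytest.fixture(scope="session")
def micro_rule(rules):
    return rules[ComplicationClass.MICROVASCULAR]


def make_patient(
    patient_id="P0001",
    baseline=8.0,
    month6=None,
    target=7.0,
    parameter="hba1c",
    direction=TargetDirection.AT_MOST,
    followup_months=6.5,
    care_plan=(),
    extra_measurements=(),
):
    """Hand-build a patient with a baseline and optional 6-month measurement."""
    enrollment = dt.date(2020, 1, 1)
    measurements = [
        Measurement(
            parameter=parameter,
            date=enrollment,
            value=baseline,
            target_value=target,
            target_direction=direction,
        )
    ]
    if month6 is not None:
        measurements.append(
            Measurement(
                parameter=parameter,
                date=enrollment + dt.timedelta(days=183),
                value=month6,
                target_value=target,
                target_direction=direction,
            )
        )
    measurements.extend(extra_measurements)
    return PatientRecord(
        patient_id=patient_id,
        diabetes_type=2,
        enrollment_date=enrollment,
        followup_months=followup_months,
        measurements=tuple(measurements),
        care_plan=tuple(care_plan),
    )


def make_care_item(name, planned_per_year, performed, enrollment=dt.date(2020, 1, 1)):
    dates = tuple(enrollment + dt.timedelta(days=30 * (j + 1)) for j in range(performed))
    return CarePlanItem(name=name, planned_per_year=planned_per_year, performed_dates=dates)
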