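"""Patient-level outcome computations: changes, target classes, adherence."""

import datetime as dt

import numpy as np
import pytest

from diabia.clinical import (
    Measurement,
    OutcomeCategory,
    TargetDirection,
    adherence,
    classify_target,
    cohort_summary,
    hba1c_change,
    measurement_at,
    parameter_change,
)
from conftest import make_care_item, make_patient


class TestChange:
    def test_six_month_decrease(self):
        rec = make_patient(baseline=8.2, month6=7.4)
        assert hba1c_change(rec) == pytest.approx(-0.8)

    def test_no_change(self):
        rec = make_patient(baseline=7.5, month6=7.5)
        assert hba1c_change(rec) == 0.0

    def test_missing_endpoint_is_missing_not_error(self):
        rec = make_patient(baseline=8.2, month6=None)
        assert hba1c_change(rec) is None

    def test_measurement_outside_six_week_window_not_matched(self):
        enrollment = dt.date(2020, 1, 1)
        far = Measurement(
            parameter="hba1c", date=enrollment + dt.timedelta(days=120), value=7.0
        )
        rec = make_patient(baseline=8.0, month6=None, extra_measurements=(far,))
        # day 120 is ~63 days from the nominal 6-month timepoint: no match
        assert measurement_at(rec, "hba1c", 6.0) is None
        # but it is within the window of the 3-month timepoint
        assert measurement_at(rec, "hba1c", 3.0) is far

    def test_nearest_measurement_wins(self):
        enrollment = dt.date(2020, 1, 1)
        near = Measurement(
            parameter="hba1c", date=enrollment + dt.timedelta(days=190), value=7.1
        )
        rec = make_patient(baseline=8.0, month6=7.6, extra_measurements=(near,))
        # day 183 measurement is nearer the nominal timepoint than day 190
        assert hba1c_change(rec) == pytest.approx(-0.4)

    def test_invalid_window_rejected(self):
        rec = make_patient(baseline=8.0, month6=7.0)
        with pytest.raises(ValueError, match="window_months"):
            parameter_change(rec, "hba1c", window_months=5)


class TestClassifyTarget:
    def test_reached(self):
        rec = make_patient(baseline=8.0, month6=6.9, target=7.0)
        assert classify_target(rec, "hba1c").category is OutcomeCategory.REACHED_OR_MAINTAINED

    def test_improved_not_reached(self):
        rec = make_patient(baseline=8.0, month6=7.5, target=7.0)
        assert classify_target(rec, "hba1c").category is OutcomeCategory.IMPROVED_NOT_REACHED

    def test_at_least_direction_for_hdl(self):
        rec = make_patient(
            baseline=0.9, month6=0.8, target=1.0,
            parameter="hdl", direction=TargetDirection.AT_LEAST,
        )
        assert classify_target(rec, "hdl").category is OutcomeCategory.NOT_IMPROVED

    def test_maintained_counts_as_reached(self):
        # already at target at baseline and still there at 6 months
        rec = make_patient(baseline=6.8, month6=6.8, target=7.0)
        assert classify_target(rec, "hba1c").category is OutcomeCategory.REACHED_OR_MAINTAINED

    def test_missing_when_endpoint_absent(self):
        rec = make_patient(baseline=8.0, month6=None)
        assert classify_target(rec, "hba1c").category is OutcomeCategory.MISSING

    def test_unknown_parameter_errors(self):
        rec = make_patient(baseline=8.0, month6=7.0)
        with pytest.raises(KeyError, match="no target direction"):
            classify_target(rec, "ferritin")


class TestAdherence:
    def test_prorated_expected_count(self):
        # planned 4/yr over 6 months -> 2 expected; 2 performed -> 100%
        rec = make_patient(
            followup_months=6.0, care_plan=[make_care_item("hba1c_test", 4, 2)]
        )
        overall, per_item = adherence(rec)
        assert per_item["hba1c_test"] == pytest.approx(100.0)
        assert overall == pytest.approx(100.0)

    def test_half_of_expected(self):
        rec = make_patient(
            followup_months=12.0, care_plan=[make_care_item("lipid_test", 2, 1)]
        )
        _, per_item = adherence(rec)
        assert per_item["lipid_test"] == pytest.approx(50.0)

    def test_zero_performed_everywhere(self):
        rec = make_patient(
            followup_months=8.0,
            care_plan=[make_care_item("a", 4, 0), make_care_item("b", 1, 0)],
        )
        overall, per_item = adherence(rec)
        assert overall == 0.0 and set(per_item.values()) == {0.0}

    def test_expected_count_floored_at_one(self):
        # an annual test is due at least once during any >= 6-month follow-up
        rec = make_patient(
            followup_months=6.0, care_plan=[make_care_item("eye_examination", 1, 1)]
        )
        _, per_item = adherence(rec)
        assert per_item["eye_examination"] == pytest.approx(100.0)

    def test_capped_at_100_and_overall_is_unweighted_mean(self):
        rec = make_patient(
            followup_months=12.0,
            care_plan=[make_care_item("a", 2, 5), make_care_item("b", 2, 1)],
        )
        overall, per_item = adherence(rec)
        assert per_item["a"] == 100.0
        assert overall == pytest.approx((100.0 + 50.0) / 2)

    def test_zero_planned_frequency_excluded_with_warning(self):
        rec = make_patient(
            followup_months=6.0,
            care_plan=[make_care_item("a", 0, 3), make_care_item("b", 4, 2)],
        )
        with pytest.warns(UserWarning, match="zero"):
            overall, per_item = adherence(rec)
        assert set(per_item) == {"b"}

    def test_no_care_plan_errors(self):
        rec = make_patient()
        with pytest.raises(ValueError, match="no care-plan"):
            adherence(rec)


class TestCohortSummary:
    def test_two_point_statistics(self):
        recs = [
            make_patient("P1", baseline=8.0, month6=7.0),
            make_patient("P2", baseline=7.5, month6=7.5),
        ]
        summary = cohort_summary(recs)
        assert summary["change"]["mean"] == pytest.approx(-0.5)
        assert summary["change"]["sd"] == pytest.approx(0.707, abs=1e-3)
        assert summary["change"]["n_missing"] == 0

    def test_all_below_seven_at_followup(self):
        recs = [
            make_patient(f"P{i}", baseline=8.0 + 0.1 * i, month6=6.5 + 0.05 * i)
            for i in range(5)
        ]
        summary = cohort_summary(recs)
        assert summary["bands"].loc["<7", "followup"] == pytest.approx(1.0)

    def test_categories_partition_paired_subset(self):
        recs = [
            make_patient("P1", baseline=8.0, month6=6.9, target=7.0),  # reached
            make_patient("P2", baseline=8.0, month6=7.5, target=7.0),  # improved
            make_patient("P3", baseline=8.0, month6=8.3, target=7.0),  # not improved
            make_patient("P4", baseline=8.0, month6=None, target=7.0),  # missing
        ]
        summary = cohort_summary(recs)
        counts = summary["target_categories"]["counts"]
        assert counts == {
            "reached_or_maintained": 1,
            "improved_not_reached": 1,
            "not_improved": 1,
            "missing": 1,
        }
        paired = summary["change"]["n"]
        assert sum(v for k, v in counts.items() if k != "missing") == paired

    def test_matches_independent_recomputation(self):
        rng = np.random.default_rng(7)
        recs = []
        changes = []
        for i in range(40):
            b = float(rng.uniform(6, 11))
            paired = i % 5 != 0
            m6 = float(rng.uniform(5.5, 10.5)) if paired else None
            recs.append(make_patient(f"P{i}", baseline=b, month6=m6))
            if paired:
                changes.append(m6 - b)
        summary = cohort_summary(recs)
        assert summary["change"]["mean"] == pytest.approx(np.mean(changes))
        assert summary["change"]["sd"] == pytest.approx(np.std(changes, ddof=1))
        assert summary["change"]["median"] == pytest.approx(np.median(changes))
        assert summary["change"]["n_missing"] == sum(1 for i in range(40) if i % 5 == 0)

    def test_empty_cohort_errors(self):
        with pytest.raises(ValueError, match="empty"):
            cohort_summary([])
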