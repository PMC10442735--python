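"""Scenario costing, budget impact, per-patient view, market-share scaling."""

import numpy as np
import pandas as pd
import pytest

from diabia.budget_engine import (
    budget_impact,
    market_share_scenario,
    per_patient_net_impact,
    run_budget_model,
    scenario_costs,
)
from diabia.parameters import CohortProfile, ModelConfig


def brute_force_scenario(config, cohort):
    """Independent per-year, per-complication loop using only the closed-form
    multiplier (the cohort HbA1c levels sit on the 0.1 grid, so the grid
    rounding inside the engine is a no-op here)."""
    thresholds = {r.complication_class: (r.threshold, r.increment_per_point) for r in config.risk_rules}

    def mult(h, klass):
        t, inc = thresholds[klass]
        return 1.0 + inc * max(0.0, h - t)

    comp_cost = {}
    events = {}
    for k in range(1, 6):
        pop = config.population.years[k - 1].prevalence + config.population.years[k - 1].incidence
        total = 0.0
        for comp in config.complications:
            if k == 1:
                inc = 0.5 * (
                    min(1, comp.baseline_incidence * mult(cohort.hba1c_baseline, comp.complication_class))
                    + min(1, comp.baseline_incidence * mult(cohort.hba1c_6mo, comp.complication_class))
                )
            else:
                inc = min(
                    1, comp.baseline_incidence * mult(cohort.hba1c_6mo, comp.complication_class)
                )
            events[(k, comp.name)] = inc * pop
            total += inc * pop * comp.cost_2021_zar
        comp_cost[k] = total
    return events, comp_cost


class TestScenarioCosts:
    def test_agrees_with_brute_force_oracle(self, config):
        for key in ("standard_of_care", "mydiacare"):
            cohort = config.cohorts[key]
            result = scenario_costs(cohort, config, monitoring=config.monitoring[key])
            events, comp_cost = brute_force_scenario(config, cohort)
            for k in range(1, 6):
                assert result.complication_cost.loc[k] == pytest.approx(
                    comp_cost[k], rel=1e-6
                )
                for comp in config.complications:
                    assert result.events.loc[k, comp.name] == pytest.approx(
                        events[(k, comp.name)], rel=1e-6
                    )

    def test_total_is_complication_plus_monitoring(self, config):
        without, with_, _ = run_budget_model(config)
        for res in (without, with_):
            assert np.allclose(
                res.total_cost, res.complication_cost + res.monitoring_cost
            )
            assert (res.summary() >= 0).all().all()

    def test_zero_incidences_give_zero_complication_cost(self, config):
        data = config.model_dump()
        for comp in data["complications"]:
            comp["baseline_incidence"] = 0.0
        cfg = ModelConfig.model_validate(data)
        result = scenario_costs(
            cfg.cohorts["standard_of_care"], cfg, monitoring=cfg.monitoring["standard_of_care"]
        )
        assert (result.complication_cost == 0).all()
        assert (result.monitoring_cost > 0).all()

    def test_linearity_in_unit_costs(self, config):
        base = scenario_costs(
            config.cohorts["standard_of_care"],
            config,
            monitoring=config.monitoring["standard_of_care"],
        )
        data = config.model_dump()
        for comp in data["complications"]:
            comp["cost_2021_zar"] *= 3.0
        scaled_cfg = ModelConfig.model_validate(data)
        scaled = scenario_costs(
            scaled_cfg.cohorts["standard_of_care"],
            scaled_cfg,
            monitoring=scaled_cfg.monitoring["standard_of_care"],
        )
        assert np.allclose(scaled.complication_cost, 3.0 * base.complication_cost)


class TestBudgetImpact:
    def test_identical_scenarios_give_zero_deltas(self, config):
        res = scenario_costs(
            config.cohorts["mydiacare"], config, monitoring=config.monitoring["mydiacare"]
        )
        impact = budget_impact(res, res)
        assert (impact.events_avoided == 0).all().all()
        assert (impact.net_impact == 0).all()
        assert impact.per_patient_year1 == 0

    def test_antisymmetry(self, config):
        without, with_, _ = run_budget_model(config)
        fwd = budget_impact(without, with_)
        rev = budget_impact(with_, without)
        pd.testing.assert_frame_equal(fwd.cost_avoided, -rev.cost_avoided)
        pd.testing.assert_series_equal(fwd.net_impact, -rev.net_impact)

    def test_net_impact_decomposition(self, config):
        _, _, impact = run_budget_model(config)
        assert np.allclose(
            impact.net_impact,
            impact.complication_cost_avoided + impact.monitoring_delta,
        )
        assert impact.cumulative_net_impact == pytest.approx(impact.net_impact.sum())

    def test_raising_with_cohort_6mo_hba1c_never_increases_net_impact(self, config):
        impacts = []
        for h6 in (7.2, 7.6, 8.0, 8.2):
            data = config.model_dump()
            data["cohorts"]["mydiacare"]["hba1c_6mo"] = h6
            _, _, impact = run_budget_model(ModelConfig.model_validate(data))
            impacts.append(impact.net_impact.sum())
        assert all(a >= b for a, b in zip(impacts, impacts[1:]))

    def test_mismatched_population_rejected(self, config):
        without, _, _ = run_budget_model(config)
        data = config.model_dump()
        data["population"]["years"][0]["prevalence"] += 1000
        other_cfg = ModelConfig.model_validate(data)
        other = scenario_costs(
            other_cfg.cohorts["mydiacare"],
            other_cfg,
            monitoring=other_cfg.monitoring["mydiacare"],
        )
        with pytest.raises(ValueError, match="population"):
            budget_impact(without, other)


class TestPerPatient:
    def test_is_year1_net_over_year1_treated(self, config):
        _, _, impact = run_budget_model(config)
        expected = impact.net_impact.iloc[0] / config.population.treated(1)
        assert per_patient_net_impact(impact) == pytest.approx(expected)

    def test_equal_scenarios_unchanged_by_common_scaling(self, config):
        # doubling both scenarios' costs equally leaves a zero delta at zero
        res = scenario_costs(
            config.cohorts["mydiacare"], config, monitoring=config.monitoring["mydiacare"]
        )
        impact = budget_impact(res, res)
        assert per_patient_net_impact(impact) == 0.0


class TestMarketShare:
    def test_identity_and_zero_shares(self, config):
        _, _, impact = run_budget_model(config)
        same = market_share_scenario(impact, [1.0] * 5)
        pd.testing.assert_series_equal(same.net_impact, impact.net_impact)
        none = market_share_scenario(impact, [0.0] * 5)
        assert (none.net_impact == 0).all()

    def test_each_year_scaled_by_its_share(self, config):
        _, _, impact = run_budget_model(config)
        shares = [0.02, 0.03, 0.04, 0.05, 0.06]
        scaled = market_share_scenario(impact, shares)
        for k, share in zip(range(1, 6), shares):
            assert scaled.net_impact.loc[k] == pytest.approx(
                share * impact.net_impact.loc[k]
            )
        assert scaled.cumulative_net_impact == pytest.approx(
            sum(s * impact.net_impact.loc[k] for k, s in zip(range(1, 6), shares))
        )

    def test_share_outside_unit_interval_rejected(self, config):
        _, _, impact = run_budget_model(config)
        with pytest.raises(ValueError, match=r"\[0, 1\]"):
            market_share_scenario(impact, [0.02, 0.03, 0.04, 0.05, 1.5])
        with pytest.raises(ValueError, match="one share per model year"):
            market_share_scenario(impact, [0.02, 0.03])
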