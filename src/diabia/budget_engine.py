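"""Scenario costing and net budget impact over the five-year horizon.

For each scenario and model year the engine computes expected complication
event counts (adjusted incidence x treated population), complication costs
(events x 2021 unit cost), monitoring costs (per-patient annual cost x
treated population) and their total.  The budget impact of adopting the
program is the element-wise difference without-minus-with, so positive
numbers are savings.

Event counts and costs are carried as real numbers throughout; rounding to
whole events or whole ZAR happens only in rendered reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import (
    HORIZON_YEARS,
    CohortProfile,
    ModelConfig,
    MonitoringProfile,
    PopulationProjection,
)
from .risk_model import year_incidence

__all__ = [
    "ScenarioResult",
    "BudgetImpactResult",
    "scenario_costs",
    "budget_impact",
    "per_patient_net_impact",
    "market_share_scenario",
    "run_budget_model",
]

_YEARS = pd.RangeIndex(1, HORIZON_YEARS + 1, name="year")


@dataclass(frozen=True)
class ScenarioResult:
    """Per-year costs and expected event counts for one scenario."""

    label: str
    treated: pd.Series  # patients per model year
    events: pd.DataFrame  # year x complication, expected event counts
    event_costs: pd.DataFrame  # year x complication, ZAR
    monitoring_cost: pd.Series  # ZAR per year

    @property
    def complication_cost(self) -> pd.Series:
        return self.event_costs.sum(axis=1).rename("complication_cost_zar")

    @property
    def total_cost(self) -> pd.Series:
        return (self.complication_cost + self.monitoring_cost).rename("total_cost_zar")

    def summary(self) -> pd.DataFrame:
        """Year-indexed cost table (treated population, cost components)."""
        return pd.DataFrame(
            {
                "treated_population": self.treated,
                "complication_cost_zar": self.complication_cost,
                "monitoring_cost_zar": self.monitoring_cost,
                "total_cost_zar": self.total_cost,
            }
        )


@dataclass(frozen=True)
class BudgetImpactResult:
    """Differences (scenario without minus scenario with) per model year.

    Positive values are events or costs avoided by adopting the program.
    """

    treated: pd.Series
    events_avoided: pd.DataFrame  # year x complication
    cost_avoided: pd.DataFrame  # year x complication, ZAR
    monitoring_delta: pd.Series  # ZAR per year; negative when monitoring grows
    net_impact: pd.Series = field(init=False)

    def __post_init__(self) -> None:
        net = (self.cost_avoided.sum(axis=1) + self.monitoring_delta).rename(
            "net_impact_zar"
        )
        object.__setattr__(self, "net_impact", net)

    @property
    def complication_cost_avoided(self) -> pd.Series:
        return self.cost_avoided.sum(axis=1).rename("complication_cost_avoided_zar")

    @property
    def cumulative_net_impact(self) -> float:
        return float(self.net_impact.sum())

    @property
    def per_patient_year1(self) -> float:
        return per_patient_net_impact(self)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "treated_population": self.treated,
                "complication_cost_avoided_zar": self.complication_cost_avoided,
                "monitoring_delta_zar": self.monitoring_delta,
                "net_impact_zar": self.net_impact,
            }
        )


def scenario_costs(
    cohort: CohortProfile,
    config: ModelConfig,
    population: PopulationProjection | None = None,
    monitoring: MonitoringProfile | None = None,
    *,
    label: str | None = None,
) -> ScenarioResult:
    """Cost one scenario over the model horizon.

    ``population`` and ``monitoring`` default to the configuration's
    projection and to the monitoring profile whose label matches the cohort
    (falling back to a zero-cost profile if none matches).
    """
    population = population or config.population
    if len(population.years) != HORIZON_YEARS:
        raise ValueError(
            f"population projection must span {HORIZON_YEARS} years, "
            f"got {len(population.years)}"
        )
    if monitoring is None:
        monitoring = next(
            (m for m in config.monitoring.values() if m.label == cohort.label),
            MonitoringProfile(label=cohort.label, annual_cost_per_patient_zar=0.0),
        )
    rules = {rule.complication_class: rule for rule in config.risk_rules}
    treated = pd.Series(
        [population.treated(k) for k in _YEARS], index=_YEARS, name="treated_population"
    ).astype(float)
    events = pd.DataFrame(
        {
            comp.name: [
                year_incidence(comp, cohort, k, rules) * treated[k] for k in _YEARS
            ]
            for comp in config.complications
        },
        index=_YEARS,
    )
    unit_costs = pd.Series(
        {comp.name: comp.cost_2021_zar for comp in config.complications}
    )
    event_costs = events * unit_costs
    monitoring_cost = (
        monitoring.annual_cost_per_patient_zar * treated
    ).rename("monitoring_cost_zar")
    return ScenarioResult(
        label=label or cohort.label,
        treated=treated,
        events=events,
        event_costs=event_costs,
        monitoring_cost=monitoring_cost,
    )


def budget_impact(without: ScenarioResult, with_: ScenarioResult) -> BudgetImpactResult:
    """Net budget impact of the 'with' scenario relative to the 'without'."""
    if not without.treated.equals(with_.treated):
        raise ValueError("scenarios must share the same population projection")
    if list(without.events.columns) != list(with_.events.columns):
        raise ValueError("scenarios must cover the same complications")
    return BudgetImpactResult(
        treated=without.treated,
        events_avoided=without.events - with_.events,
        cost_avoided=without.event_costs - with_.event_costs,
        monitoring_delta=(without.monitoring_cost - with_.monitoring_cost).rename(
            "monitoring_delta_zar"
        ),
    )


def per_patient_net_impact(result: BudgetImpactResult) -> float:
    """Year-1 net budget impact divided by the year-1 treated population."""
    pop = float(result.treated.iloc[0])
    if pop <= 0:
        raise ValueError("year-1 treated population must be positive")
    return float(result.net_impact.iloc[0]) / pop


def market_share_scenario(
    result: BudgetImpactResult, shares: "list[float] | np.ndarray"
) -> BudgetImpactResult:
    """Scale each year's avoided events/costs by that year's program uptake.

    ``shares`` gives the fraction of the treated population enrolled in the
    program per model year (one entry per year, each in [0, 1]); the default
    published uptake path is 2% in year 1 growing by 1 point per year.
    """
    shares = np.asarray(shares, dtype=float)
    if shares.shape != (HORIZON_YEARS,):
        raise ValueError(f"need one share per model year ({HORIZON_YEARS}), got {shares.shape}")
    if np.any((shares < 0) | (shares > 1)):
        raise ValueError(f"market shares must lie in [0, 1], got {shares.tolist()}")
    scale = pd.Series(shares, index=result.treated.index)
    return BudgetImpactResult(
        treated=result.treated,
        events_avoided=result.events_avoided.mul(scale, axis=0),
        cost_avoided=result.cost_avoided.mul(scale, axis=0),
        monitoring_delta=result.monitoring_delta * scale,
    )


DEFAULT_UPTAKE_SHARES = [0.02, 0.03, 0.04, 0.05, 0.06]


def run_budget_model(
    config: ModelConfig,
) -> tuple[ScenarioResult, ScenarioResult, BudgetImpactResult]:
    """Cost both configured scenarios and their difference."""
    without = scenario_costs(
        config.cohorts["standard_of_care"],
        config,
        monitoring=config.monitoring["standard_of_care"],
        label="standard_of_care",
    )
    with_ = scenario_costs(
        config.cohorts["mydiacare"],
        config,
        monitoring=config.monitoring["mydiacare"],
        label="mydiacare",
    )
    return without, with_, budget_impact(without, with_)
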