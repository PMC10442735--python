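"""One-way deterministic sensitivity analysis and named alternative scenarios.

The tornado analysis perturbs one model input at a time by a multiplicative
variance (the published analysis used +/-10%), rebuilds the full budget model
at the low and high values with everything else held at base, and records
the year-1 net budget impact per treated patient.  Items are returned in
tornado order: descending output range.

HbA1c levels are varied multiplicatively like every other parameter, i.e.
+/-10% of the level itself, since the published analysis applied a uniform
10% variance to all inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import pandas as pd

from .budget_engine import BudgetImpactResult, run_budget_model
from .parameters import ModelConfig

__all__ = [
    "SensitivityItem",
    "dsa_parameter_names",
    "one_way_dsa",
    "tornado_table",
    "equal_baseline_scenario",
]


@dataclass(frozen=True)
class SensitivityItem:
    parameter: str
    base_value: float
    low_value: float
    high_value: float
    output_low: float  # per-patient year-1 net impact at the low input, ZAR
    output_high: float  # ... at the high input, ZAR

    @property
    def output_range(self) -> float:
        return abs(self.output_high - self.output_low)


def _setters(config: ModelConfig) -> dict[str, Callable[[ModelConfig, float], ModelConfig]]:
    """Registry of perturbable scalar inputs, keyed by dotted name.

    Each setter returns a new configuration with one value replaced; the
    pydantic models are frozen, so perturbation goes through a dump/validate
    round trip.
    """

    def set_path(cfg: ModelConfig, path: list, value: float) -> ModelConfig:
        data = cfg.model_dump()
        node = data
        for key in path[:-1]:
            node = node[key]
        node[path[-1]] = value
        return ModelConfig.model_validate(data)

    registry: dict[str, Callable[[ModelConfig, float], ModelConfig]] = {}

    for i, comp in enumerate(config.complications):
        registry[f"cost_2021.{comp.name}"] = (
            lambda cfg, v, i=i: set_path(cfg, ["complications", i, "cost_2021_zar"], v)
        )
        registry[f"incidence.{comp.name}"] = (
            lambda cfg, v, i=i: set_path(cfg, ["complications", i, "baseline_incidence"], v)
        )
    for key in config.cohorts:
        registry[f"hba1c.{key}.baseline"] = (
            lambda cfg, v, key=key: set_path(cfg, ["cohorts", key, "hba1c_baseline"], v)
        )
        registry[f"hba1c.{key}.6mo"] = (
            lambda cfg, v, key=key: set_path(cfg, ["cohorts", key, "hba1c_6mo"], v)
        )
    registry["population.year1.prevalence"] = lambda cfg, v: set_path(
        cfg, ["population", "years", 0, "prevalence"], int(round(v))
    )
    for key in config.monitoring:
        registry[f"monitoring.{key}"] = (
            lambda cfg, v, key=key: set_path(
                cfg, ["monitoring", key, "annual_cost_per_patient_zar"], v
            )
        )
    return registry


def _current_value(config: ModelConfig, name: str) -> float:
    parts = name.split(".")
    if parts[0] == "cost_2021":
        return config.complication(parts[1]).cost_2021_zar
    if parts[0] == "incidence":
        return config.complication(parts[1]).baseline_incidence
    if parts[0] == "hba1c":
        cohort = config.cohorts[parts[1]]
        return cohort.hba1c_baseline if parts[2] == "baseline" else cohort.hba1c_6mo
    if parts[0] == "population":
        return float(config.population.years[0].prevalence)
    if parts[0] == "monitoring":
        return config.monitoring[parts[1]].annual_cost_per_patient_zar
    raise KeyError(name)


def dsa_parameter_names(config: ModelConfig) -> list[str]:
    """Dotted names of all inputs the tornado analysis varies by default."""
    return list(_setters(config))


def one_way_dsa(
    config: ModelConfig,
    parameters: Sequence[str] | None = None,
    variance: float = 0.10,
) -> list[SensitivityItem]:
    """One-way deterministic sensitivity of the per-patient net impact.

    Parameters
    ----------
    config
        Base configuration; never mutated.
    parameters
        Dotted input names (see :func:`dsa_parameter_names`); defaults to the
        full registry: the seven unit costs and baseline incidences, the four
        cohort HbA1c levels, year-1 prevalence and the two monitoring costs.
    variance
        Multiplicative half-width; each input is evaluated at
        ``value * (1 - variance)`` and ``value * (1 + variance)``.

    Returns
    -------
    list of :class:`SensitivityItem` sorted by descending output range.
    """
    if variance < 0:
        raise ValueError(f"variance must be non-negative, got {variance}")
    registry = _setters(config)
    names = list(parameters) if parameters is not None else list(registry)
    unknown = [n for n in names if n not in registry]
    if unknown:
        raise KeyError(
            f"unknown DSA parameter(s) {unknown}; valid names: {sorted(registry)}"
        )
    items = []
    for name in names:
        base = _current_value(config, name)
        outputs = []
        for factor in (1 - variance, 1 + variance):
            perturbed = registry[name](config, base * factor)
            _, _, impact = run_budget_model(perturbed)
            outputs.append(impact.per_patient_year1)
        items.append(
            SensitivityItem(
                parameter=name,
                base_value=base,
                low_value=base * (1 - variance),
                high_value=base * (1 + variance),
                output_low=outputs[0],
                output_high=outputs[1],
            )
        )
    items.sort(key=lambda it: (-it.output_range, it.parameter))
    return items


def tornado_table(items: Sequence[SensitivityItem]) -> pd.DataFrame:
    """Tornado items as a frame (one row per parameter, tornado order)."""
    return pd.DataFrame(
        [
            {
                "parameter": it.parameter,
                "base_value": it.base_value,
                "low_value": it.low_value,
                "high_value": it.high_value,
                "output_low_zar_per_patient": it.output_low,
                "output_high_zar_per_patient": it.output_high,
                "output_range_zar_per_patient": it.output_range,
            }
            for it in items
        ]
    )


def equal_baseline_scenario(config: ModelConfig) -> BudgetImpactResult:
    """Alternative scenario with both cohorts starting from HbA1c 7.8%.

    The standard-of-care cohort is held flat at 7.8% (no 6-month change);
    the program cohort improves from 7.8% to 7.2%.  This isolates the
    program effect from the baseline difference between the source cohorts.
    """
    data = config.model_dump()
    data["cohorts"]["standard_of_care"]["hba1c_baseline"] = 7.8
    data["cohorts"]["standard_of_care"]["hba1c_6mo"] = 7.8
    data["cohorts"]["mydiacare"]["hba1c_baseline"] = 7.8
    data["cohorts"]["mydiacare"]["hba1c_6mo"] = 7.2
    _, _, impact = run_budget_model(ModelConfig.model_validate(data))
    return impact
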