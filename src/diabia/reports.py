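"""Full-pipeline orchestration: runs every stage, writes CSV tables, a JSON
headline summary and a run manifest."""

from __future__ import annotations

import datetime as dt
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .budget_engine import DEFAULT_UPTAKE_SHARES, market_share_scenario, run_budget_model
from .clinical import cohort_summary
from .cohort import CohortSpec, generate, write_cohort
from .parameters import ModelConfig, load_model_config, parameter_audit, save_model_config
from .risk_model import incidence_table
from .sensitivity import equal_baseline_scenario, one_way_dsa, tornado_table

__all__ = ["RunManifest", "run_full_analysis"]

logger = logging.getLogger("diabia")


@dataclass
class RunManifest:
    timestamp: str
    config_hash: str
    seed: int | None
    version: str
    files: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2)


def _config_hash(config: ModelConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            logger.info("stage %s", name)
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise RuntimeError(f"stage '{name}' failed: {exc}") from exc

        return inner

    return wrap


def headline_summary(config: ModelConfig, variance: float = 0.10) -> dict:
    """Headline model quantities as a JSON-ready dict.

    All monetary values in ZAR; totals are exact sums of their parts.
    """
    without, with_, impact = run_budget_model(config)
    equal = equal_baseline_scenario(config)
    uptake = market_share_scenario(impact, DEFAULT_UPTAKE_SHARES)
    y1 = impact.treated.index[0]
    return {
        "year1_treated_population": float(impact.treated.loc[y1]),
        "scenarios": {
            name: {
                "year1_complication_cost_zar": float(res.complication_cost.loc[y1]),
                "year1_monitoring_cost_zar": float(res.monitoring_cost.loc[y1]),
                "year1_total_cost_zar": float(res.total_cost.loc[y1]),
            }
            for name, res in (("without_program", without), ("with_program", with_))
        },
        "base_case": {
            "year1_complication_cost_avoided_zar": float(impact.complication_cost_avoided.loc[y1]),
            "year1_monitoring_delta_zar": float(impact.monitoring_delta.loc[y1]),
            "year1_net_impact_zar": float(impact.net_impact.loc[y1]),
            "cumulative_net_impact_zar": impact.cumulative_net_impact,
            "year1_net_impact_per_patient_zar": impact.per_patient_year1,
            "year1_nephropathy_cost_avoided_zar": float(impact.cost_avoided.loc[y1, "nephropathy"]),
        },
        "equal_baseline_scenario": {
            "year1_net_impact_zar": float(equal.net_impact.iloc[0]),
            "year1_net_impact_per_patient_zar": equal.per_patient_year1,
        },
        "market_share_scenario": {
            "shares": DEFAULT_UPTAKE_SHARES,
            "year1_net_impact_zar": float(uptake.net_impact.iloc[0]),
            "cumulative_net_impact_zar": uptake.cumulative_net_impact,
        },
        "dsa_variance": variance,
    }


def run_full_analysis(
    config_path: str | Path | None,
    out_dir: str | Path,
    seed: int | None = None,
    variance: float = 0.10,
    cohort_spec: CohortSpec | None = None,
) -> RunManifest:
    """Execute every stage of the analysis and write all outputs.

    Runs the budget engine for both scenarios, the tornado sensitivity
    analysis, the named alternative scenarios and — when ``seed`` is given
    (or a cohort spec is passed) — synthetic cohort generation followed by
    the clinical pipeline.  Writes per-stage CSVs, ``summary.json`` with the
    headline quantities, and ``manifest.json`` listing every emitted file.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    config = load_model_config(config_path)
    manifest = RunManifest(
        timestamp=dt.datetime.now().isoformat(timespec="seconds"),
        config_hash=_config_hash(config),
        seed=seed,
        version=__version__,
    )

    def emit(name: str, obj) -> Path:
        path = out_dir / name
        if isinstance(obj, pd.DataFrame):
            obj.to_csv(path, index=not isinstance(obj.index, pd.RangeIndex) or obj.index.name is not None)
        else:
            path.write_text(obj)
        manifest.files.append(name)
        return path

    @_stage("budget_engine")
    def _budget():
        without, with_, impact = run_budget_model(config)
        emit("incidence_table.csv", incidence_table(config))
        emit("scenario_without.csv", without.summary())
        emit("scenario_with.csv", with_.summary())
        emit("events_avoided.csv", impact.events_avoided)
        emit("cost_avoided.csv", impact.cost_avoided)
        emit("budget_impact.csv", impact.summary())
        return impact

    @_stage("sensitivity")
    def _sensitivity():
        emit("tornado.csv", tornado_table(one_way_dsa(config, variance=variance)))
        equal = equal_baseline_scenario(config)
        emit("equal_baseline_scenario.csv", equal.summary())

    @_stage("market_share")
    def _market(impact):
        uptake = market_share_scenario(impact, DEFAULT_UPTAKE_SHARES)
        emit("market_share_scenario.csv", uptake.summary())

    @_stage("synthetic_cohort")
    def _cohort() -> None:
        spec = cohort_spec or CohortSpec(seed=seed if seed is not None else 0)
        records = generate(spec)
        paths = write_cohort(records, out_dir)
        manifest.files.extend(p.name for p in paths.values())
        summary = cohort_summary(records)
        bands = summary.pop("bands")
        emit("hba1c_bands.csv", bands)
        emit("clinical_summary.json", json.dumps(summary, indent=2, default=float))

    impact = _budget()
    _sensitivity()
    _market(impact)
    if seed is not None or cohort_spec is not None:
        _cohort()

    emit("parameter_audit.csv", parameter_audit(config))
    save_model_config(config, out_dir / "resolved_config.json")
    manifest.files.append("resolved_config.json")
    emit("summary.json", json.dumps(headline_summary(config, variance=variance), indent=2))
    (out_dir / "manifest.json").write_text(manifest.to_json())
    manifest.files.append("manifest.json")
    return manifest
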