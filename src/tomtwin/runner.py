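"""End-to-end season runs: configuration, orchestration, reports, manifests.

``run_season`` composes weather -> schedule expansion -> climate/crop
co-simulation -> quality/economics over the fixed season calendar
(planting 16 Dec 2019, last harvest 29 May 2020). Runs are deterministic
given the config; every run can write a manifest (config hash, seeds,
version) sufficient to reproduce outputs exactly.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import pandas as pd

from . import __version__
from .climate_twin import ClimateSeries, GreenhouseParams, ResourceLedger, simulate_climate
from .crop_twin import CropModel, CropParams, HarvestRecord
from .quality_economics import (
    EconomicResult,
    PriceModel,
    QualityParams,
    harvests_dataframe,
    score_season,
)
from .strategy import CropPlan, SetpointSchedule, load_strategy, make_preset, validate
from .synthetic_weather import WeatherSeries, generate_weather

__all__ = ["RunConfig", "SeasonResult", "run_season", "compare_presets"]

log = logging.getLogger("tomtwin")


@dataclass
class RunConfig:
    """Configuration of one season run."""

    preset: int | None = 306
    strategy_path: str | None = None      # custom strategy file (overrides preset)
    weather_seed: int = 1
    quality_seed: int = 1
    cloud_persistence: float = 0.85
    latitude: float = 52.0
    output_dir: str | None = None
    verbosity: int = 0
    greenhouse_overrides: dict = field(default_factory=dict)
    crop_overrides: dict = field(default_factory=dict)
    quality_overrides: dict = field(default_factory=dict)
    price_overrides: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "preset": self.preset,
            "strategy_path": self.strategy_path,
            "weather_seed": self.weather_seed,
            "quality_seed": self.quality_seed,
            "cloud_persistence": self.cloud_persistence,
            "latitude": self.latitude,
            "greenhouse_overrides": self.greenhouse_overrides,
            "crop_overrides": self.crop_overrides,
            "quality_overrides": self.quality_overrides,
            "price_overrides": self.price_overrides,
        }

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class SeasonResult:
    config: RunConfig
    weather: WeatherSeries
    climate: ClimateSeries
    ledger: ResourceLedger
    crop: CropModel
    harvests: list[HarvestRecord]
    economics: EconomicResult
    schedule: SetpointSchedule
    plan: CropPlan

    @property
    def total_yield_kg(self) -> float:
        return self.economics.total_yield_kg

    def manifest(self) -> dict:
        return {
            "tomtwin_version": __version__,
            "config": self.config.to_dict(),
            "config_hash": self.config.digest(),
            "seeds": {"weather": self.config.weather_seed,
                      "quality": self.config.quality_seed},
            "net_profit": self.economics.net_profit,
            "income": self.economics.income,
            "yield_kg": self.total_yield_kg,
        }

    def write_outputs(self, outdir) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        self.weather.to_csv(out / "weather.csv")
        self.climate.daily().to_csv(out / "climate_daily.csv")
        self.ledger.to_csv(out / "resources.csv")
        self.crop.daily_dataframe().to_csv(out / "crop_daily.csv", index=False)
        harvests_dataframe(self.harvests).to_csv(out / "harvests.csv", index=False)
        pd.DataFrame([self.economics.to_row()]).to_csv(out / "economics.csv", index=False)
        with open(out / "manifest.json", "w") as fh:
            json.dump(self.manifest(), fh, indent=2, default=str)


def _strategy_for(config: RunConfig) -> tuple[SetpointSchedule, CropPlan]:
    if config.strategy_path is not None:
        return load_strategy(config.strategy_path)
    if config.preset is None:
        raise ValueError("config needs either a preset id or a strategy path")
    return make_preset(config.preset)


def run_season(
    config: RunConfig,
    schedule: SetpointSchedule | None = None,
    plan: CropPlan | None = None,
    weather: WeatherSeries | None = None,
) -> SeasonResult:
    """Run the full pipeline for one season.

    ``schedule``/``plan``/``weather`` may be passed explicitly (e.g. a
    perturbed schedule for a sensitivity run); otherwise they come from
    the config's preset/strategy and weather seed. Raises ``ValueError``
    with a validation report for invalid strategies.
    """
    if schedule is None or plan is None:
        schedule, plan = _strategy_for(config)
    violations = validate(schedule, plan)
    if violations:
        report = "\n".join(str(v) for v in violations)
        raise ValueError(f"invalid strategy:\n{report}")

    if weather is None:
        weather = generate_weather(
            start_date=schedule.start, end_date=schedule.end,
            latitude=config.latitude, seed=config.weather_seed,
            cloud_persistence=config.cloud_persistence)

    gh = GreenhouseParams(**config.greenhouse_overrides)
    cp = CropParams(**config.crop_overrides)
    crop = CropModel(plan, cp)

    milestones = {"first_truss": False, "first_harvest": False, "topped": False}

    def day_cb(day_index, _slice, _out):
        from datetime import timedelta
        day = schedule.start + timedelta(days=day_index)
        records = crop.on_day_end(day)
        if not milestones["first_truss"] and crop.state.trusses:
            milestones["first_truss"] = True
            log.info("first truss initiated on %s", day)
        if not milestones["first_harvest"] and records:
            milestones["first_harvest"] = True
            log.info("first harvest on %s", day)
        if not milestones["topped"] and crop.state.topped:
            milestones["topped"] = True
            log.info("crop topped on %s", day)

    climate, ledger = simulate_climate(
        weather, schedule, gh,
        crop_feedback=crop.feedback,
        day_callback=day_cb,
        drain_fraction_target=plan.drain_fraction_target,
        supply_ec=plan.supply_ec,
    )
    log.info("final harvest complete; %d harvest events, %.2f kg/m2",
             len(crop.harvests), crop.state.cum_yield_kg)

    economics = score_season(
        crop.harvests, ledger, plan, schedule.start,
        price_model=PriceModel(**config.price_overrides),
        quality=QualityParams(**config.quality_overrides),
        seed=config.quality_seed,
    )
    result = SeasonResult(
        config=config, weather=weather, climate=climate, ledger=ledger,
        crop=crop, harvests=crop.harvests, economics=economics,
        schedule=schedule, plan=plan,
    )
    if config.output_dir:
        result.write_outputs(config.output_dir)
    return result


def compare_presets(results: list[SeasonResult]) -> pd.DataFrame:
    """Ranking table (sorted by net profit) for two or more season runs."""
    if len(results) < 2:
        raise ValueError("compare_presets needs at least 2 runs")
    rows = []
    for r in results:
        row = {"preset": r.config.preset}
        row.update(r.economics.to_row())
        rows.append(row)
    df = pd.DataFrame(rows).sort_values("net_profit", ascending=False).reset_index(drop=True)
    return df
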