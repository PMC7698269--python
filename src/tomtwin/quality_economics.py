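"""Fruit quality, Brix-dependent seasonal pricing, costs, profit and RUE.

Brix is centred on 8.7 deg for the reference strategy and is deliberately
NOT a function of drain EC (no such effect exists for this cultivar); a
monotone saturating surrogate maps Brix to a 0-100 flavour score. Pricing
is a weekly base (declining winter -> summer) plus a Brix premium, with a
floor. Costs use the published tariffs: electricity 0.08/0.04 EUR/kWh
(on-peak 07:00-23:00 / off-peak), heat 0.03 EUR/kWh, CO2 tiered
0.08 EUR/kg up to 12 kg/m2 then 0.20, labour 0.0085 EUR/stem/m2/day,
plants 2.00 EUR (1-stem) / 2.20 EUR (2-stem). Water/nutrient prices
default to 0 (not published) with config override.

Water-use efficiency uses net crop uptake (supply minus re-used drain):
gross-supply magnitudes are inconsistent with the ~25 L/kg scale this
reproduces.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .climate_twin import ResourceLedger
from .crop_twin import HarvestRecord
from .strategy import CropPlan

__all__ = [
    "QualityParams",
    "PriceModel",
    "EconomicResult",
    "assign_brix",
    "flavor_surrogate",
    "price_of",
    "compute_costs",
    "compute_income",
    "resource_use_efficiency",
    "score_season",
]

ELECTRICITY_PEAK_PRICE = 0.08   # EUR/kWh, 07:00-23:00
ELECTRICITY_OFFPEAK_PRICE = 0.04
HEAT_PRICE = 0.03               # EUR/kWh
CO2_PRICE_LOW = 0.08            # EUR/kg up to the tier break
CO2_PRICE_HIGH = 0.20           # EUR/kg above
CO2_TIER_BREAK = 12.0           # kg/m2
LABOR_PRICE = 0.0085            # EUR/stem/m2/day
PLANT_PRICE_1STEM = 2.00        # EUR/plant
PLANT_PRICE_2STEM = 2.20


@dataclass
class QualityParams:
    brix_base: float = 8.7
    brix_noise_sd: float = 0.3
    dm_reference: float = 0.090
    dm_brix_coeff: float = 30.0     # deg Brix per unit dry-matter-fraction deviation
    dm_noise_sd: float = 0.0015     # spread of per-harvest dry-matter fraction


@dataclass
class PriceModel:
    """Weekly base price (declining to summer) + Brix premium, floored."""

    base_week0: float = 3.60        # EUR/kg in the planting week (mid December)
    weekly_decline: float = 0.070   # EUR/kg per week
    brix_premium: float = 0.12      # EUR/kg per deg Brix above the reference
    brix_reference: float = 8.0
    floor: float = 1.20             # EUR/kg

    def base(self, week: int) -> float:
        if week < 0:
            raise ValueError("week precedes the season")
        return max(self.floor, self.base_week0 - self.weekly_decline * week)


def price_of(brix: float, week: int, model: PriceModel | None = None) -> float:
    """Price (EUR/kg) for fruit of a given Brix in a given season week."""
    m = model or PriceModel()
    return max(m.floor, m.base(week) + m.brix_premium * (brix - m.brix_reference))


def assign_brix(
    harvest: HarvestRecord,
    quality: QualityParams,
    rng: np.random.Generator,
    strategy_modifier: float = 0.0,
) -> tuple[float, float]:
    """Assign (brix, dm_fraction) to a harvest record (mutates it).

    Brix = base + dry-matter deviation term + strategy modifier + seeded
    noise. Drain EC is intentionally not an input: no EC->Brix effect
    exists for this cultivar.
    """
    dm = harvest.dm_fraction + rng.normal(0.0, quality.dm_noise_sd)
    brix = (
        quality.brix_base
        + quality.dm_brix_coeff * (dm - quality.dm_reference)
        + strategy_modifier
        + rng.normal(0.0, quality.brix_noise_sd)
    )
    harvest.brix = brix
    harvest.dm_fraction = dm
    return brix, dm


def flavor_surrogate(brix: float) -> float:
    """Monotone saturating Brix -> flavour score (0-100).

    A documented surrogate for the proprietary flavour model, which needs
    laboratory inputs that are out of scope. Inputs outside [4, 14] Brix
    are clamped with a warning.
    """
    if brix < 4.0 or brix > 14.0:
        warnings.warn(f"Brix {brix} outside [4, 14]; clamping", stacklevel=2)
        brix = min(max(brix, 4.0), 14.0)
    return 100.0 / (1.0 + math.exp(-0.9 * (brix - 8.2)))


@dataclass
class EconomicResult:
    income: float                   # EUR/m2
    costs: dict = field(default_factory=dict)
    net_profit: float = 0.0
    rue: dict = field(default_factory=dict)
    total_yield_kg: float = 0.0
    mean_brix: float = 0.0

    @property
    def total_costs(self) -> float:
        return sum(self.costs.values())

    def to_row(self) -> dict:
        row = {"income": self.income, "net_profit": self.net_profit,
               "total_costs": self.total_costs, "yield_kg": self.total_yield_kg,
               "mean_brix": self.mean_brix}
        row.update({f"cost_{k}": v for k, v in self.costs.items()})
        row.update({f"rue_{k}": v for k, v in self.rue.items()})
        return row


def compute_costs(
    ledger_totals: dict,
    plan: CropPlan,
    stem_days_integral: float | None = None,
    water_price_per_m3: float = 0.0,
    nutrient_price_per_kg: float = 0.0,
) -> dict:
    """Cost breakdown (EUR/m2) at the published tariffs."""
    for key in ("heat_mj", "electricity_peak_kwh", "electricity_offpeak_kwh", "co2_dosed_kg"):
        if ledger_totals[key] < 0.0:
            raise ValueError(f"negative ledger entry {key}")
    stems = plan.initial_stem_density
    per_plant = PLANT_PRICE_2STEM if plan.plants_are_two_stem else PLANT_PRICE_1STEM
    stems_per_plant = 2.0 if plan.plants_are_two_stem else 1.0
    plants = stems / stems_per_plant * per_plant

    co2 = ledger_totals["co2_dosed_kg"]
    co2_cost = CO2_PRICE_LOW * min(co2, CO2_TIER_BREAK) + CO2_PRICE_HIGH * max(0.0, co2 - CO2_TIER_BREAK)

    if stem_days_integral is None:
        stem_days_integral = plan.stem_days_integral()
    water_m3 = ledger_totals.get("water_supplied_l", 0.0) / 1000.0
    nutrients_kg = water_m3 * ledger_totals.get("supply_ec", 0.0)  # 1 EC ~ 1 kg salts/m3
    return {
        "plants": plants,
        "electricity_peak": ledger_totals["electricity_peak_kwh"] * ELECTRICITY_PEAK_PRICE,
        "electricity_offpeak": ledger_totals["electricity_offpeak_kwh"] * ELECTRICITY_OFFPEAK_PRICE,
        "heat": ledger_totals["heat_mj"] / 3.6 * HEAT_PRICE,
        "co2": co2_cost,
        "labor": LABOR_PRICE * stem_days_integral,
        "water_nutrients": water_m3 * water_price_per_m3 + nutrients_kg * nutrient_price_per_kg,
    }


def compute_income(
    harvests: list[HarvestRecord],
    season_start,
    model: PriceModel | None = None,
) -> float:
    """Sum of fresh weight x price(brix, week) over all harvests (EUR/m2)."""
    m = model or PriceModel()
    total = 0.0
    for h in harvests:
        week = (h.date - season_start).days // 7
        brix = h.brix if h.brix is not None else m.brix_reference
        total += h.fresh_weight * price_of(brix, week, m)
    return total


def resource_use_efficiency(ledger_totals: dict, total_yield_kg: float) -> dict:
    """Resource use per kg tomato; water uses net crop uptake."""
    if total_yield_kg <= 0.0:
        raise ValueError("resource use efficiency undefined at zero yield")
    water_per_kg = ledger_totals["water_uptake_l"] / total_yield_kg
    return {
        "heat_mj_per_kg": ledger_totals["heat_mj"] / total_yield_kg,
        "electricity_kwh_per_kg": (
            ledger_totals["electricity_peak_kwh"] + ledger_totals["electricity_offpeak_kwh"]
        ) / total_yield_kg,
        "co2_kg_per_kg": ledger_totals["co2_dosed_kg"] / total_yield_kg,
        "water_l_per_kg": water_per_kg,
        "nutrients_g_per_kg": water_per_kg * ledger_totals.get("supply_ec", 0.0),
    }


def score_season(
    harvests: list[HarvestRecord],
    ledger: ResourceLedger | dict,
    plan: CropPlan,
    season_start,
    price_model: PriceModel | None = None,
    quality: QualityParams | None = None,
    seed: int = 0,
) -> EconomicResult:
    """Full techno-economic scoring of a simulated season.

    Assigns Brix to every harvest (seeded), prices them, computes the
    cost breakdown and resource-use efficiencies, and returns the result
    with net_profit = income - sum(costs) exactly.
    """
    totals = ledger.totals() if isinstance(ledger, ResourceLedger) else dict(ledger)
    q = quality or QualityParams()
    rng = np.random.default_rng(seed)
    for h in harvests:
        if h.brix is None:
            assign_brix(h, q, rng, strategy_modifier=plan.brix_modifier)
    income = compute_income(harvests, season_start, price_model)
    costs = compute_costs(totals, plan)
    total_yield = sum(h.fresh_weight for h in harvests)
    rue = resource_use_efficiency(totals, total_yield) if total_yield > 0 else {}
    masses = np.array([h.fresh_weight for h in harvests]) if harvests else np.array([])
    brixes = np.array([h.brix for h in harvests]) if harvests else np.array([])
    mean_brix = float(np.average(brixes, weights=masses)) if masses.sum() > 0 else float("nan")
    return EconomicResult(
        income=income,
        costs=costs,
        net_profit=income - sum(costs.values()),
        rue=rue,
        total_yield_kg=total_yield,
        mean_brix=mean_brix,
    )


def harvests_dataframe(harvests: list[HarvestRecord]) -> pd.DataFrame:
    return pd.DataFrame([h.__dict__ for h in harvests])
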