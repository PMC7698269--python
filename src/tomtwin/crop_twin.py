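"""Source-sink cherry-tomato crop model with per-truss bookkeeping.

Hourly canopy photosynthesis (Beer-law interception, rectangular-hyperbola
light response with CO2-dependent asymptote) feeds a daily carbohydrate
balance: maintenance respiration scaled by Q10, then partitioning between
the vegetative pool and per-truss fruit pools proportional to their
potential growth rates (sink strengths). Growth is sink-limited whenever
potential sinks cannot absorb the day's assimilate (juvenile phase,
post-topping); the surplus is discarded, not buffered.

Truss initiation is linear in diurnal-average temperature through two
anchors (1.1 trusses/week at 19 degC, 1.47 at 24 degC); each truss
accumulates physiological age as a temperature sum above a base and is
harvested as a unit once ripe. Fruit pruning trims each new truss to the
plan target, hard-capped at 16 (single) / 20 (split) fruits.

Known bias: ripening does not accelerate after topping, so the final
late-season yield boost seen in real crops is under-predicted. This is
left as-is deliberately.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd

from .strategy import FRUIT_CAP, CropPlan

__all__ = [
    "CropParams",
    "CropState",
    "TrussCohort",
    "StemCohort",
    "HarvestRecord",
    "truss_initiation_rate",
    "fit_juvenile_delay",
    "predict_trusses_per_stem",
    "canopy_photosynthesis",
    "daily_carbon_update",
    "develop_and_harvest",
    "apply_crop_actions",
    "transpiration_and_co2_uptake",
    "CropModel",
    "TRUSS_RATE_ANCHORS",
]

#: (temperature degC, trusses/stem/week) anchors of the linear truss rate.
TRUSS_RATE_ANCHORS = ((19.0, 1.1), (24.0, 1.47))

#: Slope implied by the anchors: 0.074 trusses/week/degC.
TRUSS_RATE_SLOPE = (TRUSS_RATE_ANCHORS[1][1] - TRUSS_RATE_ANCHORS[0][1]) / (
    TRUSS_RATE_ANCHORS[1][0] - TRUSS_RATE_ANCHORS[0][0]
)


@dataclass
class CropParams:
    """Crop-model coefficients (defaults calibrated at desk scale)."""

    t_base: float = 4.0                 # degC base for temperature sums
    ripening_cd: float = 935.0          # degC*d to ripeness (~55 d at 21 degC)
    juvenile_delay_cd: float = 89.2     # degC*d before a new stem initiates its
                                        # first truss (~0.73 weeks at 21.34 degC)
    dm_fraction: float = 0.090          # fruit dry-matter fraction
    fruit_potential_dm: float = 1.60    # g DM potential final mass per fruit
    k_extinction: float = 0.70          # Beer-law canopy extinction
    lai_max: float = 3.5                # leaf pruning folded into an LAI ceiling
    sla_effective: float = 0.012        # m2 leaf per g vegetative DM
    alpha: float = 9.3e-3               # g CH2O/m2/h per umol/m2/s absorbed PAR
    pmax_ref: float = 10.2              # g CH2O/m2/h asymptote at saturating CO2
    co2_km: float = 300.0               # ppm half-saturation of the asymptote
    conv_efficiency: float = 0.72       # g DM per g CH2O for growth
    rm_veg: float = 0.013               # maintenance g CH2O/g DM/d at 20 degC
    rm_fruit: float = 0.008
    q10: float = 1.6
    veg_sink_per_stem: float = 1.5      # g DM/stem/d potential vegetative growth
    juvenile_rgr_max: float = 0.10      # 1/d relative growth ceiling of a young
                                        # (sink-limited) crop
    closed_canopy_veg_factor: float = 0.30  # vegetative sink damping once the
                                            # LAI ceiling is reached (leaf pruning)
    initial_veg_dm: float = 10.0        # g DM/m2 at transplant
    transp_par_coeff: float = 0.55      # g H2O/m2/h per umol/m2/s absorbed PAR
    transp_vpd_coeff: float = 9.0       # g H2O/m2/h per g/m3 humidity deficit
    dark_transp_factor: float = 0.25    # night share of the VPD term


def truss_initiation_rate(t_avg: float, clamp_range=(15.0, 30.0)) -> float:
    """Truss initiation rate (trusses/stem/week), linear in diurnal mean T.

    Passes exactly through the two anchors (19 degC, 1.1) and
    (24 degC, 1.47); inputs outside ``clamp_range`` are clamped with a
    warning.
    """
    lo, hi = clamp_range
    if t_avg < lo or t_avg > hi:
        warnings.warn(f"truss rate evaluated outside [{lo}, {hi}] degC; clamping", stacklevel=2)
        t_avg = min(max(t_avg, lo), hi)
    return TRUSS_RATE_ANCHORS[0][1] + TRUSS_RATE_SLOPE * (t_avg - TRUSS_RATE_ANCHORS[0][0])


def fit_juvenile_delay(
    trusses_per_stem: float,
    t_avg: float,
    planting_date: date,
    topping_date: date,
) -> float:
    """Fit the juvenile delay (weeks) from one observed season row.

    Solves trusses/stem = rate(t_avg) x (weeks planting->topping - delay)
    for the delay.
    """
    weeks = (topping_date - planting_date).days / 7.0
    return weeks - trusses_per_stem / truss_initiation_rate(t_avg)


def predict_trusses_per_stem(
    t_avg: float,
    planting_date: date,
    topping_date: date,
    juvenile_delay_weeks: float,
) -> float:
    """Closed-form trusses/stem at a constant diurnal-average temperature."""
    weeks = (topping_date - planting_date).days / 7.0
    return truss_initiation_rate(t_avg) * (weeks - juvenile_delay_weeks)


def _temp_factor(temp_c: float) -> float:
    # near-flat (+/-5%) over the moderate 18-24 degC range with a mild
    # positive tilt, declining more steeply outside
    if 18.0 <= temp_c <= 24.0:
        tilt = 0.017 * (temp_c - 21.0)
        return 1.0 + min(max(tilt, -0.048), 0.048)
    if temp_c < 18.0:
        return max(0.4, 0.952 - 0.04 * (18.0 - temp_c))
    return max(0.4, 1.048 - 0.02 * (temp_c - 24.0))


def canopy_photosynthesis(
    par_in: float,
    co2_in: float,
    temp_in: float,
    lai: float,
    params: CropParams | None = None,
) -> float:
    """Gross canopy assimilation (g CH2O/m2/h).

    Beer-law interception over the LAI; rectangular hyperbola in absorbed
    PAR with a CO2-saturating asymptote; weak temperature dependence in
    the moderate range.
    """
    p = params or CropParams()
    if par_in <= 0.0 or lai <= 0.0:
        return 0.0
    i_abs = par_in * (1.0 - math.exp(-p.k_extinction * lai))
    pmax = p.pmax_ref * co2_in / (co2_in + p.co2_km)
    a = p.alpha * i_abs
    return _temp_factor(temp_in) * pmax * a / (a + pmax)


@dataclass
class TrussCohort:
    """Trusses initiated together: ``density`` trusses/m2 of one age."""

    init_date: date
    density: float                 # trusses/m2
    fruits_per_truss: int
    age_cd: float = 0.0            # physiological age, degC*d above base
    dm: float = 0.0                # g DM/m2 fruit mass on this cohort
    truss_type: str = "single"


@dataclass
class StemCohort:
    """Stems added together; new stems wait out a thermal juvenile delay."""

    density: float                 # stems/m2
    delay_cd_remaining: float
    truss_acc: float = 0.0         # continuous trusses initiated per stem


@dataclass
class HarvestRecord:
    date: date
    trusses_harvested: float       # trusses/m2
    fresh_weight: float            # kg/m2
    mean_fruit_weight: float       # g fresh per fruit
    fruit_growth_period: float     # days initiation -> harvest
    dm_fraction: float
    brix: float | None = None      # filled by the quality module


@dataclass
class CropState:
    """Whole-crop state with per-truss bookkeeping."""

    stem_cohorts: list[StemCohort] = field(default_factory=list)
    trusses: list[TrussCohort] = field(default_factory=list)
    veg_dm: float = 10.0           # g DM/m2 vegetative pool
    fruit_dm: float = 0.0          # g DM/m2 on-plant fruit pool
    carb_buffer: float = 0.0       # g CH2O/m2 (kept at zero: surplus is discarded)
    cum_trusses_harvested: float = 0.0
    cum_yield_kg: float = 0.0
    cum_fruits_initiated: float = 0.0
    topped: bool = False

    @property
    def stem_density(self) -> float:
        return sum(s.density for s in self.stem_cohorts)

    @property
    def plant_load(self) -> float:
        """Concurrently growing fruits per m2 (unharvested trusses)."""
        return sum(t.density * t.fruits_per_truss for t in self.trusses)

    @property
    def lai(self) -> float:
        """Leaf area index implied by the vegetative pool (default coefficients)."""
        p = CropParams()
        return min(p.lai_max, p.sla_effective * self.veg_dm)


def _lai_of(state: CropState, p: CropParams) -> float:
    return min(p.lai_max, p.sla_effective * state.veg_dm)


def _fruit_sink_of(truss: TrussCohort, p: CropParams) -> float:
    """Potential growth (g DM/m2/d) of one truss cohort (bell-shaped in age)."""
    x = min(truss.age_cd / p.ripening_cd, 1.0)
    shape = 6.0 * x * (1.0 - x)
    per_fruit = p.fruit_potential_dm / (p.ripening_cd / 17.0)  # ~g/fruit/d at 21 degC
    return truss.density * truss.fruits_per_truss * per_fruit * shape


def apply_crop_actions(state: CropState, plan: CropPlan, day: date, p: CropParams) -> CropState:
    """Apply dated stem-density changes and enforce fruit-pruning caps."""
    target = plan.stem_density_on(day)
    current = state.stem_density
    if target > current + 1e-9 and not state.topped:
        state.stem_cohorts.append(
            StemCohort(density=target - current, delay_cd_remaining=p.juvenile_delay_cd))
    elif target < current - 1e-9:
        # lower newest cohorts first; their initiated trusses remain
        deficit = current - target
        for cohort in reversed(state.stem_cohorts):
            take = min(cohort.density, deficit)
            cohort.density -= take
            deficit -= take
            if deficit <= 1e-12:
                break
    cap = FRUIT_CAP[plan.truss_type]
    for truss in state.trusses:
        if truss.fruits_per_truss > cap:
            truss.fruits_per_truss = cap
    return state


def daily_carbon_update(
    hourly_assimilation,
    hourly_temps,
    state: CropState,
    p: CropParams | None = None,
) -> dict:
    """One day of carbohydrate accounting; mutates ``state``.

    Returns the carbon ledger for the day (all in g CH2O/m2):
    ``assim - maintenance - growth_ch2o - discarded + pool_debit == 0``.
    """
    p = p or CropParams()
    assim = float(np.sum(hourly_assimilation))
    t_avg = float(np.mean(hourly_temps))
    q = p.q10 ** ((t_avg - 20.0) / 10.0)
    maint_veg = p.rm_veg * state.veg_dm * q
    maint_fruit = p.rm_fruit * state.fruit_dm * q
    maint = maint_veg + maint_fruit

    net = assim - maint
    pool_debit = 0.0
    growth_ch2o = 0.0
    discarded = 0.0
    veg_inc = fruit_inc = 0.0
    fruit_allocs: list[float] = [0.0] * len(state.trusses)

    if net < 0.0:
        # starvation: pools shrink by the uncovered respiration share
        deficit = -net
        share_veg = maint_veg / maint if maint > 0 else 0.5
        state.veg_dm = max(0.0, state.veg_dm - deficit * share_veg)
        state.fruit_dm = max(0.0, state.fruit_dm - deficit * (1.0 - share_veg))
        pool_debit = deficit
    else:
        growth_pot_dm = net * p.conv_efficiency
        fruit_sinks = [_fruit_sink_of(t, p) for t in state.trusses]
        fruit_sink = sum(fruit_sinks)
        veg_sink = p.veg_sink_per_stem * state.stem_density
        # young plants cannot process more assimilate than a relative-growth
        # ceiling; the juvenile crop is sink-limited
        veg_sink = min(veg_sink, p.juvenile_rgr_max * state.veg_dm)
        if _lai_of(state, p) >= p.lai_max - 1e-9:
            veg_sink *= p.closed_canopy_veg_factor
        total_sink = fruit_sink + veg_sink
        alloc_dm = min(growth_pot_dm, total_sink)
        discarded = (growth_pot_dm - alloc_dm) / p.conv_efficiency
        growth_ch2o = alloc_dm / p.conv_efficiency
        if total_sink > 0.0:
            fruit_inc = alloc_dm * fruit_sink / total_sink
            veg_inc = alloc_dm - fruit_inc
        if fruit_sink > 0.0 and fruit_inc > 0.0:
            fruit_allocs = [fruit_inc * s / fruit_sink for s in fruit_sinks]
            for truss, add in zip(state.trusses, fruit_allocs):
                truss.dm += add
        state.veg_dm += veg_inc
        state.fruit_dm += fruit_inc

    return {
        "assim": assim,
        "maintenance": maint,
        "growth_ch2o": growth_ch2o,
        "veg_increment_dm": veg_inc,
        "fruit_increment_dm": fruit_inc,
        "discarded": discarded,
        "pool_debit": pool_debit,
        "t_avg": t_avg,
    }


def develop_and_harvest(
    state: CropState,
    t_avg: float,
    day: date,
    plan: CropPlan,
    p: CropParams | None = None,
) -> list[HarvestRecord]:
    """Advance development one day; initiate and harvest trusses.

    Physiological age accumulates as the temperature sum above
    ``p.t_base``; a truss is harvested (whole) once its age reaches the
    ripening threshold. New trusses appear at the temperature-linear
    initiation rate per stem until the topping date.
    """
    p = p or CropParams()
    dd = max(0.0, t_avg - p.t_base)

    if day >= plan.topping_date:
        state.topped = True

    cap = FRUIT_CAP[plan.truss_type]
    fruits = min(plan.fruits_per_truss_target, cap)
    if not state.topped:
        rate_day = truss_initiation_rate(t_avg) / 7.0
        for stems in state.stem_cohorts:
            if stems.density <= 0.0:
                continue
            if stems.delay_cd_remaining > 0.0:
                stems.delay_cd_remaining -= dd
                continue
            before = stems.truss_acc
            stems.truss_acc += rate_day
            n_new = int(stems.truss_acc) - int(before)
            if n_new > 0:
                state.trusses.append(TrussCohort(
                    init_date=day, density=stems.density * n_new,
                    fruits_per_truss=fruits, truss_type=plan.truss_type))
                state.cum_fruits_initiated += stems.density * n_new * fruits

    records: list[HarvestRecord] = []
    if day <= plan.last_harvest_date:
        keep: list[TrussCohort] = []
        for truss in state.trusses:
            truss.age_cd += dd
            if truss.age_cd >= p.ripening_cd and truss.density > 0.0:
                fresh_kg = truss.dm / p.dm_fraction / 1000.0
                n_fruits = truss.density * truss.fruits_per_truss
                records.append(HarvestRecord(
                    date=day,
                    trusses_harvested=truss.density,
                    fresh_weight=fresh_kg,
                    mean_fruit_weight=(fresh_kg * 1000.0 / n_fruits) if n_fruits > 0 else 0.0,
                    fruit_growth_period=(day - truss.init_date).days,
                    dm_fraction=p.dm_fraction,
                ))
                state.fruit_dm = max(0.0, state.fruit_dm - truss.dm)
                state.cum_trusses_harvested += truss.density
                state.cum_yield_kg += fresh_kg
            else:
                keep.append(truss)
        state.trusses = keep
    return records


def transpiration_and_co2_uptake(
    lai: float,
    par_in: float,
    co2_in: float,
    temp_in: float,
    humidity_deficit: float,
    veg_dm: float,
    fruit_dm: float,
    p: CropParams | None = None,
) -> tuple[float, float, float]:
    """Slot-level crop fluxes: (g H2O/m2/h, g CO2/m2/h, g CH2O/m2/h gross).

    Transpiration is proportional to absorbed PAR plus a vapour-deficit
    term; CO2 uptake is gross assimilation in CO2 mass units minus a
    continuous maintenance-respiration release (so night uptake <= 0).
    """
    p = p or CropParams()
    assim = canopy_photosynthesis(par_in, co2_in, temp_in, lai, p)
    i_abs = max(par_in, 0.0) * (1.0 - math.exp(-p.k_extinction * lai))
    size = min(1.0, lai / 2.0)
    vpd_term = p.transp_vpd_coeff * max(humidity_deficit, 0.0) * size
    if par_in > 1.0:
        transp = p.transp_par_coeff * i_abs + vpd_term
    else:
        transp = p.dark_transp_factor * vpd_term
    q = p.q10 ** ((temp_in - 20.0) / 10.0)
    resp_hourly = (p.rm_veg * veg_dm + p.rm_fruit * fruit_dm) * q / 24.0
    co2_uptake = (assim - resp_hourly) * 44.0 / 30.0
    return transp, co2_uptake, assim


@dataclass
class DailyCropRow:
    date: date
    lai: float
    stem_density: float
    plant_load: float
    trusses_per_stem: float
    cum_yield_kg: float
    cum_trusses: float
    assim: float
    discarded: float


class CropModel:
    """Stateful season driver: slot fluxes + end-of-day crop update.

    Wire ``feedback`` into ``simulate_climate(crop_feedback=...)`` and
    ``on_day_end`` into its ``day_callback``.
    """

    def __init__(self, plan: CropPlan, params: CropParams | None = None):
        self.plan = plan
        self.p = params or CropParams()
        self.state = CropState(veg_dm=self.p.initial_veg_dm)
        self.state.stem_cohorts.append(
            StemCohort(density=plan.initial_stem_density,
                       delay_cd_remaining=self.p.juvenile_delay_cd))
        self.harvests: list[HarvestRecord] = []
        self.daily_rows: list[DailyCropRow] = []
        self.carbon_ledger: list[dict] = []
        self.max_plant_load = 0.0
        self.max_fruits_per_truss = 0
        self._assim_hours: list[float] = []
        self._temp_hours: list[float] = []
        self._slot_assim_acc = 0.0
        self._slot_temp_acc = 0.0
        self._slot_count = 0

    @property
    def lai(self) -> float:
        return max(_lai_of(self.state, self.p), 0.05)

    def feedback(self, slot_index: int, rec_prev: dict | None) -> tuple[float, float]:
        """Crop fluxes for the coming slot from the previous slot's climate.

        Returns (transpiration g/m2/slot, CO2 uptake g/m2/slot).
        """
        if rec_prev is None:
            return 0.0, 0.0
        deficit = max(
            0.0,
            _sat(rec_prev["temp_in"]) - rec_prev["abs_humidity_in"],
        )
        transp_h, co2_h, assim_h = transpiration_and_co2_uptake(
            self.lai, rec_prev["par_in"], rec_prev["co2_in"], rec_prev["temp_in"],
            deficit, self.state.veg_dm, self.state.fruit_dm, self.p)
        self._slot_assim_acc += assim_h
        self._slot_temp_acc += rec_prev["temp_in"]
        self._slot_count += 1
        if self._slot_count == 12:  # close the hour
            self._assim_hours.append(self._slot_assim_acc / 12.0)
            self._temp_hours.append(self._slot_temp_acc / 12.0)
            self._slot_assim_acc = self._slot_temp_acc = 0.0
            self._slot_count = 0
        return transp_h / 12.0, co2_h / 12.0

    def on_day_end(self, day: date) -> list[HarvestRecord]:
        assim_hours = self._assim_hours or [0.0]
        temp_hours = self._temp_hours or [18.0]
        self._assim_hours = []
        self._temp_hours = []

        apply_crop_actions(self.state, self.plan, day, self.p)
        ledger = daily_carbon_update(assim_hours, temp_hours, self.state, self.p)
        ledger["date"] = day
        self.carbon_ledger.append(ledger)
        records = develop_and_harvest(self.state, ledger["t_avg"], day, self.plan, self.p)
        self.harvests.extend(records)

        self.max_plant_load = max(self.max_plant_load, self.state.plant_load)
        if self.state.trusses:
            self.max_fruits_per_truss = max(
                self.max_fruits_per_truss,
                max(t.fruits_per_truss for t in self.state.trusses))
        cohort0 = self.state.stem_cohorts[0]
        self.daily_rows.append(DailyCropRow(
            date=day, lai=self.lai, stem_density=self.state.stem_density,
            plant_load=self.state.plant_load, trusses_per_stem=cohort0.truss_acc,
            cum_yield_kg=self.state.cum_yield_kg,
            cum_trusses=self.state.cum_trusses_harvested,
            assim=ledger["assim"], discarded=ledger["discarded"]))
        return records

    def daily_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame([r.__dict__ for r in self.daily_rows])


def _sat(temp_c: float) -> float:
    es = 0.61078 * math.exp(17.27 * temp_c / (temp_c + 237.3))
    return 2166.7 * es / (temp_c + 273.15)
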