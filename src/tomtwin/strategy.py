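"""Control strategies: setpoint schedules, crop plans, presets, perturbations.

A :class:`SetpointSchedule` holds per-day setpoint templates (day/night
values) that are expanded lazily to 5-minute slots; a :class:`CropPlan`
holds the planting/stem-density/pruning/topping calendar. Six presets
(301..306) emulate the archetypal strategies of the six compartments:
schedules are open-loop -- closed-loop actuation lives in the climate
model. Perturbation operators (temperature shift, lighting hours, CO2)
implement the sensitivity-experiment vocabulary.

Preset quantitative levels are calibrated so that a simulated season
reproduces the documented per-compartment seasonal averages (temperature
within 0.2 degC, yield/income envelopes); see ``preset_calibration`` notes
in :data:`_PRESET_SPECS`.
"""

from __future__ import annotations

import copy
import math
import warnings
from dataclasses import dataclass, field
from datetime import date, timedelta

import numpy as np
import pandas as pd
import yaml

from .synthetic_weather import SEASON_END, SEASON_START, solar_elevation

__all__ = [
    "SetpointSchedule",
    "CropPlan",
    "Violation",
    "make_preset",
    "preset_ids",
    "validate",
    "validate_slots",
    "shift_temperature",
    "adjust_lighting_hours",
    "adjust_co2",
    "set_weekly_lighting_hours",
    "save_strategy",
    "load_strategy",
]

PRESET_IDS = (301, 302, 303, 304, 305, 306)

#: Hard fruit-per-truss caps: harvest is per truss, so maturity spread
#: within a truss limits it to 16 (single) / 20 (split) fruits.
FRUIT_CAP = {"single": 16, "split": 20}

_DAY_FIELDS = (
    "light_hours",
    "led_enabled",
    "led_blue",
    "led_red",
    "led_farred",
    "led_white",
    "vent_temp_day",
    "vent_temp_night",
    "min_rail_day",
    "min_rail_night",
    "min_crop_pipe",
    "co2_sp",
    "co2_capacity",
    "screen_energy_night",
    "screen_blackout_night",
    "min_vent_opening",
    "humidity_deficit_sp",
    "irrigation_interval",
)


@dataclass
class SetpointSchedule:
    """Daily setpoint templates over a season, expandable to 5-min slots.

    Each field is a per-day numpy array of length ``n_days``. Day/night
    values are resolved at expansion: a slot counts as "day" when lamps
    are scheduled on or the sun is up. Lamp photoperiods are centred on
    solar noon (12:00 local solar time).
    """

    start: date
    end: date
    light_hours: np.ndarray          # h/day of lamp operation (HPS, + LED if enabled)
    led_enabled: np.ndarray          # bool: LED runs alongside HPS
    led_blue: np.ndarray             # % of channel capacity
    led_red: np.ndarray
    led_farred: np.ndarray
    led_white: np.ndarray
    vent_temp_day: np.ndarray        # degC ventilation line
    vent_temp_night: np.ndarray
    min_rail_day: np.ndarray         # degC minimum rail-pipe temperature
    min_rail_night: np.ndarray
    min_crop_pipe: np.ndarray        # degC minimum crop-pipe temperature
    co2_sp: np.ndarray               # ppm
    co2_capacity: np.ndarray         # g/m2/h dosing capacity
    screen_energy_night: np.ndarray  # % closed at night
    screen_blackout_night: np.ndarray
    min_vent_opening: np.ndarray     # %
    humidity_deficit_sp: np.ndarray  # g/m3
    irrigation_interval: np.ndarray  # min between irrigation turns

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def copy(self) -> "SetpointSchedule":
        return copy.deepcopy(self)

    def day_index(self, d: date) -> int:
        return (d - self.start).days

    def week_of_day(self, day: int) -> int:
        return day // 7

    @property
    def n_weeks(self) -> int:
        return math.ceil(self.n_days / 7)

    def expand(self, timestamps: pd.DatetimeIndex, latitude: float = 52.0) -> dict:
        """Expand daily templates to per-slot setpoint arrays.

        Returns a dict of numpy arrays aligned with ``timestamps``:
        hps_on, led_on, led channel intensities, vent_temp, min_rail_pipe,
        min_crop_pipe, co2_sp, co2_capacity, screen_energy,
        screen_blackout, min_vent_opening, humidity_deficit_sp,
        irrigation_interval, is_day.
        """
        day0 = pd.Timestamp(self.start)
        day_idx = ((timestamps - day0).days).to_numpy()
        if day_idx.min() < 0 or day_idx.max() >= self.n_days:
            raise ValueError("timestamps fall outside the schedule calendar")
        hour = timestamps.hour.to_numpy(float) + timestamps.minute.to_numpy(float) / 60.0

        lh = self.light_hours[day_idx]
        # half-open window [noon - lh/2, noon + lh/2) so an h-hour
        # photoperiod occupies exactly 12*h five-minute slots
        lamp_on = (hour >= 12.0 - lh / 2.0) & (hour < 12.0 + lh / 2.0)
        sun_up = solar_elevation(timestamps, latitude) > 0.0
        is_day = lamp_on | sun_up

        def dn(day_arr, night_arr):
            return np.where(is_day, day_arr[day_idx], night_arr[day_idx])

        led_on = lamp_on & self.led_enabled[day_idx].astype(bool)
        return {
            "hps_on": lamp_on,
            "led_on": led_on,
            "led_blue": np.where(led_on, self.led_blue[day_idx], 0.0),
            "led_red": np.where(led_on, self.led_red[day_idx], 0.0),
            "led_farred": np.where(led_on, self.led_farred[day_idx], 0.0),
            "led_white": np.where(led_on, self.led_white[day_idx], 0.0),
            "vent_temp": dn(self.vent_temp_day, self.vent_temp_night),
            "min_rail_pipe": dn(self.min_rail_day, self.min_rail_night),
            "min_crop_pipe": self.min_crop_pipe[day_idx],
            "co2_sp": self.co2_sp[day_idx],
            "co2_capacity": self.co2_capacity[day_idx],
            "screen_energy": np.where(is_day, 0.0, self.screen_energy_night[day_idx]),
            "screen_blackout": np.where(is_day, 0.0, self.screen_blackout_night[day_idx]),
            "min_vent_opening": self.min_vent_opening[day_idx],
            "humidity_deficit_sp": self.humidity_deficit_sp[day_idx],
            "irrigation_interval": self.irrigation_interval[day_idx],
            "is_day": is_day,
        }


@dataclass
class CropPlan:
    """Planting, stem-density, pruning and topping calendar."""

    planting_date: date = SEASON_START
    initial_stem_density: float = 3.0          # stems/m2, within [2.6, 4.0]
    stem_density_changes: list[tuple[date, float]] = field(default_factory=list)
    fruits_per_truss_target: int = 13
    truss_type: str = "single"                 # "single" | "split"
    topping_date: date = date(2020, 4, 17)
    last_harvest_date: date = SEASON_END
    plants_are_two_stem: bool = True
    supply_ec: float = 3.2                     # dS/m season-average supply EC
    drain_fraction_target: float = 0.30        # share of supply not taken up
    brix_modifier: float = 0.0                 # per-strategy Brix offset, |x| <= 0.8

    def copy(self) -> "CropPlan":
        return copy.deepcopy(self)

    def stem_density_on(self, d: date) -> float:
        dens = self.initial_stem_density
        for when, value in sorted(self.stem_density_changes):
            if d >= when:
                dens = value
        return dens

    def stem_days_integral(self) -> float:
        """Integral of stem density over the season, in stem-days/m2."""
        total = 0.0
        d = self.planting_date
        while d <= self.last_harvest_date:
            total += self.stem_density_on(d)
            d += timedelta(days=1)
        return total


@dataclass(frozen=True)
class Violation:
    field: str
    where: str
    rule: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"{self.field} @ {self.where}: {self.rule}"


# ---------------------------------------------------------------------------
# presets


def _phases(n_days: int, start: date, breakpoints: list[tuple[date, float]]) -> np.ndarray:
    """Piecewise-constant per-day array from (date, value) breakpoints.

    The first breakpoint must be on or before ``start``.
    """
    out = np.empty(n_days)
    val = breakpoints[0][1]
    for i in range(n_days):
        d = start + timedelta(days=i)
        for when, v in breakpoints:
            if d >= when:
                val = v
        out[i] = val
    return out


def _taper(n_days: int, start_val: float, end_val: float, taper_from_day: int) -> np.ndarray:
    """Constant until ``taper_from_day`` then linear to ``end_val``."""
    out = np.full(n_days, float(start_val))
    if taper_from_day < n_days - 1:
        ramp = np.linspace(start_val, end_val, n_days - taper_from_day)
        out[taper_from_day:] = ramp
    return out


# Archetype parameters per compartment. Temperature levels are vent-line
# setpoints calibrated (see scratch calibration runs) so the simulated
# seasonal air-temperature averages land within 0.2 degC of the documented
# per-compartment averages: 301 21.34, 302 22.04, 303 22.70, 304 21.37,
# 305 21.40, 306 23.25 degC. Lighting: 305 heaviest (~48% lamp share of
# PAR), 302/304 lightest (~41%), others intermediate. CO2: 301 highest
# dosage, 303 lowest (~7.2 kg/m2). 303 doubles stems to 8.0/m2 just before
# its 17 April topping.
_PRESET_SPECS: dict[int, dict] = {
    301: dict(
        temp_day=[(date(2019, 12, 16), 23.7)],
        temp_night=[(date(2019, 12, 16), 21.5)],
        light=dict(base=13.7, end=6.7, taper_day=75),
        led=True,
        co2_sp=[(date(2019, 12, 16), 900.0)],
        co2_cap=6.5,
        topping=date(2020, 4, 30),
        stems=(3.4, [(date(2020, 1, 15), 5.0), (date(2020, 3, 1), 5.6)]),
        fpt=14,
        supply_ec=3.0,
        drain_frac=0.34,
        brix_mod=0.10,
    ),
    302: dict(
        temp_day=[(date(2019, 12, 16), 24.4)],
        temp_night=[(date(2019, 12, 16), 22.2)],
        light=dict(base=14.0, end=5.5, taper_day=75),
        led=True,
        co2_sp=[(date(2019, 12, 16), 870.0)],
        co2_cap=6.0,
        topping=date(2020, 4, 16),
        stems=(2.6, [(date(2020, 1, 20), 5.0), (date(2020, 2, 20), 5.7)]),
        fpt=14,
        supply_ec=3.2,
        drain_frac=0.35,
        brix_mod=0.20,
    ),
    303: dict(
        # reference growers: relatively high temperatures throughout
        temp_day=[(date(2019, 12, 16), 25.1)],
        temp_night=[(date(2019, 12, 16), 23.0)],
        light=dict(base=13.9, end=6.6, taper_day=75),
        led=True,
        co2_sp=[(date(2019, 12, 16), 580.0), (date(2020, 4, 15), 750.0)],
        co2_cap=6.0,
        topping=date(2020, 4, 17),
        stems=(4.0, [(date(2020, 2, 1), 5.0), (date(2020, 4, 10), 8.0)]),
        fpt=13,
        supply_ec=3.6,
        drain_frac=0.38,
        brix_mod=0.0,
    ),
    304: dict(
        temp_day=[(date(2019, 12, 16), 23.6)],
        temp_night=[(date(2019, 12, 16), 21.5)],
        light=dict(base=14.0, end=5.5, taper_day=75),
        led=True,
        co2_sp=[(date(2019, 12, 16), 860.0), (date(2020, 4, 1), 600.0)],
        co2_cap=6.5,
        topping=date(2020, 4, 23),
        stems=(3.0, [(date(2020, 2, 1), 4.8), (date(2020, 3, 15), 5.5)]),
        fpt=15,
        supply_ec=2.9,
        drain_frac=0.40,
        brix_mod=0.10,
    ),
    305: dict(
        # warm start, moderate middle, warm finish; heaviest lighting
        temp_day=[(date(2019, 12, 16), 24.4), (date(2020, 1, 20), 23.1),
                  (date(2020, 5, 1), 24.8)],
        temp_night=[(date(2019, 12, 16), 22.2), (date(2020, 1, 20), 21.0),
                    (date(2020, 5, 1), 22.6)],
        light=dict(base=14.0, end=7.4, taper_day=75),
        led=True,
        co2_sp=[(date(2019, 12, 16), 560.0)],
        co2_cap=6.0,
        topping=date(2020, 4, 24),
        stems=(3.0, [(date(2020, 2, 1), 4.6), (date(2020, 3, 15), 5.0)]),
        fpt=16,
        supply_ec=3.6,
        drain_frac=0.33,
        brix_mod=0.40,
    ),
    306: dict(
        # best strategy: warm start and finish, balanced middle
        temp_day=[(date(2019, 12, 16), 26.3), (date(2020, 1, 20), 25.3),
                  (date(2020, 5, 1), 26.8)],
        temp_night=[(date(2019, 12, 16), 24.1), (date(2020, 1, 20), 23.2),
                    (date(2020, 5, 1), 24.6)],
        light=dict(base=13.8, end=6.5, taper_day=75),
        led=True,
        co2_sp=[(date(2019, 12, 16), 780.0)],
        co2_cap=6.0,
        topping=date(2020, 4, 21),
        stems=(3.0, [(date(2020, 2, 1), 4.8), (date(2020, 3, 10), 5.85)]),
        fpt=13,
        supply_ec=3.3,
        drain_frac=0.32,
        brix_mod=0.20,
    ),
}


def preset_ids() -> tuple[int, ...]:
    return PRESET_IDS


def make_preset(
    compartment_id: int,
    start: date = SEASON_START,
    end: date = SEASON_END,
) -> tuple[SetpointSchedule, CropPlan]:
    """Build the archetype schedule/plan pair for a compartment (301..306)."""
    if compartment_id not in _PRESET_SPECS:
        raise ValueError(f"unknown compartment id {compartment_id!r}; expected one of {PRESET_IDS}")
    spec = _PRESET_SPECS[compartment_id]
    n = (end - start).days + 1

    light = spec["light"]
    schedule = SetpointSchedule(
        start=start,
        end=end,
        light_hours=_taper(n, light["base"], light["end"], light["taper_day"]),
        led_enabled=np.full(n, bool(spec["led"])),
        led_blue=np.full(n, 100.0),
        led_red=np.full(n, 100.0),
        led_farred=np.full(n, 100.0),
        led_white=np.full(n, 100.0),
        vent_temp_day=_phases(n, start, spec["temp_day"]),
        vent_temp_night=_phases(n, start, spec["temp_night"]),
        min_rail_day=np.full(n, 35.0),
        min_rail_night=np.full(n, 40.0),
        min_crop_pipe=np.full(n, 0.0),
        co2_sp=_phases(n, start, spec["co2_sp"]),
        co2_capacity=np.full(n, float(spec["co2_cap"])),
        screen_energy_night=np.full(n, 95.0),
        screen_blackout_night=np.full(n, 95.0),
        min_vent_opening=np.full(n, 1.0),
        humidity_deficit_sp=np.full(n, 2.0),
        irrigation_interval=np.full(n, 60.0),
    )
    init_dens, changes = spec["stems"]
    plan = CropPlan(
        planting_date=start,
        initial_stem_density=init_dens,
        stem_density_changes=list(changes),
        fruits_per_truss_target=spec["fpt"],
        truss_type="single",
        topping_date=spec["topping"],
        last_harvest_date=end,
        plants_are_two_stem=True,
        supply_ec=spec["supply_ec"],
        drain_fraction_target=spec["drain_frac"],
        brix_modifier=spec["brix_mod"],
    )
    return schedule, plan


# ---------------------------------------------------------------------------
# validation


def validate(schedule: SetpointSchedule, plan: CropPlan) -> list[Violation]:
    """Check all schedule/plan invariants; returns violations (never raises)."""
    v: list[Violation] = []
    n = schedule.n_days

    def day_str(i):
        return str(schedule.start + timedelta(days=i))

    for name in ("led_blue", "led_red", "led_farred", "led_white",
                 "screen_energy_night", "screen_blackout_night", "min_vent_opening"):
        arr = getattr(schedule, name)
        bad = np.flatnonzero((arr < 0.0) | (arr > 100.0))
        for i in bad[:5]:
            v.append(Violation(name, day_str(i), "percentage outside [0, 100]"))

    bad = np.flatnonzero((schedule.co2_sp < 300.0) | (schedule.co2_sp > 1200.0))
    for i in bad[:5]:
        v.append(Violation("co2_sp", day_str(i), "CO2 setpoint outside [300, 1200] ppm"))

    bad = np.flatnonzero(schedule.irrigation_interval <= 0.0)
    for i in bad[:5]:
        v.append(Violation("irrigation_interval", day_str(i), "must be positive"))

    bad = np.flatnonzero((schedule.light_hours < 0.0) | (schedule.light_hours > 24.0))
    for i in bad[:5]:
        v.append(Violation("light_hours", day_str(i), "lighting hours outside [0, 24]"))

    if not (2.6 <= plan.initial_stem_density <= 4.0):
        v.append(Violation("initial_stem_density", str(plan.planting_date),
                           "initial stem density outside [2.6, 4.0] stems/m2"))
    d = plan.planting_date
    while d <= plan.last_harvest_date:
        dens = plan.stem_density_on(d)
        if not (2.6 <= dens <= 8.0):
            v.append(Violation("stem_density", str(d),
                               f"stem density {dens} outside [2.6, 8.0] stems/m2"))
            break
        d += timedelta(days=1)

    cap = FRUIT_CAP.get(plan.truss_type)
    if cap is None:
        v.append(Violation("truss_type", "-", f"unknown truss type {plan.truss_type!r}"))
    elif plan.fruits_per_truss_target > cap:
        v.append(Violation("fruits_per_truss_target", "-",
                           f"target {plan.fruits_per_truss_target} exceeds cap {cap} for {plan.truss_type} trusses"))

    if not (plan.planting_date < plan.topping_date < plan.last_harvest_date):
        v.append(Violation("topping_date", str(plan.topping_date),
                           "requires planting_date < topping_date < last_harvest_date"))
    if abs(plan.brix_modifier) > 0.8:
        v.append(Violation("brix_modifier", "-", "strategy Brix modifier outside [-0.8, +0.8]"))
    return v


def validate_slots(slots: dict) -> list[Violation]:
    """Check per-slot invariants on an expanded setpoint dict.

    In particular the hardware coupling: LED power is wired through the
    HPS supply, so LED can only run additionally to HPS.
    """
    v: list[Violation] = []
    led = np.asarray(slots["led_on"], dtype=bool)
    hps = np.asarray(slots["hps_on"], dtype=bool)
    for i in np.flatnonzero(led & ~hps)[:5]:
        v.append(Violation("led_on", f"slot {i}",
                           "LED on requires HPS on (LED power is coupled to the HPS supply)"))
    for name in ("led_blue", "led_red", "led_farred", "led_white",
                 "screen_energy", "screen_blackout", "min_vent_opening"):
        arr = np.asarray(slots[name], dtype=float)
        for i in np.flatnonzero((arr < 0.0) | (arr > 100.0))[:5]:
            v.append(Violation(name, f"slot {i}", "percentage outside [0, 100]"))
    return v


# ---------------------------------------------------------------------------
# perturbation operators (identity at zero; touch only the named fields)


def shift_temperature(schedule: SetpointSchedule, delta: float) -> SetpointSchedule:
    """Shift vent-temperature and minimum-pipe setpoints by ``delta`` degC.

    ``|delta|`` must be <= 2. The bound applies to the cumulative shift
    from the base strategy: apply this operator once to the unperturbed
    schedule rather than stacking calls.
    """
    if abs(delta) > 2.0 + 1e-12:
        raise ValueError(f"temperature shift {delta} outside [-2, +2] degC")
    out = schedule.copy()
    out.vent_temp_day = out.vent_temp_day + delta
    out.vent_temp_night = out.vent_temp_night + delta
    out.min_rail_day = out.min_rail_day + delta
    out.min_rail_night = out.min_rail_night + delta
    out.min_crop_pipe = out.min_crop_pipe + delta
    return out


def adjust_lighting_hours(schedule: SetpointSchedule, delta_hours_per_day: float) -> SetpointSchedule:
    """Lengthen/shorten the daily lamp block by ``delta_hours_per_day``.

    The block stays centred on its photoperiod midpoint (solar noon);
    intensity is untouched. Results clamp to [0, 24] h (with a warning
    when clamping occurs).
    """
    if abs(delta_hours_per_day) > 3.0 + 1e-12:
        raise ValueError(f"lighting delta {delta_hours_per_day} outside [-3, +3] h/day")
    out = schedule.copy()
    new = out.light_hours + delta_hours_per_day
    if np.any(new < 0.0) or np.any(new > 24.0):
        warnings.warn("lighting hours clamped to [0, 24] h/day", stacklevel=2)
    out.light_hours = np.clip(new, 0.0, 24.0)
    return out


def adjust_co2(schedule: SetpointSchedule, sp_offset: float, capacity_kg_ha_h: float) -> SetpointSchedule:
    """Shift the CO2 setpoint and replace the dosing capacity.

    ``sp_offset`` in [-100, +50] ppm; ``capacity_kg_ha_h`` in [50, 200]
    kg/ha/h (recorded on the schedule in g/m2/h; 1 kg/ha = 0.1 g/m2).
    """
    if not (-100.0 <= sp_offset <= 50.0):
        raise ValueError(f"CO2 setpoint offset {sp_offset} outside [-100, +50] ppm")
    if not (50.0 <= capacity_kg_ha_h <= 200.0):
        raise ValueError(f"CO2 capacity {capacity_kg_ha_h} outside [50, 200] kg/ha/h")
    out = schedule.copy()
    out.co2_sp = out.co2_sp + sp_offset
    out.co2_capacity = np.full_like(out.co2_capacity, capacity_kg_ha_h * 0.1)
    return out


def set_weekly_lighting_hours(schedule: SetpointSchedule, hours_by_week: list[float]) -> SetpointSchedule:
    """Override the photoperiod (h/day) per season week.

    ``hours_by_week`` must have one entry per week of the season, each in
    [0, 20] h/day.
    """
    if len(hours_by_week) != schedule.n_weeks:
        raise ValueError(
            f"expected {schedule.n_weeks} weekly entries for this season, got {len(hours_by_week)}")
    arr = np.asarray(hours_by_week, dtype=float)
    if np.any((arr < 0.0) | (arr > 20.0)):
        raise ValueError("weekly lighting hours must be within [0, 20] h/day")
    out = schedule.copy()
    days = np.arange(out.n_days)
    out.light_hours = arr[days // 7].copy()
    return out


def weekly_lighting_hours(schedule: SetpointSchedule) -> np.ndarray:
    """Mean photoperiod (h/day) per season week of a schedule."""
    n = schedule.n_days
    weeks = np.arange(n) // 7
    return np.array([schedule.light_hours[weeks == w].mean() for w in range(schedule.n_weeks)])


# ---------------------------------------------------------------------------
# plain-text serialization (YAML sections per actuator; lossless round-trip)


def save_strategy(path, schedule: SetpointSchedule, plan: CropPlan) -> None:
    doc = {
        "calendar": {"start": schedule.start.isoformat(), "end": schedule.end.isoformat()},
        "schedule": {name: getattr(schedule, name).tolist() for name in _DAY_FIELDS},
        "crop_plan": {
            "planting_date": plan.planting_date.isoformat(),
            "initial_stem_density": plan.initial_stem_density,
            "stem_density_changes": [[d.isoformat(), v] for d, v in plan.stem_density_changes],
            "fruits_per_truss_target": plan.fruits_per_truss_target,
            "truss_type": plan.truss_type,
            "topping_date": plan.topping_date.isoformat(),
            "last_harvest_date": plan.last_harvest_date.isoformat(),
            "plants_are_two_stem": plan.plants_are_two_stem,
            "supply_ec": plan.supply_ec,
            "drain_fraction_target": plan.drain_fraction_target,
            "brix_modifier": plan.brix_modifier,
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


def load_strategy(path) -> tuple[SetpointSchedule, CropPlan]:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    start = date.fromisoformat(doc["calendar"]["start"])
    end = date.fromisoformat(doc["calendar"]["end"])
    sched_kwargs = {
        name: np.asarray(doc["schedule"][name],
                         dtype=bool if name == "led_enabled" else float)
        for name in _DAY_FIELDS
    }
    schedule = SetpointSchedule(start=start, end=end, **sched_kwargs)
    cp = doc["crop_plan"]
    plan = CropPlan(
        planting_date=date.fromisoformat(cp["planting_date"]),
        initial_stem_density=cp["initial_stem_density"],
        stem_density_changes=[(date.fromisoformat(d), v) for d, v in cp["stem_density_changes"]],
        fruits_per_truss_target=cp["fruits_per_truss_target"],
        truss_type=cp["truss_type"],
        topping_date=date.fromisoformat(cp["topping_date"]),
        last_harvest_date=date.fromisoformat(cp["last_harvest_date"]),
        plants_are_two_stem=cp["plants_are_two_stem"],
        supply_ec=cp["supply_ec"],
        drain_fraction_target=cp["drain_fraction_target"],
        brix_modifier=cp["brix_modifier"],
    )
    return schedule, plan
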