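"""Sensitivity sweeps, weekly marginal lighting, lighting optimizer, EC-Brix.

Every sweep re-simulates the full season per grid point against ONE fixed
weather realization (the seed is recorded in the curve), so the
zero-perturbation point reproduces the baseline bit-for-bit. Interactions
between growth factors are deliberately not co-optimized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .crop_twin import HarvestRecord
from .runner import RunConfig, SeasonResult, run_season
from .strategy import (
    adjust_co2,
    adjust_lighting_hours,
    make_preset,
    set_weekly_lighting_hours,
    shift_temperature,
    weekly_lighting_hours,
)
from .synthetic_weather import generate_weather

__all__ = [
    "SensitivityCurve",
    "sweep_co2",
    "sweep_temperature",
    "sweep_lighting",
    "weekly_lighting_marginal",
    "optimize_weekly_lighting",
    "ec_brix_correlation",
]


@dataclass
class SensitivityCurve:
    axis: str
    values: list            # perturbation grid (tuples for the CO2 sweep)
    delta_net_profit: list  # EUR/m2 vs baseline
    delta_yield: list       # kg/m2 vs baseline
    preset: int
    seed: int
    baseline_net_profit: float = 0.0
    baseline_yield: float = 0.0

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame({
            self.axis: [str(v) for v in self.values],
            "delta_net_profit": self.delta_net_profit,
            "delta_yield": self.delta_yield,
            "preset": self.preset,
            "seed": self.seed,
        })


def _baseline(preset: int, weather, seed: int) -> tuple[SeasonResult, RunConfig]:
    config = RunConfig(preset=preset, weather_seed=seed, quality_seed=seed)
    result = run_season(config, weather=weather)
    return result, config


def _shared_weather(preset: int, weather, seed: int):
    if weather is not None:
        return weather
    schedule, _ = make_preset(preset)
    return generate_weather(schedule.start, schedule.end, seed=seed)


def sweep_co2(
    preset: int,
    offsets_ppm,
    capacities_kg_ha_h,
    weather=None,
    seed: int = 1,
) -> SensitivityCurve:
    """Net-profit response to joint (setpoint offset, dosing capacity) grid.

    Offsets within [-100, +50] ppm, capacities within [50, 200] kg/ha/h;
    one full re-simulation per grid point.
    """
    weather = _shared_weather(preset, weather, seed)
    base, config = _baseline(preset, weather, seed)
    schedule0, plan = make_preset(preset)
    values, d_profit, d_yield = [], [], []
    for off, cap in zip(offsets_ppm, capacities_kg_ha_h):
        if off == 0.0 and cap is None:
            res = base
            values.append((0.0, None))
        else:
            cap_eff = cap if cap is not None else 150.0
            sched = adjust_co2(schedule0, off, cap_eff)
            res = run_season(config, schedule=sched, plan=plan, weather=weather)
            values.append((off, cap))
        d_profit.append(res.economics.net_profit - base.economics.net_profit)
        d_yield.append(res.total_yield_kg - base.total_yield_kg)
    return SensitivityCurve("co2_offset_capacity", values, d_profit, d_yield,
                            preset, seed, base.economics.net_profit, base.total_yield_kg)


def sweep_temperature(preset: int, deltas_c, weather=None, seed: int = 1) -> SensitivityCurve:
    """Net-profit response to temperature-setpoint shifts within [-2, +2] degC."""
    weather = _shared_weather(preset, weather, seed)
    base, config = _baseline(preset, weather, seed)
    schedule0, plan = make_preset(preset)
    d_profit, d_yield = [], []
    for delta in deltas_c:
        if delta == 0.0:
            res = base
        else:
            res = run_season(config, schedule=shift_temperature(schedule0, delta),
                             plan=plan, weather=weather)
        d_profit.append(res.economics.net_profit - base.economics.net_profit)
        d_yield.append(res.total_yield_kg - base.total_yield_kg)
    return SensitivityCurve("temperature_delta_c", list(deltas_c), d_profit, d_yield,
                            preset, seed, base.economics.net_profit, base.total_yield_kg)


def sweep_lighting(preset: int, deltas_h, weather=None, seed: int = 1) -> SensitivityCurve:
    """Net-profit response to daily lighting-hour changes within [-3, +3] h."""
    weather = _shared_weather(preset, weather, seed)
    base, config = _baseline(preset, weather, seed)
    schedule0, plan = make_preset(preset)
    d_profit, d_yield = [], []
    for delta in deltas_h:
        if delta == 0.0:
            res = base
        else:
            res = run_season(config, schedule=adjust_lighting_hours(schedule0, delta),
                             plan=plan, weather=weather)
        d_profit.append(res.economics.net_profit - base.economics.net_profit)
        d_yield.append(res.total_yield_kg - base.total_yield_kg)
    return SensitivityCurve("lighting_delta_h", list(deltas_h), d_profit, d_yield,
                            preset, seed, base.economics.net_profit, base.total_yield_kg)


def weekly_lighting_marginal(
    preset: int,
    weather=None,
    seed: int = 1,
    added_hours: float = 2.0,
    weeks=None,
) -> pd.DataFrame:
    """Per-week marginal value of +``added_hours`` h/day for that week only.

    One re-simulation per season week (14 additional lamp-hours per
    perturbed week at the default +2 h/day); all other weeks unchanged.
    """
    weather = _shared_weather(preset, weather, seed)
    base, config = _baseline(preset, weather, seed)
    schedule0, plan = make_preset(preset)
    hours0 = weekly_lighting_hours(schedule0)
    week_list = list(range(len(hours0))) if weeks is None else list(weeks)
    rows = []
    for w in week_list:
        hours = hours0.copy()
        hours[w] = min(20.0, hours[w] + added_hours)
        sched = set_weekly_lighting_hours(schedule0, hours.tolist())
        res = run_season(config, schedule=sched, plan=plan, weather=weather)
        rows.append({
            "week": w,
            "delta_net_profit": res.economics.net_profit - base.economics.net_profit,
            "delta_yield": res.total_yield_kg - base.total_yield_kg,
        })
    df = pd.DataFrame(rows)
    df.attrs["preset"] = preset
    df.attrs["seed"] = seed
    return df


def optimize_weekly_lighting(
    preset: int,
    weather=None,
    seed: int = 1,
    step: float = 1.0,
    max_iters: int = 3,
    bounds: tuple[float, float] = (0.0, 20.0),
    weeks=None,
) -> tuple[np.ndarray, float, list[float]]:
    """Coordinate ascent on weekly lighting hours to maximize net profit.

    Cyclic coordinate order, +/-``step`` h/day moves, accepting only
    improvements, until a full pass yields none or ``max_iters`` passes.
    ``weeks`` optionally restricts the optimized coordinates (the rest of
    the season stays at the baseline photoperiod). Returns (optimized
    hours/week, profit gain >= 0, objective trace).
    """
    if step <= 0.0:
        raise ValueError("step must be positive")
    weather = _shared_weather(preset, weather, seed)
    base, config = _baseline(preset, weather, seed)
    schedule0, plan = make_preset(preset)
    hours = weekly_lighting_hours(schedule0).copy()
    week_list = list(range(len(hours))) if weeks is None else list(weeks)

    def objective(h) -> float:
        sched = set_weekly_lighting_hours(schedule0, list(h))
        return run_season(config, schedule=sched, plan=plan, weather=weather).economics.net_profit

    current = base.economics.net_profit
    trace = [current]
    for _ in range(max_iters):
        improved = False
        for w in week_list:
            for direction in (+step, -step):
                cand = hours.copy()
                cand[w] = min(max(cand[w] + direction, bounds[0]), bounds[1])
                if cand[w] == hours[w]:
                    continue
                val = objective(cand)
                if val > current + 1e-12:
                    hours, current = cand, val
                    trace.append(current)
                    improved = True
                    break
        if not improved:
            break
    return hours, current - base.economics.net_profit, trace


def ec_brix_correlation(
    drain_ec: pd.Series,
    harvests: list[HarvestRecord],
    window_days: int = 35,
) -> tuple[float | None, pd.DataFrame]:
    """Pearson correlation of harvest Brix vs trailing-window mean drain EC.

    For each harvest, the drain EC is averaged over the ``window_days``
    days prior to the harvest date (the nominal fruit growth period).
    Needs >= 3 harvests; returns (None, table) when the correlation is
    undefined (constant Brix or constant EC), rather than 0.
    """
    if len(harvests) < 3:
        raise ValueError("need at least 3 harvests for a correlation")
    idx = pd.DatetimeIndex(pd.to_datetime(drain_ec.index))
    ec = pd.Series(drain_ec.to_numpy(float), index=idx).sort_index()
    rows = []
    for h in harvests:
        end = pd.Timestamp(h.date)
        start = end - pd.Timedelta(days=window_days)
        win = ec[(ec.index > start) & (ec.index <= end)]
        if len(win) == 0 or h.brix is None:
            continue
        rows.append({"date": h.date, "brix": h.brix, "mean_drain_ec": float(win.mean())})
    table = pd.DataFrame(rows)
    if len(table) < 3:
        raise ValueError("fewer than 3 harvests overlap the EC series")
    b = table["brix"].to_numpy()
    e = table["mean_drain_ec"].to_numpy()
    if np.std(b) < 1e-12 or np.std(e) < 1e-12:
        return None, table
    r = float(np.corrcoef(b, e)[0, 1])
    return r, table
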