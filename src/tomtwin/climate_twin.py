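"""Lumped greenhouse physics: weather + setpoints -> indoor climate + resources.

A single well-mixed air node with an exact-exponential energy update,
P-band ventilation and heating control, a CO2 mass balance with dosing
toward the setpoint, a humidity balance (transpiration source,
ventilation/condensation sinks, fogging toward the humidity-deficit
setpoint) and turn-based fertigation. Crop transpiration and CO2 uptake
enter through a callback evaluated with a one-slot lag (explicit
co-simulation).

Controller gains are not part of the control vocabulary; they are
configurable with documented defaults.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .strategy import SetpointSchedule
from .synthetic_weather import WeatherSeries

__all__ = [
    "GreenhouseParams",
    "ClimateState",
    "ClimateSeries",
    "ResourceLedger",
    "par_inside",
    "step_climate",
    "simulate_climate",
    "fertigation_step",
    "saturation_humidity",
]

DT = 300.0  # s per slot
RHO_CP = 1210.0  # J/m3/K air volumetric heat capacity
PPM_TO_G_M3 = 1.83e-3  # g CO2 per m3 per ppm (at ~20 degC)


@dataclass
class GreenhouseParams:
    """Construction/equipment parameters with compartment defaults."""

    floor_area: float = 96.0                # m2
    height: float = 4.0                     # m air volume per m2 floor
    light_transmissivity: float = 0.65      # cover PAR/solar transmissivity
    vent_area_ratio: float = 0.3            # m2 opening per m2 floor
    hps_par_capacity: float = 100.0         # umol/m2/s
    led_par_capacity: float = 97.0          # umol/m2/s PAR (blue 11 + red 49 + white 37)
    led_farred_capacity: float = 12.0       # umol/m2/s far-red (not counted as PAR)
    heat_capacity_rail: float = 180.0       # W/m2 peak
    heat_capacity_crop_pipe: float = 30.0   # W/m2 peak
    co2_dose_capacity: float = 15.0         # g/m2/h device maximum
    fog_capacity: float = 330.0             # g/m2/h
    hps_efficacy: float = 1.8               # umol/J electric
    led_efficacy: float = 2.5               # umol/J electric
    envelope_conductance: float = 6.5       # W/m2/K (typical Venlo, calibration parameter)
    screen_conductance_factor: float = 0.50  # U multiplier with energy screen closed
    screen_light_loss: float = 0.25         # light fraction blocked by closed energy screen
    blackout_light_loss: float = 0.99
    solar_heat_fraction: float = 0.70       # absorbed share of transmitted global
    lamp_heat_fraction: float = 0.88        # sensible-heat share of lamp electric power
    air_heat_capacity: float = 60000.0      # J/m2/K effective (air + crop + structure)
    heat_p_gain: float = 150.0               # W/m2/K heating P control
    heat_vent_gap: float = 2.0              # degC heating line below ventilation line
    vent_p_band: float = 4.0                # degC proportional band for window opening
    vent_max_flux: float = 0.045            # m3/m2/s at full opening, reference wind
    leakage_flux: float = 0.00025           # m3/m2/s infiltration
    co2_p_band: float = 50.0                # ppm proportional band for dosing
    co2_outside: float = 410.0              # ppm
    pipe_conductance: float = 0.9           # W/m2/K air-coupling of min-pipe floors
    ec_mixing_tau: float = 5.0 * 86400.0    # s root-zone EC relaxation time
    drain_ec_factor: float = 1.15           # steady drain EC relative to supply EC

    @property
    def heat_capacity_total(self) -> float:
        return self.heat_capacity_rail + self.heat_capacity_crop_pipe


def saturation_humidity(temp_c: float) -> float:
    """Saturation absolute humidity (g/m3) at air temperature (degC)."""
    es = 0.61078 * math.exp(17.27 * temp_c / (temp_c + 237.3))  # kPa
    return 2166.7 * es / (temp_c + 273.15)


def par_inside(
    par_outside: float,
    hps_on: bool,
    led_on: bool,
    led_channels: tuple[float, float, float, float] = (100.0, 100.0, 100.0, 100.0),
    screen_energy: float = 0.0,
    screen_blackout: float = 0.0,
    params: GreenhouseParams | None = None,
) -> float:
    """PAR at crop level (umol/m2/s): transmitted sun + lamps (far-red excluded).

    ``led_channels`` are (blue, red, far-red, white) intensities in %.
    Far-red photons are not counted as PAR.
    """
    p = params or GreenhouseParams()
    if par_outside < 0.0:
        raise ValueError("par_outside must be non-negative")
    screen_factor = (1.0 - p.screen_light_loss * screen_energy / 100.0) * (
        1.0 - p.blackout_light_loss * screen_blackout / 100.0
    )
    par = p.light_transmissivity * screen_factor * par_outside
    if hps_on:
        par += p.hps_par_capacity
    if led_on:
        blue, red, _farred, white = led_channels
        # channel capacities: blue 11, red 49, white 37 umol/m2/s
        par += 11.0 * blue / 100.0 + 49.0 * red / 100.0 + 37.0 * white / 100.0
    return par


def fertigation_step(
    radiation_sum_since_last_turn: float,
    irrigation_interval: float,
    crop_transpiration: float,
    supply_ec: float,
    drain_ec: float,
    drain_fraction_target: float = 0.30,
    params: GreenhouseParams | None = None,
    elapsed_s: float | None = None,
) -> tuple[float, float, float]:
    """One irrigation turn: (supply, drain, new drain EC).

    Supply is sized from the transpiration integral since the previous
    turn so that the drain fraction lands at the configured target
    (drain = supply - uptake, never negative). Drain EC relaxes toward
    the effective supply EC with a root-zone mixing time constant.
    Units: L/m2 for water (1 g/m2 water = 1e-3 L/m2).
    """
    if crop_transpiration < 0.0 or radiation_sum_since_last_turn < 0.0:
        raise ValueError("fertigation inputs must be non-negative")
    p = params or GreenhouseParams()
    uptake = crop_transpiration
    supply = uptake / max(1.0 - drain_fraction_target, 1e-6)
    drain = max(supply - uptake, 0.0)
    dt = elapsed_s if elapsed_s is not None else irrigation_interval * 60.0
    # root-zone salts concentrate more under high evaporative demand, so
    # the drain-EC target rises with the radiation sum of the turn
    rad_mj = radiation_sum_since_last_turn / 1e6
    target_ec = supply_ec * p.drain_ec_factor * (0.92 + 0.10 * min(rad_mj, 2.5))
    new_ec = target_ec + (drain_ec - target_ec) * math.exp(-dt / p.ec_mixing_tau)
    return supply, drain, new_ec


@dataclass
class ClimateState:
    temp_in: float = 18.0
    co2_in: float = 410.0
    abs_humidity_in: float = 12.0
    drain_ec: float = 3.0


def _physics_step(
    st: ClimateState,
    # weather
    g_rad: float, t_out: float, ah_out: float, wind: float, par_out: float,
    # setpoints
    hps_on: bool, led_on: bool, led_b: float, led_r: float, led_fr: float,
    led_w: float, vent_temp: float, min_rail: float, min_crop: float,
    co2_sp: float, co2_cap: float, scr_e: float, scr_b: float,
    min_vent: float, hd_sp: float,
    # crop feedback (previous slot)
    transp: float, co2_uptake: float,
    p: GreenhouseParams, dt: float,
) -> dict:
    """Advance one slot; returns flux record incl. next-state values."""
    # --- lamps
    par_lamp = 0.0
    elec = 0.0
    if hps_on:
        par_lamp += p.hps_par_capacity
        elec += p.hps_par_capacity / p.hps_efficacy
    if led_on:
        par_lamp += 11.0 * led_b / 100.0 + 49.0 * led_r / 100.0 + 37.0 * led_w / 100.0
        led_umol = (11.0 * led_b + 49.0 * led_r + 37.0 * led_w + 12.0 * led_fr) / 100.0
        elec += led_umol / p.led_efficacy

    screen_light = (1.0 - p.screen_light_loss * scr_e / 100.0) * (
        1.0 - p.blackout_light_loss * scr_b / 100.0)
    par_in = p.light_transmissivity * screen_light * par_out + par_lamp

    # --- heating control: P-control toward the heating line plus
    # min-pipe power floors, capped at installed capacity
    heat_line = vent_temp - p.heat_vent_gap
    q_demand = p.heat_p_gain * (heat_line - st.temp_in)
    q_floor = min(p.heat_capacity_rail,
                  max(0.0, p.pipe_conductance * (min_rail - st.temp_in)))
    q_floor += min(p.heat_capacity_crop_pipe,
                   max(0.0, p.pipe_conductance * (min_crop - st.temp_in)))
    q_heat = min(max(q_demand, q_floor, 0.0), p.heat_capacity_total)

    # --- ventilation: proportional opening above the vent line
    opening = min_vent + 100.0 * max(0.0, st.temp_in - vent_temp) / p.vent_p_band
    opening = min(max(opening, min_vent), 100.0)
    g_vent = p.leakage_flux + (opening / 100.0) * p.vent_max_flux * (0.5 + wind / 8.0)

    # --- energy balance (exact exponential update of the linear node)
    u_eff = p.envelope_conductance * (1.0 - (1.0 - p.screen_conductance_factor) * scr_e / 100.0)
    loss_coeff = u_eff + RHO_CP * g_vent
    q_sun = p.solar_heat_fraction * p.light_transmissivity * screen_light * g_rad
    q_lamp = p.lamp_heat_fraction * elec
    t_eq = t_out + (q_sun + q_lamp + q_heat) / loss_coeff
    t_next = t_eq + (st.temp_in - t_eq) * math.exp(-loss_coeff * dt / p.air_heat_capacity)

    # --- CO2 mass balance (g/m2 column of height p.height), integrated
    # exactly for the linear ventilation sink (stable at any opening)
    dosing_allowed = hps_on or par_out > 1.0
    cap = min(co2_cap, p.co2_dose_capacity)
    dose_rate = min(cap, max(0.0, cap * (co2_sp - st.co2_in) / p.co2_p_band)) \
        if dosing_allowed else 0.0
    dose = dose_rate * dt / 3600.0  # g/m2 this slot
    col = p.height * PPM_TO_G_M3  # g/m2 per ppm
    k_vent = g_vent / p.height  # 1/s air-exchange rate
    decay = math.exp(-k_vent * dt)
    src_co2 = (dose - co2_uptake) / dt  # g/m2/s
    conc0 = st.co2_in * PPM_TO_G_M3
    conc_eq = p.co2_outside * PPM_TO_G_M3 + src_co2 / g_vent
    conc1 = conc_eq + (conc0 - conc_eq) * decay
    # vented mass closes the balance exactly
    vent_co2 = dose - co2_uptake - (conc1 - conc0) * p.height
    co2_next = max(conc1 / PPM_TO_G_M3, 50.0)
    if co2_next == 50.0:  # clamp: account the deficit as reduced uptake
        co2_uptake = st.co2_in * col + dose - vent_co2 - 50.0 * col

    # --- humidity balance (g/m3 in a p.height column), same exact update
    ah_sat = saturation_humidity(st.temp_in)
    deficit = max(ah_sat - st.abs_humidity_in, 0.0)
    fog = 0.0
    if deficit > hd_sp:
        fog = min(p.fog_capacity * dt / 3600.0, (deficit - hd_sp) * p.height * 0.5)
    src_h2o = (transp + fog) / dt  # g/m2/s
    ah_eq = ah_out + src_h2o / g_vent
    ah_next = ah_eq + (st.abs_humidity_in - ah_eq) * decay
    cond = 0.0
    sat_next = saturation_humidity(t_next)
    if ah_next > sat_next:
        cond = (ah_next - sat_next) * p.height
        ah_next = sat_next
    ah_next = max(ah_next, 0.5)

    if not (math.isfinite(t_next) and math.isfinite(co2_next) and math.isfinite(ah_next)):
        raise FloatingPointError("non-finite climate state encountered")

    return {
        "temp_in": t_next,
        "co2_in": co2_next,
        "abs_humidity_in": ah_next,
        "par_in": par_in,
        "vent_opening": opening,
        "heat_power": q_heat,
        "lamp_electric_power": elec,
        "co2_dose_rate": dose_rate,
        "co2_dose": dose,
        "co2_vented": vent_co2,
        "co2_uptake": co2_uptake,
        "q_sun": q_sun,
        "fog": fog,
        "condensation": cond,
        "screen_energy": scr_e,
        "screen_blackout": scr_b,
    }


def step_climate(
    state: ClimateState,
    weather_slot: dict,
    setpoint_slot: dict,
    params: GreenhouseParams | None = None,
    dt: float = DT,
    transpiration: float = 0.0,
    co2_uptake: float = 0.0,
) -> tuple[ClimateState, dict]:
    """Advance the indoor climate one 5-min slot.

    ``weather_slot`` needs keys global_radiation, temp_out, ah_out (or
    rh_out), wind, par_outside; ``setpoint_slot`` the expanded schedule
    keys. Raises on non-finite state.
    """
    p = params or GreenhouseParams()
    for v in (state.temp_in, state.co2_in, state.abs_humidity_in):
        if not math.isfinite(v):
            raise FloatingPointError("non-finite climate state on entry")
    if "ah_out" in weather_slot:
        ah_out = weather_slot["ah_out"]
    else:
        ah_out = saturation_humidity(weather_slot["temp_out"]) * weather_slot["rh_out"] / 100.0
    rec = _physics_step(
        state,
        weather_slot["global_radiation"], weather_slot["temp_out"], ah_out,
        weather_slot["wind"], weather_slot["par_outside"],
        bool(setpoint_slot["hps_on"]), bool(setpoint_slot["led_on"]),
        float(setpoint_slot.get("led_blue", 100.0)), float(setpoint_slot.get("led_red", 100.0)),
        float(setpoint_slot.get("led_farred", 100.0)), float(setpoint_slot.get("led_white", 100.0)),
        float(setpoint_slot["vent_temp"]), float(setpoint_slot.get("min_rail_pipe", 0.0)),
        float(setpoint_slot.get("min_crop_pipe", 0.0)),
        float(setpoint_slot.get("co2_sp", 400.0)), float(setpoint_slot.get("co2_capacity", 15.0)),
        float(setpoint_slot.get("screen_energy", 0.0)), float(setpoint_slot.get("screen_blackout", 0.0)),
        float(setpoint_slot.get("min_vent_opening", 0.0)), float(setpoint_slot.get("humidity_deficit_sp", 99.0)),
        transpiration, co2_uptake, p, dt,
    )
    new_state = ClimateState(
        temp_in=rec["temp_in"], co2_in=rec["co2_in"],
        abs_humidity_in=rec["abs_humidity_in"], drain_ec=state.drain_ec,
    )
    return new_state, rec


_SERIES_FIELDS = (
    "temp_in", "co2_in", "abs_humidity_in", "par_in", "vent_opening",
    "screen_energy", "screen_blackout", "heat_power", "lamp_electric_power",
    "co2_dose_rate", "irrigation_supply", "drain", "drain_ec",
)


@dataclass
class ClimateSeries:
    """Per-slot indoor climate and actuator trajectories."""

    timestamps: pd.DatetimeIndex
    data: dict = field(default_factory=dict)  # name -> np.ndarray

    def __getattr__(self, name):
        data = object.__getattribute__(self, "data")
        if name in data:
            return data[name]
        raise AttributeError(name)

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.data)
        df.insert(0, "timestamp", self.timestamps)
        return df

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        df.to_csv(path, index=False)

    def daily(self) -> pd.DataFrame:
        """Daily derived quantities: PAR sum mol/m2/d, heat kWh/m2/d,
        electricity kWh/m2/d, CO2 dose g/m2/d, water L/m2/d, mean temp."""
        df = self.to_dataframe().set_index("timestamp")
        out = pd.DataFrame({
            "par_sum_mol": df["par_in"].resample("1D").sum() * DT / 1e6,
            "heat_kwh": df["heat_power"].resample("1D").sum() * DT / 3.6e6,
            "electricity_kwh": df["lamp_electric_power"].resample("1D").sum() * DT / 3.6e6,
            "co2_dose_g": df["co2_dose_rate"].resample("1D").sum() * DT / 3600.0,
            "water_supply_l": df["irrigation_supply"].resample("1D").sum(),
            "temp_mean": df["temp_in"].resample("1D").mean(),
            "co2_day_mean": df["co2_in"][df["par_in"] > 1.0].resample("1D").mean(),
        })
        return out


@dataclass
class ResourceLedger:
    """Season-cumulative resource use (per-slot cumulative arrays)."""

    timestamps: pd.DatetimeIndex
    heat: np.ndarray                 # MJ/m2 cumulative
    electricity_peak: np.ndarray     # kWh/m2 cumulative (07:00-23:00)
    electricity_offpeak: np.ndarray  # kWh/m2 cumulative
    co2_dosed: np.ndarray            # kg/m2 cumulative
    co2_vented: np.ndarray           # kg/m2 cumulative (bookkeeping)
    co2_uptake: np.ndarray           # kg/m2 cumulative crop uptake
    water_supplied: np.ndarray       # L/m2 cumulative
    water_drained: np.ndarray        # L/m2 cumulative
    supply_ec: float = 3.0           # dS/m season average

    @property
    def water_uptake(self) -> np.ndarray:
        return self.water_supplied - self.water_drained

    def totals(self) -> dict:
        return {
            "heat_mj": float(self.heat[-1]),
            "electricity_peak_kwh": float(self.electricity_peak[-1]),
            "electricity_offpeak_kwh": float(self.electricity_offpeak[-1]),
            "co2_dosed_kg": float(self.co2_dosed[-1]),
            "water_supplied_l": float(self.water_supplied[-1]),
            "water_drained_l": float(self.water_drained[-1]),
            "water_uptake_l": float(self.water_uptake[-1]),
            "supply_ec": self.supply_ec,
        }

    def to_csv(self, path) -> None:
        df = pd.DataFrame({
            "timestamp": self.timestamps.strftime("%Y-%m-%dT%H:%M:%S"),
            "heat_mj": self.heat,
            "electricity_peak_kwh": self.electricity_peak,
            "electricity_offpeak_kwh": self.electricity_offpeak,
            "co2_dosed_kg": self.co2_dosed,
            "water_supplied_l": self.water_supplied,
            "water_drained_l": self.water_drained,
        })
        df.to_csv(path, index=False)


def simulate_climate(
    weather: WeatherSeries,
    schedule: SetpointSchedule,
    params: GreenhouseParams | None = None,
    crop_feedback=None,
    day_callback=None,
    drain_fraction_target: float = 0.30,
    supply_ec: float = 3.0,
    initial_state: ClimateState | None = None,
) -> tuple[ClimateSeries, ResourceLedger]:
    """Run the climate model over a season.

    ``crop_feedback(slot_index, rec_prev)`` returns (transpiration g/m2
    per slot, CO2 uptake g/m2 per slot) for the coming slot, evaluated
    from the previous slot's climate record (one-slot lag). ``rec_prev``
    is None at the first slot. ``day_callback(day_index, slice)`` fires
    after the last slot of each day. Deterministic: all randomness lives
    in the weather.
    """
    p = params or GreenhouseParams()
    ts = weather.timestamps
    n = len(ts)
    sp = schedule.expand(ts, latitude=weather.latitude)
    if n != (schedule.n_days * 288):
        raise ValueError("weather series does not cover the schedule calendar")

    # pre-extract plain-python lists for the loop
    g_rad = weather.global_radiation.tolist()
    t_out = weather.temp_out.tolist()
    rh_out = weather.rh_out.tolist()
    wind = weather.wind.tolist()
    par_out = weather.par_outside.tolist()
    hps = sp["hps_on"].tolist()
    led = sp["led_on"].tolist()
    led_b = sp["led_blue"].tolist()
    led_r = sp["led_red"].tolist()
    led_fr = sp["led_farred"].tolist()
    led_w = sp["led_white"].tolist()
    vent_t = sp["vent_temp"].tolist()
    min_rail = sp["min_rail_pipe"].tolist()
    min_crop = sp["min_crop_pipe"].tolist()
    co2_sp_l = sp["co2_sp"].tolist()
    co2_cap_l = sp["co2_capacity"].tolist()
    scr_e = sp["screen_energy"].tolist()
    scr_b = sp["screen_blackout"].tolist()
    min_v = sp["min_vent_opening"].tolist()
    hd_sp_l = sp["humidity_deficit_sp"].tolist()
    irr_int = sp["irrigation_interval"].tolist()
    hours = ts.hour.to_numpy()
    peak_mask = ((hours >= 7) & (hours < 23)).tolist()

    out = {name: np.zeros(n) for name in _SERIES_FIELDS}
    cum_heat = np.zeros(n)
    cum_ep = np.zeros(n)
    cum_eo = np.zeros(n)
    cum_co2 = np.zeros(n)
    cum_co2v = np.zeros(n)
    cum_co2u = np.zeros(n)
    cum_ws = np.zeros(n)
    cum_wd = np.zeros(n)

    st = initial_state or ClimateState(temp_in=18.0, co2_in=p.co2_outside,
                                       abs_humidity_in=11.0, drain_ec=supply_ec)
    rec = None
    heat_acc = ep_acc = eo_acc = co2_acc = co2v_acc = co2u_acc = 0.0
    ws_acc = wd_acc = 0.0
    transp_turn = 0.0  # g/m2 accumulated since last irrigation turn
    rad_turn = 0.0
    mins_since_turn = 0.0
    drain_ec = supply_ec * p.drain_ec_factor

    for i in range(n):
        if crop_feedback is not None:
            transp, co2_upt = crop_feedback(i, rec)
        else:
            transp, co2_upt = 0.0, 0.0
        ah_out = saturation_humidity(t_out[i]) * rh_out[i] / 100.0
        rec = _physics_step(
            st, g_rad[i], t_out[i], ah_out, wind[i], par_out[i],
            hps[i], led[i], led_b[i], led_r[i], led_fr[i], led_w[i],
            vent_t[i], min_rail[i], min_crop[i], co2_sp_l[i], co2_cap_l[i],
            scr_e[i], scr_b[i], min_v[i], hd_sp_l[i],
            transp, co2_upt, p, DT,
        )
        st.temp_in = rec["temp_in"]
        st.co2_in = rec["co2_in"]
        st.abs_humidity_in = rec["abs_humidity_in"]

        # --- fertigation turns
        transp_turn += transp
        rad_turn += g_rad[i] * DT
        mins_since_turn += DT / 60.0
        supply = drain = 0.0
        if mins_since_turn >= irr_int[i] and transp_turn > 0.0:
            s_g, d_g, drain_ec = fertigation_step(
                rad_turn, irr_int[i], transp_turn, supply_ec, drain_ec,
                drain_fraction_target, p, elapsed_s=mins_since_turn * 60.0)
            supply, drain = s_g * 1e-3, d_g * 1e-3  # g/m2 -> L/m2
            transp_turn = rad_turn = 0.0
            mins_since_turn = 0.0

        # --- bookkeeping
        heat_acc += rec["heat_power"] * DT / 1e6  # MJ
        e_kwh = rec["lamp_electric_power"] * DT / 3.6e6
        if peak_mask[i]:
            ep_acc += e_kwh
        else:
            eo_acc += e_kwh
        co2_acc += rec["co2_dose"] / 1e3
        co2v_acc += rec["co2_vented"] / 1e3
        co2u_acc += rec["co2_uptake"] / 1e3
        ws_acc += supply
        wd_acc += drain

        out["temp_in"][i] = rec["temp_in"]
        out["co2_in"][i] = rec["co2_in"]
        out["abs_humidity_in"][i] = rec["abs_humidity_in"]
        out["par_in"][i] = rec["par_in"]
        out["vent_opening"][i] = rec["vent_opening"]
        out["screen_energy"][i] = rec["screen_energy"]
        out["screen_blackout"][i] = rec["screen_blackout"]
        out["heat_power"][i] = rec["heat_power"]
        out["lamp_electric_power"][i] = rec["lamp_electric_power"]
        out["co2_dose_rate"][i] = rec["co2_dose_rate"]
        out["irrigation_supply"][i] = supply
        out["drain"][i] = drain
        out["drain_ec"][i] = drain_ec
        cum_heat[i] = heat_acc
        cum_ep[i] = ep_acc
        cum_eo[i] = eo_acc
        cum_co2[i] = co2_acc
        cum_co2v[i] = co2v_acc
        cum_co2u[i] = co2u_acc
        cum_ws[i] = ws_acc
        cum_wd[i] = wd_acc

        if day_callback is not None and (i + 1) % 288 == 0:
            day_callback((i + 1) // 288 - 1, slice(i + 1 - 288, i + 1), out)

    series = ClimateSeries(timestamps=ts, data=out)
    ledger = ResourceLedger(
        timestamps=ts, heat=cum_heat, electricity_peak=cum_ep,
        electricity_offpeak=cum_eo, co2_dosed=cum_co2, co2_vented=cum_co2v,
        co2_uptake=cum_co2u, water_supplied=cum_ws, water_drained=cum_wd,
        supply_ec=supply_ec,
    )
    return series, ledger
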