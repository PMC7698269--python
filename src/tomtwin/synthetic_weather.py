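"""Seeded synthetic outside weather for a Dutch greenhouse season.

Generates 5-minute series of global radiation, PAR, temperature, humidity
and wind with realistic seasonal/diurnal structure: clear-sky radiation
from solar geometry, attenuated by a first-order autoregressive cloudiness
process; temperature as seasonal trend + diurnal cycle + AR(1) noise.

The generator is calibrated only loosely (clear-sky physical bounds for
the latitude); it is a stand-in for weather sensors, not a reanalysis.
All times are local solar time; no daylight-saving handling.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

__all__ = [
    "WeatherSeries",
    "generate_weather",
    "par_from_global",
    "solar_elevation",
    "clearsky_ghi",
    "SEASON_START",
    "SEASON_END",
]

#: Default season calendar (planting to last harvest).
SEASON_START = date(2019, 12, 16)
SEASON_END = date(2020, 5, 29)

#: Default site latitude (Bleiswijk, NL).
DEFAULT_LATITUDE = 52.0

#: PAR content of global radiation: ~47% of global is PAR, at ~2.1 umol/J,
#: i.e. ~1.0 umol/s of PAR photons per W of global radiation.
PAR_PER_GLOBAL = 1.0  # umol/m2/s per W/m2

_SOLAR_CONSTANT = 1361.0  # W/m2


def solar_elevation(timestamps: pd.DatetimeIndex, latitude: float) -> np.ndarray:
    """Solar elevation angle (degrees) at local solar time.

    Standard declination/hour-angle formulas; adequate for clear-sky
    bounds and day/night masking.
    """
    doy = timestamps.dayofyear.to_numpy(dtype=float)
    hour = (
        timestamps.hour.to_numpy(dtype=float)
        + timestamps.minute.to_numpy(dtype=float) / 60.0
    )
    decl = np.radians(23.45) * np.sin(2.0 * np.pi * (284.0 + doy) / 365.0)
    hang = np.radians(15.0 * (hour - 12.0))
    lat = math.radians(latitude)
    sin_el = np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.cos(hang)
    return np.degrees(np.arcsin(np.clip(sin_el, -1.0, 1.0)))


def clearsky_ghi(timestamps: pd.DatetimeIndex, latitude: float) -> np.ndarray:
    """Clear-sky global horizontal irradiance (W/m2), Haurwitz-type model.

    Zero whenever the sun is at or below the horizon.
    """
    el = np.radians(solar_elevation(timestamps, latitude))
    sin_el = np.sin(el)
    ghi = np.where(
        sin_el > 0.0,
        1098.0 * sin_el * np.exp(-0.059 / np.clip(sin_el, 1e-6, None)),
        0.0,
    )
    return ghi


def par_from_global(global_radiation, factor: float = PAR_PER_GLOBAL):
    """Convert global radiation (W/m2) to PAR photon flux (umol/m2/s).

    Linear with a configurable factor (default 1.0 umol/s per W global,
    i.e. 2.1 umol/J applied to the ~47% PAR fraction of global).
    """
    arr = np.asarray(global_radiation, dtype=float)
    if np.any(arr < 0.0):
        raise ValueError("global radiation must be non-negative")
    out = arr * factor
    return float(out) if np.isscalar(global_radiation) else out


@dataclass
class WeatherSeries:
    """Outside weather at a fixed 5-minute step.

    Attributes
    ----------
    timestamps : pd.DatetimeIndex
        Strictly increasing, uniform 5-min spacing.
    global_radiation : np.ndarray
        W/m2, >= 0, exactly 0 when solar elevation <= 0.
    par_outside : np.ndarray
        umol/m2/s.
    temp_out, rh_out, wind : np.ndarray
        degC, % (0, 100], m/s (>= 0).
    """

    timestamps: pd.DatetimeIndex
    global_radiation: np.ndarray
    par_outside: np.ndarray
    temp_out: np.ndarray
    rh_out: np.ndarray
    wind: np.ndarray
    latitude: float = DEFAULT_LATITUDE
    seed: int | None = field(default=None, repr=False)

    def __len__(self) -> int:
        return len(self.timestamps)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "timestamp": self.timestamps,
                "global_radiation_wm2": self.global_radiation,
                "par_outside_umol": self.par_outside,
                "temp_out_c": self.temp_out,
                "rh_out_pct": self.rh_out,
                "wind_ms": self.wind,
            }
        )

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df["timestamp"] = df["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        df.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, latitude: float = DEFAULT_LATITUDE) -> "WeatherSeries":
        df = pd.read_csv(path, parse_dates=["timestamp"])
        return cls(
            timestamps=pd.DatetimeIndex(df["timestamp"]),
            global_radiation=df["global_radiation_wm2"].to_numpy(float),
            par_outside=df["par_outside_umol"].to_numpy(float),
            temp_out=df["temp_out_c"].to_numpy(float),
            rh_out=df["rh_out_pct"].to_numpy(float),
            wind=df["wind_ms"].to_numpy(float),
            latitude=latitude,
        )

    def daily_radiation_integral(self) -> pd.Series:
        """Daily global radiation sums in MJ/m2/d."""
        s = pd.Series(self.global_radiation, index=self.timestamps)
        return s.resample("1D").sum() * 300.0 / 1e6


def _ar1(rng: np.random.Generator, n: int, rho: float) -> np.ndarray:
    """Standard-normal AR(1) series with lag-1 correlation rho."""
    eps = rng.standard_normal(n)
    out = np.empty(n)
    out[0] = eps[0]
    c = math.sqrt(max(1.0 - rho * rho, 0.0))
    for i in range(1, n):
        out[i] = rho * out[i - 1] + c * eps[i]
    return out


def generate_weather(
    start_date: date = SEASON_START,
    end_date: date = SEASON_END,
    latitude: float = DEFAULT_LATITUDE,
    seed: int = 0,
    cloud_persistence: float = 0.85,
) -> WeatherSeries:
    """Generate a seeded synthetic season of 5-min outside weather.

    Parameters
    ----------
    start_date, end_date : date
        Inclusive calendar span of the series.
    latitude : float
        Site latitude in degrees, within [40, 60].
    seed : int
        Seed for all randomness; identical seeds give bitwise-identical
        series.
    cloud_persistence : float
        Lag-1 autocorrelation (0-1) of the hourly cloudiness process.
    """
    if end_date <= start_date:
        raise ValueError(f"end_date {end_date} must be after start_date {start_date}")
    if not (40.0 <= latitude <= 60.0):
        raise ValueError(f"latitude {latitude} outside supported range [40, 60]")
    if not (0.0 <= cloud_persistence <= 1.0):
        raise ValueError("cloud_persistence must be within [0, 1]")

    ts = pd.date_range(
        start=pd.Timestamp(start_date),
        end=pd.Timestamp(end_date) + pd.Timedelta(hours=23, minutes=55),
        freq="5min",
    )
    n = len(ts)
    rng = np.random.default_rng(seed)

    # --- radiation: clear sky x AR(1) cloud attenuation (hourly resolution)
    ghi_clear = clearsky_ghi(ts, latitude)
    n_hours = n // 12 + 2
    z = _ar1(rng, n_hours, cloud_persistence)
    # map N(0,1) to an attenuation factor in (0.15, 1.0]; skewed clear
    atten_h = 0.15 + 0.85 / (1.0 + np.exp(-(0.9 * z + 0.8)))
    atten = np.repeat(atten_h, 12)[:n]
    global_rad = ghi_clear * atten

    # --- temperature: seasonal trend + diurnal cycle + AR(1) noise
    doy = ts.dayofyear.to_numpy(float)
    hour = ts.hour.to_numpy(float) + ts.minute.to_numpy(float) / 60.0
    seasonal = 8.5 - 6.0 * np.cos(2.0 * np.pi * (doy - 15.0) / 365.0)
    clearness = np.repeat(atten_h, 12)[:n]
    diurnal_amp = 2.0 + 3.0 * clearness
    diurnal = -diurnal_amp * np.cos(2.0 * np.pi * (hour - 14.0) / 24.0)
    t_noise = 2.2 * np.repeat(_ar1(rng, n_hours, 0.95), 12)[:n]
    temp_out = seasonal + diurnal + t_noise

    # --- humidity: high at night, dips by day, never saturated/zero
    rh_noise = 6.0 * np.repeat(_ar1(rng, n_hours, 0.9), 12)[:n]
    rh_out = np.clip(88.0 - 10.0 * diurnal / np.maximum(diurnal_amp, 1e-9) - 4.0
                     + rh_noise, 25.0, 100.0)
    rh_out = np.where(rh_out <= 0.0, 1.0, rh_out)

    # --- wind: folded AR(1) around a seasonal mean
    w_noise = np.repeat(_ar1(rng, n_hours, 0.9), 12)[:n]
    wind = np.abs(3.5 + 1.6 * w_noise)

    return WeatherSeries(
        timestamps=ts,
        global_radiation=global_rad,
        par_outside=par_from_global(global_rad),
        temp_out=temp_out,
        rh_out=rh_out,
        wind=wind,
        latitude=latitude,
        seed=seed,
    )
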