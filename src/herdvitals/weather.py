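"""Psychrometric derivations and temperature–humidity indices (THI).

Weather records from a farm station (air temperature, relative humidity, wind,
surface pressure at 15-min cadence) are enriched with dew-point and wet-bulb
temperatures and a suite of nine THI formulations from the dairy heat-stress
literature.  The wet-bulb temperature is solved from the psychrometer balance
by bisection; dew point uses the Magnus–Tetens approximation.

Physical ordering Tdp <= Twet <= T (dry bulb) holds for all valid inputs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

# Magnus-Tetens saturation-vapour-pressure coefficients (over water).
MAGNUS_A = 17.27
MAGNUS_B = 237.7  # degC
# Psychrometer constant for an aspirated psychrometer, degC^-1.
PSYCHROMETER_A = 6.6e-4
STANDARD_PRESSURE_HPA = 1013.25

THI_KEYS = tuple(f"THI{i}" for i in range(1, 10))

#: Provenance of each THI formulation (dry-bulb T and RH in %, Tdp/Twet in degC;
#: several are degF-era forms, hence the 1.8x + 32 factors).
THI_SOURCES = {
    "THI1": "Thom (1959), dry+wet bulb, degF form",
    "THI2": "NRC (1971) / Kelly & Bond, dry bulb + RH",
    "THI3": "Mader et al. (2006), dry bulb + RH",
    "THI4": "NRC (1971), dry+wet bulb",
    "THI5": "Bianca (1962), 0.35T + 0.65Twb",
    "THI6": "Kibler (1964), dry bulb + dew point",
    "THI7": "Yousef (1985), dry bulb + dew point",
    "THI8": "Ingraham et al. (1979), dry bulb + RH",
    "THI9": "Bianca (1962), 0.15T + 0.85Twb",
}


@dataclass(frozen=True)
class WeatherRecord:
    """One weather-station sample."""

    timestamp: pd.Timestamp
    T: float  # air temperature, degC
    RH: float  # relative humidity, %
    wind_speed: float  # km/h
    wind_dir: float  # degrees, [0, 360)
    pressure: float = STANDARD_PRESSURE_HPA  # hPa

    def __post_init__(self):
        if not (0.0 < self.RH <= 100.0):
            raise ValueError(f"RH must be in (0, 100], got {self.RH}")
        if not (0.0 <= self.wind_dir < 360.0):
            raise ValueError(f"wind_dir must be in [0, 360), got {self.wind_dir}")


@dataclass(frozen=True)
class WeatherDerived:
    """Psychrometric quantities derived from a :class:`WeatherRecord`."""

    Tdp: float
    Twet: float
    thi: dict = field(default_factory=dict)  # THI1..THI9


def saturation_vapor_pressure(T):
    """Saturation vapour pressure over water (hPa), Magnus-Tetens."""
    T = np.asarray(T, dtype=float)
    return 6.112 * np.exp(MAGNUS_A * T / (MAGNUS_B + T))


def dew_point(T, RH):
    """Dew-point temperature (degC) from dry bulb T (degC) and RH (%).

    Magnus-Tetens inversion: gamma = aT/(b+T) + ln(RH/100), Tdp = b*gamma/(a-gamma).
    """
    T = np.asarray(T, dtype=float)
    RH = np.asarray(RH, dtype=float)
    if np.any(RH <= 0) or np.any(RH > 100):
        raise ValueError("RH must be in (0, 100]")
    gamma = MAGNUS_A * T / (MAGNUS_B + T) + np.log(RH / 100.0)
    out = MAGNUS_B * gamma / (MAGNUS_A - gamma)
    return float(out) if out.ndim == 0 else out


def _psychrometric_balance(Tw, T, e_actual, pressure):
    # Root at the wet-bulb temperature: es(Tw) - A*p*(T - Tw) - e = 0
    return saturation_vapor_pressure(Tw) - PSYCHROMETER_A * pressure * (T - Tw) - e_actual


def wet_bulb(T, RH, pressure=STANDARD_PRESSURE_HPA, tol=1e-4, max_iter=100):
    """Wet-bulb temperature (degC) by bisection on the psychrometer equation.

    Solves e(Tdp) = es(Tw) - A*p*(T - Tw) for Tw on the bracket [Tdp, T].
    At saturation (RH=100) the bracket degenerates and Twet = T exactly.
    """
    T = float(T)
    RH = float(RH)
    if not (0.0 < RH <= 100.0):
        raise ValueError("RH must be in (0, 100]")
    if pressure <= 0:
        raise ValueError("pressure must be positive")
    if RH == 100.0:
        return T
    tdp = dew_point(T, RH)
    e_actual = saturation_vapor_pressure(tdp)
    lo, hi = tdp, T
    f_lo = _psychrometric_balance(lo, T, e_actual, pressure)
    f_hi = _psychrometric_balance(hi, T, e_actual, pressure)
    if f_lo * f_hi > 0:  # numerically degenerate bracket (RH ~ 100)
        return T
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        f_mid = _psychrometric_balance(mid, T, e_actual, pressure)
        if abs(f_mid) < tol:
            return mid
        if f_lo * f_mid <= 0:
            hi = mid
        else:
            lo, f_lo = mid, f_mid
    return 0.5 * (lo + hi)


def thi_suite(T, RH, Tdp=None, Twet=None):
    """Evaluate the nine-equation THI suite; returns dict THI1..THI9.

    Each formula is monotone non-decreasing in T at fixed RH. Sources per key
    are recorded in :data:`THI_SOURCES`.
    """
    T = float(T)
    RH = float(RH)
    if Tdp is None:
        Tdp = dew_point(T, RH)
    if Twet is None:
        Twet = wet_bulb(T, RH)
    tf = 1.8 * T + 32.0  # degF dry bulb
    thi = {
        "THI1": 0.4 * (T + Twet) * 1.8 + 32.0 + 15.0,
        "THI2": tf - (0.55 - 0.0055 * RH) * (tf - 58.0),
        "THI3": 0.8 * T + RH / 100.0 * (T - 14.4) + 46.4,
        "THI4": 0.72 * (T + Twet) + 40.6,
        "THI5": (0.35 * T + 0.65 * Twet) * 1.8 + 32.0,
        "THI6": (0.55 * T + 0.2 * Tdp) * 1.8 + 32.0 + 17.5,
        "THI7": T + 0.36 * Tdp + 41.2,
        "THI8": 1.8 * T - (1.0 - RH / 100.0) * (T - 14.3) + 32.0,
        "THI9": (0.15 * T + 0.85 * Twet) * 1.8 + 32.0,
    }
    return thi


def derive(record: WeatherRecord) -> WeatherDerived:
    """Full psychrometric derivation for one record."""
    tdp = dew_point(record.T, record.RH)
    twet = wet_bulb(record.T, record.RH, record.pressure)
    return WeatherDerived(Tdp=tdp, Twet=twet, thi=thi_suite(record.T, record.RH, tdp, twet))


def derive_frame(df: pd.DataFrame) -> pd.DataFrame:
    """Append Tdp, Twet and THI1..THI9 columns to a weather table.

    Expects columns T, RH and optionally pressure (defaults to sea level).
    """
    out = df.copy()
    pressure = out["pressure"] if "pressure" in out else pd.Series(
        STANDARD_PRESSURE_HPA, index=out.index
    )
    out["Tdp"] = dew_point(out["T"].to_numpy(), out["RH"].to_numpy())
    out["Twet"] = [
        wet_bulb(t, rh, p)
        for t, rh, p in zip(out["T"], out["RH"], pressure)
    ]
    thi_rows = [
        thi_suite(t, rh, tdp, tw)
        for t, rh, tdp, tw in zip(out["T"], out["RH"], out["Tdp"], out["Twet"])
    ]
    for key in THI_KEYS:
        out[key] = [row[key] for row in thi_rows]
    return out


def match_weather(recording_timestamp, series: pd.DataFrame) -> pd.Series:
    """Nearest-timestamp weather record for a recording; ties break earlier.

    The station logs every 15 min while recordings carry arbitrary
    per-cow timestamps, so exact joins are not possible.
    """
    if len(series) == 0:
        raise ValueError("weather series is empty")
    ts = pd.Timestamp(recording_timestamp)
    stamps = pd.to_datetime(series["timestamp"])
    if not stamps.is_monotonic_increasing:
        raise ValueError("weather series must be sorted by timestamp")
    if ts < stamps.iloc[0]:
        warnings.warn(
            f"recording at {ts} precedes first weather record {stamps.iloc[0]}; "
            "using the first record",
            stacklevel=2,
        )
        return series.iloc[0]
    deltas = (stamps - ts).abs()
    # idxmin returns the first (earliest) index on ties
    return series.loc[deltas.idxmin()]
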