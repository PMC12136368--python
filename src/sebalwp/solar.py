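"""Solar geometry: declination, hour angle, extraterrestrial radiation, daylength.

All angles in radians internally; latitudes enter in decimal degrees. The
daily quantities follow the FAO-56 conventions (day-of-year based inverse
relative distance and declination), which are accurate to well under 1% for
energy-balance purposes.
"""

from __future__ import annotations

import datetime as _dt
import math

import numpy as np

from .constants import SOLAR_CONSTANT_MJ_MIN

__all__ = [
    "day_of_year",
    "inverse_relative_distance",
    "declination",
    "sunset_hour_angle",
    "daylength_hours",
    "extraterrestrial_radiation_daily",
    "cos_solar_zenith",
]


def day_of_year(date: _dt.date) -> int:
    return date.timetuple().tm_yday


def inverse_relative_distance(doy: int) -> float:
    """d_r, squared inverse relative Earth-Sun distance."""
    return 1.0 + 0.033 * math.cos(2.0 * math.pi * doy / 365.0)


def declination(doy: int) -> float:
    """Solar declination (rad)."""
    return 0.409 * math.sin(2.0 * math.pi * doy / 365.0 - 1.39)


def sunset_hour_angle(lat_deg, doy: int):
    """omega_s (rad); argument clipped so polar day/night degrade gracefully."""
    phi = np.deg2rad(lat_deg)
    delta = declination(doy)
    x = np.clip(-np.tan(phi) * np.tan(delta), -1.0, 1.0)
    return np.arccos(x)

def daylength_hours(lat_deg, doy: int):
    """Maximum possible sunshine duration N (h)."""
    return 24.0 / math.pi * sunset_hour_angle(lat_deg, doy)


def extraterrestrial_radiation_daily(lat_deg, doy: int):
    """Daily extraterrestrial radiation Ra (MJ m-2 d-1)."""
    phi = np.deg2rad(lat_deg)
    delta = declination(doy)
    dr = inverse_relative_distance(doy)
    ws = sunset_hour_angle(lat_deg, doy)
    ra = (
        24.0 * 60.0 / math.pi
        * SOLAR_CONSTANT_MJ_MIN
        * dr
        * (ws * np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.sin(ws))
    )
    return np.maximum(ra, 0.0)


def cos_solar_zenith(lat_deg, doy: int, solar_time_h: float):
    """cos(theta) for a horizontal surface at local solar time (decimal hours).

    Negative values (sun below the horizon) are clipped to 0.
    """
    phi = np.deg2rad(lat_deg)
    delta = declination(doy)
    omega = math.pi / 12.0 * (solar_time_h - 12.0)  # hour angle
    cz = np.sin(phi) * np.sin(delta) + np.cos(phi) * np.cos(delta) * np.cos(omega)
    return np.maximum(cz, 0.0)
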