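"""FAO-56 Penman-Monteith reference evapotranspiration and validation table.

Implements the standard daily FAO-56 chain: saturation/actual vapor pressure,
psychrometric constant, Angstrom solar radiation from sunshine hours, net
radiation, and the Penman-Monteith combination equation

    ET0 = [0.408 D (Rn - G) + g 900/(T+273) u2 (es - ea)] / [D + g (1 + 0.34 u2)]

with G = 0 at the daily step. Crop ET is ETc = Kc * ET0. The validation table
compares Penman-Monteith daily ET against energy-balance (SEBAL) daily ET at
matched stations/dates; relative error is expressed against the SEBAL value.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import solar

__all__ = [
    "MetDaily",
    "CropConfig",
    "sat_vapor_pressure",
    "vapor_terms",
    "pm_radiation",
    "penman_monteith_et0",
    "et0_series",
    "crop_et",
    "validate",
]

SIGMA_MJ = 4.903e-9  # Stefan-Boltzmann, MJ K-4 m-2 d-1
ANGSTROM_AS = 0.25
ANGSTROM_BS = 0.50


@dataclass
class MetDaily:
    """One station-day of meteorology driving Penman-Monteith."""

    date: _dt.date
    tmax_c: float
    tmin_c: float
    tmean_c: float
    rh_pct: float
    wind_2m_ms: float
    sunshine_h: float
    precip_mm: float = 0.0
    elev_m: float = 0.0
    lat_deg: float = 0.0

    def __post_init__(self) -> None:
        if not (self.tmin_c <= self.tmean_c <= self.tmax_c):
            raise ValueError(
                f"temperatures must satisfy Tmin <= Tmean <= Tmax "
                f"(got {self.tmin_c}, {self.tmean_c}, {self.tmax_c})"
            )
        if not (0.0 <= self.rh_pct <= 100.0):
            raise ValueError(f"relative humidity outside [0, 100]: {self.rh_pct}")
        if self.wind_2m_ms < 0:
            raise ValueError("wind speed must be non-negative")
        n_max = float(solar.daylength_hours(self.lat_deg, solar.day_of_year(self.date)))
        if not (0.0 <= self.sunshine_h <= n_max + 1e-9):
            raise ValueError(
                f"sunshine hours {self.sunshine_h} exceed daylength {n_max:.2f} h"
            )


@dataclass
class CropConfig:
    """Kc schedule keyed by growth stage, with an explicit crop calendar.

    ``stages`` is an ordered list of (stage_start_date, kc); a date belongs to
    the last stage whose start is <= date. Dates outside [sowing, harvest]
    carry no crop ET.
    """

    name: str
    sowing: _dt.date
    harvest: _dt.date
    stages: list = field(default_factory=list)  # [(date, kc), ...]

    def __post_init__(self) -> None:
        if self.sowing >= self.harvest:
            raise ValueError("sowing must precede harvest")
        dates = [d for d, _ in self.stages]
        if dates != sorted(dates):
            raise ValueError("Kc stages must be ordered by start date")
        for _, kc in self.stages:
            if not (0.0 < kc <= 1.5):
                raise ValueError(f"Kc out of range (0, 1.5]: {kc}")

    def kc(self, date: _dt.date) -> float | None:
        if not (self.sowing <= date <= self.harvest):
            return None
        current = None
        for start, kc in self.stages:
            if start <= date:
                current = kc
        return current


def sat_vapor_pressure(t_c):
    """e0(T) = 0.6108 exp(17.27 T / (T + 237.3)) [kPa]."""
    t = np.asarray(t_c, dtype=float)
    return 0.6108 * np.exp(17.27 * t / (t + 237.3))


def vapor_terms(met: MetDaily) -> tuple[float, float, float, float]:
    """(es, ea, Delta, gamma) in kPa and kPa/degC.

    es averages the saturation pressure at Tmax and Tmin; ea = es * RH/100;
    Delta is the saturation-curve slope at Tmean; gamma follows from the
    elevation-adjusted barometric pressure.
    """
    es = (sat_vapor_pressure(met.tmax_c) + sat_vapor_pressure(met.tmin_c)) / 2.0
    ea = es * met.rh_pct / 100.0
    delta = 4098.0 * sat_vapor_pressure(met.tmean_c) / (met.tmean_c + 237.3) ** 2
    p = 101.3 * ((293.0 - 0.0065 * met.elev_m) / 293.0) ** 5.26
    gamma = 0.665e-3 * p
    return float(es), float(ea), float(delta), float(gamma)


def pm_radiation(met: MetDaily) -> float:
    """Daily net radiation Rn (MJ m-2 d-1) from sunshine hours.

    Ra from solar geometry; Rs by the Angstrom formula (as=0.25, bs=0.50);
    Rns = 0.77 Rs; Rnl from air temperature, humidity and cloudiness.
    """
    doy = solar.day_of_year(met.date)
    ra = float(solar.extraterrestrial_radiation_daily(met.lat_deg, doy))
    n_max = float(solar.daylength_hours(met.lat_deg, doy))
    if met.sunshine_h > n_max + 1e-9:
        raise ValueError("sunshine hours exceed daylength")
    rel = met.sunshine_h / n_max if n_max > 0 else 0.0
    rs = (ANGSTROM_AS + ANGSTROM_BS * rel) * ra
    rso = (0.75 + 2e-5 * met.elev_m) * ra
    rns = 0.77 * rs
    _, ea, _, _ = vapor_terms(met)
    tmax_k4 = (met.tmax_c + 273.16) ** 4
    tmin_k4 = (met.tmin_c + 273.16) ** 4
    cloud = np.clip(rs / rso, 0.0, 1.0) if rso > 0 else 0.0
    rnl = SIGMA_MJ * (tmax_k4 + tmin_k4) / 2.0 * (0.34 - 0.14 * np.sqrt(ea)) * (1.35 * cloud - 0.35)
    return float(rns - rnl)


def penman_monteith_et0(met: MetDaily, g_mj: float = 0.0) -> float:
    """Daily reference ET0 (mm/d), floored at 0; daily soil heat flux G = 0."""
    es, ea, delta, gamma = vapor_terms(met)
    rn = pm_radiation(met)
    t = met.tmean_c
    u2 = met.wind_2m_ms
    denom = delta + gamma * (1.0 + 0.34 * u2)
    assert denom > 0, "PM denominator must be positive for valid met input"
    num = 0.408 * delta * (rn - g_mj) + gamma * (900.0 / (t + 273.0)) * u2 * (es - ea)
    return max(num / denom, 0.0)


def et0_series(met_df: pd.DataFrame) -> pd.DataFrame:
    """Vectorised ET0 over a station-day table.

    Expects the met CSV columns (station_id, date, tmax_c, tmin_c, tmean_c,
    rh_pct, wind_2m_ms, sunshine_h, precip_mm, elev_m, lat, lon); returns the
    frame with an ``et0_mm`` column appended.
    """
    out = met_df.copy()
    et0 = []
    for row in out.itertuples(index=False):
        met = MetDaily(
            date=pd.Timestamp(row.date).date(),
            tmax_c=row.tmax_c,
            tmin_c=row.tmin_c,
            tmean_c=row.tmean_c,
            rh_pct=row.rh_pct,
            wind_2m_ms=row.wind_2m_ms,
            sunshine_h=row.sunshine_h,
            precip_mm=getattr(row, "precip_mm", 0.0),
            elev_m=row.elev_m,
            lat_deg=row.lat,
        )
        et0.append(penman_monteith_et0(met))
    out["et0_mm"] = et0
    return out


def crop_et(et0: pd.Series, crop: CropConfig) -> pd.Series:
    """ETc = Kc(stage(date)) * ET0; dates outside the crop calendar are NaN.

    ``et0`` must be indexed by date (datetime-like or datetime.date).
    """
    values = {}
    for d, v in et0.items():
        date = pd.Timestamp(d).date()
        kc = crop.kc(date)
        values[d] = kc * v if kc is not None else np.nan
    return pd.Series(values, name=f"etc_{crop.name}")


def validate(pairs: pd.DataFrame) -> pd.DataFrame:
    """Build the validation table from matched PM / SEBAL daily-ET pairs.

    ``pairs`` needs columns (station, date, et_pm, et_sebal). Absolute error
    is |et_sebal - et_pm| (mm/d); relative error is expressed as a percent of
    the SEBAL value. Rows with et_sebal = 0 get a NaN relative error and a
    ``flagged`` mark.
    """
    required = {"station", "date", "et_pm", "et_sebal"}
    missing = required - set(pairs.columns)
    if missing:
        raise ValueError(f"validation input missing column(s): {sorted(missing)}")
    out = pairs.copy()
    out["abs_error"] = (out["et_sebal"] - out["et_pm"]).abs()
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = 100.0 * out["abs_error"] / out["et_sebal"]
    out["rel_error_pct"] = np.where(out["et_sebal"] != 0, rel, np.nan)
    out["flagged"] = out["et_sebal"] == 0
    return out
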