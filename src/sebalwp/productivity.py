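"""Temporal upscaling of evaporative fraction, water productivity and the
WP-environment correlation analysis.

Between satellite overpasses the daily evaporative fraction Lambda_24 is
interpolated per pixel (linear in time, held constant before the first and
after the last overpass) and multiplied by the daily net radiation to give a
daily ET series; monthly and seasonal totals follow by summation. Water
productivity converts zone yields (kg/mu, 1 mu = 666.667 m2) and seasonal ET
(mm) into kg of grain per m3 of water. Pearson correlations between the WP
raster and environmental factors (elevation, temperature, precipitation) are
computed per zone with a two-tailed t-test at the 0.01 level.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .constants import MU_M2, SECONDS_PER_DAY
from .energy import latent_heat_of_vaporization
from .grids import check_aligned, valid_mask

__all__ = [
    "ETSeries",
    "WPResult",
    "interpolate_daily_et",
    "water_productivity",
    "zonal_stats",
    "correlate_wp",
]


@dataclass
class ETSeries:
    dates: list  # every day in the window
    et_daily: np.ndarray  # (days, rows, cols) mm/d
    monthly: dict  # (year, month) -> mm raster
    seasonal: np.ndarray  # mm raster
    lambda_daily_at: dict = field(default_factory=dict)  # date -> interpolated Lambda


@dataclass
class WPResult:
    wp: np.ndarray  # kg/m3
    seasonal_et_mm: np.ndarray
    yield_raster: np.ndarray  # kg/mu
    zonal: pd.DataFrame
    flagged_pixels: int = 0


def _interp_stack(dates: list, stack: np.ndarray, targets: list) -> np.ndarray:
    """Per-pixel linear interpolation in time with boundary hold.

    ``stack`` is (n_overpass, rows, cols); returns (len(targets), rows, cols).
    At an overpass date the overpass grid is returned bit-for-bit.
    """
    t0 = dates[0].toordinal()
    xs = np.array([d.toordinal() - t0 for d in dates], dtype=float)
    out = np.empty((len(targets),) + stack.shape[1:], dtype=stack.dtype)
    lookup = {d: i for i, d in enumerate(dates)}
    for j, day in enumerate(targets):
        if day in lookup:
            out[j] = stack[lookup[day]]  # exact, no arithmetic
            continue
        x = day.toordinal() - t0
        if x <= xs[0]:
            out[j] = stack[0]
        elif x >= xs[-1]:
            out[j] = stack[-1]
        else:
            i = int(np.searchsorted(xs, x)) - 1
            w = (x - xs[i]) / (xs[i + 1] - xs[i])
            out[j] = (1.0 - w) * stack[i] + w * stack[i + 1]
    return out


def interpolate_daily_et(
    overpass_dates: list,
    lambda24_stack: np.ndarray,
    rn24_by_date,
    ts_stack: np.ndarray,
    window: tuple[_dt.date, _dt.date],
) -> ETSeries:
    """Daily-evaporation-ratio interpolation to a daily/monthly/seasonal ET series.

    ``rn24_by_date`` maps each day in the window to a daily-mean net-radiation
    raster (W/m2) or scalar. ``ts_stack`` supplies per-overpass surface
    temperatures for the latent-heat-of-vaporisation term and is interpolated
    alongside Lambda.
    """
    if len(overpass_dates) < 1:
        raise ValueError("at least one overpass is required")
    order = np.argsort([d.toordinal() for d in overpass_dates])
    dates = [overpass_dates[i] for i in order]
    lam = np.asarray(lambda24_stack, dtype=float)[order]
    ts = np.asarray(ts_stack, dtype=float)[order]
    start, end = window
    if dates[0] > end or dates[-1] < start:
        raise ValueError("no overpass inside the requested window")
    days = [d.date() for d in pd.date_range(start, end, freq="D")]

    lam_d = _interp_stack(dates, lam, days)
    ts_d = _interp_stack(dates, ts, days)
    shape = lam.shape[1:]
    et = np.empty((len(days),) + shape)
    for j, day in enumerate(days):
        rn24 = rn24_by_date[day] if not callable(rn24_by_date) else rn24_by_date(day)
        rn24 = np.asarray(rn24, dtype=float)
        lv = latent_heat_of_vaporization(ts_d[j])
        et[j] = np.maximum(SECONDS_PER_DAY * lam_d[j] * rn24 / lv, 0.0)

    monthly: dict = {}
    for j, day in enumerate(days):
        key = (day.year, day.month)
        monthly.setdefault(key, np.zeros(shape))
        monthly[key] = monthly[key] + et[j]
    # seasonal as the sum of monthly totals so the additivity is exact in
    # floating point, not just to rounding
    seasonal = sum(monthly.values())
    lam_at = {d: lam_d[days.index(d)] for d in dates if start <= d <= end}
    return ETSeries(dates=days, et_daily=et, monthly=monthly, seasonal=seasonal, lambda_daily_at=lam_at)


def water_productivity(
    yields: pd.DataFrame | np.ndarray,
    seasonal_et_mm: np.ndarray,
    zones: np.ndarray | None = None,
    crop_mask: np.ndarray | None = None,
) -> WPResult:
    """WP [kg/m3] = (yield / mu-area) / (ET depth in m).

    ``yields`` is either a per-pixel kg/mu raster or a (zone_id,
    yield_kg_per_mu) table combined with ``zones``. Cropped pixels with zero
    or invalid ET are masked and counted in ``flagged_pixels``.
    """
    et = np.asarray(seasonal_et_mm, dtype=float)
    if isinstance(yields, pd.DataFrame):
        if zones is None:
            raise ValueError("a zone raster is required with a zone-yield table")
        check_aligned(et, zones)
        yr = np.full(et.shape, np.nan)
        for row in yields.itertuples(index=False):
            yr[zones == row.zone_id] = row.yield_kg_per_mu
    else:
        yr = np.asarray(yields, dtype=float)
        check_aligned(et, yr)
    if np.any(yr[np.isfinite(yr)] < 0):
        raise ValueError("yields must be non-negative")

    ok = valid_mask(et, yr)
    if crop_mask is not None:
        ok &= np.asarray(crop_mask, dtype=bool)
    bad = ok & ~(et > 0)
    ok &= et > 0
    wp = np.full(et.shape, np.nan)
    wp[ok] = (yr[ok] / MU_M2) / (et[ok] / 1000.0)
    zonal = zonal_stats(wp, zones) if zones is not None else pd.DataFrame()
    return WPResult(wp=wp, seasonal_et_mm=et, yield_raster=yr, zonal=zonal, flagged_pixels=int(bad.sum()))


def zonal_stats(values: np.ndarray, zones: np.ndarray) -> pd.DataFrame:
    """Per-zone mean/min/max/count over valid pixels; empty zones are omitted."""
    values = np.asarray(values, dtype=float)
    zones = np.asarray(zones)
    check_aligned(values, zones)
    rows = []
    for z in np.unique(zones):
        if z <= 0:
            continue
        sel = (zones == z) & np.isfinite(values)
        if not sel.any():
            continue
        v = values[sel]
        rows.append({"zone_id": int(z), "mean": v.mean(), "min": v.min(), "max": v.max(), "count": int(sel.sum())})
    return pd.DataFrame(rows)


def correlate_wp(
    wp: np.ndarray,
    factors: dict,
    zones: np.ndarray,
    alpha: float = 0.01,
    min_pixels: int = 10,
) -> pd.DataFrame:
    """Pearson correlation of WP against each factor raster, per zone.

    Returns one row per (zone, factor) with r, the two-tailed p-value and a
    significance flag at ``alpha``. Zones with fewer than ``min_pixels``
    joint-valid pixels, or a zero-variance variable, yield a flagged row with
    NaN statistics.
    """
    wp = np.asarray(wp, dtype=float)
    zones = np.asarray(zones)
    for name, f in factors.items():
        check_aligned(wp, f, zones)
    rows = []
    for z in np.unique(zones):
        if z <= 0:
            continue
        in_zone = zones == z
        for name, f in factors.items():
            f = np.asarray(f, dtype=float)
            sel = in_zone & valid_mask(wp, f)
            n = int(sel.sum())
            if n < min_pixels or np.std(wp[sel]) == 0 or np.std(f[sel]) == 0:
                rows.append({"zone_id": int(z), "factor": name, "r": np.nan, "p": np.nan,
                             "n": n, "significant": False, "flagged": True})
                continue
            r, p = stats.pearsonr(wp[sel], f[sel])
            rows.append({"zone_id": int(z), "factor": name, "r": float(r), "p": float(p),
                         "n": n, "significant": bool(p < alpha), "flagged": False})
    return pd.DataFrame(rows)
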