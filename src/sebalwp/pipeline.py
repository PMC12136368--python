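"""End-to-end driver: scenes -> surface parameters -> energy balance ->
temporal upscaling -> water productivity -> validation -> manifest.

Every raster in a run must sit on one grid; the driver rejects mismatches at
ingestion. All algorithm switches actually used, anchor diagnostics, stage
timings and output checksums are recorded in a JSON run manifest so a run is
reproducible from its manifest alone.
"""

from __future__ import annotations

import datetime as _dt
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .constants import MJ_DAY_TO_W
from .energy import compute_fluxes, daily_et
from .fao56 import MetDaily, penman_monteith_et0, pm_radiation, validate
from .grids import GridGeometry
from .io import (
    PipelineConfig,
    read_met_daily,
    read_met_instant,
    read_raster,
    read_scene,
    read_yields,
    sha256_of,
    write_raster,
)
from .metgrid import grid_met
from .productivity import correlate_wp, interpolate_daily_et, water_productivity
from .surface import derive_surface_fields

logger = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_pipeline"]


@dataclass
class RunManifest:
    config: dict
    version: str = __version__
    timings_s: dict = field(default_factory=dict)
    anchors: dict = field(default_factory=dict)
    warnings: list = field(default_factory=list)
    outputs: dict = field(default_factory=dict)  # path -> sha256
    completed: bool = False

    def write(self, path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=1, default=str))


def _station_pixel(geometry: GridGeometry, x: float, y: float) -> tuple[int, int]:
    col = int(round((x - geometry.origin_x) / geometry.cell_size - 0.5))
    row = int(round((geometry.origin_y - y) / geometry.cell_size - 0.5))
    row = min(max(row, 0), geometry.rows - 1)
    col = min(max(col, 0), geometry.cols - 1)
    return row, col


def _nearest_station(inst: pd.DataFrame, date, geometry: GridGeometry) -> pd.Series:
    day = inst[inst["date"] == date]
    if day.empty:
        raise ValueError(f"no instantaneous met record for overpass date {date}")
    cx = geometry.origin_x + geometry.cols * geometry.cell_size / 2.0
    cy = geometry.origin_y - geometry.rows * geometry.cell_size / 2.0
    d2 = (day["x_m"] - cx) ** 2 + (day["y_m"] - cy) ** 2
    return day.loc[d2.idxmin()]


def _met_daily_records(df: pd.DataFrame) -> list[MetDaily]:
    out = []
    for r in df.itertuples(index=False):
        out.append(
            MetDaily(
                date=r.date, tmax_c=r.tmax_c, tmin_c=r.tmin_c, tmean_c=r.tmean_c,
                rh_pct=r.rh_pct, wind_2m_ms=r.wind_2m_ms, sunshine_h=r.sunshine_h,
                precip_mm=r.precip_mm, elev_m=r.elev_m, lat_deg=r.lat,
            )
        )
    return out


def run_pipeline(config: PipelineConfig) -> RunManifest:
    manifest = RunManifest(config=config.to_dict())
    outdir = Path(config.out)
    outdir.mkdir(parents=True, exist_ok=True)
    t_start = time.perf_counter()

    def _tick(stage: str, t0: float) -> float:
        manifest.timings_s[stage] = round(time.perf_counter() - t0, 4)
        return time.perf_counter()

    try:
        t0 = time.perf_counter()
        dem, geometry, _ = read_raster(config.dem)
        zones_f, _, _ = read_raster(config.zones, expect_geometry=geometry)
        zones = zones_f.astype(int)
        scenes = [read_scene(p) for p in config.scenes]
        for sc in scenes:
            if sc.geometry != geometry:
                raise ValueError(f"scene grid differs from DEM grid")
        met_daily = read_met_daily(config.met_daily)
        met_inst = read_met_instant(config.met_instant)
        yields = read_yields(config.yields)
        t0 = _tick("ingest", t0)

        # --- per-scene energy balance ---
        overpass_dates, lam_stack, ts_stack, et24_maps = [], [], [], {}
        for sc in sorted(scenes, key=lambda s: s.date):
            surf = derive_surface_fields(sc)
            st = _nearest_station(met_inst, sc.date, geometry)
            fluxes, pair = compute_fluxes(
                surf,
                date=sc.date,
                overpass_time=sc.overpass_time,
                latitude_deg=sc.latitude,
                ta_k=float(st["ta_c"]) + 273.15,
                u_station=float(st["wind_2m_ms"]),
                elevation_m=dem,
                stability=config.stability,
                cold_ndvi_quantile=config.cold_ndvi_quantile,
                hot_ndvi_quantile=config.hot_ndvi_quantile,
            )
            manifest.anchors[sc.date.isoformat()] = {
                "cold": list(pair.cold), "hot": list(pair.hot),
                "ts_cold": pair.ts_cold, "ts_hot": pair.ts_hot,
                "dt_a": pair.dt_a, "dt_b": pair.dt_b,
                "iterations": pair.iterations, "converged": pair.converged,
            }
            if not pair.converged:
                manifest.warnings.append(f"{sc.date}: stability loop not converged")
            overpass_dates.append(sc.date)
            lam_stack.append(fluxes.lambda_inst)
            ts_stack.append(surf.lst)
            p = outdir / f"lambda_{sc.date.isoformat()}.tif"
            write_raster(p, fluxes.lambda_inst, geometry, ["lambda24"])
            manifest.outputs[str(p)] = sha256_of(p)
        t0 = _tick("energy_balance", t0)

        # --- daily net radiation grids from station met ---
        start = _dt.date.fromisoformat(config.season_start) if config.season_start else min(overpass_dates)
        end = _dt.date.fromisoformat(config.season_end) if config.season_end else max(overpass_dates)
        season = met_daily[(met_daily["date"] >= start) & (met_daily["date"] <= end)]
        rn24_by_date = {}
        for date, day_df in season.groupby("date"):
            st = day_df.copy()
            st["rn24_w"] = [pm_radiation(m) * MJ_DAY_TO_W for m in _met_daily_records(st)]
            rn24_by_date[date] = grid_met(st, dem, geometry, "rn24_w")
        missing_days = [d.date() for d in pd.date_range(start, end, freq="D") if d.date() not in rn24_by_date]
        if missing_days:
            raise ValueError(f"met series does not cover the season: {len(missing_days)} day(s) missing")
        t0 = _tick("rn24_gridding", t0)

        # --- temporal upscaling and water productivity ---
        series = interpolate_daily_et(
            overpass_dates, np.stack(lam_stack), rn24_by_date, np.stack(ts_stack), (start, end)
        )
        p = outdir / "seasonal_et.tif"
        write_raster(p, series.seasonal, geometry, ["seasonal_et_mm"])
        manifest.outputs[str(p)] = sha256_of(p)

        wp_res = water_productivity(yields, series.seasonal, zones=zones)
        p = outdir / "wp.tif"
        write_raster(p, wp_res.wp, geometry, ["wp_kg_m3"])
        manifest.outputs[str(p)] = sha256_of(p)
        p = outdir / "wp_zonal.csv"
        wp_res.zonal.to_csv(p, index=False)
        manifest.outputs[str(p)] = sha256_of(p)
        t0 = _tick("water_productivity", t0)

        # --- WP vs environment ---
        st_mean = season.groupby("station_id").agg(
            {"tmean_c": "mean", "precip_mm": "sum", "x_m": "first", "y_m": "first", "elev_m": "first"}
        ).reset_index()
        t_grid = grid_met(st_mean, dem, geometry, "tmean_c")
        p_grid = grid_met(st_mean, dem, geometry, "precip_mm")
        corr = correlate_wp(wp_res.wp, {"dem": dem, "temperature": t_grid, "precipitation": p_grid}, zones)
        p = outdir / "wp_correlation.csv"
        corr.to_csv(p, index=False)
        manifest.outputs[str(p)] = sha256_of(p)
        t0 = _tick("correlation", t0)

        # --- Penman-Monteith validation at the stations ---
        rows = []
        day_index = {d: i for i, d in enumerate(series.dates)}
        if not {"x_m", "y_m"} <= set(met_daily.columns):
            manifest.warnings.append("met CSV lacks x_m/y_m station coordinates; validation table skipped")
            overpass_dates = []
        for date in overpass_dates:
            day_df = met_daily[met_daily["date"] == date]
            for r in day_df.itertuples(index=False):
                met = MetDaily(
                    date=r.date, tmax_c=r.tmax_c, tmin_c=r.tmin_c, tmean_c=r.tmean_c,
                    rh_pct=r.rh_pct, wind_2m_ms=r.wind_2m_ms, sunshine_h=r.sunshine_h,
                    precip_mm=r.precip_mm, elev_m=r.elev_m, lat_deg=r.lat,
                )
                row, col = _station_pixel(geometry, r.x_m, r.y_m)
                et_seb = float(series.et_daily[day_index[date], row, col])
                rows.append({
                    "station": r.station_id, "date": date,
                    "et_pm": config.validation_kc * penman_monteith_et0(met),
                    "et_sebal": et_seb,
                })
        vtable = validate(pd.DataFrame(rows)) if rows else pd.DataFrame()
        p = outdir / "validation.csv"
        vtable.to_csv(p, index=False)
        manifest.outputs[str(p)] = sha256_of(p)
        manifest.timings_s["total"] = round(time.perf_counter() - t_start, 4)
        _tick("validation", t0)
        manifest.completed = True
    finally:
        manifest.write(outdir / "manifest.json")
    return manifest
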