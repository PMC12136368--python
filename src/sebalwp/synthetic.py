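"""Synthetic scenes, meteorology and yield tables with known ground truth.

The generator is the test bed for the whole retrieval chain. It prescribes a
smooth evaporative-fraction field Lambda (Gaussian bumps on a northeast-to-
southwest gradient, mimicking a real landscape), plants one ideal cold anchor
(Lambda = 1: maximum NDVI, minimum surface temperature) and one ideal hot
anchor (Lambda = 0: minimum NDVI, maximum surface temperature), and then
*inverts* the same energy-balance equations the retrieval uses to find the
surface-temperature field that makes the prescribed Lambda the exact answer.
Reflectance bands are synthesised so the NDVI and broadband-albedo retrievals
reproduce the intended surface fields; the thermal band is the brightness
temperature whose emissivity correction returns the constructed Ts.

On a zero-noise scene the retrieval must therefore return Lambda equal to
the truth to numerical precision - that property is the pipeline's core
oracle. Gaussian sensor noise (reflectance and thermal) can be layered on
top to emulate realistic acquisitions.

What the generator does NOT emulate: atmospheric path radiance, clouds
beyond a binary mask, sensor PSF/adjacency, topographic illumination.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import solar
from .constants import CP_AIR, MJ_DAY_TO_W, SECONDS_PER_DAY, STEFAN_BOLTZMANN
from .energy import (
    latent_heat_of_vaporization,
    net_radiation,
    sensible_heat,
    shortwave_down,
    soil_heat_flux,
)
from .fao56 import MetDaily, pm_radiation
from .grids import GridGeometry
from .surface import (
    SceneStack,
    bt_from_lst,
    compute_albedo,
    compute_emissivity,
    compute_roughness,
)

__all__ = ["SynthConfig", "SceneTruth", "generate_scene", "generate_met", "generate_yield", "generate_zones", "generate_bundle"]


@dataclass(frozen=True)
class SynthConfig:
    """All knobs of the synthetic study conditions; one seed fixes everything."""

    rows: int = 100
    cols: int = 100
    cell_size: float = 30.0  # m
    date: _dt.date = _dt.date(2020, 8, 10)
    overpass_time: float = 10.5  # local solar decimal hours
    latitude: float = 37.8  # deg N
    seed: int = 42
    ndvi_range: tuple = (0.05, 0.85)
    ts_range: tuple = (290.0, 315.0)  # K, cold/hot anchor surface temperatures
    reflectance_noise: float = 0.004  # 1-sigma, reflectance fraction (OLI-class SNR)
    thermal_noise_k: float = 0.1  # 1-sigma, K: white sensor noise (TIRS-class NEdT)
    lambda_constant: float | None = None  # degenerate uniform-Lambda scene
    base_elev_m: float = 800.0
    relief_m: float = 150.0
    n_stations: int = 5
    season: tuple = (_dt.date(2020, 4, 1), _dt.date(2020, 9, 30))
    revisit_days: int = 16
    n_zones: int = 5
    # station meteorology (daily means; a seasonal cosine of amplitude
    # met_seasonal_amp_c modulates the temperatures deterministically)
    met_tmax_c: float = 29.0
    met_tmin_c: float = 17.0
    met_rh_pct: float = 55.0
    met_wind_ms: float = 2.2
    met_sunshine_frac: float = 0.65  # fraction of daylength
    met_precip_mm: float = 1.6  # daily mean
    met_seasonal_amp_c: float = 6.0
    met_temp_noise_c: float = 1.5
    met_rh_noise: float = 8.0
    met_wind_noise: float = 0.6
    met_sun_noise: float = 0.12
    overpass_ta_offset_c: float = 3.0  # Ta at overpass above daily mean
    # zone yields (kg/mu)
    yield_range: tuple = (386.794, 754.896)
    yield_mean: float = 577.046
    yield_std: float = 60.0

    def __post_init__(self) -> None:
        if self.rows < 10 or self.cols < 10:
            raise ValueError("grid must be at least 10 x 10 to place distinct anchors")
        lo, hi = self.ndvi_range
        if not (-1.0 <= lo < hi <= 1.0):
            raise ValueError("ndvi_range must be an increasing pair within [-1, 1]")
        tlo, thi = self.ts_range
        if not (250.0 <= tlo < thi <= 340.0):
            raise ValueError("ts_range must be an increasing pair within [250, 340] K")
        if self.met_tmax_c < self.met_tmin_c:
            raise ValueError("configured Tmax is below Tmin")
        if not (0.0 <= self.met_rh_pct <= 100.0):
            raise ValueError("relative humidity outside [0, 100]")
        if not (0.0 <= self.met_sunshine_frac <= 1.0):
            raise ValueError("sunshine fraction outside [0, 1]")
        for name in ("reflectance_noise", "thermal_noise_k", "met_temp_noise_c",
                     "met_rh_noise", "met_wind_noise", "met_sun_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        ylo, yhi = self.yield_range
        if not (0.0 < ylo < yhi):
            raise ValueError("yield_range must be an increasing positive pair")
        if self.n_stations < 1:
            raise ValueError("at least one met station required")
        if self.n_zones < 1:
            raise ValueError("at least one zone required")

    @property
    def geometry(self) -> GridGeometry:
        return GridGeometry(rows=self.rows, cols=self.cols, cell_size=self.cell_size)


@dataclass
class SceneTruth:
    """Ground truth planted in one synthetic scene."""

    lambda_true: np.ndarray  # evaporative fraction in [0, 1]
    et24_true: np.ndarray  # mm/d under noise-free met
    anchor_cold_index: tuple[int, int]
    anchor_hot_index: tuple[int, int]
    ts_true: np.ndarray | None = None  # constructed surface temperature (K)
    ndvi_true: np.ndarray | None = None
    albedo_true: np.ndarray | None = None
    rn24_true_w: float = float("nan")


def _unit_coords(rows: int, cols: int) -> tuple[np.ndarray, np.ndarray]:
    rr, cc = np.mgrid[0:rows, 0:cols]
    return rr / max(rows - 1, 1), cc / max(cols - 1, 1)


def _smooth_bumps(rng: np.random.Generator, shape, n_bumps: int = 4, amp: float = 1.0) -> np.ndarray:
    """Sum of random 2-D Gaussian bumps on the unit square."""
    rn, cn = _unit_coords(*shape)
    f = np.zeros(shape)
    for _ in range(n_bumps):
        r0, c0 = rng.uniform(0.0, 1.0, size=2)
        s = rng.uniform(0.15, 0.40)
        a = rng.uniform(-1.0, 1.0) * amp
        f += a * np.exp(-((rn - r0) ** 2 + (cn - c0) ** 2) / (2.0 * s**2))
    return f


def _minmax(f: np.ndarray, lo: float, hi: float) -> np.ndarray:
    fmin, fmax = f.min(), f.max()
    if fmax == fmin:
        return np.full_like(f, (lo + hi) / 2.0)
    return lo + (hi - lo) * (f - fmin) / (fmax - fmin)


def _place_anchors(rng: np.random.Generator, rows: int, cols: int) -> tuple[tuple[int, int], tuple[int, int]]:
    """Two interior pixels, well separated (cold toward SW, hot toward NE)."""
    min_sep2 = (0.4 * min(rows, cols)) ** 2
    for _ in range(100):
        cr = int(rng.integers(rows // 2, rows - 2))
        ccol = int(rng.integers(1, cols // 2))
        hr = int(rng.integers(1, rows // 2))
        hcol = int(rng.integers(cols // 2, cols - 2))
        if (cr - hr) ** 2 + (ccol - hcol) ** 2 >= min_sep2:
            return (cr, ccol), (hr, hcol)
    raise ValueError("grid too small to place distinct anchor pixels")


def met_means_at(config: SynthConfig, date: _dt.date) -> dict:
    """Deterministic (noise-free) station meteorology for one day.

    Temperatures follow a seasonal cosine peaking around mid-July; the other
    elements sit at their configured means.
    """
    doy = solar.day_of_year(date)
    seas = config.met_seasonal_amp_c * np.cos(2.0 * np.pi * (doy - 200) / 365.0)
    n_max = float(solar.daylength_hours(config.latitude, doy))
    return {
        "tmax_c": config.met_tmax_c + seas,
        "tmin_c": config.met_tmin_c + seas,
        "tmean_c": (config.met_tmax_c + config.met_tmin_c) / 2.0 + seas,
        "rh_pct": config.met_rh_pct,
        "wind_2m_ms": config.met_wind_ms,
        "sunshine_h": config.met_sunshine_frac * n_max,
        "precip_mm": config.met_precip_mm,
        "daylength_h": n_max,
    }


def _rn24_true_w(config: SynthConfig, elev_m: float) -> float:
    """Daily net radiation (W/m2) under the noise-free met for the scene date."""
    m = met_means_at(config, config.date)
    met = MetDaily(
        date=config.date,
        tmax_c=m["tmax_c"],
        tmin_c=m["tmin_c"],
        tmean_c=m["tmean_c"],
        rh_pct=m["rh_pct"],
        wind_2m_ms=m["wind_2m_ms"],
        sunshine_h=m["sunshine_h"],
        elev_m=elev_m,
        lat_deg=config.latitude,
    )
    return pm_radiation(met) * MJ_DAY_TO_W


def generate_dem(config: SynthConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth terrain, higher toward the northeast (row 0, last column)."""
    rn, cn = _unit_coords(config.rows, config.cols)
    trend = ((1.0 - rn) + cn) / 2.0  # 1 at NE corner, 0 at SW corner
    dem = config.base_elev_m + config.relief_m * (2.0 * trend - 1.0)
    dem += _smooth_bumps(rng, (config.rows, config.cols), n_bumps=3, amp=0.2 * config.relief_m)
    return dem


def _invert_ts_for_lambda(
    lam_true: np.ndarray,
    ndvi: np.ndarray,
    albedo: np.ndarray,
    emissivity: np.ndarray,
    z0m: np.ndarray,
    dem: np.ndarray,
    config: SynthConfig,
    anchors,
    ta_k: float,
    u2: float,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Surface-temperature field whose energy-balance retrieval returns lam_true.

    Newton iteration on Ts per pixel, running the *actual* retrieval forward
    model (including anchor calibration and the stability loop) at each step,
    so the constructed scene is exact with respect to the code that will be
    tested against it.

    The hot anchor bounds the achievable dryness: a pixel with more available
    energy than the hot anchor cannot be made drier than the calibration line
    allows while keeping the anchor the warmest pixel. Where a prescribed
    Lambda is physically unreachable (the pixel pins at the temperature cap),
    the *truth is adjusted* to the achieved value - the returned lam field is
    the authoritative ground truth.

    Returns (ts, lam) with lam possibly adjusted at pinned pixels.
    """
    ts_cold, ts_hot = config.ts_range
    (cr, cc), (hr, hc) = anchors
    lam = lam_true.copy()
    ts = ts_cold + (1.0 - lam) * (ts_hot - ts_cold)
    ts[cr, cc] = ts_cold
    ts[hr, hc] = ts_hot
    rs = shortwave_down(config.date, config.overpass_time, config.latitude, dem)
    lo, hi = ts_cold + 1e-3, ts_hot - 1e-3
    for _ in range(max_iter):
        rad = net_radiation(albedo, rs, ts, ta_k, emissivity, dem)
        g = soil_heat_flux(ts, albedo, ndvi, rad.rn)
        h, pair, diag = sensible_heat(
            ts, z0m, u2, anchors, rad.rn, g,
            ta_k=ta_k, elevation_m=dem, return_diagnostics=True,
        )
        avail = rad.rn - g
        lam_rec = (avail - h) / avail
        err = lam_rec - lam
        if float(np.nanmax(np.abs(err))) < tol:
            break
        # d(lambda)/d(Ts): sensible-heat slope plus the available-energy feedback
        h_prime = diag["rho"] * CP_AIR * pair.dt_b / diag["rah"]
        avail_prime = -4.0 * emissivity * STEFAN_BOLTZMANN * ts**3
        slope = (-h_prime + h * avail_prime / avail) / avail
        step = np.clip(err / slope, -5.0, 5.0)
        pinned = ((ts >= hi) & (step < 0)) | ((ts <= lo) & (step > 0))
        if bool(np.all(pinned | (np.abs(err) < tol))):
            # remaining misfit sits entirely on boundary-limited pixels:
            # accept the achievable Lambda there as the truth
            lam = np.where(pinned, np.clip(lam_rec, 0.0, 1.0), lam)
            lam[cr, cc], lam[hr, hc] = 1.0, 0.0
            err = lam_rec - lam
            if float(np.nanmax(np.abs(err))) < tol:
                break
        ts = ts - step
        ts = np.clip(ts, lo, hi)
        ts[cr, cc] = ts_cold
        ts[hr, hc] = ts_hot
    else:
        raise RuntimeError("energy-balance inversion did not converge; scene configuration infeasible")
    return ts, lam


def generate_scene(config: SynthConfig, dem: np.ndarray | None = None) -> tuple[SceneStack, SceneTruth, np.ndarray]:
    """Build one acquisition: (SceneStack, SceneTruth, DEM raster).

    Identical config (including seed) gives bit-identical output. ``dem``
    lets a multi-scene bundle share one terrain; by default the scene draws
    its own.
    """
    rng = np.random.default_rng(config.seed)
    rows, cols = config.rows, config.cols
    shape = (rows, cols)
    rn_u, cn_u = _unit_coords(rows, cols)

    dem_own = generate_dem(config, rng)  # rng draws consumed either way
    if dem is None:
        dem = dem_own
    anchors = _place_anchors(rng, rows, cols)
    (cr, cc), (hr, hc) = anchors

    # --- evaporative-fraction truth: NE -> SW increasing gradient + bumps ---
    gradient = (rn_u + (1.0 - cn_u)) / 2.0  # 0 at NE corner, 1 at SW corner
    lam = 0.15 + 0.70 * gradient + _smooth_bumps(rng, shape, n_bumps=4, amp=0.35)
    lam = _minmax(lam, 0.05, 0.95)  # interior strictly inside (0, 1)
    degenerate = config.lambda_constant is not None
    if degenerate:
        lam = np.full(shape, float(config.lambda_constant))
    else:
        lam[cr, cc] = 1.0  # planted cold anchor
        lam[hr, hc] = 0.0  # planted hot anchor

    # --- NDVI truth: tracks moisture, planted extremes at the anchors ---
    nd_lo, nd_hi = config.ndvi_range
    margin = 0.02 * (nd_hi - nd_lo)
    ndvi = lam + 0.15 * _smooth_bumps(rng, shape, n_bumps=3, amp=1.0)
    ndvi = _minmax(ndvi, nd_lo + margin, nd_hi - margin)
    ndvi[cr, cc] = nd_hi
    ndvi[hr, hc] = nd_lo

    # --- reflectance bands realising NDVI and a smooth albedo target ---
    s_vis = 0.35  # red + nir total
    red = s_vis / 2.0 * (1.0 - ndvi)
    nir = s_vis / 2.0 * (1.0 + ndvi)
    blue = 0.5 * red
    green = 0.65 * red
    lam_s = _minmax(lam, 0.0, 1.0)
    albedo_target = 0.24 - 0.08 * lam_s + _smooth_bumps(rng, shape, n_bumps=2, amp=0.01)
    swir = (albedo_target + 0.0018 - 0.356 * blue - 0.130 * red - 0.373 * nir) / (0.085 + 0.072)
    swir = np.clip(swir, 0.0, 1.0)
    bands = {"blue": blue, "green": green, "red": red, "nir": nir, "swir1": swir, "swir2": swir}
    albedo = compute_albedo(bands)  # realised truth
    emissivity = compute_emissivity(ndvi)
    z0m = compute_roughness(ndvi, albedo)

    # --- overpass meteorology (noise-free values; the forward model input) ---
    means = met_means_at(config, config.date)
    ta_k = means["tmean_c"] + config.overpass_ta_offset_c + 273.15
    u2 = means["wind_2m_ms"]

    # --- surface temperature consistent with the prescribed Lambda ---
    ts_cold, ts_hot = config.ts_range
    if degenerate:
        ts = np.full(shape, (ts_cold + ts_hot) / 2.0)
    else:
        ts, lam = _invert_ts_for_lambda(
            lam, ndvi, albedo, emissivity, z0m, dem, config, anchors, ta_k, u2
        )

    bt = bt_from_lst(ts, emissivity)

    # --- sensor noise (draws always consumed, so the rng stream is stable) ---
    for name in ("blue", "green", "red", "nir", "swir1", "swir2"):
        noise = rng.normal(0.0, 1.0, size=shape)
        bands[name] = np.clip(bands[name] + config.reflectance_noise * noise, 0.0, 1.0)
    bt_noise = rng.normal(0.0, 1.0, size=shape)
    bt = bt + config.thermal_noise_k * bt_noise
    # swir bands must stay independent observations
    bands["swir2"] = np.clip(
        swir + config.reflectance_noise * rng.normal(0.0, 1.0, size=shape), 0.0, 1.0
    )

    scene = SceneStack(
        bands=bands,
        thermal=bt,
        geometry=config.geometry,
        date=config.date,
        overpass_time=config.overpass_time,
        latitude=config.latitude,
    )

    rn24_w = _rn24_true_w(config, float(dem.mean()))
    lv = latent_heat_of_vaporization(ts)
    et24 = np.maximum(SECONDS_PER_DAY * lam * rn24_w / lv, 0.0)
    truth = SceneTruth(
        lambda_true=lam,
        et24_true=et24,
        anchor_cold_index=(cr, cc),
        anchor_hot_index=(hr, hc),
        ts_true=ts,
        ndvi_true=ndvi,
        albedo_true=albedo,
        rn24_true_w=rn24_w,
    )
    return scene, truth, dem


def generate_met(config: SynthConfig, dem: np.ndarray | None = None) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Station daily series over the season plus overpass-time records.

    Returns (daily, instant) DataFrames. Daily columns follow the met CSV
    contract (station_id, date, tmax_c, tmin_c, tmean_c, rh_pct, wind_2m_ms,
    sunshine_h, precip_mm, elev_m, lat, lon) plus local grid coordinates
    x_m/y_m used for spatial interpolation.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 7]))
    geom = config.geometry
    if dem is None:
        dem = generate_dem(config, np.random.default_rng(config.seed))

    rows_out = []
    inst_out = []
    start, end = config.season
    dates = pd.date_range(start, end, freq="D")
    doys = np.array([d.timetuple().tm_yday for d in dates.date])
    seas = config.met_seasonal_amp_c * np.cos(2.0 * np.pi * (doys - 200) / 365.0)
    n_max = np.array([float(solar.daylength_hours(config.latitude, int(j))) for j in doys])

    for s in range(config.n_stations):
        srow = int(rng.integers(0, config.rows))
        scol = int(rng.integers(0, config.cols))
        x, y = geom.cell_center(srow, scol)
        elev = float(dem[srow, scol])
        lat = config.latitude + (srow - config.rows / 2) * geom.cell_size / -111000.0
        lon = 112.0 + (scol - config.cols / 2) * geom.cell_size / 88000.0

        nd = len(dates)
        tmean = (config.met_tmax_c + config.met_tmin_c) / 2.0 + seas + rng.normal(0, config.met_temp_noise_c, nd)
        half = (config.met_tmax_c - config.met_tmin_c) / 2.0
        spread_hi = np.abs(rng.normal(half, config.met_temp_noise_c / 2.0, nd)) + 0.1
        spread_lo = np.abs(rng.normal(half, config.met_temp_noise_c / 2.0, nd)) + 0.1
        tmax = tmean + spread_hi
        tmin = tmean - spread_lo
        rh = np.clip(config.met_rh_pct + rng.normal(0, config.met_rh_noise, nd), 2.0, 100.0)
        wind = np.maximum(config.met_wind_ms + rng.normal(0, config.met_wind_noise, nd), 0.1)
        sun_frac = np.clip(config.met_sunshine_frac + rng.normal(0, config.met_sun_noise, nd), 0.0, 1.0)
        sunshine = sun_frac * n_max
        if config.met_temp_noise_c == 0 and config.met_rh_noise == 0 and config.met_wind_noise == 0 and config.met_sun_noise == 0:
            precip = np.full(nd, config.met_precip_mm)
        else:
            wet = rng.random(nd) < 0.35
            precip = np.where(wet, rng.gamma(1.2, config.met_precip_mm / 0.35 / 1.2, nd), 0.0)
        df = pd.DataFrame(
            {
                "station_id": f"S{s:02d}",
                "date": dates.date,
                "tmax_c": tmax,
                "tmin_c": tmin,
                "tmean_c": tmean,
                "rh_pct": rh,
                "wind_2m_ms": wind,
                "sunshine_h": sunshine,
                "precip_mm": precip,
                "elev_m": elev,
                "lat": lat,
                "lon": lon,
                "x_m": float(np.asarray(x)),
                "y_m": float(np.asarray(y)),
            }
        )
        rows_out.append(df)

        # instantaneous records at every candidate overpass date
        for d in overpass_dates(config):
            i = int(np.searchsorted(dates.date, d))
            inst_out.append(
                {
                    "station_id": f"S{s:02d}",
                    "date": d,
                    "time_h": config.overpass_time,
                    "ta_c": float(tmean[i] + config.overpass_ta_offset_c),
                    "wind_2m_ms": float(wind[i]),
                    "elev_m": elev,
                    "lat": lat,
                    "lon": lon,
                    "x_m": float(np.asarray(x)),
                    "y_m": float(np.asarray(y)),
                }
            )

    daily = pd.concat(rows_out, ignore_index=True)
    instant = pd.DataFrame(inst_out)
    return daily, instant


def overpass_dates(config: SynthConfig) -> list[_dt.date]:
    """Satellite revisit dates inside the season, anchored on the scene date."""
    start, end = config.season
    step = _dt.timedelta(days=config.revisit_days)
    d = config.date
    while d - step >= start:
        d -= step
    out = []
    while d <= end:
        out.append(d)
        d += step
    return out


def generate_zones(config: SynthConfig) -> np.ndarray:
    """Integer zone raster: n_zones vertical bands (1..n), 0 = nodata."""
    _, cn_u = _unit_coords(config.rows, config.cols)
    zones = np.minimum((cn_u * config.n_zones).astype(int) + 1, config.n_zones)
    return zones


def generate_yield(zones: np.ndarray, config: SynthConfig) -> pd.DataFrame:
    """Zone -> yield (kg/mu) table, drawn within the configured range."""
    ids = np.unique(zones)
    ids = ids[ids > 0]
    if ids.size == 0:
        raise ValueError("zone raster contains no zones")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    lo, hi = config.yield_range
    draws = rng.normal(config.yield_mean, config.yield_std, size=ids.size) if config.yield_std > 0 else np.full(ids.size, config.yield_mean)
    draws = np.clip(draws, lo, hi)
    return pd.DataFrame({"zone_id": ids.astype(int), "yield_kg_per_mu": draws})


def generate_bundle(config: SynthConfig, outdir) -> dict:
    """Write a complete input bundle (scenes for every overpass, DEM, zones,
    met CSVs, yield CSV) and return the paths plus in-memory truths."""
    from . import io as _io
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    dates = overpass_dates(config)
    scene_paths = []
    truths = {}
    dem = generate_dem(config, np.random.default_rng(config.seed))
    for i, d in enumerate(dates):
        cfg_d = replace(config, date=d, seed=int(np.random.default_rng(
            np.random.SeedSequence([config.seed, 1000 + i])).integers(0, 2**31 - 1)))
        scene, truth, _ = generate_scene(cfg_d, dem=dem)
        p = outdir / f"scene_{d.isoformat()}.tif"
        _io.write_scene(scene, p)
        truths[d] = truth
        scene_paths.append(p)
        _io.write_raster(outdir / f"truth_lambda_{d.isoformat()}.tif", truth.lambda_true, config.geometry, ["lambda_true"])

    _io.write_raster(outdir / "dem.tif", dem, config.geometry, ["elevation_m"])
    zones = generate_zones(config)
    _io.write_raster(outdir / "zones.tif", zones.astype(float), config.geometry, ["zone_id"])
    daily, instant = generate_met(config, dem)
    daily.to_csv(outdir / "met_daily.csv", index=False)
    instant.to_csv(outdir / "met_instant.csv", index=False)
    yields = generate_yield(zones, config)
    yields.to_csv(outdir / "yields.csv", index=False)
    return {
        "scenes": scene_paths,
        "dem": outdir / "dem.tif",
        "zones": outdir / "zones.tif",
        "met_daily": outdir / "met_daily.csv",
        "met_instant": outdir / "met_instant.csv",
        "yields": outdir / "yields.csv",
        "truths": truths,
        "dates": dates,
    }
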