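"""Surface energy balance: net radiation, soil heat flux, anchor-calibrated
sensible heat, latent heat residual, evaporative fraction and daily ET.

The latent heat flux is never measured here; it is the residual

    lambda*ET = Rn - G - H

closed exactly at every pixel by construction. H is calibrated through a
"cold" anchor pixel (well-watered vegetation, H = 0) and a "hot" anchor
(dry bare soil, lambda*ET = 0, so H = Rn - G), between which the near-surface
temperature difference dT is assumed linear in surface temperature:
dT = a + b*Ts. The aerodynamic resistance r_ah uses a log wind profile
between 0.1 m and 2 m with friction velocity taken from the station wind
extrapolated to a 200 m blending height, iterated under Monin-Obukhov
stability corrections until r_ah changes by less than 0.1% (cap 20
iterations).

Instantaneous evaporative fraction Lambda = (Rn-G-H)/(Rn-G) is assumed
preserved over the day (Lambda_24 = Lambda_inst), which upscales the
overpass snapshot to daily ET:

    ET24 = 86400 * Lambda_24 * Rn24 / lambda_v   [mm/d]

with lambda_v the latent heat of vaporisation evaluated at Ts.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .constants import (
    CP_AIR,
    GRAVITY,
    R_DRY_AIR,
    SECONDS_PER_DAY,
    SOLAR_CONSTANT,
    STEFAN_BOLTZMANN,
    VON_KARMAN,
)
from .grids import check_aligned, valid_mask
from .solar import cos_solar_zenith, day_of_year, inverse_relative_distance

logger = logging.getLogger(__name__)

__all__ = [
    "RadiationComponents",
    "FluxFields",
    "AnchorPair",
    "DailyET",
    "shortwave_down",
    "net_radiation",
    "soil_heat_flux",
    "select_anchor_pixels",
    "sensible_heat",
    "latent_heat",
    "latent_heat_of_vaporization",
    "daily_et",
    "air_pressure_kpa",
    "air_density",
]

Z_BLEND = 200.0  # blending height for regional wind (m)
Z1, Z2 = 0.1, 2.0  # heights bracketing the dT layer (m)
Z0M_STATION = 0.03  # roughness of the met-station surface (short grass, m)


@dataclass
class RadiationComponents:
    rs_down: np.ndarray  # incoming shortwave (W/m2)
    rl_down: np.ndarray  # incoming longwave (W/m2)
    rl_up: np.ndarray  # outgoing longwave (W/m2)
    rn: np.ndarray  # net radiation (W/m2)


@dataclass
class FluxFields:
    rn: np.ndarray
    g: np.ndarray
    h: np.ndarray
    le: np.ndarray  # latent heat flux, lambda*ET (W/m2)
    lambda_inst: np.ndarray  # evaporative fraction, clipped to [0, 1]


@dataclass
class AnchorPair:
    cold: tuple[int, int]
    hot: tuple[int, int]
    ts_cold: float
    ts_hot: float
    dt_a: float  # intercept of dT = a + b*Ts (K)
    dt_b: float  # slope (K/K)
    iterations: int = 0
    converged: bool = True
    rah_cold: float = float("nan")
    rah_hot: float = float("nan")


@dataclass
class DailyET:
    rn24: np.ndarray  # daily mean net radiation (W/m2)
    lambda24: np.ndarray
    et24: np.ndarray  # mm/d
    lambda_vap: np.ndarray  # J/kg


def tau_swave(elevation_m) -> np.ndarray | float:
    """Broadband atmospheric shortwave transmissivity, 0.75 + 2e-5 z."""
    return 0.75 + 2e-5 * np.asarray(elevation_m, dtype=float)


def shortwave_down(date, solar_time_h: float, latitude_deg: float, elevation_m) -> np.ndarray:
    """Instantaneous incoming shortwave Rs_down = Gsc * cos(theta) * d_r * tau_sw.

    Returns 0 where the sun is below the horizon (with a warning, since an
    instantaneous energy balance is meaningless at night).
    """
    doy = day_of_year(date)
    cz = cos_solar_zenith(latitude_deg, doy, solar_time_h)
    if np.all(cz <= 0):
        warnings.warn("sun below horizon at overpass time; Rs_down = 0", stacklevel=2)
    dr = inverse_relative_distance(doy)
    return SOLAR_CONSTANT * cz * dr * tau_swave(elevation_m) * np.ones_like(np.asarray(elevation_m, dtype=float))


def atmospheric_emissivity(elevation_m) -> np.ndarray | float:
    """Clear-sky atmospheric emissivity, 0.85 * (-ln tau_sw)^0.09."""
    return 0.85 * (-np.log(tau_swave(elevation_m))) ** 0.09


def net_radiation(albedo, rs_down, ts, ta_k, emissivity, elevation_m=0.0) -> RadiationComponents:
    """Assemble Rn = (1-a)Rs_down + RL_down - RL_up - (1-eps)RL_down.

    RL_up = eps*sigma*Ts^4; RL_down = eps_a*sigma*Ta^4 with the clear-sky
    atmospheric emissivity. Ta is the near-surface air temperature at the
    overpass (K, scalar or raster).
    """
    if ta_k is None:
        raise ValueError("near-surface air temperature Ta is required")
    albedo = np.asarray(albedo, dtype=float)
    ts = np.asarray(ts, dtype=float)
    check_aligned(albedo, ts)
    eps = np.asarray(emissivity, dtype=float)
    eps_a = atmospheric_emissivity(elevation_m)
    rl_down = eps_a * STEFAN_BOLTZMANN * np.asarray(ta_k, dtype=float) ** 4 * np.ones_like(ts)
    rl_up = eps * STEFAN_BOLTZMANN * ts**4
    rn = (1.0 - albedo) * rs_down + rl_down - rl_up - (1.0 - eps) * rl_down
    return RadiationComponents(
        rs_down=np.broadcast_to(np.asarray(rs_down, dtype=float), ts.shape).copy(),
        rl_down=rl_down,
        rl_up=rl_up,
        rn=rn,
    )


def soil_heat_flux(ts, albedo, ndvi, rn) -> np.ndarray:
    """G = [(Ts-273.15)/a * (0.0038a + 0.0074a^2) * (1 - 0.98 NDVI^4)] * Rn.

    Clipped to [0, 0.5*Rn] for Rn > 0; pixels with zero albedo are masked.
    """
    ts = np.asarray(ts, dtype=float)
    alb = np.asarray(albedo, dtype=float)
    ndvi = np.asarray(ndvi, dtype=float)
    rn = np.asarray(rn, dtype=float)
    check_aligned(ts, alb, ndvi, rn)
    out = np.full(ts.shape, np.nan)
    ok = valid_mask(ts, alb, ndvi, rn) & (alb > 0)
    ts_c = ts[ok] - 273.15
    a = alb[ok]
    g = ts_c / a * (0.0038 * a + 0.0074 * a**2) * (1.0 - 0.98 * ndvi[ok] ** 4) * rn[ok]
    upper = 0.5 * np.maximum(rn[ok], 0.0)
    out[ok] = np.clip(g, 0.0, upper)
    return out


def select_anchor_pixels(
    ts,
    ndvi,
    mask=None,
    cold_ndvi_quantile: float = 0.95,
    hot_ndvi_quantile: float = 0.10,
) -> tuple[tuple[int, int], tuple[int, int]]:
    """Pick the cold and hot anchor pixels.

    Cold: lowest Ts among the top-NDVI pool (default top 5%); hot: highest Ts
    among the bottom-NDVI pool (default bottom 10%). Ties resolve to the
    smallest (row, col) in lexicographic order. ``mask`` restricts the search
    to land pixels (see :func:`sebalwp.surface.land_anchor_mask`).
    """
    ts = np.asarray(ts, dtype=float)
    ndvi = np.asarray(ndvi, dtype=float)
    check_aligned(ts, ndvi)
    ok = valid_mask(ts, ndvi)
    if mask is not None:
        ok &= np.asarray(mask, dtype=bool)
    n_valid = int(ok.sum())
    if n_valid < 100:
        raise ValueError(f"anchor selection needs >= 100 valid land pixels, got {n_valid}")

    nd = ndvi[ok]
    cold_thresh = np.quantile(nd, cold_ndvi_quantile)
    hot_thresh = np.quantile(nd, hot_ndvi_quantile)
    cold_pool = ok & (ndvi >= cold_thresh)
    hot_pool = ok & (ndvi <= hot_thresh)
    if not cold_pool.any() or not hot_pool.any():
        raise ValueError(
            "empty anchor candidate pool "
            f"(cold: {int(cold_pool.sum())}, hot: {int(hot_pool.sum())} pixels)"
        )

    # np.argmin/argmax on C-ordered flat index return the first occurrence,
    # which is exactly the (row, col) lexicographic tie-break.
    ts_cold = np.where(cold_pool, ts, np.inf)
    cold = np.unravel_index(int(np.argmin(ts_cold)), ts.shape)
    ts_hot = np.where(hot_pool, ts, -np.inf)
    hot = np.unravel_index(int(np.argmax(ts_hot)), ts.shape)
    return (int(cold[0]), int(cold[1])), (int(hot[0]), int(hot[1]))


def air_pressure_kpa(elevation_m):
    """Barometric pressure from elevation, P = 101.3 ((293-0.0065z)/293)^5.26."""
    z = np.asarray(elevation_m, dtype=float)
    return 101.3 * ((293.0 - 0.0065 * z) / 293.0) ** 5.26


def air_density(elevation_m, ta_k):
    """Dry-air density (kg/m3) from elevation-adjusted pressure and Ta."""
    p = air_pressure_kpa(elevation_m) * 1000.0
    return p / (R_DRY_AIR * np.asarray(ta_k, dtype=float))


def _psi_m(zeta):
    """Momentum stability correction (Paulson unstable / log-linear stable)."""
    zeta = np.asarray(zeta, dtype=float)
    out = np.zeros_like(zeta)
    un = zeta < 0
    if np.any(un):
        x = (1.0 - 16.0 * zeta[un]) ** 0.25
        out[un] = (
            2.0 * np.log((1.0 + x) / 2.0)
            + np.log((1.0 + x**2) / 2.0)
            - 2.0 * np.arctan(x)
            + np.pi / 2.0
        )
    st = zeta > 0
    out[st] = -5.0 * zeta[st]
    return out


def _psi_h(zeta):
    """Heat stability correction."""
    zeta = np.asarray(zeta, dtype=float)
    out = np.zeros_like(zeta)
    un = zeta < 0
    if np.any(un):
        x2 = np.sqrt(1.0 - 16.0 * zeta[un])
        out[un] = 2.0 * np.log((1.0 + x2) / 2.0)
    st = zeta > 0
    out[st] = -5.0 * zeta[st]
    return out


def wind_at_blending_height(u_station: float, z_measure: float = 2.0, z0m_station: float = Z0M_STATION) -> float:
    """Extrapolate the station wind to the 200 m blending height (neutral log law)."""
    if u_station <= 0:
        raise ValueError("station wind speed must be positive")
    return u_station * np.log(Z_BLEND / z0m_station) / np.log(z_measure / z0m_station)


def sensible_heat(
    ts,
    z0m,
    u_station: float,
    anchors: tuple[tuple[int, int], tuple[int, int]],
    rn,
    g,
    *,
    ta_k: float,
    elevation_m=0.0,
    stability: bool = True,
    tol: float = 1e-3,
    max_iter: int = 20,
    wind_measure_height: float = 2.0,
    return_diagnostics: bool = False,
):
    """Anchor-calibrated sensible heat flux H = rho_air * Cp * dT / r_ah.

    dT = a + b*Ts with (a, b) fixed each iteration by the two anchor
    constraints: dT = 0 at the cold pixel and H = Rn - G at the hot pixel.
    Monin-Obukhov corrections are iterated on r_ah until the maximum relative
    change drops below ``tol`` (or ``max_iter``, flagged non-converged).

    Returns (h, AnchorPair); with ``return_diagnostics`` also a dict holding
    the final r_ah and density fields (used by the synthetic-scene inverter).
    """
    ts = np.asarray(ts, dtype=float)
    z0m = np.asarray(z0m, dtype=float)
    rn = np.asarray(rn, dtype=float)
    g = np.asarray(g, dtype=float)
    check_aligned(ts, z0m, rn, g)
    (cr, cc), (hr, hc) = anchors
    ts_cold = float(ts[cr, cc])
    ts_hot = float(ts[hr, hc])
    if not ts_cold < ts_hot:
        raise ValueError(f"anchor temperatures must satisfy Ts_cold < Ts_hot (got {ts_cold} vs {ts_hot})")

    u200 = wind_at_blending_height(u_station, z_measure=wind_measure_height)
    rho = air_density(elevation_m, ta_k) * np.ones_like(ts)
    avail_hot = float(rn[hr, hc] - g[hr, hc])
    k = VON_KARMAN

    ok = valid_mask(ts, z0m, rn, g)
    ln_blend = np.where(ok, np.log(Z_BLEND / np.where(ok, z0m, 1.0)), np.nan)
    ln_layer = np.log(Z2 / Z1)

    psi_m200 = np.zeros_like(ts)
    psi_h2 = np.zeros_like(ts)
    psi_h1 = np.zeros_like(ts)
    rah_prev = None
    converged = False
    iterations = 0
    a = b = 0.0
    h = np.zeros_like(ts)
    ustar = np.full_like(ts, np.nan)
    rah = np.full_like(ts, np.nan)

    for iterations in range(1, max_iter + 1):
        with np.errstate(invalid="ignore", divide="ignore"):
            ustar = k * u200 / (ln_blend - psi_m200)
            rah = (ln_layer - psi_h2 + psi_h1) / (k * ustar)
        b = avail_hot * float(rah[hr, hc]) / (float(rho[hr, hc]) * CP_AIR) / (ts_hot - ts_cold)
        a = -b * ts_cold
        dt = a + b * ts
        with np.errstate(invalid="ignore"):
            h = rho * CP_AIR * dt / rah
        if rah_prev is not None:
            delta = np.nanmax(np.abs(rah - rah_prev) / np.abs(rah_prev))
            if delta < tol:
                converged = True
                break
        rah_prev = rah.copy()
        if not stability:
            converged = True
            break
        # Monin-Obukhov length; neutral (L -> inf) where H ~ 0
        with np.errstate(invalid="ignore", divide="ignore"):
            L = -rho * CP_AIR * ustar**3 * ts / (k * GRAVITY * h)
        L = np.where(np.abs(h) < 1e-6, np.inf, L)
        with np.errstate(invalid="ignore", divide="ignore"):
            psi_m200 = _psi_m(Z_BLEND / L)
            psi_h2 = _psi_h(Z2 / L)
            psi_h1 = _psi_h(Z1 / L)

    if not converged:
        logger.warning("sensible heat: stability loop hit %d iterations without converging", max_iter)

    pair = AnchorPair(
        cold=(cr, cc),
        hot=(hr, hc),
        ts_cold=ts_cold,
        ts_hot=ts_hot,
        dt_a=float(a),
        dt_b=float(b),
        iterations=iterations,
        converged=converged,
        rah_cold=float(rah[cr, cc]),
        rah_hot=float(rah[hr, hc]),
    )
    h = np.where(ok, h, np.nan)
    if return_diagnostics:
        return h, pair, {"rah": rah, "rho": rho, "ustar": ustar}
    return h, pair


def latent_heat(rn, g, h) -> tuple[np.ndarray, np.ndarray]:
    """Residual latent heat le = Rn - G - H and evaporative fraction.

    Lambda = le / (Rn - G), clipped to [0, 1]; pixels with Rn - G <= 0 are
    masked. ``le`` is returned unclipped so closure is exact.
    """
    rn = np.asarray(rn, dtype=float)
    g = np.asarray(g, dtype=float)
    h = np.asarray(h, dtype=float)
    check_aligned(rn, g, h)
    le = rn - g - h
    avail = rn - g
    lam = np.full(rn.shape, np.nan)
    ok = valid_mask(rn, g, h) & (avail > 0)
    lam[ok] = np.clip(le[ok] / avail[ok], 0.0, 1.0)
    le = np.where(valid_mask(rn, g, h), le, np.nan)
    return le, lam


def latent_heat_of_vaporization(ts_k) -> np.ndarray:
    """lambda_v(T) = [2.501 - 0.002361 (Ts - 273.15)] * 1e6 J/kg."""
    lam = (2.501 - 0.002361 * (np.asarray(ts_k, dtype=float) - 273.15)) * 1e6
    if np.any(lam[np.isfinite(lam)] <= 0):
        raise ValueError("nonphysical surface temperature: lambda_v <= 0")
    return lam


def daily_et(lambda24, rn24, ts_k) -> DailyET:
    """ET24 = 86400 * Lambda_24 * Rn24 / lambda_v  [mm/d], floored at 0."""
    lam24 = np.asarray(lambda24, dtype=float)
    rn24 = np.asarray(rn24, dtype=float) * np.ones_like(lam24)
    lv = latent_heat_of_vaporization(ts_k) * np.ones_like(lam24)
    et = SECONDS_PER_DAY * lam24 * rn24 / lv
    et = np.maximum(et, 0.0)
    return DailyET(rn24=rn24, lambda24=lam24, et24=et, lambda_vap=lv)


def compute_fluxes(
    surf,
    *,
    date,
    overpass_time: float,
    latitude_deg: float,
    ta_k: float,
    u_station: float,
    elevation_m=0.0,
    anchors=None,
    stability: bool = True,
    anchor_mask=None,
    cold_ndvi_quantile: float = 0.95,
    hot_ndvi_quantile: float = 0.10,
) -> tuple[FluxFields, AnchorPair]:
    """Full instantaneous energy-balance chain on one scene's SurfaceFields."""
    rs = shortwave_down(date, overpass_time, latitude_deg, elevation_m)
    rad = net_radiation(surf.albedo, rs, surf.lst, ta_k, surf.emissivity, elevation_m)
    g = soil_heat_flux(surf.lst, surf.albedo, surf.ndvi, rad.rn)
    if anchors is None:
        from .surface import land_anchor_mask

        mask = anchor_mask if anchor_mask is not None else land_anchor_mask(surf.ndvi, surf.albedo)
        anchors = select_anchor_pixels(
            surf.lst, surf.ndvi, mask,
            cold_ndvi_quantile=cold_ndvi_quantile,
            hot_ndvi_quantile=hot_ndvi_quantile,
        )
    h, pair = sensible_heat(
        surf.lst, surf.z0m, u_station, anchors, rad.rn, g,
        ta_k=ta_k, elevation_m=elevation_m, stability=stability,
    )
    le, lam = latent_heat(rad.rn, g, h)
    return FluxFields(rn=rad.rn, g=g, h=h, le=le, lambda_inst=lam), pair
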