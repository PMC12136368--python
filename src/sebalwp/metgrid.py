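"""Gridding of station meteorology onto the analysis raster.

With five or more stations a thin-plate-spline surface with an elevation
covariate is fitted: the variable is first regressed linearly on station
elevation, the residuals are interpolated exactly by a 2-D thin-plate-spline
RBF, and the elevation term is evaluated at the DEM. With fewer stations the
scheme degrades to inverse-distance-squared weighting, with a -6.5 K/km
lapse-rate adjustment applied to temperature-like variables.

Both schemes reproduce the station value exactly at a grid node whose DEM
matches the station elevation.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.interpolate import RBFInterpolator

from .grids import GridGeometry

__all__ = ["grid_met"]

LAPSE_K_PER_M = -0.0065
TEMPERATURE_VARS = {"tmean_c", "tmax_c", "tmin_c", "ta_c", "temperature"}


def _is_temperature(variable: str) -> bool:
    return variable.lower() in TEMPERATURE_VARS


def grid_met(
    stations: pd.DataFrame,
    dem: np.ndarray,
    geometry: GridGeometry,
    variable: str,
    min_stations_for_spline: int = 5,
) -> np.ndarray:
    """Interpolate one station variable to the full grid.

    ``stations`` needs columns x_m, y_m, elev_m and ``variable``; one row per
    station. Duplicate station locations are averaged first.
    """
    required = {"x_m", "y_m", "elev_m", variable}
    missing = required - set(stations.columns)
    if missing:
        raise ValueError(f"station table missing column(s): {sorted(missing)}")
    st = stations.groupby(["x_m", "y_m"], as_index=False).agg(
        {"elev_m": "mean", variable: "mean"}
    )
    n = len(st)
    if n == 0:
        raise ValueError("no stations to interpolate")

    xg, yg = geometry.xy_grids()
    pts = st[["x_m", "y_m"]].to_numpy(dtype=float)
    vals = st[variable].to_numpy(dtype=float)
    elev = st["elev_m"].to_numpy(dtype=float)

    if n >= min_stations_for_spline:
        # elevation covariate by least squares, TPS on the residuals
        A = np.column_stack([np.ones(n), elev])
        coef, *_ = np.linalg.lstsq(A, vals, rcond=None)
        resid = vals - A @ coef
        if np.ptp(pts[:, 0]) == 0 and np.ptp(pts[:, 1]) == 0:
            resid_grid = np.full(dem.shape, resid.mean())
        else:
            rbf = RBFInterpolator(pts, resid, kernel="thin_plate_spline", smoothing=0.0)
            grid_pts = np.column_stack([xg.ravel(), yg.ravel()])
            resid_grid = rbf(grid_pts).reshape(dem.shape)
        return coef[0] + coef[1] * dem + resid_grid

    # inverse-distance-squared fallback
    if _is_temperature(variable):
        vals_sl = vals - LAPSE_K_PER_M * elev  # reduce to sea level: T_sl = T - lapse*z
    else:
        vals_sl = vals
    if n == 1:
        field = np.full(dem.shape, vals_sl[0])
    else:
        d2 = np.zeros((n,) + dem.shape)
        for i in range(n):
            d2[i] = (xg - pts[i, 0]) ** 2 + (yg - pts[i, 1]) ** 2
        w = 1.0 / np.maximum(d2, 1e-12)
        field = (w * vals_sl[:, None, None]).sum(axis=0) / w.sum(axis=0)
        # exact at station nodes
        for i in range(n):
            at = d2[i] < (geometry.cell_size / 2) ** 2
            field[at] = vals_sl[i]
    if _is_temperature(variable):
        field = field + LAPSE_K_PER_M * dem
    return field
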