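"""Per-pixel surface parameters from a satellite scene.

Derives the inputs of the surface energy balance — NDVI, broadband albedo,
surface emissivity, land-surface temperature and momentum roughness length —
from a six-band reflectance stack plus a thermal band.

The retrieval choices are the standard ones of the SEBAL literature and are
each swappable via keyword arguments: a Liang-type narrow-to-broadband albedo
sum, a log-NDVI emissivity, a single-channel emissivity-corrected LST, and an
exponential NDVI/albedo roughness parameterisation. Atmospheric correction is
assumed done upstream: the reflectances and brightness temperature entering
here are surface quantities.
"""

from __future__ import annotations

import datetime as _dt
import logging
from dataclasses import dataclass, field

import numpy as np

from .constants import K1_DEFAULT, K2_DEFAULT, LAMBDA_EFF_M, RHO_C_MK
from .grids import GridGeometry, check_aligned, valid_mask

logger = logging.getLogger(__name__)

__all__ = [
    "SceneStack",
    "SurfaceFields",
    "compute_ndvi",
    "compute_albedo",
    "compute_emissivity",
    "compute_lst",
    "compute_roughness",
    "derive_surface_fields",
    "land_anchor_mask",
    "ALBEDO_COEFFS",
]

BAND_NAMES = ("blue", "green", "red", "nir", "swir1", "swir2")

# Liang (narrow-to-broadband) shortwave albedo weights; the trailing value is
# the additive offset.
ALBEDO_COEFFS = {
    "blue": 0.356,
    "green": 0.0,
    "red": 0.130,
    "nir": 0.373,
    "swir1": 0.085,
    "swir2": 0.072,
    "offset": -0.0018,
}


@dataclass
class SceneStack:
    """One satellite acquisition on a single grid.

    ``bands`` maps band name -> surface reflectance raster (fraction);
    ``thermal`` is at-surface brightness temperature (K) unless
    ``thermal_is_radiance`` is set, in which case it is spectral radiance and
    the Planck constants ``k1``/``k2`` are used to invert it.
    """

    bands: dict
    thermal: np.ndarray
    geometry: GridGeometry
    date: _dt.date
    overpass_time: float  # decimal hours, local solar time
    latitude: float  # deg, scene-representative
    thermal_is_radiance: bool = False
    k1: float = K1_DEFAULT
    k2: float = K2_DEFAULT

    def __post_init__(self) -> None:
        missing = [b for b in BAND_NAMES if b not in self.bands]
        if missing:
            raise ValueError(f"scene is missing reflectance band(s): {missing}")
        check_aligned(*self.bands.values(), self.thermal, shape=self.geometry.shape)
        for name in BAND_NAMES:
            band = self.bands[name]
            ok = valid_mask(band)
            if np.any((band[ok] < 0) | (band[ok] > 1)):
                raise ValueError(f"band {name!r} has reflectance outside [0, 1]")
        if not self.thermal_is_radiance:
            bt = self.thermal
            ok = valid_mask(bt)
            if np.any((bt[ok] < 200) | (bt[ok] > 350)):
                raise ValueError("brightness temperature outside [200, 350] K")

    @property
    def mask(self) -> np.ndarray:
        """Valid where every band and the thermal channel are finite."""
        return valid_mask(*(self.bands[b] for b in BAND_NAMES), self.thermal)


@dataclass
class SurfaceFields:
    ndvi: np.ndarray
    albedo: np.ndarray
    emissivity: np.ndarray
    lst: np.ndarray  # surface temperature Ts (K)
    z0m: np.ndarray  # momentum roughness length (m)
    geometry: GridGeometry | None = None
    params: dict = field(default_factory=dict)

    @property
    def mask(self) -> np.ndarray:
        return valid_mask(self.ndvi, self.albedo, self.emissivity, self.lst, self.z0m)


def compute_ndvi(red: np.ndarray, nir: np.ndarray) -> np.ndarray:
    """(NIR - red) / (NIR + red); masked (NaN) where the denominator is 0."""
    red = np.asarray(red, dtype=float)
    nir = np.asarray(nir, dtype=float)
    check_aligned(red, nir)
    denom = nir + red
    out = np.full(red.shape, np.nan)
    ok = valid_mask(red, nir) & (denom != 0)
    out[ok] = (nir[ok] - red[ok]) / denom[ok]
    return out


def compute_albedo(bands: dict, coeffs: dict | None = None) -> np.ndarray:
    """Broadband shortwave albedo as a weighted sum of band reflectances.

    Clipped to [0, 1]; NaN propagates from any contributing band.
    """
    c = dict(ALBEDO_COEFFS if coeffs is None else coeffs)
    offset = c.pop("offset", 0.0)
    missing = [b for b, w in c.items() if w != 0.0 and b not in bands]
    if missing:
        raise ValueError(f"albedo needs band(s) {missing}")
    total = None
    for name, w in c.items():
        if w == 0.0:
            continue
        term = w * np.asarray(bands[name], dtype=float)
        total = term if total is None else total + term
    return np.clip(total + offset, 0.0, 1.0)


def compute_emissivity(ndvi: np.ndarray, clip: tuple[float, float] = (0.90, 0.99)) -> np.ndarray:
    """Broadband surface emissivity from NDVI.

    Vegetated pixels (NDVI > 0.157) follow 1.009 + 0.047 ln(NDVI); sparse
    ground gets 0.955; NDVI <= 0 is treated as water (0.985). Clipped to the
    physically expected land range.
    """
    ndvi = np.asarray(ndvi, dtype=float)
    eps = np.full(ndvi.shape, np.nan)
    ok = valid_mask(ndvi)
    veg = ok & (ndvi > 0.157)
    bare = ok & (ndvi > 0) & ~veg
    water = ok & (ndvi <= 0)
    eps[veg] = 1.009 + 0.047 * np.log(ndvi[veg])
    eps[bare] = 0.955
    eps[water] = 0.985
    eps[ok] = np.clip(eps[ok], clip[0], clip[1])
    return eps


def brightness_temperature(radiance: np.ndarray, k1: float = K1_DEFAULT, k2: float = K2_DEFAULT) -> np.ndarray:
    """Invert the band-integrated Planck function: BT = K2 / ln(K1/L + 1)."""
    L = np.asarray(radiance, dtype=float)
    out = np.full(L.shape, np.nan)
    ok = valid_mask(L) & (L > 0)
    out[ok] = k2 / np.log(k1 / L[ok] + 1.0)
    return out


def compute_lst(
    thermal: np.ndarray,
    emissivity: np.ndarray,
    *,
    thermal_is_radiance: bool = False,
    k1: float = K1_DEFAULT,
    k2: float = K2_DEFAULT,
) -> np.ndarray:
    """Surface temperature via the single-channel emissivity correction.

    Ts = BT / (1 + (lambda_eff * BT / rho_c) * ln(eps)); since ln(eps) <= 0
    for eps <= 1, the correction always raises Ts relative to BT.
    """
    eps = np.asarray(emissivity, dtype=float)
    ok_eps = valid_mask(eps)
    if np.any(eps[ok_eps] <= 0):
        raise ValueError("emissivity must be positive")
    bt = brightness_temperature(thermal, k1, k2) if thermal_is_radiance else np.asarray(thermal, dtype=float)
    check_aligned(bt, eps)
    out = np.full(bt.shape, np.nan)
    ok = valid_mask(bt, eps)
    c = LAMBDA_EFF_M / RHO_C_MK
    out[ok] = bt[ok] / (1.0 + c * bt[ok] * np.log(eps[ok]))
    return out


def bt_from_lst(lst: np.ndarray, emissivity: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`compute_lst`: the BT a sensor would report."""
    c = LAMBDA_EFF_M / RHO_C_MK
    return lst / (1.0 - c * lst * np.log(emissivity))


def compute_roughness(
    ndvi: np.ndarray,
    albedo: np.ndarray,
    a: float = 1.096,
    b: float = -5.307,
    floor: float = 0.001,
) -> np.ndarray:
    """Momentum roughness length z0m = exp(a * NDVI/albedo + b), floored (m)."""
    ndvi = np.asarray(ndvi, dtype=float)
    alb = np.asarray(albedo, dtype=float)
    check_aligned(ndvi, alb)
    out = np.full(ndvi.shape, np.nan)
    ok = valid_mask(ndvi, alb)
    zero_alb = ok & (alb == 0)
    if np.any(zero_alb):
        logger.warning("z0m: %d pixels with zero albedo floored at %.3g m", int(zero_alb.sum()), floor)
        out[zero_alb] = floor
    pos = ok & (alb > 0)
    with np.errstate(over="ignore"):
        out[pos] = np.exp(a * ndvi[pos] / alb[pos] + b)
    out[ok] = np.maximum(out[ok], floor)
    return out


def land_anchor_mask(ndvi: np.ndarray, albedo: np.ndarray) -> np.ndarray:
    """Pixels eligible for anchor search: excludes water (NDVI <= 0) and
    bright snow/cloud remnants (albedo > 0.45)."""
    ok = valid_mask(ndvi, albedo)
    return ok & (ndvi > 0) & (albedo <= 0.45)


def derive_surface_fields(scene: SceneStack, **kwargs) -> SurfaceFields:
    """Full SceneStack -> SurfaceFields chain, masking nodata consistently."""
    mask = scene.mask
    ndvi = compute_ndvi(scene.bands["red"], scene.bands["nir"])
    albedo = compute_albedo(scene.bands, coeffs=kwargs.get("albedo_coeffs"))
    emissivity = compute_emissivity(ndvi)
    lst = compute_lst(
        scene.thermal,
        emissivity,
        thermal_is_radiance=scene.thermal_is_radiance,
        k1=scene.k1,
        k2=scene.k2,
    )
    z0m = compute_roughness(ndvi, albedo)
    for arr in (ndvi, albedo, emissivity, lst, z0m):
        arr[~mask] = np.nan
    return SurfaceFields(
        ndvi=ndvi,
        albedo=albedo,
        emissivity=emissivity,
        lst=lst,
        z0m=z0m,
        geometry=scene.geometry,
        params={"albedo_coeffs": dict(kwargs.get("albedo_coeffs") or ALBEDO_COEFFS)},
    )
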