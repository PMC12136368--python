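"""File formats: rasters (TIFF + JSON geo-sidecar), CSV tables, YAML config
and the run manifest.

Rasters are written with :mod:`tifffile` as float64 TIFF; the accompanying
``<name>.tif.json`` sidecar carries the grid geometry (origin, cell size),
band names and any scene metadata (acquisition date, overpass time,
latitude, Planck constants). Every raster read is checked against the run's
single grid; mismatches are rejected at ingestion, never resampled.
"""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .grids import GridGeometry
from .surface import BAND_NAMES, SceneStack

__all__ = [
    "write_raster",
    "read_raster",
    "write_scene",
    "read_scene",
    "read_met_daily",
    "read_met_instant",
    "read_yields",
    "PipelineConfig",
    "load_config",
    "sha256_of",
]

MET_DAILY_COLUMNS = [
    "station_id", "date", "tmax_c", "tmin_c", "tmean_c", "rh_pct",
    "wind_2m_ms", "sunshine_h", "precip_mm", "elev_m", "lat", "lon",
]


def _sidecar(path: Path) -> Path:
    return Path(str(path) + ".json")


def write_raster(path, data: np.ndarray, geometry: GridGeometry, band_names: list, meta: dict | None = None) -> Path:
    """Write a single- or multi-band float64 raster plus its geo-sidecar."""
    path = Path(path)
    arr = np.asarray(data, dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.shape[0] != len(band_names):
        raise ValueError(f"{arr.shape[0]} bands but {len(band_names)} band names")
    if arr.shape[1:] != geometry.shape:
        raise ValueError(f"raster shape {arr.shape[1:]} does not match grid {geometry.shape}")
    tifffile.imwrite(path, arr)
    sidecar = {"geometry": geometry.to_dict(), "bands": list(band_names), "nodata": "nan"}
    if meta:
        sidecar["meta"] = meta
    _sidecar(path).write_text(json.dumps(sidecar, indent=1, default=str))
    return path


def read_raster(path, expect_geometry: GridGeometry | None = None):
    """Read a raster; returns (array, geometry, sidecar dict).

    Single-band rasters come back 2-D, multi-band as (bands, rows, cols).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sc_path = _sidecar(path)
    if not sc_path.exists():
        raise FileNotFoundError(f"raster sidecar missing: {sc_path}")
    sidecar = json.loads(sc_path.read_text())
    geometry = GridGeometry.from_dict(sidecar["geometry"])
    arr = np.asarray(tifffile.imread(path), dtype=np.float64)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.shape[1:] != geometry.shape:
        raise ValueError(f"raster {path} shape {arr.shape[1:]} contradicts its sidecar {geometry.shape}")
    if expect_geometry is not None and geometry != expect_geometry:
        raise ValueError(f"raster {path} is on a different grid than the run grid; resample upstream")
    if arr.shape[0] == 1:
        return arr[0], geometry, sidecar
    return arr, geometry, sidecar


def write_scene(scene: SceneStack, path) -> Path:
    """Scene as a 7-band raster: six reflectance bands plus the thermal band."""
    stack = np.stack([scene.bands[b] for b in BAND_NAMES] + [scene.thermal])
    meta = {
        "date": scene.date.isoformat(),
        "overpass_time": scene.overpass_time,
        "latitude": scene.latitude,
        "thermal_is_radiance": scene.thermal_is_radiance,
        "k1": scene.k1,
        "k2": scene.k2,
    }
    return write_raster(path, stack, scene.geometry, list(BAND_NAMES) + ["thermal"], meta)


def read_scene(path) -> SceneStack:
    arr, geometry, sidecar = read_raster(path)
    names = sidecar.get("bands", [])
    missing = [b for b in BAND_NAMES if b not in names]
    if missing:
        raise ValueError(f"scene {path} is missing band(s): {missing}")
    if "thermal" not in names:
        raise ValueError(f"scene {path} is missing band(s): ['thermal']")
    meta = sidecar.get("meta", {})
    for key in ("date", "overpass_time", "latitude"):
        if key not in meta:
            raise ValueError(f"scene {path} sidecar is missing metadata field {key!r}")
    if arr.ndim == 2:
        arr = arr[None]
    bands = {name: arr[i] for i, name in enumerate(names)}
    return SceneStack(
        bands={b: bands[b] for b in BAND_NAMES},
        thermal=bands["thermal"],
        geometry=geometry,
        date=_dt.date.fromisoformat(meta["date"]),
        overpass_time=float(meta["overpass_time"]),
        latitude=float(meta["latitude"]),
        thermal_is_radiance=bool(meta.get("thermal_is_radiance", False)),
        k1=float(meta.get("k1", 774.8853)),
        k2=float(meta.get("k2", 1321.0789)),
    )


def read_met_daily(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in MET_DAILY_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"met CSV missing column(s): {missing}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def read_met_instant(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in ("station_id", "date", "ta_c", "wind_2m_ms"):
        if c not in df.columns:
            raise ValueError(f"instantaneous met CSV missing column {c!r}")
    df["date"] = pd.to_datetime(df["date"]).dt.date
    return df


def read_yields(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for c in ("zone_id", "yield_kg_per_mu"):
        if c not in df.columns:
            raise ValueError(f"yield CSV missing column {c!r}")
    return df


def sha256_of(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# configuration


@dataclass
class PipelineConfig:
    """Every switch and constant of one end-to-end run.

    Unknown keys in a config file are errors: silent typos must not change
    the science. All defaults are recorded in the run manifest.
    """

    # inputs
    scenes: list = field(default_factory=list)
    dem: str = ""
    zones: str = ""
    met_daily: str = ""
    met_instant: str = ""
    yields: str = ""
    out: str = "out"
    # algorithm switches
    g_formula: str = "bastiaanssen"
    stability: bool = True
    cold_ndvi_quantile: float = 0.95
    hot_ndvi_quantile: float = 0.10
    interpolation: str = "linear"
    validation_kc: float = 1.0  # Kc applied to ET0 for the validation table
    season_start: str = ""
    season_end: str = ""
    # constants (documented; informational in the manifest)
    cp_air: float = 1004.0
    sigma: float = 5.67e-8
    gsc: float = 1367.0
    mu_m2: float = 666.667
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("cp_air", "sigma", "gsc", "mu_m2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"constant {name} must be positive")
        if self.g_formula not in {"bastiaanssen"}:
            raise ValueError(f"unknown g_formula {self.g_formula!r}")
        if self.interpolation not in {"linear"}:
            raise ValueError(f"unknown interpolation method {self.interpolation!r}")

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path) -> PipelineConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    return PipelineConfig(**raw)
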