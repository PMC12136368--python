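import datetime as dt

import numpy as np
import pytest

from sebalwp.energy import compute_fluxes
from sebalwp.surface import derive_surface_fields
from sebalwp.synthetic import SynthConfig, generate_scene, met_means_at


@pytest.fixture(scope="session")
def clean_scene():
    """Zero-noise 100x100 synthetic scene with its truth and terrain."""
    cfg = SynthConfig(reflectance_noise=0.0, thermal_noise_k=0.0, seed=42)
    scene, truth, dem = generate_scene(cfg)
    return cfg, scene, truth, dem


@pytest.fixture(scope="session")
def clean_retrieval(clean_scene):
    """Full retrieval on the zero-noise scene: (cfg, truth, surf, fluxes, pair)."""
    cfg, scene, truth, dem = clean_scene
    surf = derive_surface_fields(scene)
    m = met_means_at(cfg, cfg.date)
    fluxes, pair = compute_fluxes(
        surf,
        date=cfg.date,
        overpass_time=cfg.overpass_time,
        latitude_deg=cfg.latitude,
        ta_k=m["tmean_c"] + cfg.overpass_ta_offset_c + 273.15,
        u_station=m["wind_2m_ms"],
        elevation_m=dem,
    )
    return cfg, truth, surf, fluxes, pair


@pytest.fixture
def met_record():
    """A plausible mid-latitude summer station-day."""
    from sebalwp.fao56 import MetDaily

    return MetDaily(
        date=dt.date(2020, 8, 10),
        tmax_c=30.2,
        tmin_c=17.9,
        tmean_c=24.0,
        rh_pct=58.0,
        wind_2m_ms=2.1,
        sunshine_h=8.6,
        precip_mm=0.0,
        elev_m=780.0,
        lat_deg=37.6,
    )
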