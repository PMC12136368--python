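# Methods

## The problem

Crop water productivity (WP, kg of grain per m³ of water consumed) requires a
map of seasonal evapotranspiration (ET). Over a province-scale rain-fed
region no flux-tower network can provide that, so ET is retrieved from
satellite thermal imagery with a surface-energy-balance model and validated
against station-based FAO-56 Penman–Monteith reference ET. This package
implements that chain end to end — retrieval, validation, temporal
upscaling, WP mapping and the WP–environment correlation analysis — and
ships a synthetic-scene generator whose ground truth is exact, so every
stage is testable without any satellite download.

## Energy-balance retrieval (SEBAL scheme)

Latent heat is the residual of the instantaneous surface energy balance at
overpass time,

    λE = Rn − G − H          [W/m²]

with, per pixel:

* **Net radiation** Rn = (1−α)·Rs↓ + RL↓ − RL↑ − (1−ε)·RL↓.
  Rs↓ = Gsc·cosθ·d_r·τsw with Gsc = 1367 W/m² and a broadband
  transmissivity τsw = 0.75 + 2·10⁻⁵·z; RL↑ = ε·σ·Ts⁴;
  RL↓ = εa·σ·Ta⁴ with the clear-sky atmospheric emissivity
  εa = 0.85·(−ln τsw)^0.09.
* **Soil heat flux** G = [(Ts−273.15)/α · (0.0038α + 0.0074α²) ·
  (1 − 0.98·NDVI⁴)]·Rn, clipped to [0, 0.5·Rn]. The division by α follows
  the original SEBAL formulation; the config records this as
  `g_formula = "bastiaanssen"`.
* **Sensible heat** H = ρair·Cp·dT/r_ah with Cp = 1004 J/(kg·K). The
  near-surface temperature difference is taken linear in surface
  temperature, dT = a + b·Ts, and the two coefficients are fixed by two
  *anchor pixels*: a cold, well-watered pixel where H = 0 (dT = 0) and a
  hot, dry pixel where λE = 0 (H = Rn − G). Anchor selection: the cold
  anchor is the coolest pixel among the top-5% NDVI pixels, the hot anchor
  the warmest among the bottom-10% NDVI land pixels (water, NDVI ≤ 0, and
  bright pixels, α > 0.45, excluded); ties resolve to the smallest
  (row, col). The aerodynamic resistance r_ah uses a log profile between
  z1 = 0.1 m and z2 = 2 m with friction velocity from the station wind
  extrapolated to a 200 m blending height, iterated under Monin–Obukhov
  stability corrections (Paulson unstable / log-linear stable branches)
  until max |Δr_ah|/r_ah < 10⁻³, cap 20 iterations (non-convergence is
  flagged, never silently accepted).
* **Evaporative fraction** Λ = (Rn−G−H)/(Rn−G), clipped to [0, 1], masked
  where Rn−G ≤ 0. λE itself is kept unclipped so the closure
  Rn − G − H − λE = 0 is a floating-point identity.

Surface parameters feeding the balance are the standard SEBAL-literature
choices, each swappable: Liang broadband albedo
(0.356·blue + 0.130·red + 0.373·nir + 0.085·swir1 + 0.072·swir2 − 0.0018),
log-NDVI emissivity (1.009 + 0.047·ln NDVI for NDVI > 0.157, 0.955 for
sparse ground, 0.985 for water, clipped to [0.90, 0.99]), single-channel
emissivity-corrected LST (Ts = BT / (1 + (λeff·BT/ρc)·ln ε), λeff = 10.9 µm,
ρc = 1.438·10⁻² m·K), and exponential roughness
z0m = exp(1.096·NDVI/α − 5.307) floored at 1 mm. Atmospheric correction is
assumed done upstream. No split-window LST, BRDF or topographic-illumination
correction is attempted.

## Daily and seasonal ET

The evaporative fraction is assumed preserved over the day (Λ24 = Λinst; no
advective correction), so

    ET24 = 86400 · Λ24 · Rn24 / λv        [mm/d]

with λv = [2.501 − 0.002361·(Ts−273.15)]·10⁶ J/kg. Daily net radiation Rn24
comes from the station met via the FAO-56 daily radiation balance (Angström
a_s = 0.25, b_s = 0.50), gridded as below, not from the instantaneous scene.

Between overpasses Λ24 is interpolated per pixel, linearly in time with
boundary hold ("daily evaporation ratio interpolation"); at an overpass date
the scene's own Λ is used bit-for-bit. Daily ET grids are summed to monthly
and seasonal totals; the seasonal total is computed as the sum of the
monthly totals so the additivity is exact in floating point. Linear
interpolation is the simplest scheme consistent with per-day evaporation
ratios; the config records the choice (`interpolation: linear`) and the
module boundary allows a spline drop-in.

## Reference ET and validation

FAO-56 Penman–Monteith at the daily step:

    ET0 = [0.408·Δ·(Rn−G) + γ·900/(T+273)·u2·(es−ea)] / [Δ + γ·(1+0.34·u2)]

with G = 0 (daily convention), es the mean of saturation pressures at Tmax
and Tmin, ea = es·RH/100, Δ the saturation-curve slope at Tmean, and
γ = 0.665·10⁻³·P from elevation-adjusted pressure. Crop ET is ETc = Kc·ET0
with a user-supplied Kc schedule. The validation table reports, per matched
station/date pair, the absolute error |ET_SEBAL − ET_PM| and the relative
error **as a percent of the SEBAL value**; that denominator convention is
the one consistent with all rows of the published comparison this table
mirrors (PM denominators reproduce none of them).

## Meteorological gridding

Station variables are gridded by a thin-plate-spline surface with an
elevation covariate when ≥ 5 stations are available: a linear regression on
station elevation, an exact 2-D TPS interpolation of the residuals, and the
elevation term evaluated at the DEM. With fewer stations the scheme falls
back to inverse-distance-squared weighting with a −6.5 K/km lapse adjustment
for temperature-like variables. Both reproduce the station value exactly at
a grid node whose DEM matches the station elevation. This keeps the
interpolation fully in-repo and testable.

## Water productivity and correlation

WP [kg/m³] = (yield / 666.667 m²) / (ET / 1000), i.e. ≈ 1.5·yield/ET with
yield in kg/mu and ET in mm — the mu-to-m² constant is stated explicitly
because yields and WP conventionally mix those units. Cropped pixels with
zero ET are masked and counted. Zone statistics (mean/min/max/count) come
from valid pixels only; empty zones are omitted with a warning.
Correlations between the WP raster and elevation / temperature /
precipitation are Pearson r over the joint-valid pixels of each zone
(pixel-level, not zone-mean-level: with a handful of zones no zone-level
correlation could reach significance), with a two-tailed t-test and a
significance flag at α = 0.01. Zones under 10 pixels or zero-variance
variables give flagged NaN rows.

## The synthetic-scene generator

The generator is the package's oracle; its defaults are the study
conditions of the tests.

* **Truth field.** Λ is a sum of random 2-D Gaussian bumps on a
  northeast→southwest gradient (mimicking terrain-driven moisture), scaled
  to [0.05, 0.95] in the interior. Exactly one cold anchor (Λ = 1, maximum
  NDVI, minimum Ts) and one hot anchor (Λ = 0, minimum NDVI, maximum Ts)
  are planted, so each anchor criterion is satisfied strictly and uniquely.
* **Exact inversion.** Surface temperature is *derived from* Λ, not the
  other way around: a per-pixel Newton iteration runs the actual retrieval
  forward model (including anchor calibration and the stability loop) and
  solves for the Ts field whose retrieved Λ equals the truth to 10⁻⁹. The
  hot anchor bounds the achievable dryness — a pixel with more available
  energy than the hot anchor cannot be driven to Λ ≈ 0 within the
  calibration line — and where that happens the truth is adjusted to the
  achievable value, keeping the construction exact rather than
  approximately feasible. Zero-noise recovery is therefore a machine-
  precision test of the whole chain, not a tolerance test.
* **Bands.** Red/NIR realise the NDVI truth exactly (fixed red+NIR total);
  SWIR bands are solved from a smooth broadband-albedo target; the thermal
  band is the brightness temperature whose emissivity correction returns
  the constructed Ts (closed-form inverse).
* **Noise.** Per-pixel white Gaussian noise: 0.004 reflectance units
  (OLI-class SNR) and 0.1 K thermal (TIRS-class NEΔT). The generator does
  *not* emulate spatially correlated atmospheric residuals, clouds beyond a
  binary mask, sensor PSF, or topographic illumination — so passing noisy
  tests demonstrates robustness to sensor noise, not to atmospheric
  miscorrection. Correlated error chiefly attacks anchor selection and
  would need a separate study.
* **Meteorology.** Daily station series over the season: a deterministic
  seasonal cosine (amplitude 6 °C, peak mid-July) around configured means
  (Tmax 29 / Tmin 17 °C, RH 55%, wind 2.2 m/s, sunshine 65% of daylength —
  a mid-latitude semi-arid summer), plus Gaussian noise and gamma-
  distributed wet-day precipitation. Physical orderings (Tmin ≤ Tmean ≤
  Tmax, sunshine ≤ daylength) hold by construction. Overpass air
  temperature sits 3 °C above the daily mean (mid-morning).
* **Yields.** Zone yields are normal draws (mean 577.046, sd 60 kg/mu)
  clamped to [386.794, 754.896] kg/mu — the span reported for the region
  the defaults emulate. The survey protocol behind such tables is not
  modelled; zone yields are treated as given scalars.
* **Determinism.** One integer seed drives every draw through seeded
  generators; identical config ⇒ bit-identical rasters and tables.

## Numerical choices and degenerate inputs

* NDVI with zero denominator, zero-albedo pixels in G, and Rn−G ≤ 0 pixels
  are masked (NaN), never propagated silently.
* Negative ET and Λ are floored at 0; Λ capped at 1 (cold-pixel definition).
* Anchor pools use configurable NDVI quantiles (0.95 / 0.10), chosen to be
  robust on 100×100 scenes; pools that empty after masking raise with a
  diagnostic.
* The stability loop returns its last iterate with a warning flag on
  non-convergence; wind ≤ 0 and inverted anchor temperatures are rejected.
* Rasters are float64 TIFF with a JSON sidecar carrying grid geometry and
  scene metadata; every ingestion checks the run's single grid and rejects
  mismatches rather than resampling. Config files reject unknown keys.

## Problem sizes

The test suite and the acceptance script run on 100×100 scenes (10⁴
pixels), 10 noisy replicates, 50 randomized met records for the
Penman–Monteith cross-check, and 100 replicates of 10⁴ pixels for the
correlation null — sizes at which every property under test (anchor
calibration, interpolation error, null calibration) is already fully
expressed; the whole suite runs in seconds.

## Known limitations

* Λ24 = Λinst ignores advection; under strong regional advection daily ET
  is biased low. No METRIC-style reference-ET-fraction upscaling.
* Single-station instantaneous wind per scene; no gridded wind.
* The dT–Ts line is global per scene; lateral heterogeneity in air
  temperature is folded into the calibration.
* WP attribution is correlational only; no causal claims, no irrigation
  optimization, no multi-year trends.
* The generator's realism limits are listed above; conclusions about real
  imagery require real validation data.
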