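# Methods

This note documents the models behind the `pasture` package: what each one
assumes, the parameters that matter, and the design choices made where the
underlying science left the design open.

## The pipeline

The package links remote sensing to rotational-grazing decisions in five
steps:

1. **NDVI** from a two-band reflectance raster:
   NDVI = (NIR₇₈₀ − RED₆₆₀)/(NIR₇₈₀ + RED₆₆₀), per pixel.
2. **Biomass calibration**: standing dry matter per pixel or paddock from
   the exponential relation `biomass = α·exp(β·NDVI)` (kg DM ha⁻¹), fitted
   to plot-scale harvest data.
3. **Regrowth simulation**: a daily radiation-use-efficiency (RUE) kernel
   turns weather into a pasture growth rate (kg DM ha⁻¹ d⁻¹).
4. **Morphogenesis and digestibility**: a thermal-time tiller model turns
   residual sward height and temperature into leaf stage, blade length,
   NDF, NDFD and DMD.
5. **Rotation planning**: standing biomass plus the growth rate give
   back-calculated post-grazing residuals, pre-grazing forecasts,
   days-to-target and a grazing wedge.

Each step is an independent module; the agreement-statistics module
(`evaluation`) closes the loop by quantifying how well any estimate matches
a reference.

## NDVI and aggregation

Pixel membership in a polygon or point buffer uses **pixel-center
containment**: a pixel belongs iff its center falls inside. The rule is
standard, reproducible, and invariant to raster tiling (verified by test);
edge pixels are not area-weighted. NDVI of senescent/soil pixels is kept at
this layer — thresholding is a calibration-level concern, since real swards
show meaningful NDVI well below 0.3. All geometry lives in a projected CRS
in metres; geographic coordinates are rejected with a reprojection hint
rather than silently mis-measured, because buffer radii (e.g. the 1-m
point-intersection protocol) must be true distances.

Rasters are carried in a light container (array + affine transform + CRS
label + nodata) with GeoTIFF-style I/O via `tifffile` (ModelPixelScale,
ModelTiepoint and GDAL_NODATA tags); round-trips are bit-exact.

## Exponential biomass calibration

`fit_exponential` estimates (α, β) by nonlinear least squares on the
original biomass scale — so the reported R² refers to biomass, the
quantity managers care about — initialized from the log-linear regression
ln(biomass) = ln α + β·NDVI. A flat response is detected and returns
α = geometric mean with an `uninformative` flag. Predictions above the
NDVI saturation threshold (default 0.8, where the index stops responding
to additional leaf area, roughly LAI > 3) are **flagged, never
truncated**. Height-based calibrations (towed pasture-meter in mm, sward
stick in cm) carry their unit in the type; a unit mismatch is an error
because the two instruments genuinely use different units and silent
coercion is the classic failure mode.

The species-pooling decision uses the extra-sum-of-squares F-test between
a pooled and two per-species exponential fits, pooling when p > 0.05.
Under its own assumptions (additive, homoscedastic errors) the test is
nominal — the acceptance suite verifies a ~5% type-I rate by simulation.
With multiplicative (lognormal) noise the original-scale F-test is
anticonservative; if errors are believed multiplicative, fit and test on
the log scale instead (the log-linear machinery is exposed).

## Growth kernel

Daily above-ground growth is

    dB/dt = RUE · (S·f_PAR) · (1 − e^(−k·LAI)) · f_T · min(f_water, f_N)

with S the daily solar radiation (MJ m⁻² d⁻¹). This is a deliberately
reduced process model: **soil water and nitrogen balances are not
simulated**; stress enters as exogenous multipliers in [0, 1] supplied by
the caller. The contract downstream is only a daily growth rate, and this
keeps every term inspectable.

Defaults (all overridable in `params/defaults.yaml`):

| parameter | default | unit | note |
|---|---|---|---|
| RUE | 0.9 | g DM MJ⁻¹ PAR | above-ground net; 0.8–1.2 typical for temperate pasture |
| k (extinction) | 0.6 | – | grass canopies 0.5–0.7 |
| f_PAR | 0.48 | – | PAR fraction of global radiation |
| SLA | 25 | m² kg⁻¹ | temperate C3 forage |
| leaf partition | 0.6 | – | share of growth returning to leaf area |
| T_base | 4 | °C | C3 grasses |
| T_opt | 16–25 | °C | plateau of the piecewise-linear response |

Thermal time accrues as max(0, (Tmin+Tmax)/2 − T_base). LAI feeds back
from leaf-partitioned growth via SLA; there is no senescence pool in this
kernel (leaf-level senescence lives in the tiller model), so multi-month
ungrazed simulations overstate standing biomass — horizons of one or two
rotations (≤ ~30 d) are the intended use. Mass balance (final = initial +
Σ growth) is exact to floating tolerance and tested over 90 days.

## Tiller morphogenesis and nutritive value

The tiller model is driven purely by thermal time: a new leaf is initiated
every phyllochron; a leaf elongates at a fixed rate for an elongation
duration (default 0.33 × lifespan) and senesces when its age exceeds the
leaf lifespan. Leaf stage counts live leaves produced **since
defoliation** (the standard grazing leaf-stage convention; the cut stubble
leaf is excluded), with the youngest counted fractionally by its
elongation progress. It therefore rises monotonically during regrowth and
plateaus near lifespan/phyllochron live leaves.

Grazing severity enters through a sheath-tube proxy: the elongation
duration (hence the potential final blade length) scales with
(residual height / 6 cm)^0.5. Severe grazing thus shortens the successive
leaves — and, through the length coefficients below, improves their
quality.

Nutritive value follows leaf demography:

* maturity = length-weighted mean relative leaf age of live leaves;
* NDF interpolates linearly from `ndf_min` (young sward) to `ndf_max`
  (fully aged sward) in maturity; NDFD decays from `ndfd_max` to
  `ndfd_min` likewise;
* the sward's *potential* final blade length shifts both (+0.15 % NDF and
  −0.30 % NDFD per cm of deviation from the reference-residual length) —
  using the potential rather than the instantaneous mean length keeps
  quality dynamics smooth across leaf-appearance events;
* DMD = (100 − NDF) + NDF·NDFD/100 − metabolic correction, i.e.
  neutral-detergent solubles treated as fully digestible (the summative
  convention; an assumption, flagged here).

The in-vitro branch implements the 24-h assay arithmetic: NDFD =
(NDF_incubated − NDF_residual)/NDF_incubated, true DMD = 1 −
NDF_residual/DM_incubated, apparent DMD = true DMD − metabolic
correction. The correction constant ships as **119** with g kg⁻¹ units
(11.9 percentage points); the figure is sometimes printed as mg kg⁻¹, but
the assay convention it comes from is g kg⁻¹, and 0.0119 points would be
a physiologically meaningless correction.

Species parameter files: tall fescue is the reference set (lifespan
630 °Cd, phyllochron 210 °Cd, elongation 0.15 cm °Cd⁻¹ — the two rates are
literature-plausible defaults and user-replaceable). Perennial ryegrass is
derived by four fixed adjustments reflecting its faster leaf turnover and
better feed quality: lifespan 330 °Cd, appearance and elongation rates
two-fold fescue's, minimum NDF 5 units lower, maximum NDFD 20 units
higher. `derive_ryegrass()` applies exactly these rules and the packaged
YAML is asserted against them in tests. Whether NDF/NDFD dynamics are
linear or saturating in leaf age is not settled; linear is the default and
the interpolation is isolated in one function.

## Rotation planner

post-grazing = UAV − G·days_of_regrowth (floored at 0 with an
inconsistency flag); pre-grazing = UAV + G·days_in_rotation;
days-to-target = ⌈(Target − UAV)/G⌉. Days are rounded **up** because
reaching the target is a ≥ constraint; the ceiling guarantees
pre_grazing(days_to_target) ≥ target, property-tested over randomized
states. A zero growth rate below target yields an infinite sentinel with a
flag, not an exception. The wedge ranks paddocks by descending biomass
with a stable sort (ties keep input order, so plans are reproducible), and
the recommended rotation extension is the largest day-deficit among
paddocks forecast below target. Management defaults: pre-grazing target
2700, post-grazing 1300, minimum farm cover warning 1800 kg DM ha⁻¹. The
growth rate may be one farm-level value or per-paddock rates from the
growth module.

## Agreement statistics

Lin's CCC uses population (1/n) moments — at small n, mixing in sample
moments changes the value, so the convention is fixed and documented;
Cb = CCC/r. The accuracy regression is reference ~ estimate with t-tests
of intercept = 0 and slope = 1 (sample-moment OLS). RE = RMSE / mean of
the **reference** series × 100. Method comparison scores an estimate
against the mean of two controls, reports paired two-sided t-tests
(α = 0.05) and the fraction of deviations within ±500 kg DM ha⁻¹. Missing
pairs are dropped listwise with a reported count, never imputed.

## Synthetic scenes

The generator emulates the study platform: two blocks of eight 1-ha
(200 × 50 m) paddocks. The biomass field is lognormal (default mean 1800
kg DM ha⁻¹, CV 0.45, clipped to 250–4000) with spatial structure from
Gaussian-filtered white noise (correlation length = filter σ, default
30 m) — cheap and sufficient for testing aggregation logic, not a
variogram-calibrated geostatistical simulation. Reflectance is constructed
by inverting the true calibration (defaults α = 66.5, β = 5.32, chosen so
the biomass range 226–4208 kg DM ha⁻¹ maps onto NDVI 0.23–0.78): NIR is a
fixed canopy profile and the red band is solved from the target NDVI,
because only NDVI matters downstream. Observation noise is multiplicative
lognormal on biomass (the true noise structure of UAV reflectance is not
known; the CV is configurable). A noiseless scene therefore round-trips
biomass → NDVI → biomass to machine precision, which is what the
closed-loop tests exploit.

What the generator does **not** emulate: sensor physics, orthomosaic
stitching artifacts, bidirectional reflectance, mixed pixels at paddock
edges, or dead-material spectral contamination. Passing closed-loop tests
therefore demonstrates the pipeline's internal consistency, not field
accuracy.

Synthetic weather draws AR(1) temperature anomalies around a seasonal
profile, gamma-distributed wet-day rainfall, and radiation co-varying
negatively with rain; the `constant` profile (20 °C, 20 MJ, dry) gives the
fixed 16 °Cd d⁻¹ clock used by deterministic model tests. All randomness
flows from a single integer seed through named generators.

## Problem sizes

Tests and the acceptance script run on scenes of 2–16 paddocks at 2–5 m
pixels (the 6-cm flight resolution is configurable but pointless for unit
testing), 72-plot calibrations matching the study design, 200-rep
bootstraps, and 500-rep null simulations; the whole suite completes in
well under a minute.

## Known limitations

* The growth kernel's stress factors are inputs, not predictions; there is
  no soil water/N state, so drought dynamics cannot emerge.
* The tiller model tracks a single representative tiller — no tiller
  demography, no legume fraction (the study pastures carried 15–40%
  legume), no dead-material pool after leaf senescence (senesced leaves
  leave the live pool at once, producing small sawtooth oscillations in
  sward quality at steady state).
* The NDF/NDFD length coefficients and the sheath-proxy exponent are
  plausible but uncalibrated against tissue data; they are exposed in the
  species YAML files precisely so they can be refitted.
* CCC/Cb sentinels are NaN when either series has zero variance; callers
  must handle that case.
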