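# Methods

## Coordinate model

All georeferencing is geographic WGS84 degrees. Grids are regular,
north-up, 0-based row-major with the origin at the upper-left *corner*:
pixel (u, v) has its centre at

    lat = lat_origin − (u + 0.5) · pixel_height
    lon = lon_origin + (v + 0.5) · pixel_width

Pixel footprints are half-open boxes — longitude [west, east), latitude
(south, north] — so footprints tile the plane and every point belongs
to exactly one pixel. Where metric distances are needed (kriging,
routes, row geometry) coordinates are projected to a local
equirectangular frame: 1° latitude = πR/180 m and 1° longitude scaled
by cos(latitude) at the anchor. At field scale (hundreds of metres near
38° N) the distortion of this approximation is far below a UAV pixel.

Rasters travel as multiband float32 GeoTIFFs (via tifffile) carrying
ModelPixelScale/ModelTiepoint tags and a GeoKeyDirectory declaring
EPSG:4326; band names, radiometry tag and nodata fill value ride in the
ImageDescription as JSON. Nodata is NaN in memory and a declared fill
value (default −9999) on disk. Files in a projected CRS are rejected
with an explicit error rather than silently misread.

## NDVI and radiometry

NDVI = (NIR − Red)/(NIR + Red) per pixel. The ratio is invariant under
a common positive rescaling of both bands, so it is computed on
whichever radiometry (surface reflectance or raw digital numbers) a
raster declares — but a band stack mixing the two is rejected, because
the ratio is only scale-invariant when both bands share a scale.
NIR + Red = 0 makes the ratio undefined; such pixels become nodata
rather than 0, which would masquerade as moderate vigour.

Vigour classes use half-open bins: low < t_low ≤ medium < t_high ≤
high. "Tertile" mode places the breaks at the empirical 33.3/66.7
percentiles of valid values. Rendered palettes follow the vigour-map
convention red = low, yellow = medium, green = high.

## Footprint correspondence and aggregation

A UAV pixel belongs to the satellite cell whose half-open footprint
contains its *centre* (a point test, not an area weighting). With the
study GSDs — 10 m satellite, 5 cm UAV, aligned origins — each interior
cell receives exactly 200 × 200 = 40,000 centres; the implementation
realises the box test as a floor on the row/column offset, and the
half-pixel margin between any centre and any cell edge (1/400 of a
cell) keeps floating-point rounding harmless.

Aggregated NDVI sums per-pixel UAV NDVI over a selected set (whole
cell, canopy-only, inter-row-only) per cell. Two denominator modes:

* **restricted** (default): divide by the selected set's cardinality — a
  true conditional mean, so NDVI_vin is genuinely "canopy vigour";
  exact identity: NDVI_uav = (|P_vin|·NDVI_vin + |P_int|·NDVI_int)/|P|.
* **printed**: divide by the full cell cardinality |P(i,j)| even for the
  restricted sums; exact identity: NDVI_uav = NDVI_vin + NDVI_int.

Both identities hold to machine precision and are asserted in tests.
Cells whose footprint coverage by the UAV extent falls below 95% (or
whose selected set is empty) are nodata — partially seen cells would
otherwise report a biased mean.

Note the deliberate asymmetry with rendering: a satellite sensor
averages *reflectances* inside its IFOV and the ratio comes after
(ratio of means), while aggregation averages per-pixel *ratios* (mean
of ratios). On mixed pixels these differ — that difference is the
mixing artefact the decomposition corrects, and the test suite asserts
it is nonzero on non-constant scenes.

## Canopy segmentation

Canopy vs inter-row is separable in NDVI at 5 cm GSD, so the partition
thresholds the UAV NDVI map: Otsu's between-class-variance maximiser on
a 256-bin histogram by default, or a user threshold (canopy is
NDVI ≥ t). Cleanup: morphological opening with a 2-pixel disc and
removal of connected canopy components under 0.1 m² (both
configurable, both chosen for 5 cm speckle; disable them to get the
raw threshold). Inter-row is the complement over valid pixels, so the
partition is disjoint and exhaustive by construction.

Row azimuth is estimated by scanning candidate directions at 0.5°
steps over [0°, 180°): the NDVI field is projected onto the across-row
axis, binned at pixel resolution, and scored with an F-like statistic
(between-bin mean square over within-bin mean square). The true row
direction preserves the 2 m periodicity and scores orders of magnitude
above the median candidate; a parabolic refinement around the peak
gives sub-step accuracy. If the peak score is below 3× the median the
map is declared structureless (warning, NaN). The F form is used
instead of the raw profile variance because bin populations change
with projection angle, which inflates the raw variance of diagonal
projections even on pure noise; the default ratio 3 sits between the
~1.4–1.9 reached by noise maps and the >10³ reached by row scenes.

## Soil-moisture kriging and calibration

Moisture is estimated at survey points as a clipped linear combination
of covariates (raw capacitance counts, NDVI, rainfall, ...), then
interpolated by **ordinary kriging**: the best linear unbiased
predictor under an unknown constant mean, solving the augmented
semivariance system with a Lagrange multiplier enforcing Σw = 1.
γ(0) = 0 on the diagonal, so samples are honoured exactly; γ(0⁺)
equals the nugget. Variogram families use the practical-range
parameterisation (95% of the sill reached at `range_m`):
exponential 1 − e^(−3h/a), gaussian 1 − e^(−3(h/a)²), spherical
1.5(h/a) − 0.5(h/a)³.

Variogram fitting is weighted least squares of the chosen family to
the empirical semivariogram (15 lag bins up to half the maximum
pairwise distance) with N(h)/h² weights — the common geostatistical
default, which privileges the short lags that carry the range
information. Single-realisation WLS estimates of range and sill are
noisy; the recovery tests therefore simulate five independent fields
under a nested survey design (half base stations, half satellites at
0.5–6 m offsets, which pins the short-lag behaviour) and check the
*median* fitted parameters, testing the estimator rather than one
realisation's luck.

Calibration against in-situ probes is an exhaustive grid search over
(variogram × covariate-coefficient × intercept) configurations: each
candidate's covariate model produces sample estimates, those are
kriged at the probe locations, and the configuration minimising mean
absolute error against the probe readings wins; ties break towards
smaller nugget, then smaller range. Soil-moisture values are
everywhere constrained to the capacitance probe's calibrated 0–0.57
VWC range.

## Alerts and routing

A satellite-grid cell becomes an attention point when its kriged
moisture falls below `moisture_min` (default 0.25 VWC, a plausible
irrigation trigger for loam; site-specific in practice) or its canopy
NDVI falls below `ndvi_min` (default 0.45). Severity is the summed
fractional shortfall (threshold − value)/threshold over triggered
reasons. Nodata cells are never flagged.

The route is a closed tour from a depot ordered by a
permutation-encoded GA: order crossover (OX), swap mutation,
tournament selection of size 3, elitism of 1. The objective is the
weighted scalarisation w_dist · tour_length + w_priority ·
Σ rank·severity, so severity can pull urgent cells forward at the cost
of distance; with w_priority = 0 it is a plain TSP. Defaults: 100
individuals, 300 generations, crossover 0.9, mutation 0.8. The high
swap-mutation rate keeps diversity under the strong elitist/tournament
pressure; with it the GA reproduces the exhaustive 8-point optimum on
every random instance tried, and elitism makes the best objective
non-increasing across generations. Runs are deterministic given the
seed.

## Synthetic scene simulator

The simulator lays out canopy strips of `canopy_width_m` (default 1 m)
every `row_spacing_m` (default 2 m) along `row_azimuth_deg` in a local
metric frame, converted to degrees at the scene latitude. Vigour is
base + linear trend + smoothed Gaussian noise, clipped to [0, 1].
Reflectance is linear in vigour —

    canopy: red = 0.18 − 0.12·v   nir = 0.25 + 0.55·v
    soil:   nir = 0.30, red set so soil NDVI = soil_ndvi_mean (default 0.15)

— making canopy NDVI strictly increasing in vigour and spanning
~0.3–0.86, a typical vine/soil contrast. Moisture is a smoothed,
mean-centred, unit-variance Gaussian random field scaled to
`moisture_sd` (default 0.06 VWC) around `moisture_mean` (0.30 VWC)
with a 30 m correlation length, clipped to the probe range. Rendering
to any coarser GSD is exact area-weighted block averaging of
reflectance; partial edge blocks average what they cover.

What the simulator does *not* emulate: atmospheric and BRDF effects,
shadows, phenological change between acquisition dates, georegistration
error between platforms, weeds/cover crops in the inter-row, and any
nonlinearity between vigour and reflectance. Tests passing on these
scenes therefore demonstrate the correctness of the pipeline's
geometry, arithmetic and estimators — not robustness to those
real-data effects; segmentation IoU ≈ 1 here is an upper bound, not a
field expectation.

## Pipeline determinism and problem sizes

The pipeline (simulate → NDVI → segment → fuse×3 → calibrate/krige →
advise → route) is configured by one schema-validated document; unknown
keys are rejected, and requesting canopy fusion with segmentation
disabled fails validation before execution. A single global seed fans
out to per-stage seeds via `SeedSequence([seed, stage_index])` (kept
below 2³¹), so partial reruns match full runs. The manifest records
config, stage seeds, outputs and SHA-256 checksums and contains nothing
time-dependent: identical configs give byte-identical manifests.

Default test/demo problem sizes are desk-scale by design: scenes of
30–60 m sides at 5–10 cm ground resolution (≈10⁵–10⁶ ground-truth
pixels), 40–200 kriging samples, 8–21 route points. These exercise
every code path, including the exact 200 × 200 footprint ratio, while
keeping the full suite and the acceptance script within a few minutes
on one CPU.
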