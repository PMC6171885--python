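# Methods

This note documents the models, conventions and design choices behind
`fmc-hazard`, in the order the pipeline runs them.

## Scope and data model

The pipeline operates on a planar, axis-aligned grid of square 500 m pixels
(25 ha), with a season axis of 31 eight-day composite dates (days of year
121, 129, …, 361; May–December). Rasters are numpy arrays with `NaN` as the
missing marker (sentinel −9999 on disk); land cover is categorical with
codes {0 other, 1 grassland, 2 shrubland, 3 chaco_forest}. "Other"
(cultivated land, water, urban) has no FMC equation and is always missing.
Fire events are shapely polygons with a start date (year, day of year) and
an area in hectares. Raster files are written as TIFF with the grid
metadata embedded as JSON in the description tag; fires as GeoJSON;
tables as CSV; thresholds and configuration as YAML.

## Index computation and smoothing

NDVI, EVI and GVMI follow their standard definitions; any pixel-date with a
missing input band (or reflectance outside [−0.1, 1.1] after scaling) is
missing, as is any date where a denominator vanishes. Smoothing is
Savitzky–Golay along the date axis with half-width 3 (a ±24-day window) and
polynomial order 2. Order 2 is our choice: it is the conventional order for
8-day vegetation-index series and preserves the seasonal curvature that the
forest equation integrates. The filter is implemented as an explicit linear
operator (31×31 weight matrix), with three consequences that the tests
verify: it is exactly linear, it reproduces polynomials up to order 2
exactly, and boundary points are handled by refitting the polynomial over
the *truncated* window rather than mirror padding — season edges therefore
never see phantom data. Missing values are linearly interpolated before
filtering when a gap spans at most 2 consecutive composites; longer gaps,
and gaps touching either end of the season, stay missing.

The cumulative predictor *I* ("integral") is defined here as the running
sum of smoothed NDVI over composite dates from the season start through the
current date, in composite-step units. The calibration literature that
introduced the predictor does not pin down its units or window in a way we
can verify, so this running-sum convention is a documented assumption; the
definition is a single pluggable function (`compute_integral`) so a
trapezoidal or windowed variant can be swapped without touching callers.
All synthetic ground truth is generated under the same convention, which
keeps every internal consistency check exact. *I* accumulates smoothed
NDVI and is not itself re-smoothed.

## FMC mapping

One linear equation per land cover (coefficients in the README) is applied
per pixel and date. The coefficients are data, not code: they default to
the Sierras Chicas calibration and can be overridden in configuration for
re-calibrated regions. Outputs are deliberately not clamped — the observed
calibration range spans roughly 6–183 %, and negative or very large
estimates are preserved and merely counted in a diagnostics report, so that
configuration problems surface rather than disappear. Land-cover maps are
era-specific (default split: up to 2006 / from 2007) and are selected by
the year of the data being mapped; fires use the era map of their own year.
Fine-scale categorical maps are aggregated to the analysis grid with a
majority filter; ties break toward the lowest class code, a deterministic
and documented rule.

## Pre-fire extraction

Each fire is matched to the last composite *strictly* before its start day:
the composite window containing the ignition day may already include the
burn signal. Strictness is a flag for sensitivity analyses. Pixels belong
to a fire when their centers fall inside the polygon (the standard
zonal-statistics convention). Fires below 100 ha (four pixels) are
excluded. Pixel-level samples carry each burned pixel's cover and pre-fire
FMC and feed the threshold derivation; fire-level samples pool all covers
into one zonal mean per fire ("one fire = one sample") and feed the size
statistics, discarding fires with more than 25 % of their in-grid area
lacking FMC. Fires extending beyond the mapped grid are clipped and the
coverage fraction recomputed over the in-grid part. Size classes are
half-open and low-inclusive: small [100, 500), medium [500, 1000),
large [1000, ∞) ha.

## Hazard thresholds and classification

Per-cover thresholds are the P60/P85/P97 percentiles of the pre-fire pixel
FMC distribution, computed by linear interpolation of order statistics
(the order statistic at rank 1 + (n−1)p). The percentile choices are
configuration with those values as defaults — users wanting a more
conservative product can raise them. Covers with fewer than 30 samples
(configurable) are omitted rather than given unstable cuts. Classification
is inclusive on the hazardous side (FMC equal to a cut gets the more
hazardous class), the conservative convention for an early-warning product.
A built-in consequence worth stating: evaluating a sample against
thresholds derived from that same sample necessarily yields ≈ 60/25/12/3 %
in Extreme/High/Moderate/Low (up to 100/n discreteness), so that split is
a construction identity, not an empirical finding; the informative
comparison is against *external* thresholds, which must be fully specified
(the chaparral-derived extreme/high cuts of 60 % and 77 % have no published
moderate/low companion, so that third cut is required configuration, never
a hardcoded guess).

## Fire-size statistics

Small vs. large fires are compared with the tie-corrected Kruskal–Wallis
rank test (scipy's implementation; the degenerate all-equal case returns
H = 0, p = 1). Medium fires are excluded from the two-group comparison by
default, mirroring analyses where intermediate sizes are too few to test.
Quantile regression of fire size on mean pre-fire FMC is fitted at deciles
τ = 0.1…0.9 by solving the pinball-loss minimization exactly as a linear
program (HiGHS); a brute-force grid-search oracle in the tests confirms the
minima on small datasets. Goodness of fit per τ is the Koenker–Machado
pseudo-R¹, 1 − V(τ)/Ṽ(τ), with Ṽ the loss of the intercept-only fit (the
empirical τ-quantile) — the definition reported by the standard quantile
regression software, which keeps published values comparison-valid. Slope
uncertainty comes from a seeded nonparametric bootstrap over fires
(percentile 95 % CI and a two-sided sign-based p-value); rank-inversion
inference is not implemented. Fitted quantile curves can cross in finite
samples; a crossing report flags violations at a reference FMC instead of
silently accepting or "repairing" them.

## Seasonal summaries

Per cover and composite date, the spatial mean FMC of each year is averaged
across the years of a stratum. Years are stratified by the burned fraction
of the mapped (non-"other") area: > 3 % high activity, < 1 % low, the
interval between belonging to neither (strict inequalities). Dispersion is
reported three ways — pooled across years and space (the default error
bar), mean spatial sd, and inter-annual sd of the yearly means — because
"average standard deviation" is ambiguous across those choices. Durations
below a threshold count 8 days per composite with strict inequality; all
published duration figures in this line of work are multiples of 8, which
is what that convention produces.

## Synthetic-data generator

The generator defines the study conditions for all tests.

* **Land cover**: Gaussian-smoothed (σ = 4 pixels) seeded noise thresholded
  at the quantiles of the requested proportions — spatially clumped patches
  with class frequencies pinned to the target. Defaults: 35 % grassland,
  30 % shrubland, 25 % forest, 10 % other.
* **FMC trajectories**: per cover, a piecewise-linear template declining
  from a season-start value to a minimum in August–September (day of
  minimum constrained to DOY 213–273), then recovering linearly, plus AR(1)
  noise (lag-1 correlation 0.6) with stationary sd 7–9 %, truncated at 0.
  Defaults (start → minimum at DOY): grassland 90 → 40 % at 245, forest
  110 → 65 % at 241, shrubland 130 → 95 % at 249. These emulate the
  published seasonal ranges — grasslands driest, shrublands wettest — but
  the trajectory *form* is a stand-in; no distributional claim is attached
  to it. A per-year additive offset supports constructing high/low activity
  strata with a known contrast.
* **Exact inversion**: indices are manufactured so that the mapping stage
  reproduces the latent FMC to machine precision. Grassland EVI solves its
  equation directly. Forest NDVI is solved sequentially through the
  integral recursion I_t = I_{t−1} + NDVI_t. Shrubland fixes NDVI and GVMI
  trajectories and solves EVI — the only sequentially solvable choice given
  the integral term; its GVMI profile is chosen to balance the integral
  term so the solved EVI stays in a physically invertible range all season.
  Reflectance is then obtained by inverting the index definitions at a
  fixed NIR profile (red from NDVI, blue from EVI, SWIR from GVMI). Band
  values exist only to exercise index computation; nothing radiative is
  simulated.
* **Fires**: ignition dates and pixels are sampled with mild preference for
  low FMC (e-folding 60 %), so small fires occur across the whole moisture
  range; the FMC–size coupling lives in the cap — a fire's maximum area is
  60 000 · exp(−0.05 · FMC_local) ha, with FMC_local the 5×5-pixel mean at
  ignition. Target sizes are Pareto (α = 0.6, minimum 50 ha) truncated at
  the cap; fires grow as random connected pixel patches and are stored as
  pixel-set polygons (rasterized from birth), sidestepping sub-pixel area
  ambiguity. Fires start strictly after the first composite so a pre-fire
  map always exists. Under these defaults the generator reproduces the
  qualitative targets it is specified to have: large fires at lower median
  pre-fire FMC than small fires and a negative upper-decile size-on-FMC
  slope, across seeds.
* Synthetic rasters are generated directly at the 500 m analysis grid; the
  30 m → 500 m majority resampling is exercised on small fixture rasters
  instead of oversized fine grids.

What passing tests on synthetic scenes do **not** show: robustness to real
atmospheric/QA artifacts, to land-cover misclassification, to fire-date
errors, or to FMC model error — on real data the equations are approximate
(calibration R² 0.57–0.88), whereas the generator makes them exact by
construction.

## Numerical choices and degenerate inputs

Percentiles everywhere use the linear-interpolation convention; reproducing
published percentile tables under a different convention can differ in the
last decimal, which is why reproduction tolerances are ±0.2. The LP fitter
refuses zero-variance predictors (singular fit) and the band inversion
refuses EVI ≈ 0 (blue unsolvable), naming the offending pixel/date. Index
inversions outside [−1.5, 1.5] warn but keep values — they signal an
unrealistic configuration, not a numerical failure. Seeded `numpy`
Generators flow from a single configured seed (spawned per year and
purpose), making scenes, fires, bootstraps and pipelines bit-reproducible.

## Problem sizes

Tests and examples run on 48×48 to 100×100 grids with 1–4 seasons and
~200 fires per statistical scene; replicate counts are 20 for the
stochastic generator properties. These sizes put every Monte-Carlo check
comfortably inside its sampling tolerance while keeping the whole suite
fast; all are configuration, and nothing in the implementation depends on
grid size.

## Known limitations

* The integral predictor's convention is an assumption (see above);
  absolute FMC values from real imagery depend on it for forests and
  shrublands.
* Equation coefficients are region-specific; applying the defaults outside
  the Chaco Serrano calibration domain is extrapolation.
* No atmospheric correction, QA filtering, cloud masking or reprojection:
  inputs are assumed analysis-ready on a common grid.
* Rank-inversion CIs for quantile-regression slopes are not implemented
  (bootstrap only).
* Hazard classes quantify potential fire activity given moisture; they are
  not a fire-behavior or suppression-difficulty forecast, and moisture
  alone under-represents hazard in forests.
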