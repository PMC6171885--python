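# fmc-hazard

Fuel moisture content (FMC) is the water mass of vegetation fuels as a
percentage of their dry mass; dry fuels ignite easily and carry fire, wet
fuels do not. `fmc-hazard` is a Python library (with a thin CLI) for turning
8-day satellite surface-reflectance composites into land-cover-specific FMC
maps and percentile-based wildfire hazard classes, aimed at fire ecologists
and people building operational early-warning systems for fire-prone
seasonally dry landscapes such as the Chaco Serrano of central Argentina.

## What it computes

**FMC mapping.** For each 8-day composite date of the May–December fire
season (days of year 121–361, 31 dates), spectral indices are computed from
red/NIR/blue/SWIR reflectance —

- NDVI = (NIR − red) / (NIR + red)
- EVI = 2.5 (NIR − red) / (NIR + 6 red − 7.5 blue + 1)
- GVMI = ((NIR + 0.1) − (SWIR + 0.02)) / ((NIR + 0.1) + (SWIR + 0.02))
- *I* (integral) = running sum of smoothed NDVI over the season's composites

— smoothed along the date axis with a Savitzky–Golay filter (±3 composites,
order 2), and fed to one fitted empirical equation per land cover:

| land cover | equation (FMC in % dry weight) |
|---|---|
| grassland (fuelbed) | FMC = 540.09 · EVI − 31.16 |
| Chaco Serrano forest (live) | FMC = 1.88 · *I* + 246.39 · NDVI − 63.06 |
| shrubland (live) | FMC = 334.53 · EVI − 305.98 · GVMI − 7.05 · *I* + 199.72 |

**Hazard thresholds.** For every fire ≥ 100 ha in a fire database, the FMC
map immediately *before* ignition is sampled inside the burned polygon. The
per-cover P60 / P85 / P97 percentiles of these pre-fire pixel values bound
four hazard classes — FMC ≤ P60 is Extreme, ≤ P85 High, ≤ P97 Moderate,
above that Low — so that, by construction, the two most hazardous classes
would have flagged ~85 % of the area that actually burned.

**Statistics.** Fire-level zonal means (one fire = one sample, fires with
> 25 % missing FMC discarded) support a tie-corrected Kruskal–Wallis test
between small (100–500 ha) and large (≥ 1000 ha) fires, and decile quantile
regressions of fire size on pre-fire FMC with Koenker–Machado pseudo-R¹
(fitted exactly as a linear program on the pinball loss, bootstrap CIs).
Seasonal summaries average FMC per cover and date across years stratified
by fire activity (burned area > 3 % = high, < 1 % = low) and count the days
(8 per composite) spent below each hazard cut.

**Synthetic scenes.** Because reflectance archives and fire databases are
large and proprietary to assemble, a first-class generator produces clumped
land-cover rasters, seasonal FMC trajectories with an August–September
minimum plus AR(1) noise, index/reflectance stacks that invert the
equations above *exactly*, and fire events whose maximum size is capped by
a decreasing function of local pre-fire moisture. Every analysis stage is
therefore testable end-to-end, with known ground truth, offline.

## Worked example

```python
import numpy as np
import fmc_hazard as fh
from fmc_hazard.synthetic import FireParams

config = fh.SimulationConfig(rows=60, cols=60, years=(2008,), seed=5,
                             fire_params=FireParams(expected_per_year=220))
landcover = fh.generate_landcover(config)
latent = fh.generate_fmc(config, landcover, 2008)
fires = fh.generate_fires(latent, landcover, config)

pixels = fh.extract_pixel_samples(fires, {2008: latent})
thresholds = fh.derive_thresholds(pixels)
samples = fh.extract_fire_samples(fires, {2008: latent})
print(thresholds.to_dict()["grassland"])
print(fh.summarize_by_size(samples)[["size_class", "n", "median"]])
print("KW:", fh.compare_small_large(samples))
```

prints

```
{'extreme': 64.43..., 'high': 80.79..., 'moderate': 92.97...}
  size_class    n  median
0      small  117    86.0
1     medium   20    85.0
2      large   12    71.8
KW: (5.2277..., 0.0222...)
```

The grassland Extreme/High/Moderate cuts are the P60/P85/P97 of 2544
burned-pixel FMC samples; large fires burned at a median pre-fire FMC
~14 points lower than small fires, and the Kruskal–Wallis test rejects
equal distributions (p ≈ 0.02) — the moisture–fire-size coupling the
hazard product relies on. `examples/` contains one narrative script per
capability (inversion identity, threshold derivation, size statistics,
seasonal curves, full pipeline); `fmc-hazard run --config my.yaml` drives
the same stages from the shell.

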