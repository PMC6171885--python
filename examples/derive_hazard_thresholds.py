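"""Derive per-cover hazard thresholds from pre-fire burned-pixel samples.

Simulates a fire season, extracts the FMC of every burned pixel from the
last composite before each fire, computes the P60/P85/P97 percentiles per
land cover (the Extreme/High/Moderate cut points), and checks what share
of the burned pixels each hazard class would have flagged.
"""

import fmc_hazard as fh
from fmc_hazard.synthetic import FireParams

config = fh.SimulationConfig(
    rows=60, cols=60, years=(2008,), seed=5,
    fire_params=FireParams(expected_per_year=220))
landcover = fh.generate_landcover(config)
latent = fh.generate_fmc(config, landcover, 2008)
fires = fh.generate_fires(latent, landcover, config)

pixels = fh.extract_pixel_samples(fires, {2008: latent})
thresholds = fh.derive_thresholds(pixels)

print(f"{len(fires)} fires, {len(pixels)} burned-pixel samples")
for name, cuts in thresholds.to_dict().items():
    if name == "provenance":
        continue
    print(f"{name:>12}: extreme <= {cuts['extreme']:.1f} %, "
          f"high <= {cuts['high']:.1f} %, moderate <= {cuts['moderate']:.1f} %")

table = fh.evaluate_classification(pixels, thresholds)
print(table.to_string(index=False, float_format=lambda v: f"{v:6.1f}"))
# By construction of the percentile cuts, ~60 % of burned pixels fall in
# Extreme, ~25 % in High, ~12 % in Moderate and ~3 % in Low: the hazardous
# classes capture most of the area that actually burned.
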