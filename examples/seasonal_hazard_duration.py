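"""Seasonal FMC curves, activity strata and hazard-exceedance durations.

Simulates two seasons with high-fire-activity years generated 12 FMC
points drier, builds the per-cover seasonal mean curves of each stratum,
recovers the configured offset, and counts how long each curve spends
below a hazard threshold (8 days per composite).
"""

import fmc_hazard as fh

config = fh.SimulationConfig(rows=80, cols=80, years=(2008, 2009), seed=17,
                             year_fmc_offset={2008: -12.0})
landcover = fh.generate_landcover(config)
stacks = {y: fh.generate_fmc(config, landcover, y) for y in config.years}

curves = fh.seasonal_curves(stacks, {"high_activity": [2008],
                                     "low_activity": [2009]})
extreme_cut = 55.0  # grassland Extreme threshold (FMC %)
for cover in ("grassland", "shrubland", "chaco_forest"):
    high = fh.select_curve(curves, cover, "high_activity")
    low = fh.select_curve(curves, cover, "low_activity")
    diff = fh.stratum_difference(high, low)
    print(f"{cover:>12}: FMC {diff:5.1f} points lower in high-activity years; "
          f"below {extreme_cut:.0f} % for {fh.days_below(high, extreme_cut):3d} days "
          f"(high) vs {fh.days_below(low, extreme_cut):3d} days (low)")
# The recovered offsets sit near the configured 12 points, and dry years
# spend weeks longer under the extreme-hazard cut — the contrast an
# operational early-warning product is designed to surface.
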