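"""Land-cover-specific empirical FMC mapping.

Applies one fitted linear equation per land cover to the smoothed index
stacks to produce 8-day fuel-moisture maps (percent dry weight):

* grasslands (fuelbed moisture): ``FMC = 540.09 EVI - 31.16``
* Chaco Serrano forest (live FMC): ``FMC = 1.88 I + 246.39 NDVI - 63.06``
* shrublands (live FMC): ``FMC = 334.53 EVI - 305.98 GVMI - 7.05 I + 199.72``

where ``I`` is the cumulative NDVI integral. Values are deliberately not
clamped: negative or very large outputs are preserved and only counted in a
diagnostics report, since the calibration range is the caller's concern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import (
    CHACO_FOREST,
    GRASSLAND,
    OTHER,
    SEASON_DOYS,
    SHRUBLAND,
    GridSpec,
    LandCoverMap,
)
from .indices import IndexStack


class ConfigurationError(ValueError):
    """Invalid or inconsistent pipeline configuration."""


@dataclass(frozen=True)
class EquationSet:
    """Per-cover linear coefficients of the empirical FMC models.

    Defaults are the equations calibrated for the Sierras Chicas; override
    only to slot in models re-fitted for another region.
    """

    grassland_evi: float = 540.09
    grassland_intercept: float = -31.16
    forest_integral: float = 1.88
    forest_ndvi: float = 246.39
    forest_intercept: float = -63.06
    shrub_evi: float = 334.53
    shrub_gvmi: float = -305.98
    shrub_integral: float = -7.05
    shrub_intercept: float = 199.72


DEFAULT_EQUATIONS = EquationSet()


@dataclass
class FMCStack:
    """Per-date FMC rasters (% dry weight) with the land cover used per pixel."""

    data: np.ndarray  # (dates, rows, cols), NaN where no equation applies
    grid: GridSpec
    year: int
    landcover: np.ndarray
    doys: np.ndarray = field(default_factory=lambda: SEASON_DOYS.copy())

    def at_doy(self, doy: int) -> np.ndarray:
        idx = np.searchsorted(self.doys, doy)
        if idx >= len(self.doys) or self.doys[idx] != doy:
            raise ValueError(f"DOY {doy} is not on this stack's date axis")
        return self.data[int(idx)]

    def diagnostics(self, low: float = 0.0, high: float = 200.0) -> dict:
        """Count of estimates outside a plausible FMC range (no clamping)."""
        valid = ~np.isnan(self.data)
        return {
            "n_valid": int(valid.sum()),
            "n_below": int((self.data[valid] < low).sum()),
            "n_above": int((self.data[valid] > high).sum()),
        }


def majority_resample(fine: np.ndarray, block: int) -> np.ndarray:
    """Aggregate a categorical raster by the modal class of each block.

    Dimensions not divisible by ``block`` are padded with the "other" code
    before aggregation. Ties are broken toward the lowest class code.
    """
    if block <= 0:
        raise ValueError("block factor must be a positive integer")
    fine = np.asarray(fine)
    rows, cols = fine.shape
    pr = (-rows) % block
    pc = (-cols) % block
    if pr or pc:
        fine = np.pad(fine, ((0, pr), (0, pc)), constant_values=OTHER)
    r, c = fine.shape
    blocks = fine.reshape(r // block, block, c // block, block).swapaxes(1, 2)
    blocks = blocks.reshape(r // block, c // block, block * block)
    codes = np.unique(fine)
    # counts per code, stacked along a leading axis ordered by ascending code;
    # argmax returns the first (lowest-code) maximum, our documented tie rule
    counts = np.stack([(blocks == code).sum(axis=2) for code in codes])
    return codes[np.argmax(counts, axis=0)]


def select_landcover(year: int, maps: list[LandCoverMap]) -> LandCoverMap:
    """Pick the land-cover map whose era covers ``year`` (exactly one must)."""
    for i, a in enumerate(maps):
        for b in maps[i + 1:]:
            if a.year_range[0] <= b.year_range[1] and b.year_range[0] <= a.year_range[1]:
                raise ConfigurationError(
                    f"overlapping era ranges {a.year_range} and {b.year_range}"
                )
    covering = [m for m in maps if m.covers(year)]
    if not covering:
        raise ConfigurationError(f"no land-cover map covers year {year}")
    return covering[0]


def estimate_fmc(
    indices: IndexStack,
    landcover: LandCoverMap,
    equations: EquationSet = DEFAULT_EQUATIONS,
) -> FMCStack:
    """Evaluate the per-cover empirical equation on every pixel and date."""
    if landcover.grid.shape != indices.grid.shape:
        raise ValueError("index stack and land cover must share the grid")
    q = equations
    out = np.full_like(indices.ndvi, np.nan)
    grass = landcover.mask(GRASSLAND)
    shrub = landcover.mask(SHRUBLAND)
    forest = landcover.mask(CHACO_FOREST)
    out[:, grass] = q.grassland_evi * indices.evi[:, grass] + q.grassland_intercept
    out[:, forest] = (
        q.forest_integral * indices.integral[:, forest]
        + q.forest_ndvi * indices.ndvi[:, forest]
        + q.forest_intercept
    )
    out[:, shrub] = (
        q.shrub_evi * indices.evi[:, shrub]
        + q.shrub_gvmi * indices.gvmi[:, shrub]
        + q.shrub_integral * indices.integral[:, shrub]
        + q.shrub_intercept
    )
    return FMCStack(
        data=out,
        grid=indices.grid,
        year=indices.year,
        landcover=np.asarray(landcover.classes).copy(),
        doys=np.asarray(indices.doys).copy(),
    )
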