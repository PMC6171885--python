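"""Pre-fire FMC extraction.

Matches every fire to the last composite strictly before its start date,
intersects the burned polygon with the grid (pixel-center rule) and the
land cover, and produces the two sample tables the analyses run on:

* pixel samples — one row per burned pixel per fire, carrying the pixel's
  land cover and its pre-fire FMC (feeds the hazard-threshold derivation);
* fire samples — one row per fire with the zonal mean FMC over all covers
  pooled (one fire = one sample; feeds the fire-size statistics).

Fires smaller than 100 ha are excluded, as are fires missing FMC estimates
on more than 25 % of their in-grid area.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry

from .grids import COVER_CODES, GridSpec
from .mapping import FMCStack

logger = logging.getLogger(__name__)

PIXEL_SAMPLE_COLUMNS = ["fire_id", "cover", "fmc", "row", "col", "year", "doy_used"]
FIRE_SAMPLE_COLUMNS = [
    "fire_id", "mean_fmc", "area_ha", "size_class", "coverage", "year", "doy_used",
]

#: Fire size class bounds in hectares: small [100, 500), medium [500, 1000),
#: large [1000, inf). Low-inclusive half-open intervals.
SIZE_CLASS_BOUNDS = (100.0, 500.0, 1000.0)


class UnmatchableFireError(ValueError):
    """Fire starts on or before the first composite of its season."""


@dataclass(frozen=True)
class FireEvent:
    """A burned-area polygon with its start date and mapped area."""

    fire_id: str
    geometry: BaseGeometry
    year: int
    start_doy: int
    area_ha: float

    def __post_init__(self) -> None:
        if self.area_ha <= 0:
            raise ValueError(f"fire {self.fire_id}: area must be positive")
        if not 1 <= self.start_doy <= 366:
            raise ValueError(f"fire {self.fire_id}: start DOY outside the year")


def size_class(area_ha: float, bounds: tuple[float, float, float] = SIZE_CLASS_BOUNDS) -> str:
    """small / medium / large classification of a fire's area."""
    small, medium, large = bounds
    if area_ha < small:
        return "below_minimum"
    if area_ha < medium:
        return "small"
    if area_ha < large:
        return "medium"
    return "large"


def match_prefire_date(fire: FireEvent, composite_doys: np.ndarray, strict: bool = True) -> int:
    """Last composite DOY before the fire's start (strictly before by default).

    Strictness is deliberate: the composite window containing the ignition
    day may already carry the burn signal.
    """
    doys = np.asarray(composite_doys)
    if strict:
        earlier = doys[doys < fire.start_doy]
    else:
        earlier = doys[doys <= fire.start_doy]
    if earlier.size == 0:
        raise UnmatchableFireError(
            f"fire {fire.fire_id} (DOY {fire.start_doy}) has no earlier composite"
        )
    return int(earlier.max())


def rasterize_fire(fire: FireEvent, grid: GridSpec) -> tuple[np.ndarray, np.ndarray]:
    """Pixels whose centers fall inside the fire polygon (row, col arrays).

    Only the grid window overlapping the polygon's bounds is tested; a fire
    entirely off-grid yields an empty set with a warning.
    """
    xmin, ymin, xmax, ymax = fire.geometry.bounds
    # candidate window in row/col space (rows advance toward decreasing y)
    c0 = max(0, int(np.floor((xmin - grid.x0) / grid.pixel_size)))
    c1 = min(grid.cols, int(np.ceil((xmax - grid.x0) / grid.pixel_size)))
    r0 = max(0, int(np.floor((grid.y0 - ymax) / grid.pixel_size)))
    r1 = min(grid.rows, int(np.ceil((grid.y0 - ymin) / grid.pixel_size)))
    if c0 >= c1 or r0 >= r1:
        logger.warning("fire %s does not overlap the grid", fire.fire_id)
        return np.array([], dtype=int), np.array([], dtype=int)
    cols = np.arange(c0, c1)
    rows = np.arange(r0, r1)
    xs = grid.x0 + (cols + 0.5) * grid.pixel_size
    ys = grid.y0 - (rows + 0.5) * grid.pixel_size
    xx, yy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(fire.geometry, xx.ravel(), yy.ravel()).reshape(xx.shape)
    rr, cc = np.nonzero(inside)
    if rr.size == 0:
        logger.warning("fire %s covers no pixel centers", fire.fire_id)
    return rows[rr], cols[cc]


def _prefire_raster(
    fire: FireEvent, fmc_stacks: dict[int, FMCStack], strict: bool
) -> tuple[FMCStack, int] | None:
    stack = fmc_stacks.get(fire.year)
    if stack is None:
        logger.info("excluding fire %s: no FMC stack for year %d", fire.fire_id, fire.year)
        return None
    try:
        doy = match_prefire_date(fire, stack.doys, strict=strict)
    except UnmatchableFireError as exc:
        logger.info("excluding fire %s: %s", fire.fire_id, exc)
        return None
    return stack, doy


def extract_pixel_samples(
    fires: list[FireEvent],
    fmc_stacks: dict[int, FMCStack],
    min_area_ha: float = 100.0,
    strict_prefire: bool = True,
) -> pd.DataFrame:
    """One record per valid burned pixel per retained fire.

    A pixel contributes a record when its land cover has an FMC equation
    (grassland / shrubland / forest) and its pre-fire FMC estimate is not
    missing. The land cover is the per-pixel cover the FMC stack was
    estimated against (the era map of the fire's own year).
    """
    records: list[tuple] = []
    for fire in fires:
        if fire.area_ha < min_area_ha:
            logger.info("excluding fire %s: area %.0f ha < %.0f ha",
                        fire.fire_id, fire.area_ha, min_area_ha)
            continue
        matched = _prefire_raster(fire, fmc_stacks, strict_prefire)
        if matched is None:
            continue
        stack, doy = matched
        rows, cols = rasterize_fire(fire, stack.grid)
        if rows.size == 0:
            continue
        fmc = stack.at_doy(doy)[rows, cols]
        cover = stack.landcover[rows, cols]
        keep = np.isin(cover, COVER_CODES) & ~np.isnan(fmc)
        for r, c, f, cv in zip(rows[keep], cols[keep], fmc[keep], cover[keep]):
            records.append((fire.fire_id, int(cv), float(f), int(r), int(c),
                            fire.year, doy))
    return pd.DataFrame(records, columns=PIXEL_SAMPLE_COLUMNS)


def extract_fire_samples(
    fires: list[FireEvent],
    fmc_stacks: dict[int, FMCStack],
    max_missing_fraction: float = 0.25,
    min_area_ha: float = 100.0,
    strict_prefire: bool = True,
    bounds: tuple[float, float, float] = SIZE_CLASS_BOUNDS,
) -> pd.DataFrame:
    """One record per retained fire: zonal mean pre-fire FMC, all covers pooled.

    Fires with missing FMC (no equation or no data) on more than
    ``max_missing_fraction`` of their in-grid pixels are discarded. Fires
    partially outside the grid are clipped and the coverage fraction is
    recomputed over the in-grid part.
    """
    records: list[tuple] = []
    for fire in fires:
        if fire.area_ha < min_area_ha:
            logger.info("excluding fire %s: area %.0f ha < %.0f ha",
                        fire.fire_id, fire.area_ha, min_area_ha)
            continue
        matched = _prefire_raster(fire, fmc_stacks, strict_prefire)
        if matched is None:
            continue
        stack, doy = matched
        rows, cols = rasterize_fire(fire, stack.grid)
        if rows.size == 0:
            continue
        fmc = stack.at_doy(doy)[rows, cols]
        valid = ~np.isnan(fmc)
        coverage = valid.sum() / rows.size
        if 1.0 - coverage > max_missing_fraction:
            logger.info("excluding fire %s: %.0f%% of area without FMC",
                        fire.fire_id, 100 * (1 - coverage))
            continue
        records.append((
            fire.fire_id, float(fmc[valid].mean()), fire.area_ha,
            size_class(fire.area_ha, bounds), float(coverage), fire.year, doy,
        ))
    return pd.DataFrame(records, columns=FIRE_SAMPLE_COLUMNS)
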