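"""Shared grid, date-axis and land-cover primitives.

Rasters are plain 2-D (or date-stacked 3-D) numpy float/int arrays; the
:class:`GridSpec` carries the minimal georeferencing needed by the pipeline
(an axis-aligned planar grid of square pixels). Missing data is ``NaN`` in
float rasters and the ``OTHER`` code (0) in categorical rasters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

# Land-cover codes. "other" covers everything without an FMC equation
# (cultivated land, water, urban) and is always treated as missing.
OTHER = 0
GRASSLAND = 1
SHRUBLAND = 2
CHACO_FOREST = 3

COVER_CODES = (GRASSLAND, SHRUBLAND, CHACO_FOREST)
COVER_NAMES = {
    OTHER: "other",
    GRASSLAND: "grassland",
    SHRUBLAND: "shrubland",
    CHACO_FOREST: "chaco_forest",
}
COVER_BY_NAME = {v: k for k, v in COVER_NAMES.items()}

#: Day-of-year axis of the 8-day composites covering one fire season
#: (May-December): 31 dates, DOY 121, 129, ..., 361.
SEASON_DOYS: np.ndarray = np.arange(121, 362, 8)

N_DATES = len(SEASON_DOYS)  # 31


def doy_index(doy: int) -> int:
    """Index of a composite DOY on the season axis (exact match required)."""
    idx = np.searchsorted(SEASON_DOYS, doy)
    if idx >= N_DATES or SEASON_DOYS[idx] != doy:
        raise ValueError(f"DOY {doy} is not a composite date of the season axis")
    return int(idx)


@dataclass(frozen=True)
class GridSpec:
    """Axis-aligned planar grid of square pixels.

    ``x0, y0`` locate the outer corner of pixel (row 0, col 0); rows advance
    toward decreasing y, as in north-up rasters. ``pixel_size`` is the edge
    length in metres (500 m for MODIS-like composites, 25 ha per pixel).
    """

    rows: int
    cols: int
    pixel_size: float = 500.0
    x0: float = 0.0
    y0: float = 0.0

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise ValueError("grid must have positive dimensions")
        if self.pixel_size <= 0:
            raise ValueError("pixel size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.rows, self.cols)

    @property
    def pixel_area_ha(self) -> float:
        return self.pixel_size * self.pixel_size / 10_000.0

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of every pixel center, each of shape (rows, cols)."""
        xs = self.x0 + (np.arange(self.cols) + 0.5) * self.pixel_size
        ys = self.y0 - (np.arange(self.rows) + 0.5) * self.pixel_size
        return np.meshgrid(xs, ys)

    def pixel_bounds(self, row: int, col: int) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of one pixel."""
        xmin = self.x0 + col * self.pixel_size
        ymax = self.y0 - row * self.pixel_size
        return (xmin, ymax - self.pixel_size, xmin + self.pixel_size, ymax)


@dataclass(frozen=True)
class LandCoverMap:
    """Categorical land-cover raster with the year range it applies to."""

    classes: np.ndarray  # int array (rows, cols) with codes {0, 1, 2, 3}
    grid: GridSpec
    year_range: tuple[int, int] = (2002, 2016)

    def __post_init__(self) -> None:
        cls = np.asarray(self.classes)
        if cls.shape != self.grid.shape:
            raise ValueError("class raster shape does not match grid")
        valid = set(COVER_CODES) | {OTHER}
        found = set(np.unique(cls).tolist())
        if not found <= valid:
            raise ValueError(f"unknown land-cover codes: {sorted(found - valid)}")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("empty year range")

    def covers(self, year: int) -> bool:
        return self.year_range[0] <= year <= self.year_range[1]

    def mask(self, code: int) -> np.ndarray:
        return np.asarray(self.classes) == code


@dataclass
class DatedStack:
    """A per-date stack of rasters on the season axis: shape (31, rows, cols)."""

    data: np.ndarray
    grid: GridSpec
    year: int
    doys: np.ndarray = field(default_factory=lambda: SEASON_DOYS.copy())

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.doys = np.asarray(self.doys)
        if self.data.ndim != 3:
            raise ValueError("stack must be 3-D (dates, rows, cols)")
        if self.data.shape[0] != len(self.doys):
            raise ValueError("date axis length does not match data")
        if self.data.shape[1:] != self.grid.shape:
            raise ValueError("raster shape does not match grid")

    def at_doy(self, doy: int) -> np.ndarray:
        return self.data[doy_index(doy)]
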