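"""Spectral indices and Savitzky-Golay temporal smoothing.

Computes NDVI, EVI and GVMI from red/NIR/blue/SWIR reflectance stacks, the
cumulative "integral" predictor (a running sum of smoothed NDVI over the
season's composite dates), and applies Savitzky-Golay smoothing along the
date axis with truncated-window boundary fits.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import SEASON_DOYS, DatedStack, GridSpec

# Reflectance outside this range (after integer scaling) is treated as missing.
REFLECTANCE_RANGE = (-0.1, 1.1)


class SmoothingWindowError(ValueError):
    """Series too short for the requested smoothing window."""


@dataclass
class ReflectanceStack:
    """Per-band surface-reflectance time series on a common grid and date axis."""

    red: np.ndarray
    nir: np.ndarray
    blue: np.ndarray
    swir: np.ndarray
    grid: GridSpec
    year: int
    doys: np.ndarray = field(default_factory=lambda: SEASON_DOYS.copy())

    def __post_init__(self) -> None:
        shapes = {np.shape(b) for b in (self.red, self.nir, self.blue, self.swir)}
        if len(shapes) != 1:
            raise ValueError("all bands must share one shape")
        for name in ("red", "nir", "blue", "swir"):
            band = np.asarray(getattr(self, name), dtype=float).copy()
            bad = (band < REFLECTANCE_RANGE[0]) | (band > REFLECTANCE_RANGE[1])
            band[bad] = np.nan
            setattr(self, name, band)
        if self.red.shape[0] != len(self.doys):
            raise ValueError("date axis length does not match bands")


@dataclass
class IndexStack:
    """NDVI/EVI/GVMI rasters per date plus the cumulative integral predictor."""

    ndvi: np.ndarray
    evi: np.ndarray
    gvmi: np.ndarray
    integral: np.ndarray
    grid: GridSpec
    year: int
    doys: np.ndarray = field(default_factory=lambda: SEASON_DOYS.copy())


def compute_ndvi(nir: np.ndarray, red: np.ndarray) -> np.ndarray:
    """NDVI = (NIR - red) / (NIR + red); missing (NaN) where undefined."""
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    denom = nir + red
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom != 0, (nir - red) / denom, np.nan)
    out[np.isnan(nir) | np.isnan(red)] = np.nan
    return out


def compute_evi(nir: np.ndarray, red: np.ndarray, blue: np.ndarray) -> np.ndarray:
    """EVI = 2.5 (NIR - red) / (NIR + 6 red - 7.5 blue + 1)."""
    nir = np.asarray(nir, dtype=float)
    red = np.asarray(red, dtype=float)
    blue = np.asarray(blue, dtype=float)
    denom = nir + 6.0 * red - 7.5 * blue + 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom != 0, 2.5 * (nir - red) / denom, np.nan)
    out[np.isnan(nir) | np.isnan(red) | np.isnan(blue)] = np.nan
    return out


def compute_gvmi(nir: np.ndarray, swir: np.ndarray) -> np.ndarray:
    """GVMI = ((NIR+0.1) - (SWIR+0.02)) / ((NIR+0.1) + (SWIR+0.02))."""
    nir = np.asarray(nir, dtype=float)
    swir = np.asarray(swir, dtype=float)
    a = nir + 0.1
    b = swir + 0.02
    denom = a + b
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(denom != 0, (a - b) / denom, np.nan)
    out[np.isnan(nir) | np.isnan(swir)] = np.nan
    return out


def _sg_matrix(n: int, halfwidth: int, order: int) -> np.ndarray:
    """Linear smoothing operator S (n x n): smoothed = S @ series.

    Interior rows are the classic Savitzky-Golay convolution weights for a
    (2*halfwidth+1)-point window; rows near the boundary fit the polynomial
    over the window truncated to the available dates (no mirror padding).
    """
    if n < 2 * halfwidth + 1:
        raise SmoothingWindowError(
            f"series of length {n} shorter than smoothing window {2 * halfwidth + 1}"
        )
    s = np.zeros((n, n))
    for i in range(n):
        lo = max(0, i - halfwidth)
        hi = min(n, i + halfwidth + 1)
        t = np.arange(lo, hi) - i  # window offsets, 0 at the evaluation point
        # weights of the order-`order` LSQ fit evaluated at offset 0
        v = np.vander(t, N=order + 1, increasing=True)
        # row of pinv giving the constant coefficient = fitted value at center
        s[i, lo:hi] = np.linalg.pinv(v)[0]
    return s


def _interpolate_gaps(series: np.ndarray, max_gap: int) -> tuple[np.ndarray, np.ndarray]:
    """Linearly fill interior NaN runs; return (filled, still-missing mask).

    Runs longer than ``max_gap`` and runs touching either end of the series
    are filled for the benefit of the filter but re-masked afterwards.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    flat = series.reshape(-1, n)
    filled = flat.copy()
    remask = np.zeros_like(flat, dtype=bool)
    idx = np.arange(n)
    for k in range(flat.shape[0]):
        row = flat[k]
        bad = np.isnan(row)
        if not bad.any():
            continue
        if bad.all():
            remask[k] = True
            filled[k] = 0.0
            continue
        filled[k] = np.interp(idx, idx[~bad], row[~bad])
        # locate NaN runs and apply the gap rule
        edges = np.flatnonzero(np.diff(np.concatenate(([0], bad.view(np.int8), [0]))))
        for start, stop in zip(edges[::2], edges[1::2]):
            run = stop - start
            if run > max_gap or start == 0 or stop == n:
                remask[k, start:stop] = True
    return filled.reshape(series.shape), remask.reshape(series.shape)


def sg_smooth(
    series: np.ndarray,
    window_halfwidth: int = 3,
    poly_order: int = 2,
    max_gap: int = 2,
) -> np.ndarray:
    """Savitzky-Golay smoothing along the last axis (the date axis).

    Interior points are the order-``poly_order`` least-squares polynomial fit
    over the ±``window_halfwidth`` window evaluated at the center; boundary
    points use the window truncated to available dates. Missing values are
    linearly interpolated before filtering when the gap spans at most
    ``max_gap`` consecutive dates, and re-masked otherwise.
    """
    series = np.asarray(series, dtype=float)
    n = series.shape[-1]
    smat = _sg_matrix(n, window_halfwidth, poly_order)
    filled, remask = _interpolate_gaps(series, max_gap)
    out = filled @ smat.T
    out[remask] = np.nan
    return out


def compute_integral(smoothed_ndvi: np.ndarray, axis: int = 0) -> np.ndarray:
    """Running sum of smoothed NDVI over composite dates (season start..t).

    Missing NDVI contributes zero to the accumulation; callers interested in
    which pixel-dates were gap-affected should inspect ``np.isnan`` of the
    input, which this function leaves untouched.
    """
    ndvi = np.asarray(smoothed_ndvi, dtype=float)
    return np.nancumsum(ndvi, axis=axis)


def compute_indices(stack: ReflectanceStack, smooth: bool = False) -> IndexStack:
    """Compute the four predictors (NDVI, EVI, GVMI, integral) from bands.

    With ``smooth=True`` the three spectral indices are Savitzky-Golay
    smoothed along the date axis before the integral is accumulated (the
    operational pipeline order); the integral always accumulates the NDVI
    series produced by this call and is never re-smoothed.
    """
    ndvi = compute_ndvi(stack.nir, stack.red)
    evi = compute_evi(stack.nir, stack.red, stack.blue)
    gvmi = compute_gvmi(stack.nir, stack.swir)
    if smooth:
        # date axis is first: move it last for the filter
        ndvi = np.moveaxis(sg_smooth(np.moveaxis(ndvi, 0, -1)), -1, 0)
        evi = np.moveaxis(sg_smooth(np.moveaxis(evi, 0, -1)), -1, 0)
        gvmi = np.moveaxis(sg_smooth(np.moveaxis(gvmi, 0, -1)), -1, 0)
    integral = compute_integral(ndvi, axis=0)
    return IndexStack(
        ndvi=ndvi, evi=evi, gvmi=gvmi, integral=integral,
        grid=stack.grid, year=stack.year, doys=stack.doys.copy(),
    )
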