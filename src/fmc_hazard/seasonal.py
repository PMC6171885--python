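"""Seasonal mean-FMC curves and fire-activity stratification.

Builds per-cover curves of mean FMC over the 31 composite dates of the
season, averaged across a stratum of years (all years, high fire activity:
burned fraction > 3 % of the mapped area, low fire activity: < 1 %), and
quantifies how long the mean curve sits below a hazard threshold. Each
composite represents an 8-day window, so exceedance durations are reported
in days as multiples of 8.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .grids import COVER_CODES, COVER_NAMES
from .mapping import FMCStack

logger = logging.getLogger(__name__)

CURVE_COLUMNS = ["cover", "stratum", "doy", "mean_fmc", "sd",
                 "sd_spatial", "sd_interannual"]


class AlignmentError(ValueError):
    """Two curves do not share a date axis / cover."""


def stratify_years(
    burned_fraction_by_year: dict[int, float],
    high_cut: float = 0.03,
    low_cut: float = 0.01,
) -> tuple[list[int], list[int], list[int]]:
    """(high-activity, low-activity, unclassified) years by burned fraction.

    Strict inequalities on both cuts; years with burned fraction in
    [low_cut, high_cut] belong to neither stratum.
    """
    high, low, rest = [], [], []
    for year, frac in sorted(burned_fraction_by_year.items()):
        if not 0.0 <= frac <= 1.0:
            raise ValueError(f"burned fraction for {year} outside [0, 1]: {frac}")
        if frac > high_cut:
            high.append(year)
        elif frac < low_cut:
            low.append(year)
        else:
            rest.append(year)
    return high, low, rest


def burned_fraction_by_year(fires, mapped_area_ha: float) -> dict[int, float]:
    """Total burned area per year divided by the mapped (non-'other') area."""
    if mapped_area_ha <= 0:
        raise ValueError("mapped area must be positive")
    out: dict[int, float] = {}
    for fire in fires:
        out[fire.year] = out.get(fire.year, 0.0) + fire.area_ha
    return {year: min(total / mapped_area_ha, 1.0) for year, total in out.items()}


def seasonal_curves(
    fmc_stacks: dict[int, FMCStack],
    strata: dict[str, list[int]],
) -> pd.DataFrame:
    """Tidy per-cover seasonal curves for each stratum of years.

    Per composite date and cover: the spatial mean FMC of each year is
    averaged across the stratum's years. Three dispersion measures are
    reported — the pooled across-years-and-space standard deviation
    (``sd``, the default error bar), the mean spatial sd (``sd_spatial``)
    and the sd of the yearly spatial means (``sd_interannual``).
    """
    rows = []
    for stratum, years in strata.items():
        years = [y for y in years if y in fmc_stacks]
        if not years:
            logger.warning("stratum '%s' has no FMC stacks; omitted", stratum)
            continue
        ref = fmc_stacks[years[0]]
        doys = np.asarray(ref.doys)
        for code in COVER_CODES:
            mask = ref.landcover == code
            # cover masks may differ across eras; use each year's own map
            year_means = []     # (years, dates) spatial means
            year_sds = []
            pooled = []         # per-date pooled pixel values across years
            for y in years:
                stack = fmc_stacks[y]
                m = stack.landcover == code
                if not m.any():
                    continue
                vals = stack.data[:, m]  # (dates, pixels)
                year_means.append(np.nanmean(vals, axis=1))
                year_sds.append(np.nanstd(vals, axis=1))
                pooled.append(vals)
            if not year_means:
                continue
            year_means = np.asarray(year_means)
            year_sds = np.asarray(year_sds)
            mean_curve = year_means.mean(axis=0)
            sd_interannual = year_means.std(axis=0, ddof=0)
            sd_spatial = year_sds.mean(axis=0)
            pooled_sd = np.array([
                np.nanstd(np.concatenate([p[t] for p in pooled])) for t in range(len(doys))
            ])
            for t, doy in enumerate(doys):
                rows.append((COVER_NAMES[code], stratum, int(doy),
                             float(mean_curve[t]), float(pooled_sd[t]),
                             float(sd_spatial[t]), float(sd_interannual[t])))
    return pd.DataFrame(rows, columns=CURVE_COLUMNS)


def select_curve(curves: pd.DataFrame, cover: str, stratum: str) -> pd.DataFrame:
    """One (cover, stratum) curve, sorted by DOY."""
    sel = curves[(curves["cover"] == cover) & (curves["stratum"] == stratum)]
    if len(sel) == 0:
        raise KeyError(f"no curve for cover={cover!r}, stratum={stratum!r}")
    return sel.sort_values("doy").reset_index(drop=True)


def days_below(curve: pd.DataFrame | np.ndarray, threshold: float,
               days_per_composite: int = 8) -> int:
    """Days the mean curve spends strictly below an FMC threshold.

    Each composite date stands for an 8-day window, so the result is
    8 x (number of dates with mean FMC < threshold).
    """
    values = (curve["mean_fmc"].to_numpy(dtype=float)
              if isinstance(curve, pd.DataFrame) else np.asarray(curve, dtype=float))
    return int(days_per_composite * np.count_nonzero(values < threshold))


def stratum_difference(high: pd.DataFrame | np.ndarray,
                       low: pd.DataFrame | np.ndarray) -> float:
    """Mean (low - high) FMC difference in percentage points across the season."""
    def _extract(c):
        if isinstance(c, pd.DataFrame):
            return c["doy"].to_numpy(), c["mean_fmc"].to_numpy(dtype=float)
        return None, np.asarray(c, dtype=float)

    doy_h, vals_h = _extract(high)
    doy_l, vals_l = _extract(low)
    if vals_h.shape != vals_l.shape:
        raise AlignmentError("curves have different lengths")
    if doy_h is not None and doy_l is not None and not np.array_equal(doy_h, doy_l):
        raise AlignmentError("curves are on different date axes")
    return float(np.mean(vals_l - vals_h))
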