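"""Percentile-based wildfire hazard thresholds and classification.

Per land cover, the P60 / P85 / P97 percentiles of the historical pre-fire
FMC distribution bound four hazard classes:

=========  =============================
class      FMC range (% dry weight)
=========  =============================
Extreme    FMC <= P60
High       P60 < FMC <= P85
Moderate   P85 < FMC <= P97
Low        FMC > P97
=========  =============================

Class boundaries are inclusive on the hazardous side — a value equal to a
threshold gets the more hazardous class, the conservative choice for an
early-warning product. Percentiles use the linear-interpolation convention
(order statistic at rank 1 + (n-1) p).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grids import COVER_BY_NAME, COVER_CODES, COVER_NAMES, LandCoverMap
from .mapping import ConfigurationError, FMCStack

logger = logging.getLogger(__name__)

# hazard class codes (descending hazard); 0 = no data
NODATA, LOW, MODERATE, HIGH, EXTREME = 0, 1, 2, 3, 4
CLASS_NAMES = {EXTREME: "Extreme", HIGH: "High", MODERATE: "Moderate",
               LOW: "Low", NODATA: "NoData"}
#: presentation order of the four real classes, most hazardous first
CLASS_ORDER = (EXTREME, HIGH, MODERATE, LOW)

DEFAULT_PERCENTILES = (60.0, 85.0, 97.0)


@dataclass(frozen=True)
class HazardThresholds:
    """Per-cover FMC cut points (extreme, high, moderate) with provenance."""

    by_cover: dict[int, tuple[float, float, float]]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for code, (te, th, tm) in self.by_cover.items():
            if not te <= th <= tm:
                raise ValueError(
                    f"{COVER_NAMES.get(code, code)}: thresholds must satisfy "
                    f"extreme <= high <= moderate, got ({te}, {th}, {tm})")

    def for_cover(self, code: int) -> tuple[float, float, float] | None:
        return self.by_cover.get(code)

    def to_dict(self) -> dict:
        out = {}
        for code, (te, th, tm) in self.by_cover.items():
            out[COVER_NAMES[code]] = {
                "extreme": float(te), "high": float(th), "moderate": float(tm)}
        if self.provenance:
            out["provenance"] = dict(self.provenance)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "HazardThresholds":
        by_cover = {}
        for name, cuts in data.items():
            if name == "provenance":
                continue
            missing = {"extreme", "high", "moderate"} - set(cuts)
            if missing:
                raise ConfigurationError(
                    f"threshold for cover '{name}' missing cut(s): {sorted(missing)}")
            by_cover[COVER_BY_NAME[name]] = (
                float(cuts["extreme"]), float(cuts["high"]), float(cuts["moderate"]))
        return cls(by_cover=by_cover, provenance=data.get("provenance", {}))

    @classmethod
    def uniform(cls, extreme: float, high: float, moderate: float,
                provenance: dict | None = None) -> "HazardThresholds":
        """The same three cuts applied to every land cover (external thresholds)."""
        for name, v in (("extreme", extreme), ("high", high), ("moderate", moderate)):
            if v is None:
                raise ConfigurationError(f"external threshold '{name}' is required")
        return cls(by_cover={c: (extreme, high, moderate) for c in COVER_CODES},
                   provenance=provenance or {"source": "external"})


def percentile(values: np.ndarray, p: float) -> float:
    """Percentile by linear interpolation of order statistics (rank 1+(n-1)p)."""
    return float(np.percentile(np.asarray(values, dtype=float), p,
                               method="linear"))


def derive_thresholds(
    pixel_samples: pd.DataFrame,
    percentiles: tuple[float, float, float] = DEFAULT_PERCENTILES,
    min_samples: int = 30,
) -> HazardThresholds:
    """Per-cover hazard thresholds from pre-fire pixel samples.

    Covers with fewer than ``min_samples`` samples are omitted with a
    warning (their pixels classify as NoData downstream).
    """
    if list(percentiles) != sorted(percentiles):
        raise ConfigurationError(f"percentiles must be increasing, got {percentiles}")
    by_cover: dict[int, tuple[float, float, float]] = {}
    counts: dict[str, int] = {}
    for code, group in pixel_samples.groupby("cover"):
        code = int(code)
        values = group["fmc"].to_numpy(dtype=float)
        if len(values) < min_samples:
            logger.warning("cover %s has %d samples (< %d); omitted from thresholds",
                           COVER_NAMES.get(code, code), len(values), min_samples)
            continue
        by_cover[code] = tuple(percentile(values, p) for p in percentiles)
        counts[COVER_NAMES.get(code, str(code))] = int(len(values))
    return HazardThresholds(
        by_cover=by_cover,
        provenance={"percentiles": tuple(float(p) for p in percentiles),
                    "convention": "linear interpolation, rank 1+(n-1)p",
                    "n_samples": counts},
    )


def classify_values(fmc: np.ndarray, cuts: tuple[float, float, float]) -> np.ndarray:
    """Hazard class codes for FMC values under one cover's cuts."""
    fmc = np.asarray(fmc, dtype=float)
    te, th, tm = cuts
    out = np.full(fmc.shape, NODATA, dtype=np.int64)
    valid = ~np.isnan(fmc)
    out[valid & (fmc <= te)] = EXTREME
    out[valid & (fmc > te) & (fmc <= th)] = HIGH
    out[valid & (fmc > th) & (fmc <= tm)] = MODERATE
    out[valid & (fmc > tm)] = LOW
    return out


def classify(
    fmc: float | np.ndarray | FMCStack,
    thresholds: HazardThresholds,
    landcover: LandCoverMap | np.ndarray | int | None = None,
):
    """Classify an FMC value, array or stack into hazard classes.

    For a scalar or plain array, ``landcover`` is a single cover code (or
    None when the thresholds are uniform across covers). For an
    :class:`FMCStack` the per-pixel cover stored on the stack (or an
    explicit map) selects each pixel's cuts; pixels of covers without
    thresholds are NoData.
    """
    if isinstance(fmc, FMCStack):
        cover = (landcover.classes if isinstance(landcover, LandCoverMap)
                 else landcover if landcover is not None else fmc.landcover)
        cover = np.asarray(cover)
        out = np.full(fmc.data.shape, NODATA, dtype=np.int64)
        for code, cuts in thresholds.by_cover.items():
            mask = cover == code
            if mask.any():
                out[:, mask] = classify_values(fmc.data[:, mask], cuts)
        return out
    # scalar / array path
    if isinstance(landcover, (LandCoverMap, np.ndarray)):
        raise TypeError("per-pixel land cover requires an FMCStack input")
    if landcover is None:
        cuts_set = set(thresholds.by_cover.values())
        if len(cuts_set) != 1:
            raise ConfigurationError(
                "thresholds differ across covers: a cover code is required")
        cuts = next(iter(cuts_set))
    else:
        cuts = thresholds.for_cover(int(landcover))
        if cuts is None:
            cuts = (np.nan, np.nan, np.nan)  # -> NoData
    scalar = np.isscalar(fmc)
    out = classify_values(np.atleast_1d(np.asarray(fmc, dtype=float)), cuts)
    return int(out[0]) if scalar else out.reshape(np.shape(fmc))


def evaluate_classification(
    pixel_samples: pd.DataFrame,
    thresholds: HazardThresholds,
) -> pd.DataFrame:
    """Per-cover percentage of burned pixels falling in each hazard class.

    Returns a tidy table (cover, hazard_class, pct, pct_cum); percentages
    sum to 100 per cover within rounding, and the cumulative column runs
    from Extreme down to Low.
    """
    rows = []
    if len(pixel_samples) == 0:
        return pd.DataFrame(rows, columns=["cover", "hazard_class", "pct", "pct_cum"])
    for code, group in pixel_samples.groupby("cover"):
        code = int(code)
        cuts = thresholds.for_cover(code)
        if cuts is None:
            logger.warning("no thresholds for cover %s; skipped",
                           COVER_NAMES.get(code, code))
            continue
        classes = classify_values(group["fmc"].to_numpy(dtype=float), cuts)
        n = len(classes)
        cum = 0.0
        for cls in CLASS_ORDER:
            pct = 100.0 * np.count_nonzero(classes == cls) / n
            cum += pct
            rows.append((COVER_NAMES.get(code, str(code)), CLASS_NAMES[cls], pct, cum))
    return pd.DataFrame(rows, columns=["cover", "hazard_class", "pct", "pct_cum"])


def compare_external(
    pixel_samples: pd.DataFrame,
    external: HazardThresholds | tuple[float, float, float],
) -> pd.DataFrame:
    """Evaluate burned-pixel samples against externally supplied thresholds.

    The external cuts (e.g. chaparral-derived extreme < 60 %, high 60-77 %)
    apply uniformly to all covers; all three cuts must be supplied — the
    moderate/low cut has no default.
    """
    if not isinstance(external, HazardThresholds):
        external = HazardThresholds.uniform(*external)
    return evaluate_classification(pixel_samples, external)
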