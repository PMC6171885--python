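"""Pipeline configuration: defaults, parsing and validation.

One YAML (or dict) drives the whole pipeline. Every default is either a
published analysis setting (percentiles 60/85/97, Savitzky-Golay window
±3 composites, minimum fire size 100 ha, 25 % missing-data rule, era split
2006/2007, activity cuts 3 %/1 %) or a documented package design choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import yaml

from .grids import COVER_BY_NAME
from .mapping import ConfigurationError, EquationSet
from .synthetic import (
    CoverParams,
    DEFAULT_COVER_PARAMS,
    DEFAULT_PROPORTIONS,
    FireParams,
    SimulationConfig,
)

_SIM_KEYS = {"rows", "cols", "pixel_area_ha", "years", "seed", "proportions",
             "cover_params", "fire_params", "year_fmc_offset"}
_TOP_KEYS = {"outdir", "seed", "simulate", "percentiles", "min_samples_per_cover",
             "sg_window_halfwidth", "sg_poly_order", "sg_max_gap",
             "min_area_ha", "max_missing_fraction", "size_class_bounds",
             "era_ranges", "high_activity_cut", "low_activity_cut",
             "external_thresholds", "taus", "n_bootstrap", "write_rasters",
             "log_level", "equations"}


@dataclass
class PipelineConfig:
    outdir: str = "fmc_hazard_run"
    seed: int = 0
    simulate: SimulationConfig = field(default_factory=SimulationConfig)
    percentiles: tuple[float, float, float] = (60.0, 85.0, 97.0)
    min_samples_per_cover: int = 30
    sg_window_halfwidth: int = 3
    sg_poly_order: int = 2
    sg_max_gap: int = 2
    min_area_ha: float = 100.0
    max_missing_fraction: float = 0.25
    size_class_bounds: tuple[float, float, float] = (100.0, 500.0, 1000.0)
    era_ranges: tuple[tuple[int, int], ...] = ((2002, 2006), (2007, 2016))
    high_activity_cut: float = 0.03
    low_activity_cut: float = 0.01
    external_thresholds: tuple[float, float, float] | None = None
    taus: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)
    n_bootstrap: int = 200
    write_rasters: bool = True
    log_level: str = "INFO"
    equations: EquationSet = field(default_factory=EquationSet)

    def __post_init__(self) -> None:
        if list(self.percentiles) != sorted(self.percentiles):
            raise ConfigurationError(
                f"percentiles must be increasing, got {self.percentiles}")
        if self.min_area_ha < 0:
            raise ConfigurationError("minimum fire area must be non-negative")
        if not 0 <= self.max_missing_fraction <= 1:
            raise ConfigurationError("max missing fraction must lie in [0, 1]")
        if list(self.size_class_bounds) != sorted(self.size_class_bounds):
            raise ConfigurationError("size-class bounds must be increasing")
        if self.sg_window_halfwidth < 1 or self.sg_poly_order < 0:
            raise ConfigurationError("invalid smoothing parameters")
        if self.low_activity_cut > self.high_activity_cut:
            raise ConfigurationError("activity cuts must satisfy low <= high")
        if self.n_bootstrap < 0:
            raise ConfigurationError("bootstrap count must be non-negative")


def _build_sim(raw: dict, seed: int) -> SimulationConfig:
    unknown = set(raw) - _SIM_KEYS
    if unknown:
        raise ConfigurationError(f"unknown simulation keys: {sorted(unknown)}")
    kwargs: dict = {"seed": seed}
    for key in ("rows", "cols", "pixel_area_ha"):
        if key in raw:
            kwargs[key] = raw[key]
    if "seed" in raw:
        kwargs["seed"] = raw["seed"]
    if "years" in raw:
        kwargs["years"] = tuple(int(y) for y in raw["years"])
    if "proportions" in raw:
        props = dict(DEFAULT_PROPORTIONS)
        for name, p in raw["proportions"].items():
            props[COVER_BY_NAME[name]] = float(p)
        kwargs["proportions"] = props
    if "cover_params" in raw:
        params = dict(DEFAULT_COVER_PARAMS)
        for name, cp in raw["cover_params"].items():
            params[COVER_BY_NAME[name]] = CoverParams(**cp)
        kwargs["cover_params"] = params
    if "fire_params" in raw:
        kwargs["fire_params"] = FireParams(**raw["fire_params"])
    if "year_fmc_offset" in raw:
        kwargs["year_fmc_offset"] = {int(y): float(v)
                                     for y, v in raw["year_fmc_offset"].items()}
    return SimulationConfig(**kwargs)


def validate_config(raw: str | dict | None) -> PipelineConfig:
    """Parse and validate a YAML text or dict into a fully defaulted config.

    Unknown keys and out-of-range values raise a descriptive
    :class:`ConfigurationError`; an empty config yields all defaults.
    """
    if raw is None:
        raw = {}
    if isinstance(raw, str):
        raw = yaml.safe_load(raw) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError("configuration must be a mapping")
    unknown = set(raw) - _TOP_KEYS
    if unknown:
        raise ConfigurationError(f"unknown configuration keys: {sorted(unknown)}")
    raw = dict(raw)
    seed = int(raw.pop("seed", 0))
    sim_raw = raw.pop("simulate", {}) or {}
    kwargs: dict = {"seed": seed, "simulate": _build_sim(sim_raw, seed)}
    for key in ("percentiles", "size_class_bounds", "taus"):
        if key in raw:
            kwargs[key] = tuple(float(v) for v in raw.pop(key))
    if "era_ranges" in raw:
        kwargs["era_ranges"] = tuple(
            (int(a), int(b)) for a, b in raw.pop("era_ranges"))
    if "external_thresholds" in raw:
        ext = raw.pop("external_thresholds")
        kwargs["external_thresholds"] = (
            None if ext is None else tuple(float(v) for v in ext))
    if "equations" in raw:
        kwargs["equations"] = EquationSet(**raw.pop("equations"))
    kwargs.update(raw)
    return PipelineConfig(**kwargs)
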