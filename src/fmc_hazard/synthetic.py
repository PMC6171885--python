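"""Synthetic scenes for exercising the full FMC-hazard pipeline.

Generates (i) clumped categorical land-cover rasters, (ii) latent per-pixel
FMC trajectories with an August-September minimum and AR(1) noise, (iii)
index stacks obtained by *exactly inverting* the empirical FMC equations
(so the mapping stage reproduces the latent truth to machine precision),
(iv) reflectance stacks obtained by inverting the index definitions, and
(v) fire events whose maximum size is capped by a decreasing function of
the local pre-fire FMC — the qualitative behaviour the downstream
statistics are designed to detect.

Reflectance exists only to exercise index computation; no radiative
transfer is simulated. All randomness flows from the configured seed.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from shapely.geometry import box
from shapely.ops import unary_union

from .grids import (
    CHACO_FOREST,
    COVER_NAMES,
    GRASSLAND,
    OTHER,
    SEASON_DOYS,
    SHRUBLAND,
    GridSpec,
    LandCoverMap,
)
from .indices import IndexStack, ReflectanceStack
from .mapping import DEFAULT_EQUATIONS, EquationSet, FMCStack
from .prefire import FireEvent

logger = logging.getLogger(__name__)

INDEX_BOUNDS = (-1.5, 1.5)  # inversion outside this range signals a bad config


class InvalidConfigError(ValueError):
    pass


class DegenerateInputError(ValueError):
    """A band cannot be solved from an index (zero denominator)."""


@dataclass(frozen=True)
class CoverParams:
    """Seasonal FMC template of one land cover.

    The trajectory declines linearly from ``start_fmc`` (first composite,
    DOY 121) to ``min_fmc`` at ``min_doy``, then recovers at
    ``recovery_rate`` %/day, capped at ``start_fmc``. AR(1) noise with
    stationary standard deviation ``noise_sd`` rides on top; trajectories
    are truncated at zero.
    """

    start_fmc: float
    min_fmc: float
    min_doy: int
    recovery_rate: float  # % dry weight per day
    noise_sd: float
    ar1: float = 0.6


DEFAULT_COVER_PARAMS: dict[int, CoverParams] = {
    # Chosen to emulate observed seasonal curves: grasslands driest, shrublands
    # wettest, minima in August-September (DOY 213-273).
    GRASSLAND: CoverParams(start_fmc=90.0, min_fmc=40.0, min_doy=245, recovery_rate=0.55, noise_sd=7.0),
    SHRUBLAND: CoverParams(start_fmc=130.0, min_fmc=95.0, min_doy=249, recovery_rate=0.50, noise_sd=9.0),
    CHACO_FOREST: CoverParams(start_fmc=110.0, min_fmc=65.0, min_doy=241, recovery_rate=0.60, noise_sd=8.0),
}

DEFAULT_PROPORTIONS: dict[int, float] = {
    GRASSLAND: 0.35, SHRUBLAND: 0.30, CHACO_FOREST: 0.25, OTHER: 0.10,
}


@dataclass(frozen=True)
class FireParams:
    """Ignition intensity and the FMC-dependent size cap.

    The maximum area a fire can reach decays exponentially with the local
    mean FMC at ignition: ``cap_ha = cap_scale_ha * exp(-cap_decay * FMC)``.
    Target sizes are Pareto-distributed (heavy tail) and truncated at the cap.
    """

    expected_per_year: float = 40.0
    cap_scale_ha: float = 60_000.0
    cap_decay: float = 0.05  # per FMC percentage point
    min_size_ha: float = 50.0
    pareto_alpha: float = 0.6
    # Ignition preferences are deliberately mild (large e-folding scales):
    # small fires must occur across the whole FMC range, while the size cap
    # (not ignition selection) carries the FMC-size coupling.
    date_weight_scale: float = 60.0  # FMC e-folding for ignition-date weights
    pixel_weight_scale: float = 60.0  # FMC e-folding for ignition-pixel weights
    local_window: int = 2  # half-width of the neighborhood defining local FMC


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of a synthetic study area and fire record."""

    rows: int = 64
    cols: int = 64
    pixel_area_ha: float = 25.0
    years: tuple[int, ...] = (2008,)
    cover_params: dict[int, CoverParams] = field(
        default_factory=lambda: dict(DEFAULT_COVER_PARAMS))
    proportions: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_PROPORTIONS))
    fire_params: FireParams = field(default_factory=FireParams)
    #: additive FMC offset per year (e.g. negative in high-fire-activity years)
    year_fmc_offset: dict[int, float] = field(default_factory=dict)
    min_doy_range: tuple[int, int] = (213, 273)  # August-September
    landcover_patch_size: float = 4.0  # Gaussian smoothing radius, pixels
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows <= 0 or self.cols <= 0:
            raise InvalidConfigError("grid must have positive dimensions")
        if self.pixel_area_ha <= 0:
            raise InvalidConfigError("pixel area must be positive")
        total = sum(self.proportions.values())
        if abs(total - 1.0) > 1e-9:
            raise InvalidConfigError(f"class proportions sum to {total}, not 1")
        if any(p < 0 for p in self.proportions.values()):
            raise InvalidConfigError("class proportions must be non-negative")
        lo, hi = self.min_doy_range
        for code, params in self.cover_params.items():
            if params.min_fmc < 0:
                raise InvalidConfigError(f"{COVER_NAMES[code]}: minimum FMC must be >= 0")
            if not lo <= params.min_doy <= hi:
                raise InvalidConfigError(
                    f"{COVER_NAMES[code]}: day of minimum {params.min_doy} outside "
                    f"[{lo}, {hi}]")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(self.rows, self.cols,
                        pixel_size=float(np.sqrt(self.pixel_area_ha * 10_000.0)))


@dataclass
class LatentFMCStack(FMCStack):
    """True (latent) FMC used to manufacture indices; 'other' pixels are NaN."""


# ---------------------------------------------------------------------------
# smooth per-date templates used for indices a cover's equation does not need

def _season_fraction() -> np.ndarray:
    return (SEASON_DOYS - SEASON_DOYS[0]) / (SEASON_DOYS[-1] - SEASON_DOYS[0])


def _dip_profile(high: float, low: float) -> np.ndarray:
    """Smooth profile dipping from ``high`` to ``low`` mid-season and back."""
    s = _season_fraction()
    return high - (high - low) * np.sin(np.pi * s) ** 2


def default_ndvi_fill() -> np.ndarray:
    return _dip_profile(0.25, 0.15)


def default_shrub_ndvi_template() -> np.ndarray:
    return _dip_profile(0.40, 0.25)


def default_evi_fill() -> np.ndarray:
    return _dip_profile(0.40, 0.30)


def default_gvmi_fill() -> np.ndarray:
    return _dip_profile(0.30, 0.10)


def default_gvmi_profile(shrub_ndvi: np.ndarray | None = None,
                         equations: EquationSet = DEFAULT_EQUATIONS,
                         level: float = 180.0) -> np.ndarray:
    """GVMI trajectory for shrubland pixels, balanced against the integral.

    Shrubland FMC depends on EVI, GVMI and the cumulative NDVI integral;
    choosing GVMI so that ``slope_GVMI*GVMI + slope_Integral*I`` is constant
    keeps the solved EVI within a physically invertible range all season.
    """
    if shrub_ndvi is None:
        shrub_ndvi = default_shrub_ndvi_template()
    integral = np.cumsum(shrub_ndvi)
    return (level + equations.shrub_integral * integral) / (-equations.shrub_gvmi)


def default_nir_profile() -> np.ndarray:
    return _dip_profile(0.24, 0.20)


# ---------------------------------------------------------------------------
# land cover

def generate_landcover(config: SimulationConfig) -> LandCoverMap:
    """Spatially clumped categorical raster with the requested proportions.

    A seeded Gaussian-smoothed noise field is thresholded at the quantiles
    of the stated proportions, which pins class frequencies to the target up
    to ties (well within ±2 percentage points on grids >= 100x100).
    """
    rng = np.random.default_rng(config.seed)
    grid = config.grid
    field_ = rng.standard_normal(grid.shape)
    field_ = ndimage.gaussian_filter(field_, sigma=config.landcover_patch_size)
    ranks = field_.ravel().argsort().argsort().reshape(grid.shape) / field_.size
    classes = np.full(grid.shape, OTHER, dtype=np.int64)
    # deterministic class order: other, grassland, shrubland, forest
    order = [OTHER, GRASSLAND, SHRUBLAND, CHACO_FOREST]
    cum = 0.0
    for code in order:
        p = config.proportions.get(code, 0.0)
        classes[(ranks >= cum) & (ranks < cum + p)] = code
        cum += p
    # ranks live on {k/size} < 1, so cum = 1 covers every pixel; guard against
    # float drift in the cumulative sum by assigning any remainder to the last
    # class with positive proportion
    last = [c for c in order if config.proportions.get(c, 0) > 0][-1]
    classes[ranks >= cum] = last
    return LandCoverMap(classes=classes, grid=grid,
                        year_range=(min(config.years), max(config.years)))


# ---------------------------------------------------------------------------
# latent FMC

def seasonal_template(params: CoverParams, doys: np.ndarray = SEASON_DOYS) -> np.ndarray:
    """Deterministic piecewise-linear seasonal FMC trajectory of one cover."""
    doys = np.asarray(doys, dtype=float)
    down = params.start_fmc + (params.min_fmc - params.start_fmc) * (
        (doys - doys[0]) / (params.min_doy - doys[0]))
    up = params.min_fmc + params.recovery_rate * (doys - params.min_doy)
    template = np.where(doys <= params.min_doy, down, np.minimum(up, params.start_fmc))
    return np.maximum(template, 0.0)


def _ar1_noise(rng: np.random.Generator, shape: tuple[int, ...],
               sd: float, phi: float) -> np.ndarray:
    """AR(1) noise along the first axis with stationary standard deviation sd."""
    n = shape[0]
    out = np.empty(shape)
    out[0] = rng.standard_normal(shape[1:]) * sd
    innov_sd = sd * np.sqrt(1.0 - phi * phi)
    for t in range(1, n):
        out[t] = phi * out[t - 1] + rng.standard_normal(shape[1:]) * innov_sd
    return out


def generate_fmc(config: SimulationConfig, landcover: LandCoverMap,
                 year: int) -> LatentFMCStack:
    """Latent FMC stack for one season: template + AR(1) noise, floored at 0."""
    if year not in config.years:
        raise InvalidConfigError(f"year {year} not in simulated years {config.years}")
    rng = np.random.default_rng([config.seed, year, 0x1F])
    offset = config.year_fmc_offset.get(year, 0.0)
    data = np.full((len(SEASON_DOYS),) + landcover.grid.shape, np.nan)
    for code, params in config.cover_params.items():
        mask = landcover.mask(code)
        if not mask.any():
            continue
        template = seasonal_template(params) + offset
        traj = template[:, None] + _ar1_noise(
            rng, (len(SEASON_DOYS), int(mask.sum())), params.noise_sd, params.ar1)
        data[:, mask] = np.maximum(traj, 0.0)
    return LatentFMCStack(data=data, grid=landcover.grid, year=year,
                          landcover=np.asarray(landcover.classes).copy())


# ---------------------------------------------------------------------------
# exact inversion: FMC -> indices -> reflectance

def fmc_to_indices(
    latent: LatentFMCStack,
    landcover: LandCoverMap,
    gvmi_profile: np.ndarray | None = None,
    equations: EquationSet = DEFAULT_EQUATIONS,
) -> IndexStack:
    """Index stack that maps back to the latent FMC exactly.

    Grassland: EVI solved from the grassland equation. Forest: NDVI solved
    sequentially through the integral recursion ``I_t = I_{t-1} + NDVI_t``
    (I_0 = 0). Shrubland: NDVI follows a fixed smooth template (so the
    integral is known), GVMI follows ``gvmi_profile``, and EVI is solved —
    the only sequentially solvable choice. Indices a cover's equation does
    not need are filled from smooth templates so the stack is dense.
    """
    q = equations
    fmc = latent.data
    nt = fmc.shape[0]
    shape = fmc.shape
    grass = landcover.mask(GRASSLAND)
    shrub = landcover.mask(SHRUBLAND)
    forest = landcover.mask(CHACO_FOREST)
    other = landcover.mask(OTHER)
    if np.isnan(fmc[:, ~other]).any():
        raise ValueError("latent FMC must be finite on every non-'other' pixel")

    ndvi_fill = default_ndvi_fill()
    evi_fill = default_evi_fill()
    gvmi_fill = default_gvmi_fill()
    shrub_ndvi = default_shrub_ndvi_template()
    if gvmi_profile is None:
        gvmi_profile = default_gvmi_profile(shrub_ndvi, q)
    gvmi_profile = np.asarray(gvmi_profile, dtype=float)

    ndvi = np.broadcast_to(ndvi_fill[:, None, None], shape).copy()
    evi = np.broadcast_to(evi_fill[:, None, None], shape).copy()
    gvmi = np.broadcast_to(gvmi_fill[:, None, None], shape).copy()

    # grassland: EVI carries the signal
    evi[:, grass] = (fmc[:, grass] + (-q.grassland_intercept)) / q.grassland_evi

    # forest: NDVI carries the signal through the integral recursion
    i_prev = np.zeros(int(forest.sum()))
    for t in range(nt):
        v = (fmc[t, forest] - q.forest_intercept - q.forest_integral * i_prev) / (
            q.forest_ndvi + q.forest_integral)
        ndvi[t, forest] = v
        i_prev = i_prev + v

    # shrubland: NDVI and GVMI follow templates, EVI carries the signal
    ndvi[:, shrub] = shrub_ndvi[:, None]
    gvmi[:, shrub] = gvmi_profile[:, None]
    shrub_integral = np.cumsum(shrub_ndvi)
    evi[:, shrub] = (
        fmc[:, shrub]
        - q.shrub_gvmi * gvmi_profile[:, None]
        - q.shrub_integral * shrub_integral[:, None]
        - q.shrub_intercept
    ) / q.shrub_evi

    for name, arr in (("NDVI", ndvi), ("EVI", evi), ("GVMI", gvmi)):
        bad = (arr < INDEX_BOUNDS[0]) | (arr > INDEX_BOUNDS[1])
        if bad.any():
            warnings.warn(
                f"{name} inversion produced {int(bad.sum())} values outside "
                f"{INDEX_BOUNDS}; the configuration is unrealistic", stacklevel=2)

    integral = np.cumsum(ndvi, axis=0)
    return IndexStack(ndvi=ndvi, evi=evi, gvmi=gvmi, integral=integral,
                      grid=latent.grid, year=latent.year)


def indices_to_reflectance(
    indices: IndexStack,
    nir_profile: np.ndarray | None = None,
) -> ReflectanceStack:
    """Band stack whose recomputed indices reproduce ``indices`` exactly.

    NIR follows the given per-date profile; red is solved from the NDVI
    definition, blue from the EVI definition and SWIR from the GVMI
    definition.
    """
    if nir_profile is None:
        nir_profile = default_nir_profile()
    nir_profile = np.asarray(nir_profile, dtype=float)
    if np.any(nir_profile <= 0) or np.any(nir_profile >= 1):
        raise ValueError("NIR profile must lie in (0, 1)")
    shape = indices.ndvi.shape
    nir = np.broadcast_to(nir_profile[:, None, None], shape).copy()

    v = indices.ndvi
    if np.any(v <= -1) or np.any(v >= 1):
        t, r, c = np.unravel_index(int(np.argmax(np.abs(v))), shape)
        raise DegenerateInputError(
            f"NDVI out of (-1, 1) at date {t}, pixel ({r}, {c}): red unsolvable")
    red = nir * (1.0 - v) / (1.0 + v)

    e = indices.evi
    if np.any(np.abs(e) < 1e-12):
        t, r, c = np.unravel_index(int(np.argmin(np.abs(e))), shape)
        raise DegenerateInputError(
            f"EVI ~ 0 at date {t}, pixel ({r}, {c}): blue unsolvable")
    blue = (nir + 6.0 * red + 1.0 - 2.5 * (nir - red) / e) / 7.5

    g = indices.gvmi
    if np.any(g <= -1) or np.any(g >= 1):
        t, r, c = np.unravel_index(int(np.argmax(np.abs(g))), shape)
        raise DegenerateInputError(
            f"GVMI out of (-1, 1) at date {t}, pixel ({r}, {c}): SWIR unsolvable")
    swir = (nir + 0.1) * (1.0 - g) / (1.0 + g) - 0.02

    return ReflectanceStack(red=red, nir=nir, blue=blue, swir=swir,
                            grid=indices.grid, year=indices.year,
                            doys=np.asarray(indices.doys).copy())


# ---------------------------------------------------------------------------
# fires

def _grow_patch(rng: np.random.Generator, seed_rc: tuple[int, int],
                n_target: int, shape: tuple[int, int]) -> list[tuple[int, int]]:
    """Random connected pixel patch grown from a seed (4-connectivity)."""
    rows, cols = shape
    patch = {seed_rc}
    frontier = [seed_rc]
    while len(patch) < n_target and frontier:
        i = rng.integers(len(frontier))
        r, c = frontier[i]
        neighbors = [(r + dr, c + dc) for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1))
                     if 0 <= r + dr < rows and 0 <= c + dc < cols
                     and (r + dr, c + dc) not in patch]
        if not neighbors:
            frontier.pop(i)
            continue
        nxt = neighbors[rng.integers(len(neighbors))]
        patch.add(nxt)
        frontier.append(nxt)
    return sorted(patch)


def _patch_polygon(patch: list[tuple[int, int]], grid: GridSpec):
    boxes = [box(*grid.pixel_bounds(r, c)) for r, c in patch]
    return unary_union(boxes)


def generate_fires(
    latent: LatentFMCStack,
    landcover: LandCoverMap,
    config: SimulationConfig,
) -> list[FireEvent]:
    """FMC-conditioned fire record for one season.

    Ignition dates and pixels are sampled with probability increasing as
    local FMC decreases; each fire is a connected pixel patch whose target
    size is heavy-tailed but truncated at a cap decaying exponentially with
    the local mean FMC at ignition. Fires start strictly after the first
    composite so a pre-fire map always exists.
    """
    fp = config.fire_params
    rng = np.random.default_rng([config.seed, latent.year, 0x2F])
    valid = ~np.all(np.isnan(latent.data), axis=0)
    if not valid.any():
        raise InvalidConfigError("no pixel with an FMC trajectory to ignite")
    n_fires = int(rng.poisson(fp.expected_per_year))
    if n_fires == 0:
        return []

    # date weights: mean valid FMC per composite, low moisture -> likely
    mean_by_date = np.nanmean(latent.data[:, valid], axis=1)
    usable_dates = np.arange(len(latent.doys) - 1)  # leave room for an offset
    wdate = np.exp(-mean_by_date[usable_dates] / fp.date_weight_scale)
    wdate /= wdate.sum()

    fires: list[FireEvent] = []
    grid = latent.grid
    pixel_area = grid.pixel_area_ha
    for k in range(n_fires):
        t = int(rng.choice(usable_dates, p=wdate))
        fmc_t = latent.data[t]
        ok = ~np.isnan(fmc_t)
        wpix = np.zeros(grid.shape)
        wpix[ok] = np.exp(-fmc_t[ok] / fp.pixel_weight_scale)
        flat = wpix.ravel()
        flat = flat / flat.sum()
        idx = int(rng.choice(flat.size, p=flat))
        r0, c0 = divmod(idx, grid.cols)
        # local mean FMC in the ignition neighborhood at ignition time: the
        # moisture a growing fire would actually encounter
        w = fp.local_window
        win = fmc_t[max(0, r0 - w):r0 + w + 1, max(0, c0 - w):c0 + w + 1]
        local_fmc = float(np.nanmean(win))
        cap_ha = fp.cap_scale_ha * np.exp(-fp.cap_decay * local_fmc)
        raw = fp.min_size_ha * (1.0 - rng.random()) ** (-1.0 / fp.pareto_alpha)
        target_ha = min(raw, cap_ha, grid.rows * grid.cols * pixel_area)
        n_pixels = max(1, int(round(target_ha / pixel_area)))
        patch = _grow_patch(rng, (r0, c0), n_pixels, grid.shape)
        start_doy = int(latent.doys[t]) + int(rng.integers(1, 8))
        fires.append(FireEvent(
            fire_id=f"{latent.year}-{k:04d}",
            geometry=_patch_polygon(patch, grid),
            year=latent.year,
            start_doy=start_doy,
            area_ha=len(patch) * pixel_area,
        ))
    return fires


# ---------------------------------------------------------------------------
# one-call scene

def simulate_scene(config: SimulationConfig) -> dict:
    """Generate land cover, latent FMC, indices, bands and fires for all years."""
    landcover = generate_landcover(config)
    out = {"landcover": landcover, "latent": {}, "indices": {},
           "reflectance": {}, "fires": []}
    for year in config.years:
        latent = generate_fmc(config, landcover, year)
        indices = fmc_to_indices(latent, landcover)
        out["latent"][year] = latent
        out["indices"][year] = indices
        out["reflectance"][year] = indices_to_reflectance(indices)
        out["fires"].extend(generate_fires(latent, landcover, config))
    return out


def config_for_strata(config: SimulationConfig, high_years: tuple[int, ...],
                      offset: float) -> SimulationConfig:
    """Copy of ``config`` with high-activity years offset downward in FMC."""
    offsets = dict(config.year_fmc_offset)
    offsets.update({y: -abs(offset) for y in high_years})
    return replace(config, year_fmc_offset=offsets)
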