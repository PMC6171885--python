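"""Readers and writers for the pipeline's on-disk formats.

Rasters are TIFF files (one per date for stacks, named
``{prefix}_{year}_{doy}.tif``) carrying the planar grid metadata as JSON in
the TIFF description tag; fires travel as a GeoJSON FeatureCollection with
properties ``fire_id, year, start_doy, area_ha``; thresholds as YAML;
sample tables and statistics as CSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
import yaml
from shapely.geometry import mapping, shape

from .grids import SEASON_DOYS, GridSpec, LandCoverMap
from .hazard import HazardThresholds
from .indices import IndexStack, ReflectanceStack
from .mapping import FMCStack
from .prefire import FireEvent

FILL_VALUE = -9999.0  # raster missing marker on disk (NaN in memory)


# ---------------------------------------------------------------------------
# rasters

def _grid_meta(grid: GridSpec, **extra) -> str:
    meta = {"rows": grid.rows, "cols": grid.cols, "pixel_size": grid.pixel_size,
            "x0": grid.x0, "y0": grid.y0}
    meta.update(extra)
    return json.dumps(meta)


def write_raster(path, data: np.ndarray, grid: GridSpec, **extra) -> None:
    data = np.asarray(data)
    if data.dtype.kind == "f":
        data = np.where(np.isnan(data), FILL_VALUE, data).astype(np.float32)
    tifffile.imwrite(path, data, description=_grid_meta(grid, **extra))


def read_raster(path) -> tuple[np.ndarray, GridSpec, dict]:
    with tifffile.TiffFile(path) as tif:
        data = tif.pages[0].asarray()
        meta = json.loads(tif.pages[0].description or "{}")
    grid = GridSpec(rows=meta.pop("rows"), cols=meta.pop("cols"),
                    pixel_size=meta.pop("pixel_size"),
                    x0=meta.pop("x0"), y0=meta.pop("y0"))
    if data.dtype.kind == "f":
        data = data.astype(float)
        data[data == FILL_VALUE] = np.nan
    return data, grid, meta


def write_landcover(path, landcover: LandCoverMap) -> None:
    tifffile.imwrite(path, np.asarray(landcover.classes).astype(np.int16),
                     description=_grid_meta(landcover.grid,
                                            year_range=list(landcover.year_range)))


def read_landcover(path) -> LandCoverMap:
    data, grid, meta = read_raster(path)
    return LandCoverMap(classes=np.asarray(data, dtype=np.int64), grid=grid,
                        year_range=tuple(meta.get("year_range", (2002, 2016))))


def write_stack(outdir, data: np.ndarray, grid: GridSpec, prefix: str,
                year: int, doys: np.ndarray = SEASON_DOYS) -> list[Path]:
    """One float TIFF per date: ``{prefix}_{year}_{doy}.tif``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for t, doy in enumerate(np.asarray(doys)):
        p = outdir / f"{prefix}_{year}_{int(doy):03d}.tif"
        write_raster(p, data[t], grid, year=int(year), doy=int(doy))
        paths.append(p)
    return paths


def read_stack(indir, prefix: str, year: int) -> tuple[np.ndarray, GridSpec, np.ndarray]:
    """Stack the per-date rasters of one prefix/year, sorted by DOY."""
    indir = Path(indir)
    files = sorted(indir.glob(f"{prefix}_{year}_*.tif"))
    if not files:
        raise FileNotFoundError(f"no '{prefix}_{year}_*.tif' rasters in {indir}")
    layers, doys = [], []
    grid = None
    for f in files:
        data, grid, meta = read_raster(f)
        layers.append(data)
        doys.append(meta["doy"])
    order = np.argsort(doys)
    return (np.stack([layers[i] for i in order]), grid,
            np.asarray(doys)[order])


def write_fmc_stack(outdir, stack: FMCStack) -> list[Path]:
    paths = write_stack(outdir, stack.data, stack.grid, "fmc", stack.year, stack.doys)
    lc = Path(outdir) / f"fmc_landcover_{stack.year}.tif"
    tifffile.imwrite(lc, stack.landcover.astype(np.int16),
                     description=_grid_meta(stack.grid, year=int(stack.year)))
    return paths + [lc]


def read_fmc_stack(indir, year: int) -> FMCStack:
    data, grid, doys = read_stack(indir, "fmc", year)
    lc, _, _ = read_raster(Path(indir) / f"fmc_landcover_{year}.tif")
    return FMCStack(data=data, grid=grid, year=year,
                    landcover=np.asarray(lc, dtype=np.int64), doys=doys)


def write_index_stack(outdir, stack: IndexStack) -> None:
    for name in ("ndvi", "evi", "gvmi", "integral"):
        write_stack(outdir, getattr(stack, name), stack.grid, name,
                    stack.year, stack.doys)


def read_index_stack(indir, year: int) -> IndexStack:
    arrays = {}
    grid = doys = None
    for name in ("ndvi", "evi", "gvmi", "integral"):
        arrays[name], grid, doys = read_stack(indir, name, year)
    return IndexStack(grid=grid, year=year, doys=doys, **arrays)


def write_reflectance_stack(outdir, stack: ReflectanceStack) -> None:
    for name in ("red", "nir", "blue", "swir"):
        write_stack(outdir, getattr(stack, name), stack.grid, name,
                    stack.year, stack.doys)


def read_reflectance_stack(indir, year: int) -> ReflectanceStack:
    arrays = {}
    grid = doys = None
    for name in ("red", "nir", "blue", "swir"):
        arrays[name], grid, doys = read_stack(indir, name, year)
    return ReflectanceStack(grid=grid, year=year, doys=doys, **arrays)


# ---------------------------------------------------------------------------
# fires

def fires_to_geojson(fires: list[FireEvent]) -> dict:
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": mapping(f.geometry),
                "properties": {"fire_id": f.fire_id, "year": f.year,
                               "start_doy": f.start_doy, "area_ha": f.area_ha},
            }
            for f in fires
        ],
    }


def fires_from_geojson(data: dict) -> list[FireEvent]:
    fires = []
    for feat in data["features"]:
        props = feat["properties"]
        fires.append(FireEvent(
            fire_id=str(props["fire_id"]), geometry=shape(feat["geometry"]),
            year=int(props["year"]), start_doy=int(props["start_doy"]),
            area_ha=float(props["area_ha"])))
    return fires


def write_fires(path, fires: list[FireEvent]) -> None:
    Path(path).write_text(json.dumps(fires_to_geojson(fires)))


def read_fires(path) -> list[FireEvent]:
    return fires_from_geojson(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# thresholds

def write_thresholds(path, thresholds: HazardThresholds) -> None:
    Path(path).write_text(yaml.safe_dump(_plain(thresholds.to_dict())))


def read_thresholds(path) -> HazardThresholds:
    return HazardThresholds.from_dict(yaml.safe_load(Path(path).read_text()))


def _plain(obj):
    """Recursively convert numpy scalars / tuples for YAML- and JSON-ability."""
    if isinstance(obj, dict):
        return {str(k): _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj
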