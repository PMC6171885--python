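"""End-to-end pipeline: simulate -> indices -> smooth -> fmc -> extract ->
thresholds -> classify -> evaluate -> stats -> season.

Each stage reads in-memory results of earlier stages, writes its outputs
under the configured directory, and records row counts and file hashes in a
JSON run manifest. A stage failure halts the run with the stage name; the
outputs of completed stages remain on disk.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np

from . import io as fio
from .config import PipelineConfig
from .grids import OTHER
from .hazard import classify, compare_external, derive_thresholds, evaluate_classification
from .indices import compute_indices, compute_integral, sg_smooth
from .mapping import estimate_fmc
from .prefire import extract_fire_samples, extract_pixel_samples
from .seasonal import (
    burned_fraction_by_year,
    days_below,
    seasonal_curves,
    select_curve,
    stratify_years,
    stratum_difference,
)
from .sizestats import compare_small_large, quantile_regression, summarize_by_size
from .synthetic import fmc_to_indices, generate_fires, generate_fmc, generate_landcover, indices_to_reflectance

logger = logging.getLogger(__name__)

STAGES = ("simulate", "indices", "smooth", "fmc", "extract", "thresholds",
          "classify", "evaluate", "stats", "season")


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline failed at stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_csv(df, path: Path) -> dict:
    df.to_csv(path, index=False, float_format="%.6f")
    return {"path": str(path), "rows": int(len(df)), "sha256": _sha256(path)}


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages on a synthetic scene and return the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "config_outdir": str(outdir)}
    state: dict = {}

    def run_stage(name, fn):
        try:
            manifest["stages"][name] = fn() or {}
        except Exception as exc:  # noqa: BLE001 - halt with stage provenance
            (outdir / "manifest.partial.json").write_text(
                json.dumps(fio._plain(manifest), indent=2))
            raise PipelineStageError(name, exc) from exc

    sim = config.simulate

    def stage_simulate():
        landcover = generate_landcover(sim)
        state["landcover"] = landcover
        state["latent"] = {}
        state["reflectance"] = {}
        fires = []
        for year in sim.years:
            latent = generate_fmc(sim, landcover, year)
            state["latent"][year] = latent
            state["reflectance"][year] = indices_to_reflectance(
                fmc_to_indices(latent, landcover, equations=config.equations))
            fires.extend(generate_fires(latent, landcover, sim))
        state["fires"] = fires
        fio.write_landcover(outdir / "landcover.tif", landcover)
        fio.write_fires(outdir / "fires.geojson", fires)
        if config.write_rasters:
            for year, refl in state["reflectance"].items():
                fio.write_reflectance_stack(outdir / "reflectance", refl)
        return {"n_fires": len(fires), "years": list(sim.years),
                "grid": list(landcover.grid.shape)}

    def stage_indices():
        state["indices"] = {y: compute_indices(r, smooth=False)
                            for y, r in state["reflectance"].items()}
        return {"years": list(state["indices"])}

    def stage_smooth():
        smoothed = {}
        for year, idx in state["indices"].items():
            def _s(a):
                return np.moveaxis(sg_smooth(
                    np.moveaxis(a, 0, -1), config.sg_window_halfwidth,
                    config.sg_poly_order, config.sg_max_gap), -1, 0)
            ndvi, evi, gvmi = _s(idx.ndvi), _s(idx.evi), _s(idx.gvmi)
            integral = compute_integral(ndvi, axis=0)
            smoothed[year] = type(idx)(ndvi=ndvi, evi=evi, gvmi=gvmi,
                                       integral=integral, grid=idx.grid,
                                       year=idx.year, doys=idx.doys)
        state["smoothed"] = smoothed
        return {"window_halfwidth": config.sg_window_halfwidth,
                "poly_order": config.sg_poly_order}

    def stage_fmc():
        stacks = {}
        for year, idx in state["smoothed"].items():
            stacks[year] = estimate_fmc(idx, state["landcover"], config.equations)
            if config.write_rasters:
                fio.write_fmc_stack(outdir / "fmc", stacks[year])
        state["fmc"] = stacks
        (outdir / "fmc_manifest.json").write_text(json.dumps(fio._plain({
            "years": list(stacks),
            "doys": list(map(int, next(iter(stacks.values())).doys)),
            "equations": vars(config.equations),
        }), indent=2))
        return {"years": list(stacks)}

    def stage_extract():
        pixels = extract_pixel_samples(
            state["fires"], state["fmc"], min_area_ha=config.min_area_ha)
        fires_df = extract_fire_samples(
            state["fires"], state["fmc"],
            max_missing_fraction=config.max_missing_fraction,
            min_area_ha=config.min_area_ha, bounds=config.size_class_bounds)
        state["pixel_samples"] = pixels
        state["fire_samples"] = fires_df
        return {"pixel_samples": _write_csv(pixels, outdir / "pixel_samples.csv"),
                "fire_samples": _write_csv(fires_df, outdir / "fire_samples.csv")}

    def stage_thresholds():
        thresholds = derive_thresholds(
            state["pixel_samples"], config.percentiles,
            min_samples=config.min_samples_per_cover)
        state["thresholds"] = thresholds
        fio.write_thresholds(outdir / "thresholds.yaml", thresholds)
        return {"thresholds": thresholds.to_dict()}

    def stage_classify():
        counts = {}
        for year, stack in state["fmc"].items():
            hazard_map = classify(stack, state["thresholds"])
            if config.write_rasters:
                fio.write_stack(outdir / "hazard", hazard_map.astype(float),
                                stack.grid, "hazard", year, stack.doys)
            vals, n = np.unique(hazard_map, return_counts=True)
            counts[year] = {int(v): int(k) for v, k in zip(vals, n)}
        return {"class_counts": counts}

    def stage_evaluate():
        table = evaluate_classification(state["pixel_samples"], state["thresholds"])
        info = {"self": _write_csv(table, outdir / "evaluation.csv")}
        if config.external_thresholds is not None:
            ext = compare_external(state["pixel_samples"], config.external_thresholds)
            info["external"] = _write_csv(ext, outdir / "evaluation_external.csv")
        return info

    def stage_stats():
        fire_df = state["fire_samples"]
        summary = summarize_by_size(fire_df)
        h, p = compare_small_large(fire_df)
        qr = quantile_regression(fire_df, taus=config.taus,
                                 n_bootstrap=config.n_bootstrap, seed=config.seed)
        return {
            "size_summary": _write_csv(summary, outdir / "size_summary.csv"),
            "kruskal_wallis": {"H": h, "p": p},
            "quantile_fits": _write_csv(qr.table, outdir / "quantile_fits.csv"),
        }

    def stage_season():
        mapped_px = int(np.count_nonzero(state["landcover"].classes != OTHER))
        mapped_ha = mapped_px * state["landcover"].grid.pixel_area_ha
        fractions = burned_fraction_by_year(state["fires"], mapped_ha)
        high, low, rest = stratify_years(fractions, config.high_activity_cut,
                                         config.low_activity_cut)
        strata = {"all": list(sim.years)}
        if high:
            strata["high_activity"] = high
        if low:
            strata["low_activity"] = low
        curves = seasonal_curves(state["fmc"], strata)
        info = {"curves": _write_csv(curves, outdir / "seasonal_curves.csv"),
                "burned_fraction": fractions,
                "strata": {"high": high, "low": low, "unclassified": rest}}
        report = []
        for code, cuts in state["thresholds"].by_cover.items():
            from .grids import COVER_NAMES
            cover = COVER_NAMES[code]
            for stratum in strata:
                curve = select_curve(curves, cover, stratum)
                report.append({"cover": cover, "stratum": stratum,
                               "days_below_extreme": days_below(curve, cuts[0]),
                               "days_below_high": days_below(curve, cuts[1])})
        if high and low:
            for code in state["thresholds"].by_cover:
                from .grids import COVER_NAMES
                cover = COVER_NAMES[code]
                diff = stratum_difference(select_curve(curves, cover, "high_activity"),
                                          select_curve(curves, cover, "low_activity"))
                report.append({"cover": cover, "stratum": "difference",
                               "low_minus_high_pp": diff})
        (outdir / "season_report.json").write_text(
            json.dumps(fio._plain(report), indent=2))
        return info

    for name, fn in zip(STAGES, (stage_simulate, stage_indices, stage_smooth,
                                 stage_fmc, stage_extract, stage_thresholds,
                                 stage_classify, stage_evaluate, stage_stats,
                                 stage_season)):
        logger.info("running stage %s", name)
        run_stage(name, fn)

    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(fio._plain(manifest), indent=2))
    return manifest
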