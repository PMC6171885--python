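"""Pre-fire date matching, polygon rasterization and sample extraction."""

import numpy as np
import pytest
from shapely.geometry import box

import fmc_hazard as fh
from fmc_hazard.grids import GRASSLAND, OTHER, SHRUBLAND, CHACO_FOREST, GridSpec, SEASON_DOYS
from fmc_hazard.mapping import FMCStack
from fmc_hazard.prefire import (
    FireEvent,
    UnmatchableFireError,
    extract_fire_samples,
    extract_pixel_samples,
    match_prefire_date,
    rasterize_fire,
    size_class,
)


def _fire(geometry, start_doy=200, year=2008, area_ha=None, fire_id="f1"):
    if area_ha is None:
        area_ha = geometry.area / 10_000.0
    return FireEvent(fire_id=fire_id, geometry=geometry, year=year,
                     start_doy=start_doy, area_ha=area_ha)


def _stack(grid, landcover, fill=80.0, year=2008):
    data = np.full((len(SEASON_DOYS),) + grid.shape, float(fill))
    data[:, landcover == OTHER] = np.nan
    return FMCStack(data=data, grid=grid, year=year, landcover=landcover)


class TestMatchPrefireDate:
    @pytest.mark.parametrize("start,expected", [(130, 129), (129, 121)])
    def test_latest_strictly_earlier_composite(self, start, expected):
        fire = _fire(box(0, -500, 500, 0), start_doy=start)
        assert match_prefire_date(fire, SEASON_DOYS) == expected

    def test_fire_on_first_composite_unmatchable(self):
        fire = _fire(box(0, -500, 500, 0), start_doy=121)
        with pytest.raises(UnmatchableFireError):
            match_prefire_date(fire, SEASON_DOYS)

    def test_non_strict_matching(self):
        fire = _fire(box(0, -500, 500, 0), start_doy=129)
        assert match_prefire_date(fire, SEASON_DOYS, strict=False) == 129


class TestRasterize:
    def test_polygon_covering_one_pixel(self):
        grid = GridSpec(4, 4)
        rows, cols = rasterize_fire(_fire(box(500, -1000, 1000, -500)), grid)
        assert list(zip(rows, cols)) == [(1, 1)]

    def test_half_pixel_without_center_excluded(self):
        grid = GridSpec(2, 2)
        # covers the left 200 m of pixel (0, 0): center at x=250 not inside
        rows, cols = rasterize_fire(_fire(box(0, -500, 200, 0)), grid)
        assert rows.size == 0

    def test_two_by_two_square_is_four_pixels(self):
        grid = GridSpec(4, 4)
        rows, cols = rasterize_fire(_fire(box(0, -1000, 1000, 0)), grid)
        assert rows.size == 4
        assert rows.size * grid.pixel_area_ha == pytest.approx(100.0)

    def test_off_grid_polygon_empty(self):
        grid = GridSpec(2, 2)
        rows, _ = rasterize_fire(_fire(box(10_000, -11_000, 11_000, -10_000)), grid)
        assert rows.size == 0


class TestSizeClass:
    @pytest.mark.parametrize("area,expected", [
        (100, "small"), (499, "small"), (500, "medium"),
        (999, "medium"), (1000, "large"), (50_000, "large"),
    ])
    def test_half_open_low_inclusive_bounds(self, area, expected):
        assert size_class(area) == expected

    def test_partition_has_no_gaps(self):
        # every area >= 100 belongs to exactly one class
        for area in np.linspace(100, 2000, 567):
            assert size_class(area) in {"small", "medium", "large"}


class TestPixelSamples:
    def test_small_fire_contributes_nothing(self):
        grid = GridSpec(4, 4)
        lc = np.full((4, 4), GRASSLAND)
        stack = _stack(grid, lc)
        fire = _fire(box(0, -1000, 1000, 0), area_ha=90.0)
        samples = extract_pixel_samples([fire], {2008: stack})
        assert len(samples) == 0

    def test_fire_spanning_three_covers(self):
        grid = GridSpec(2, 3)
        lc = np.array([[GRASSLAND, SHRUBLAND, CHACO_FOREST]] * 2)
        stack = _stack(grid, lc)
        fire = _fire(box(0, -1000, 1500, 0), area_ha=150.0)
        samples = extract_pixel_samples([fire], {2008: stack})
        assert sorted(samples["cover"].unique()) == [GRASSLAND, SHRUBLAND, CHACO_FOREST]

    def test_k_valid_pixels_give_k_records(self):
        grid = GridSpec(4, 4)
        lc = np.full((4, 4), SHRUBLAND)
        stack = _stack(grid, lc)
        fire = _fire(box(0, -1500, 1500, 0), area_ha=225.0)
        samples = extract_pixel_samples([fire], {2008: stack})
        assert len(samples) == 9

    def test_other_and_missing_pixels_skipped(self):
        grid = GridSpec(2, 2)
        lc = np.array([[GRASSLAND, OTHER], [GRASSLAND, GRASSLAND]])
        stack = _stack(grid, lc)
        stack.data[:, 1, 0] = np.nan  # missing FMC on one grassland pixel
        fire = _fire(box(0, -1000, 1000, 0), area_ha=100.0)
        samples = extract_pixel_samples([fire], {2008: stack})
        assert len(samples) == 2

    def test_sample_count_bounded_by_rasterized_count(self, fire_rich_scene):
        samples = extract_pixel_samples(fire_rich_scene["fires"],
                                        fire_rich_scene["stacks"])
        grid = fire_rich_scene["latent"].grid
        for fire in fire_rich_scene["fires"]:
            if fire.area_ha < 100:
                continue
            rows, _ = rasterize_fire(fire, grid)
            assert (samples["fire_id"] == fire.fire_id).sum() <= rows.size


class TestFireSamples:
    def _three_cover_stack(self):
        grid = GridSpec(2, 5)
        lc = np.full((2, 5), GRASSLAND)
        lc[:, 4] = OTHER
        stack = _stack(grid, lc)
        return grid, stack

    def test_thirty_percent_missing_discarded(self):
        grid, stack = self._three_cover_stack()
        # 10-pixel fire, 3 pixels on "other" (no FMC): 30 % missing
        fire = _fire(box(0, -1000, 2500, 0), area_ha=250.0)
        stack.data[:, 1, 3] = np.nan
        samples = extract_fire_samples([fire], {2008: stack})
        assert len(samples) == 0

    def test_quarter_missing_kept(self):
        grid = GridSpec(2, 4)
        lc = np.full((2, 4), GRASSLAND)
        lc[:, 3] = OTHER  # 2 of 8 pixels missing: exactly 25 %
        stack = _stack(grid, lc)
        fire = _fire(box(0, -1000, 2000, 0), area_ha=200.0)
        samples = extract_fire_samples([fire], {2008: stack})
        assert len(samples) == 1
        assert samples["coverage"].iloc[0] == pytest.approx(0.75)

    def test_exact_thousand_hectares_is_large(self):
        grid = GridSpec(8, 8)
        lc = np.full((8, 8), GRASSLAND)
        stack = _stack(grid, lc)
        fire = _fire(box(0, -2500, 4000, 0), area_ha=1000.0)
        samples = extract_fire_samples([fire], {2008: stack})
        assert samples["size_class"].iloc[0] == "large"

    def test_mean_over_valid_pixels(self):
        grid = GridSpec(1, 2)
        lc = np.full((1, 2), GRASSLAND)
        stack = _stack(grid, lc)
        stack.data[:, 0, 0] = 60.0
        stack.data[:, 0, 1] = 80.0
        fire = _fire(box(0, -500, 1000, 0), area_ha=100.0)
        samples = extract_fire_samples([fire], {2008: stack})
        assert samples["mean_fmc"].iloc[0] == pytest.approx(70.0)

    def test_all_retained_fires_have_sufficient_coverage(self, fire_rich_scene):
        samples = extract_fire_samples(fire_rich_scene["fires"],
                                       fire_rich_scene["stacks"])
        assert (samples["coverage"] >= 0.75).all()

    def test_noiseless_extraction_matches_latent_exactly(self):
        cfg = fh.SimulationConfig(
            rows=20, cols=20, seed=4,
            proportions={GRASSLAND: 1.0},
            cover_params={GRASSLAND: fh.CoverParams(90, 40, 245, 0.5, noise_sd=0.0)})
        lc = fh.generate_landcover(cfg)
        latent = fh.generate_fmc(cfg, lc, cfg.years[0])
        fire = _fire(box(0, -1000, 1000, 0), start_doy=200, area_ha=100.0)
        samples = extract_pixel_samples([fire], {2008: latent})
        expected = latent.at_doy(193)[0, 0]  # last composite before DOY 200
        assert np.allclose(samples["fmc"], expected)
        assert (samples["doy_used"] == 193).all()
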