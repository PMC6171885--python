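"""Synthetic-scene generator: land cover, FMC trajectories, inversions, fires."""

import numpy as np
import pytest

import fmc_hazard as fh
from fmc_hazard.grids import CHACO_FOREST, GRASSLAND, OTHER, SHRUBLAND
from fmc_hazard.synthetic import (
    CoverParams,
    DEFAULT_COVER_PARAMS,
    FireParams,
    InvalidConfigError,
    DegenerateInputError,
    default_nir_profile,
    seasonal_template,
)


class TestConfigValidation:
    def test_zero_area_grid_rejected(self):
        with pytest.raises(InvalidConfigError):
            fh.SimulationConfig(rows=0, cols=10)

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(InvalidConfigError):
            fh.SimulationConfig(proportions={GRASSLAND: 0.5, OTHER: 0.4})

    def test_minimum_doy_outside_august_september_rejected(self):
        params = dict(DEFAULT_COVER_PARAMS)
        params[GRASSLAND] = CoverParams(90, 40, 180, 0.5, 5.0)
        with pytest.raises(InvalidConfigError):
            fh.SimulationConfig(cover_params=params)

    def test_negative_minimum_fmc_rejected(self):
        params = dict(DEFAULT_COVER_PARAMS)
        params[GRASSLAND] = CoverParams(90, -5, 245, 0.5, 5.0)
        with pytest.raises(InvalidConfigError):
            fh.SimulationConfig(cover_params=params)


class TestLandCover:
    def test_degenerate_proportions_all_grassland(self):
        cfg = fh.SimulationConfig(rows=20, cols=20,
                                  proportions={GRASSLAND: 1.0})
        lc = fh.generate_landcover(cfg)
        assert (lc.classes == GRASSLAND).all()

    def test_seeded_determinism(self, small_config):
        a = fh.generate_landcover(small_config)
        b = fh.generate_landcover(small_config)
        assert np.array_equal(a.classes, b.classes)

    def test_frequencies_match_proportions(self):
        props = {GRASSLAND: 0.4, SHRUBLAND: 0.3, CHACO_FOREST: 0.2, OTHER: 0.1}
        cfg = fh.SimulationConfig(rows=200, cols=200, proportions=props, seed=3)
        lc = fh.generate_landcover(cfg)
        for code, target in props.items():
            freq = np.mean(lc.classes == code)
            assert abs(freq - target) <= 0.02, code


class TestLatentFmc:
    def test_noiseless_equals_template(self):
        params = {code: CoverParams(p.start_fmc, p.min_fmc, p.min_doy,
                                    p.recovery_rate, noise_sd=0.0)
                  for code, p in DEFAULT_COVER_PARAMS.items()}
        cfg = fh.SimulationConfig(rows=10, cols=10, cover_params=params, seed=2)
        lc = fh.generate_landcover(cfg)
        latent = fh.generate_fmc(cfg, lc, cfg.years[0])
        for code, p in params.items():
            mask = lc.mask(code)
            if not mask.any():
                continue
            template = seasonal_template(p)
            assert np.allclose(latent.data[:, mask], template[:, None])

    def test_other_pixels_all_missing(self, scene):
        other = scene["landcover"].mask(OTHER)
        assert np.isnan(scene["latent"].data[:, other]).all()

    def test_sample_mean_matches_template(self):
        cfg = fh.SimulationConfig(rows=40, cols=40, seed=7,
                                  proportions={GRASSLAND: 1.0})
        lc = fh.generate_landcover(cfg)
        latent = fh.generate_fmc(cfg, lc, cfg.years[0])
        p = cfg.cover_params[GRASSLAND]
        template = seasonal_template(p)
        n = lc.mask(GRASSLAND).sum()
        # mean over season and pixels; AR(1) inflates the SE of the seasonal
        # mean, so bound with the lag-sum factor (1+phi)/(1-phi)
        se = p.noise_sd / np.sqrt(n * 31 / ((1 + p.ar1) / (1 - p.ar1)))
        assert abs(np.nanmean(latent.data) - template.mean()) < 2 * se

    def test_minimum_at_configured_doy(self, scene):
        lc = scene["landcover"]
        latent = scene["latent"]
        for code, p in scene["config"].cover_params.items():
            mask = lc.mask(code)
            mean_traj = np.nanmean(latent.data[:, mask], axis=1)
            doy_at_min = fh.SEASON_DOYS[np.argmin(mean_traj)]
            assert abs(int(doy_at_min) - p.min_doy) <= 8, code

    def test_year_not_configured_rejected(self, small_config, scene):
        with pytest.raises(InvalidConfigError):
            fh.generate_fmc(small_config, scene["landcover"], 1999)


class TestFmcToIndices:
    def test_grassland_zero_fmc_evi_root(self, scene):
        lc = scene["landcover"]
        latent = scene["latent"]
        zeroed = fh.LatentFMCStack(
            data=np.where(np.isnan(latent.data), np.nan, 0.0),
            grid=latent.grid, year=latent.year, landcover=latent.landcover)
        idx = fh.fmc_to_indices(zeroed, lc)
        grass = lc.mask(GRASSLAND)
        assert np.allclose(idx.evi[:, grass], 31.16 / 540.09)

    def test_forest_first_date_inversion(self):
        # with I_0 = 0, the forest inversion at t=1 is (F + 63.06) / 248.27
        cfg = fh.SimulationConfig(rows=4, cols=4,
                                  proportions={CHACO_FOREST: 1.0}, seed=1)
        lc = fh.generate_landcover(cfg)
        data = np.full((31, 4, 4), 78.935)
        latent = fh.LatentFMCStack(data=data, grid=lc.grid, year=cfg.years[0],
                                   landcover=np.asarray(lc.classes))
        idx = fh.fmc_to_indices(latent, lc)
        assert idx.ndvi[0, 0, 0] == pytest.approx((78.935 + 63.06) / 248.27)
        assert idx.ndvi[0, 0, 0] == pytest.approx(0.57194, abs=1e-5)

    def test_unrealistic_config_warns_but_keeps_values(self, scene):
        lc = scene["landcover"]
        latent = scene["latent"]
        huge = fh.LatentFMCStack(
            data=np.where(np.isnan(latent.data), np.nan, 5000.0),
            grid=latent.grid, year=latent.year, landcover=latent.landcover)
        with pytest.warns(UserWarning, match="outside"):
            idx = fh.fmc_to_indices(huge, lc)
        assert np.isfinite(idx.evi[:, lc.mask(GRASSLAND)]).all()


class TestIndicesToReflectance:
    def test_zero_ndvi_forces_red_equal_nir(self, scene):
        idx = scene["indices"]
        modified = fh.IndexStack(
            ndvi=np.zeros_like(idx.ndvi), evi=idx.evi.copy(),
            gvmi=idx.gvmi.copy(), integral=idx.integral.copy(),
            grid=idx.grid, year=idx.year)
        refl = fh.indices_to_reflectance(modified, nir_profile=np.full(31, 0.4))
        assert np.allclose(refl.red, 0.4, atol=1e-12)

    def test_zero_gvmi_swir_closed_form(self, scene):
        idx = scene["indices"]
        modified = fh.IndexStack(
            ndvi=idx.ndvi.copy(), evi=idx.evi.copy(),
            gvmi=np.zeros_like(idx.gvmi), integral=idx.integral.copy(),
            grid=idx.grid, year=idx.year)
        refl = fh.indices_to_reflectance(modified, nir_profile=np.full(31, 0.4))
        assert np.allclose(refl.swir, 0.48, atol=1e-12)

    def test_round_trip_to_indices(self, scene):
        recomputed = fh.compute_indices(scene["reflectance"])
        for name in ("ndvi", "evi", "gvmi"):
            assert np.allclose(getattr(recomputed, name),
                               getattr(scene["indices"], name), atol=1e-9)

    def test_degenerate_evi_errors(self, scene):
        idx = scene["indices"]
        broken = fh.IndexStack(
            ndvi=idx.ndvi.copy(), evi=np.zeros_like(idx.evi),
            gvmi=idx.gvmi.copy(), integral=idx.integral.copy(),
            grid=idx.grid, year=idx.year)
        with pytest.raises(DegenerateInputError):
            fh.indices_to_reflectance(broken)

    def test_nir_profile_bounds(self, scene):
        with pytest.raises(ValueError):
            fh.indices_to_reflectance(scene["indices"],
                                      nir_profile=np.full(31, 1.2))


class TestFires:
    def test_zero_ignitions_empty_list(self, scene):
        cfg = fh.SimulationConfig(
            rows=48, cols=48, years=(2008,), seed=11,
            fire_params=FireParams(expected_per_year=0.0))
        fires = fh.generate_fires(scene["latent"], scene["landcover"], cfg)
        assert fires == []

    def test_seeded_determinism(self, scene):
        a = fh.generate_fires(scene["latent"], scene["landcover"], scene["config"])
        b = fh.generate_fires(scene["latent"], scene["landcover"], scene["config"])
        assert [f.fire_id for f in a] == [f.fire_id for f in b]
        assert all(x.geometry.equals(y.geometry) for x, y in zip(a, b))
        assert [f.start_doy for f in a] == [f.start_doy for f in b]

    def test_fires_start_after_first_composite(self, fire_rich_scene):
        assert all(f.start_doy > int(fh.SEASON_DOYS[0])
                   for f in fire_rich_scene["fires"])

    def test_large_fires_occur_at_lower_fmc(self, fire_rich_scene):
        samples = fh.extract_fire_samples(fire_rich_scene["fires"],
                                          fire_rich_scene["stacks"])
        assert len(samples) >= 100
        medians = samples.groupby("size_class")["mean_fmc"].median()
        assert medians["large"] < medians["small"]


def test_double_round_trip_identity(scene):
    """bands -> indices -> FMC reproduces the latent truth within 1e-6."""
    indices = fh.compute_indices(scene["reflectance"])
    est = fh.estimate_fmc(indices, scene["landcover"])
    latent = scene["latent"].data
    valid = ~np.isnan(latent)
    assert np.max(np.abs(est.data[valid] - latent[valid])) < 1e-6


def test_simulate_scene_bundles_everything(small_config):
    out = fh.simulate_scene(small_config)
    assert set(out) == {"landcover", "latent", "indices", "reflectance", "fires"}
    assert list(out["latent"]) == list(small_config.years)
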