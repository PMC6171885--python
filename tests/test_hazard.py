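"""Percentile thresholds, hazard classification and evaluation tables."""

import numpy as np
import pandas as pd
import pytest

import fmc_hazard as fh
from fmc_hazard.grids import CHACO_FOREST, GRASSLAND, SHRUBLAND
from fmc_hazard.hazard import (
    CLASS_NAMES,
    EXTREME,
    HIGH,
    LOW,
    MODERATE,
    NODATA,
    HazardThresholds,
    classify,
    compare_external,
    derive_thresholds,
    evaluate_classification,
)
from fmc_hazard.mapping import ConfigurationError


def _pixels(values, cover=GRASSLAND):
    return pd.DataFrame({"cover": cover, "fmc": np.asarray(values, dtype=float)})


class TestDeriveThresholds:
    def test_exact_ranks_on_uniform_grid(self):
        thr = derive_thresholds(_pixels(np.arange(101)))
        assert thr.for_cover(GRASSLAND) == pytest.approx((60.0, 85.0, 97.0))

    def test_linear_interpolation_convention(self):
        # order statistic at rank 1 + (n-1) p: for 1..100 at p=0.6 -> 60.4
        thr = derive_thresholds(_pixels(np.arange(1, 101)))
        assert thr.for_cover(GRASSLAND)[0] == pytest.approx(60.4)

    def test_cover_below_sample_floor_omitted(self):
        df = pd.concat([_pixels(np.arange(101)), _pixels([50.0] * 5, SHRUBLAND)])
        thr = derive_thresholds(df)
        assert thr.for_cover(SHRUBLAND) is None
        assert thr.for_cover(GRASSLAND) is not None

    def test_percentile_ordering_enforced(self):
        with pytest.raises(ConfigurationError):
            derive_thresholds(_pixels(np.arange(101)), percentiles=(85, 60, 97))

    def test_threshold_ordering_invariant(self, rng):
        for _ in range(5):
            thr = derive_thresholds(_pixels(rng.gamma(6.0, 10.0, size=500)))
            te, th, tm = thr.for_cover(GRASSLAND)
            assert te <= th <= tm

    def test_provenance_records_sample_size(self):
        thr = derive_thresholds(_pixels(np.arange(101)))
        assert thr.provenance["n_samples"]["grassland"] == 101


class TestClassify:
    GRASS = HazardThresholds({GRASSLAND: (54.8, 66.7, 110.6)})

    @pytest.mark.parametrize("fmc,expected", [
        (50.0, EXTREME),       # below the extreme cut
        (54.8, EXTREME),       # boundary inclusive on the hazardous side
        (60.0, HIGH),
        (66.7, HIGH),
        (100.0, MODERATE),
        (110.6, MODERATE),
        (200.0, LOW),
    ])
    def test_class_bins(self, fmc, expected):
        assert classify(fmc, self.GRASS, GRASSLAND) == expected

    def test_missing_cover_threshold_gives_nodata(self):
        assert classify(80.0, self.GRASS, SHRUBLAND) == NODATA

    def test_nan_gives_nodata(self):
        assert classify(np.array([np.nan]), self.GRASS, GRASSLAND)[0] == NODATA

    def test_monotone_in_fmc(self, rng):
        values = np.sort(rng.uniform(0, 200, size=200))
        classes = classify(values, self.GRASS, GRASSLAND)
        # lower FMC never maps to a less hazardous class
        assert (np.diff(classes) <= 0).all()

    def test_stack_classification_uses_per_pixel_cover(self, scene):
        thr = HazardThresholds({GRASSLAND: (55, 67, 111),
                                SHRUBLAND: (106, 121, 133),
                                CHACO_FOREST: (72, 105, 125)})
        est = fh.estimate_fmc(scene["indices"], scene["landcover"])
        hazard_map = classify(est, thr)
        other = scene["landcover"].mask(fh.OTHER)
        assert (hazard_map[:, other] == NODATA).all()
        assert set(np.unique(hazard_map)) <= {NODATA, LOW, MODERATE, HIGH, EXTREME}


class TestEvaluate:
    def test_self_classification_identity(self, rng):
        """Thresholds derived from a sample classify it as ~60/25/12/3 %."""
        n = 4000
        df = _pixels(rng.gamma(7.0, 8.0, size=n))
        table = evaluate_classification(df, derive_thresholds(df))
        pct = dict(zip(table["hazard_class"], table["pct"]))
        tol = 100.0 / n
        assert pct["Extreme"] == pytest.approx(60.0, abs=tol)
        assert pct["High"] == pytest.approx(25.0, abs=tol)
        assert pct["Moderate"] == pytest.approx(12.0, abs=tol)
        assert pct["Low"] == pytest.approx(3.0, abs=tol)

    def test_all_samples_below_extreme(self):
        thr = HazardThresholds({GRASSLAND: (60.0, 77.0, 120.0)})
        table = evaluate_classification(_pixels([10.0] * 50), thr)
        pct = dict(zip(table["hazard_class"], table["pct"]))
        assert pct == {"Extreme": 100.0, "High": 0.0, "Moderate": 0.0, "Low": 0.0}

    def test_percentages_sum_to_100_with_cumulative(self, rng):
        df = _pixels(rng.uniform(0, 150, size=333))
        table = evaluate_classification(df, derive_thresholds(df))
        assert table["pct"].sum() == pytest.approx(100.0)
        assert table["pct_cum"].iloc[-1] == pytest.approx(100.0)

    def test_empty_sample_set(self):
        table = evaluate_classification(_pixels([]).iloc[0:0],
                                        HazardThresholds({GRASSLAND: (1, 2, 3)}))
        assert len(table) == 0


class TestCompareExternal:
    def test_uniform_sample_closed_form(self, rng):
        # uniform on [0, 100]: P(<=60) = 60 %, P(60-77] = 17 %
        df = _pixels(rng.uniform(0.0, 100.0, size=200_00))
        table = compare_external(df, (60.0, 77.0, 90.0))
        pct = dict(zip(table["hazard_class"], table["pct"]))
        assert pct["Extreme"] == pytest.approx(60.0, abs=1.5)
        assert pct["High"] == pytest.approx(17.0, abs=1.5)

    def test_all_above_every_cut(self):
        table = compare_external(_pixels([121.0, 130.0, 150.0]), (60, 77, 120))
        pct = dict(zip(table["hazard_class"], table["pct"]))
        assert pct == {"Extreme": 0.0, "High": 0.0, "Moderate": 0.0, "Low": 100.0}

    def test_missing_cut_is_configuration_error(self):
        with pytest.raises(ConfigurationError):
            compare_external(_pixels([50.0]), (60.0, 77.0, None))

    def test_identical_thresholds_identical_tables(self, rng):
        df = _pixels(rng.uniform(0, 150, size=500))
        thr = derive_thresholds(df)
        own = evaluate_classification(df, thr)
        ext = compare_external(df, thr.for_cover(GRASSLAND))
        pd.testing.assert_frame_equal(own, ext)


def test_parameter_recovery_quantiles(rng):
    """Derived thresholds converge to the sampling distribution's quantiles."""
    n = 10_000
    mu, sd = 70.0, 15.0
    df = _pixels(rng.normal(mu, sd, size=n))
    thr = derive_thresholds(df)
    from scipy import stats
    for cut, p in zip(thr.for_cover(GRASSLAND), (0.60, 0.85, 0.97)):
        true_q = stats.norm.ppf(p, mu, sd)
        # asymptotic SE of the sample quantile: sqrt(p(1-p)/n) / f(q)
        se = np.sqrt(p * (1 - p) / n) * sd / stats.norm.pdf(stats.norm.ppf(p))
        assert abs(cut - true_q) < 2 * se


def test_thresholds_serialization_round_trip(tmp_path):
    thr = HazardThresholds({GRASSLAND: (55.0, 67.0, 110.6)},
                           provenance={"percentiles": (60.0, 85.0, 97.0)})
    from fmc_hazard import io as fio
    path = tmp_path / "thr.yaml"
    fio.write_thresholds(path, thr)
    back = fio.read_thresholds(path)
    assert back.for_cover(GRASSLAND) == pytest.approx(thr.for_cover(GRASSLAND))
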