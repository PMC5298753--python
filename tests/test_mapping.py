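"""Prediction rasters, zonal aggregation and the grazing-gradient checks."""

import numpy as np
import pytest
from shapely.geometry import box

from grasslidar import grazing_tables as gt
from grasslidar.calibration import RegressionModel
from grasslidar.mapping import (PredictionRaster, ZoneSummary,
                                aggregate_zones, metric_rasters,
                                monotonicity_report, predict_map,
                                rate_level_means, table_rate_aggregation)
from grasslidar.metrics import MetricWindow, fvc, mean_ch
from grasslidar.pointcloud import ClassLabel, PointCloud
from grasslidar.synthetic import ZoneSpec
from grasslidar.terrain import CHM_NULL, CanopyHeightModel, rasterize_chm


def _uniform_cloud(side=10.0, rel=10.0, spacing=0.25):
    xs = np.arange(spacing / 2, side, spacing)
    gx, gy = np.meshgrid(xs, xs)
    x, y = gx.ravel(), gy.ravel()
    n = x.size
    return PointCloud(x=x, y=y, z=np.zeros(n),
                      classification=np.full(n, ClassLabel.VEGETATION),
                      rel_height_cm=np.full(n, rel))


class TestMetricRasters:
    def test_uniform_canopy_gives_constant_raster(self):
        cloud = _uniform_cloud(rel=10.0)
        chm = rasterize_chm(cloud, origin=(0, 0), extent=(10, 10))
        r = metric_rasters(chm, cloud)
        np.testing.assert_allclose(r["mean_ch_cm"].values, 10.0)
        np.testing.assert_allclose(r["fvc"].values, 1.0)

    def test_bare_strip_nodata_meanch_zero_fvc(self):
        cloud = _uniform_cloud(rel=10.0)
        bare = cloud.x > 5.0
        cloud.rel_height_cm[bare] = 0.0
        cloud.classification[bare] = ClassLabel.GROUND
        chm = rasterize_chm(cloud, origin=(0, 0), extent=(10, 10))
        r = metric_rasters(chm, cloud)
        assert np.all(np.isnan(r["mean_ch_cm"].values[:, 6:]))
        np.testing.assert_allclose(r["fvc"].values[:, 6:], 0.0)

    def test_cell_equals_quadrat_metrics_at_cell_center(self, survey):
        """Any 1 m map cell reproduces the windowed quadrat metrics."""
        chm, norm = survey["chm"], survey["norm"]
        r = metric_rasters(chm, norm, extent=survey["scene"].spec.extent)
        rng = np.random.default_rng(3)
        ny, nx = r["mean_ch_cm"].values.shape
        for _ in range(20):
            i, j = rng.integers(0, ny), rng.integers(0, nx)
            w = MetricWindow(j + 0.5, i + 0.5, 1.0)
            got = r["mean_ch_cm"].values[i, j]
            expect = mean_ch(chm, w)
            if np.isnan(expect):
                assert np.isnan(got)
            else:
                assert got == pytest.approx(expect, abs=1e-9)
            got_f = r["fvc"].values[i, j]
            expect_f = fvc(norm, w)
            if np.isnan(expect_f):
                assert np.isnan(got_f)
            else:
                assert got_f == pytest.approx(expect_f, abs=1e-9)


class TestPredictMap:
    def _raster(self, values):
        return PredictionRaster("mean_ch_cm", (0, 0), 1.0,
                                np.asarray(values, float))

    def _linear(self):
        return RegressionModel(family="linear",
                               coefficients=(gt.BIOMASS_MODEL_SLOPE,
                                             gt.BIOMASS_MODEL_INTERCEPT),
                               r_squared=0.34)

    def test_intercept_at_zero_height(self):
        out = predict_map(self._raster([[0.0]]), self._linear(), "biomass")
        assert out.values[0, 0] == pytest.approx(7.081)

    def test_nodata_propagates(self):
        out = predict_map(self._raster([[np.nan, 1.0]]), self._linear(),
                          "biomass")
        assert np.isnan(out.values[0, 0])
        assert np.isfinite(out.values[0, 1])

    def test_negative_predictions_clamped_and_counted(self):
        model = RegressionModel(family="linear", coefficients=(1.0, -5.0),
                                r_squared=1.0)
        out = predict_map(self._raster([[0.0, 10.0]]), model, "biomass")
        assert out.values[0, 0] == 0.0
        assert out.n_clamped == 1

    def test_matches_scalar_application_loop(self, rng):
        vals = rng.uniform(0, 12, (6, 7))
        model = self._linear()
        out = predict_map(self._raster(vals), model, "biomass")
        for i in range(6):
            for j in range(7):
                assert out.values[i, j] == pytest.approx(
                    max(0.0, 34.785 * vals[i, j] + 7.081), abs=1e-9)


class TestZoneAggregation:
    def test_single_zone_mean_equals_raster_mean(self, rng):
        vals = rng.uniform(0, 10, (10, 10))
        r = PredictionRaster("v", (0, 0), 1.0, vals)
        z = ZoneSpec(polygon=box(0, 0, 10, 10), rate=0)
        s = aggregate_zones(r, [z])[0]
        assert s.mean == pytest.approx(vals.mean())
        assert s.n_pixels == 100

    def test_partition_recombines_to_global_mean(self, rng):
        vals = rng.uniform(0, 10, (10, 12))
        r = PredictionRaster("v", (0, 0), 1.0, vals)
        zones = [ZoneSpec(polygon=box(0, 0, 5, 10), rate=0),
                 ZoneSpec(polygon=box(5, 0, 12, 10), rate=1)]
        ss = aggregate_zones(r, zones)
        pooled = sum(s.mean * s.n_pixels for s in ss) / \
            sum(s.n_pixels for s in ss)
        assert pooled == pytest.approx(vals.mean())

    def test_empty_zone_flagged(self):
        r = PredictionRaster("v", (0, 0), 1.0, np.full((5, 5), np.nan))
        z = ZoneSpec(polygon=box(0, 0, 5, 5), rate=0)
        s = aggregate_zones(r, [z])[0]
        assert s.flags == "no_valid_pixels"

    def test_rate_zero_pooling_reproduces_published_mean(self):
        """38.0 / 30.4 / 32.7 cm replicates pool to the printed 33.7 cm."""
        ss = [ZoneSummary("W0", 0, 38.0, 100),
              ZoneSummary("M0", 0, 30.4, 100),
              ZoneSummary("E0", 0, 32.7, 100)]
        g = rate_level_means(ss)
        assert g.loc[g["rate"] == 0, "mean"].iloc[0] == pytest.approx(33.7,
                                                                      abs=0.05)
        pp = rate_level_means(ss, pooling="pixel-pooled")
        assert pp["mean"].iloc[0] == pytest.approx(33.7, abs=0.05)


class TestMonotonicity:
    def test_strictly_decreasing_passes(self):
        rep = monotonicity_report([10.0, 8.0, 6.0, 4.0, 2.0, 1.0])
        assert rep["non_increasing"] and rep["violations_at_rate"] == []

    def test_published_biomass_gradient_flags_rate_three(self):
        rep = monotonicity_report(gt.BIOMASS_RATE_PRINTED)
        assert not rep["non_increasing"]
        assert rep["violations_at_rate"] == [3]

    def test_violation_count_matches_enumeration(self, rng):
        v = rng.uniform(0, 10, 6)
        rep = monotonicity_report(v)
        expect = [i + 1 for i in range(5) if v[i + 1] > v[i]]
        assert rep["violations_at_rate"] == expect


class TestRateRankRecovery:
    def test_predicted_rate_biomass_ranks_match_truth(self, survey):
        """Default pipeline keeps the six stocking-rate biomass ranks."""
        from scipy.stats import spearmanr

        from grasslidar import pipeline as pl
        suite = pl.calibrate_suite(survey["table"], seed=0)
        maps = pl.build_maps(survey["chm"], survey["norm"], suite,
                             extent=survey["scene"].spec.extent)
        ev = pl.evaluate_zones(maps, survey["scene"].spec.zones,
                               survey["scene"])
        pred = ev["rates"]["pred_biomass"].sort_values("rate")["mean"]
        truth = ev["truth_rates"]["biomass"]
        assert spearmanr(pred, truth).statistic == pytest.approx(1.0)
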