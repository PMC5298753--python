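"""Ground surface model, normalization and CHM rasterization."""

import numpy as np
import pytest
from scipy.spatial import Delaunay

from grasslidar.pointcloud import ClassLabel, PointCloud
from grasslidar.synthetic import FlightConfig, generate_scene, simulate_flight, single_zone_spec
from grasslidar.terrain import (CHM_NULL, GroundSurfaceModel,
                                build_ground_model, normalize_heights,
                                rasterize_chm)


def _bary_oracle(points, z, queries):
    """Independent barycentric evaluation: per-triangle linear solve."""
    tri = Delaunay(points)
    out = np.full(queries.shape[0], np.nan)
    for qi, q in enumerate(queries):
        for simplex in tri.simplices:
            p = points[simplex]
            A = np.vstack([p.T, np.ones(3)])
            lam = np.linalg.solve(A, np.r_[q, 1.0])
            if np.all(lam >= -1e-10):
                out[qi] = lam @ z[simplex]
                break
    return out


class TestGroundSurfaceModel:
    def test_planar_interpolation(self):
        x = np.array([0.0, 2.0, 0.0, 2.0])
        y = np.array([0.0, 0.0, 2.0, 2.0])
        gsm = GroundSurfaceModel(x, y, 0.5 * x)
        assert gsm.elevation(1.0, 0.0)[0] == pytest.approx(0.5)

    def test_exact_at_data_points(self, rng):
        x, y = rng.uniform(0, 10, (2, 40))
        z = rng.uniform(99, 101, 40)
        gsm = GroundSurfaceModel(x, y, z)
        got = gsm.elevation(gsm.points[:, 0], gsm.points[:, 1])
        np.testing.assert_allclose(got, gsm.z, atol=1e-9)

    def test_matches_bruteforce_barycentric(self, rng):
        pts = rng.uniform(0, 20, (200, 2))
        z = 670 + 0.02 * pts[:, 0] + rng.normal(0, 0.05, 200)
        gsm = GroundSurfaceModel(pts[:, 0], pts[:, 1], z)
        q = rng.uniform(2, 18, (50, 2))
        expect = _bary_oracle(gsm.points, gsm.z, q)
        got = gsm.elevation(q[:, 0], q[:, 1])
        ok = np.isfinite(expect)  # oracle covers interior queries
        assert ok.sum() >= 40
        np.testing.assert_allclose(got[ok], expect[ok], atol=1e-9)

    def test_outside_hull_flagged_extrapolated(self):
        gsm = GroundSurfaceModel([0, 1, 0, 1], [0, 0, 1, 1], [5, 5, 5, 5.0])
        z, extra = gsm.elevation([0.5, 10.0], [0.5, 10.0],
                                 return_extrapolated=True)
        assert not extra[0] and extra[1]
        assert z[1] == pytest.approx(5.0)

    def test_degenerate_geometry_fails(self):
        with pytest.raises(ValueError):
            GroundSurfaceModel([0, 1, 2], [0, 0, 0], [1, 1, 1.0])


class TestNormalize:
    def _flat_gsm(self, z0=100.0):
        return GroundSurfaceModel([-50, 50, -50, 50], [-50, -50, 50, 50],
                                  [z0] * 4)

    def test_vegetation_height_is_subtraction_in_cm(self):
        cloud = PointCloud(x=[0.0], y=[0.0], z=[100.30],
                           classification=[ClassLabel.VEGETATION])
        out = normalize_heights(cloud, self._flat_gsm())
        assert out.rel_height_cm[0] == pytest.approx(30.0)

    def test_ground_returns_are_zero(self):
        cloud = PointCloud(x=[1.0], y=[1.0], z=[100.07],
                           classification=[ClassLabel.GROUND])
        out = normalize_heights(cloud, self._flat_gsm())
        assert out.rel_height_cm[0] == 0.0

    def test_outside_domain_flagged_and_nan(self):
        cloud = PointCloud(x=[500.0], y=[500.0], z=[101.0],
                           classification=[ClassLabel.VEGETATION])
        out = normalize_heights(cloud, self._flat_gsm())
        assert out.outside_gsm[0]
        assert np.isnan(out.rel_height_cm[0])

    def test_simulator_roundtrip_noise_free(self):
        """With noise off and truth classes, relative heights equal the
        simulator's true echo heights to 1e-6 cm (planar terrain)."""
        scene = generate_scene(single_zone_spec(20.0, 0.6, extent=(10, 10),
                                                seed=13))
        scene.terrain.amp = 0.0  # pure plane: TIN interpolation is exact
        cloud = simulate_flight(scene, FlightConfig(seed=14, noise_sd_cm=0.0))
        cloud.classification = np.where(cloud.intercepted,
                                        ClassLabel.VEGETATION,
                                        ClassLabel.GROUND).astype(np.uint8)
        gsm = build_ground_model(cloud)
        out = normalize_heights(cloud, gsm)
        veg = (cloud.classification == ClassLabel.VEGETATION) & ~out.outside_gsm
        np.testing.assert_allclose(out.rel_height_cm[veg],
                                   cloud.true_rel_h_cm[veg], atol=1e-6)


class TestRasterizeCHM:
    def _cloud(self, xs, ys, rels):
        n = len(xs)
        return PointCloud(x=xs, y=ys, z=np.zeros(n),
                          classification=np.full(n, ClassLabel.VEGETATION),
                          rel_height_cm=np.asarray(rels, float))

    def test_cell_max_rule(self):
        cloud = self._cloud([0.05, 0.15], [0.05, 0.1], [3.0, 7.0])
        chm = rasterize_chm(cloud, origin=(0.0, 0.0), extent=(0.2, 0.2))
        assert chm.values[0, 0] == pytest.approx(7.0)

    def test_empty_cell_gets_null_marker(self):
        cloud = self._cloud([0.05], [0.05], [3.0])
        chm = rasterize_chm(cloud, origin=(0.0, 0.0), extent=(1.0, 1.0))
        assert chm.values[0, 0] == 3.0
        assert np.sum(chm.values == CHM_NULL) == 24

    def test_matches_bruteforce_binning(self, rng):
        n = 2000
        x, y = rng.uniform(0, 10, (2, n))
        rel = rng.uniform(0, 40, n)
        cloud = self._cloud(x, y, rel)
        chm = rasterize_chm(cloud, origin=(0.0, 0.0), extent=(10.0, 10.0))
        ny, nx = chm.shape
        expect = np.full((ny, nx), CHM_NULL)
        for xi, yi, ri in zip(x, y, rel):
            i, j = int(np.floor(yi / 0.2)), int(np.floor(xi / 0.2))
            expect[i, j] = max(expect[i, j], ri)
        np.testing.assert_allclose(chm.values, expect, atol=1e-12)

    def test_shape_no_forbidden_values_and_conservation(self, rng):
        n = 500
        cloud = self._cloud(rng.uniform(0, 4.9, n), rng.uniform(0, 3.3, n),
                            rng.uniform(-1, 30, n))
        chm = rasterize_chm(cloud, origin=(0.0, 0.0), extent=(4.9, 3.3))
        assert chm.shape == (int(np.ceil(3.3 / 0.2)), int(np.ceil(4.9 / 0.2)))
        v = chm.values
        assert not np.any((v > CHM_NULL) & (v < 0))
        assert chm.counts.sum() == n

    def test_permutation_invariant(self, rng):
        n = 300
        x, y = rng.uniform(0, 5, (2, n))
        rel = rng.uniform(0, 20, n)
        perm = rng.permutation(n)
        a = rasterize_chm(self._cloud(x, y, rel), origin=(0, 0),
                          extent=(5, 5))
        b = rasterize_chm(self._cloud(x[perm], y[perm], rel[perm]),
                          origin=(0, 0), extent=(5, 5))
        np.testing.assert_array_equal(a.values, b.values)

    def test_bad_cell_size_fails(self):
        cloud = self._cloud([0.1], [0.1], [1.0])
        with pytest.raises(ValueError):
            rasterize_chm(cloud, cell_size=0.0)

    def test_unnormalized_cloud_fails(self):
        cloud = PointCloud(x=[0.1, 0.2, 0.3], y=[0.1, 0.2, 0.3],
                           z=[1, 1, 1.0])
        with pytest.raises(ValueError, match="normalized"):
            rasterize_chm(cloud)
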