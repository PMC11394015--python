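import numpy as np
import pytest

from azstorm.nanocluster import (CalibrationError, average_h_and_max,
                                 calibrate_sc_params, ripley_h, ripley_k,
                                 subcluster)
from azstorm.segmentation import ClusteringParams


def brute_force_k(points, r_grid, area):
    n = len(points)
    k = np.zeros(len(r_grid))
    for idx, r in enumerate(r_grid):
        count = 0
        for i in range(n):
            for j in range(n):
                if i != j and np.hypot(*(points[i] - points[j])) <= r:
                    count += 1
        k[idx] = area * count / (n * (n - 1))
    return k


def sc_blob_az(rng, centers, n_per=30, radius=12.0):
    pts = []
    for cx, cy in centers:
        rr = radius * np.sqrt(rng.uniform(size=n_per))
        tt = rng.uniform(0, 2 * np.pi, n_per)
        pts.append(np.c_[cx + rr * np.cos(tt), cy + rr * np.sin(tt)])
    return np.vstack(pts)


class TestRipley:
    def test_two_points_by_hand(self):
        # K(20) = A * 2 / (2*1) = A for two points 10 nm apart
        pts = np.array([[0.0, 0.0], [10.0, 0.0]])
        k = ripley_k(pts, [20.0], 1e4)
        assert k[0] == pytest.approx(1e4)

    def test_matches_brute_force_oracle(self, rng):
        r_grid = np.arange(0.0, 151.0, 10.0)
        for _ in range(5):
            n = rng.integers(5, 60)
            pts = rng.uniform(0, 300, size=(n, 2))
            vec = ripley_k(pts, r_grid, 9e4)
            assert np.array_equal(vec, brute_force_k(pts, r_grid, 9e4))

    def test_k_monotone_and_h_zero_at_origin(self, rng):
        pts = rng.uniform(0, 200, size=(40, 2))
        curve = ripley_h(pts, np.arange(0.0, 151.0), 4e4)
        assert np.all(np.diff(curve.k) >= 0)
        assert curve.h[0] == 0.0

    def test_poisson_null_flat(self, rng):
        # fixed-n uniform patterns with torus distances: E[K] = pi r^2
        big_l = 1500.0
        r_grid = np.arange(0.0, 151.0, 5.0)
        hs = []
        for _ in range(50):
            pts = rng.uniform(0, big_l, size=(500, 2))
            k = ripley_k(pts, r_grid, big_l**2, periodic=big_l)
            hs.append(np.sqrt(k / np.pi) - r_grid)
        hs = np.array(hs)
        ravg = hs[:, 1:].mean(axis=1)
        se = ravg.std(ddof=1) / np.sqrt(len(ravg))
        assert abs(ravg.mean()) <= 2 * se + 1e-12
        assert np.abs(hs.mean(0)).max() < 1.5

    def test_fewer_than_two_points_rejected(self):
        with pytest.raises(ValueError):
            ripley_h(np.array([[0.0, 0.0]]), np.arange(5.0), 100.0)


class TestAverageH:
    def _curve(self, r, h):
        l = h + r
        from azstorm.nanocluster import HCurve
        return HCurve(r=r, k=np.pi * l**2, n_points=10, area=1e4)

    def test_single_curve_is_its_own_argmax(self, rng):
        pts = sc_blob_az(rng, [(0.0, 0.0)], n_per=50, radius=25.0)
        curve = ripley_h(pts, np.arange(0.0, 151.0), np.pi * 25**2)
        mean_c, hmax = average_h_and_max([curve])
        assert hmax == curve.h_max_radius
        assert np.allclose(mean_c.h, curve.h)

    def test_mirrored_curves_tie_break_to_grid_start(self):
        r = np.arange(0.0, 11.0)
        up = self._curve(r, np.linspace(0, 10, len(r)))
        down = self._curve(r, -np.linspace(0, 10, len(r)))
        mean_c, hmax = average_h_and_max([up, down])
        assert np.allclose(mean_c.h, 0.0, atol=1e-9)
        assert hmax == r[0]

    def test_mismatched_grids_rejected(self):
        r1, r2 = np.arange(0.0, 11.0), np.arange(0.0, 21.0)
        with pytest.raises(ValueError):
            average_h_and_max([self._curve(r1, r1 * 0), self._curve(r2, r2 * 0)])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            average_h_and_max([])


class TestSubcluster:
    def test_two_tight_blobs_found(self, rng):
        az = sc_blob_az(rng, [(0.0, 0.0), (120.0, 0.0)], n_per=30)
        res = subcluster(az, ClusteringParams(15, 3))
        assert res.sc_count == 2

    def test_radius_area_self_consistency(self, rng):
        az = sc_blob_az(rng, [(0.0, 0.0), (150.0, 0.0), (0.0, 150.0)], n_per=40)
        res = subcluster(az, ClusteringParams(15, 3))
        for _, row in res.table.iterrows():
            assert np.pi * row["radius_nm"] ** 2 == pytest.approx(
                row["area_nm2"], rel=1e-12)

    def test_empty_az_yields_no_subclusters(self):
        res = subcluster(np.zeros((0, 2)), ClusteringParams(15, 3))
        assert res.sc_count == 0 and len(res.table) == 0

    def test_small_az_yields_no_subclusters(self, rng):
        az = sc_blob_az(rng, [(0.0, 0.0)], n_per=5)
        res = subcluster(az, ClusteringParams(15, 3))
        assert res.sc_count == 0


class TestCalibration:
    def test_brute_force_subgrid_oracle(self, rng):
        azs = [sc_blob_az(rng, [(0.0, 0.0), (130.0, 10.0), (30.0, 140.0)],
                          n_per=35, radius=20.0) for _ in range(4)]
        grid = [(mcs, ms) for mcs in (10, 15, 20, 25, 30)
                for ms in (2, 4, 6, 8, 10)]
        params, achieved, table = calibrate_sc_params(azs, 20.0, grid=grid)
        # independent exhaustive search over the same subgrid
        best = None
        for mcs, ms in grid:
            radii = []
            for az in azs:
                radii.extend(subcluster(az, ClusteringParams(mcs, ms))
                             .table["radius_nm"])
            if radii:
                err = abs(float(np.median(radii)) - 20.0)
                key = (err, mcs, ms)
                if best is None or key < best:
                    best = key
        assert (params.min_cluster_size, params.min_samples) == best[1:]
        assert abs(achieved - 20.0) == pytest.approx(best[0], abs=1e-9)

    def test_single_sc_azs_still_calibrate(self, rng):
        azs = [sc_blob_az(rng, [(0.0, 0.0)], n_per=40, radius=18.0)
               for _ in range(3)]
        params, achieved, _ = calibrate_sc_params(
            azs, 18.0, grid=[(10, 2), (20, 5), (30, 10)])
        assert achieved > 0

    def test_no_subclusters_anywhere_raises(self, rng):
        azs = [rng.uniform(0, 1000, size=(8, 2))]
        with pytest.raises(CalibrationError):
            calibrate_sc_params(azs, 25.0, grid=[(50, 25)])

    def test_invalid_target_rejected(self, rng):
        with pytest.raises(ValueError):
            calibrate_sc_params([rng.uniform(0, 100, (30, 2))], -5.0)
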