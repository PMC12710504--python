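import numpy as np
import pytest

from budpose3d.localize3d import (
    AllInvalidDepthError,
    CameraIntrinsics,
    DepthSampleSequence,
    Point3D,
    collect_depth_samples,
    deproject_pixel,
    fuse_depth,
    localize_track,
    project_point,
)
from budpose3d.tracking import KeypointTrack, gate_track


def seq(samples):
    return DepthSampleSequence(samples=list(samples), frame_ids=list(range(len(samples))))


def adaptive_oracle(samples, T=0.01):
    """Independent brute-force restatement of the adaptive fusion rule."""
    valid = [d for d in samples if d > 0]
    if not valid:
        return None
    mu = sum(valid) / len(valid)
    sigma = (sum((d - mu) ** 2 for d in valid) / len(valid)) ** 0.5
    if sigma <= T:
        return mu, "adaptive->mean"
    ordered = sorted(valid)
    m = len(ordered)
    med = ordered[m // 2] if m % 2 else (ordered[m // 2 - 1] + ordered[m // 2]) / 2
    return med, "adaptive->median"


class TestFuseDepth:
    def test_identical_samples_take_mean_branch(self):
        f = fuse_depth(seq([0.5, 0.5, 0.5]))
        assert f.d_hat == pytest.approx(0.5, abs=1e-12)
        assert f.sigma == 0.0 and f.strategy == "adaptive->mean"

    def test_stable_sequence_mean(self):
        f = fuse_depth(seq([0.50, 0.51, 0.52]))
        assert f.sigma == pytest.approx(0.008164965809, abs=1e-9)
        assert f.d_hat == pytest.approx(0.51, abs=1e-12)
        assert f.strategy == "adaptive->mean"

    def test_outlier_sequence_median(self):
        f = fuse_depth(seq([0.50, 0.52, 1.50]))
        assert f.sigma > 0.01
        assert f.d_hat == pytest.approx(0.52, abs=1e-12)
        assert f.strategy == "adaptive->median"

    def test_holes_excluded_from_valid_set(self):
        f = fuse_depth(seq([0.5, 0.0, 0.5]))
        assert f.M == 2 and f.d_hat == pytest.approx(0.5, abs=1e-12)
        assert f.strategy == "adaptive->mean"

    def test_single_strategy_returns_first_valid(self):
        f = fuse_depth(seq([0.0, 0.7, 0.9]), strategy="single")
        assert f.d_hat == 0.7 and f.strategy == "single"

    def test_even_count_median_averages_central_pair(self):
        f = fuse_depth(seq([0.1, 0.2, 0.9, 1.0]), strategy="median")
        assert f.d_hat == pytest.approx(0.55, abs=1e-12)

    def test_all_holes_raise(self):
        with pytest.raises(AllInvalidDepthError):
            fuse_depth(seq([0.0, 0.0, 0.0]))

    def test_boundary_sigma_takes_mean_branch(self):
        # binary-exact spacing: population sigma equals T exactly
        d = 2.0**-7
        f = fuse_depth(seq([0.5, 0.5 + 2 * d]), T=d)
        assert f.sigma == d
        assert f.strategy == "adaptive->mean"

    def test_unknown_strategy_rejected(self):
        with pytest.raises(ValueError, match="strategy"):
            fuse_depth(seq([0.5]), strategy="mode")

    def test_adaptive_agrees_with_bruteforce_oracle(self):
        """1,000 seeded random sequences (lengths 1-10, holes, mixed
        magnitudes) match the brute-force rule exactly."""
        rng = np.random.default_rng(2024)
        for _ in range(1000):
            n = int(rng.integers(1, 11))
            samples = rng.uniform(0.05, 3.0, size=n)
            samples[rng.random(n) < 0.25] = 0.0
            expected = adaptive_oracle(samples.tolist())
            if expected is None:
                with pytest.raises(AllInvalidDepthError):
                    fuse_depth(seq(samples))
                continue
            f = fuse_depth(seq(samples))
            assert f.d_hat == pytest.approx(expected[0], abs=1e-12)
            assert f.strategy == expected[1]

    def test_permutation_invariance(self, rng):
        samples = rng.uniform(0.1, 2.0, size=7)
        base = fuse_depth(seq(samples))
        for _ in range(10):
            f = fuse_depth(seq(rng.permutation(samples)))
            assert f.d_hat == pytest.approx(base.d_hat, abs=1e-12)
            assert f.strategy == base.strategy

    def test_depth_scale_equivariance(self, rng):
        samples = rng.uniform(0.1, 2.0, size=6)
        for c in (0.5, 3.0, 10.0):
            a = fuse_depth(seq(samples), T=0.01)
            b = fuse_depth(seq(samples * c), T=0.01 * c)
            assert b.d_hat == pytest.approx(a.d_hat * c, rel=1e-12)
            assert b.strategy == a.strategy


class TestGeometry:
    def test_principal_point_maps_to_optical_axis(self, K):
        p = deproject_pixel(K, K.cx, K.cy, 0.8)
        assert (p.X, p.Y, p.Z) == pytest.approx((0.0, 0.0, 0.8))

    def test_deproject_worked_example(self, K):
        p = deproject_pixel(K, 620, 240, 0.5)
        assert (p.X, p.Y, p.Z) == pytest.approx((0.25, 0.0, 0.5), abs=1e-12)

    def test_project_worked_example(self, K):
        assert project_point(K, Point3D(0.25, 0.0, 0.5)) == pytest.approx((620.0, 240.0))
        assert project_point(K, Point3D(0.0, 0.0, 1.0)) == (K.cx, K.cy)

    def test_roundtrips_over_random_points(self, K, rng):
        us = rng.uniform(0, K.width, 10_000)
        vs = rng.uniform(0, K.height, 10_000)
        ds = rng.uniform(0.05, 5.0, 10_000)
        for u, v, d in zip(us[:200], vs[:200], ds[:200]):
            p = deproject_pixel(K, u, v, d)
            u2, v2 = project_point(K, p)
            assert abs(u2 - u) < 1e-9 and abs(v2 - v) < 1e-9
            p2 = deproject_pixel(K, u2, v2, p.Z)
            assert abs(p2.X - p.X) < 1e-12 and abs(p2.Y - p.Y) < 1e-12

    def test_deprojection_linear_in_depth(self, K):
        p1 = deproject_pixel(K, 100, 50, 0.4)
        p2 = deproject_pixel(K, 100, 50, 0.8)
        assert (p2.X, p2.Y, p2.Z) == pytest.approx((2 * p1.X, 2 * p1.Y, 2 * p1.Z))

    def test_nonpositive_depth_rejected(self, K):
        with pytest.raises(ValueError, match="depth"):
            deproject_pixel(K, 100, 100, 0.0)
        with pytest.raises(ValueError, match="behind"):
            project_point(K, Point3D(0, 0, -1.0))

    def test_bad_intrinsics_rejected(self):
        with pytest.raises(ValueError, match="focal"):
            CameraIntrinsics(fx=-1, fy=600, cx=320, cy=240, width=640, height=480)
        with pytest.raises(ValueError, match="principal"):
            CameraIntrinsics(fx=600, fy=600, cx=700, cy=240, width=640, height=480)


class TestCollectAndLocalize:
    def test_collect_reads_kept_frames_only(self):
        track = KeypointTrack([(0, 10, 10), (1, 50, 50), (2, 11, 10)])
        gated = gate_track(track, epsilon=3)  # frames 1 and 2 both jump > 3
        maps = {0: np.full((64, 64), 0.8), 1: np.full((64, 64), 0.9),
                2: np.full((64, 64), 1.0)}
        s = collect_depth_samples(maps, gated)
        assert s.frame_ids == [0]
        assert s.samples == [0.8]

    def test_hole_recorded_but_excluded_from_M(self):
        gated = gate_track(KeypointTrack([(0, 5, 5), (1, 5, 5)]), epsilon=3)
        hole_map = np.full((32, 32), 0.7)
        hole_map[5, 5] = 0.0
        s = collect_depth_samples({0: np.full((32, 32), 0.7), 1: hole_map}, gated)
        assert s.samples == [0.7, 0.0]
        assert s.M == 1

    def test_out_of_bounds_pixel_warns_and_skips(self):
        gated = gate_track(KeypointTrack([(0, 100, 100)]), epsilon=3)
        with pytest.warns(UserWarning, match="outside"):
            s = collect_depth_samples({0: np.full((32, 32), 0.7)}, gated)
        assert s.samples == []

    def test_noiseless_pipeline_recovers_ground_truth(self, K):
        truth = Point3D(0.05, -0.02, 0.9)
        u, v = project_point(K, truth)
        track = KeypointTrack([(i, u, v) for i in range(5)], window=5)
        depth = np.zeros((K.height, K.width))
        depth[int(round(v)), int(round(u))] = truth.Z
        res = localize_track({i: depth for i in range(5)}, track, K)
        assert res.localized
        assert abs(res.point.X - truth.X) < 1e-6
        assert abs(res.point.Y - truth.Y) < 1e-6
        assert abs(res.point.Z - truth.Z) < 1e-6
        assert res.point_mm == pytest.approx((50.0, -20.0, 900.0), abs=1e-3)

    def test_outlier_frame_defeated_by_adaptive_median(self, K):
        u, v = 300.0, 200.0
        track = KeypointTrack([(i, u, v) for i in range(5)], window=5)
        maps = {i: np.full((K.height, K.width), 0.5) for i in range(5)}
        maps[2] = np.full((K.height, K.width), 5.0)  # background bleed-through
        res = localize_track(maps, track, K)
        assert res.fused.strategy == "adaptive->median"
        truth = deproject_pixel(K, u, v, 0.5)
        err_mm = np.linalg.norm(np.subtract(res.point_mm, truth.to_mm()))
        assert err_mm < 1.0

    def test_all_hole_window_is_unlocalized(self, K):
        track = KeypointTrack([(i, 50, 50) for i in range(3)])
        res = localize_track({i: np.zeros((K.height, K.width)) for i in range(3)},
                             track, K)
        assert not res.localized and res.point is None
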