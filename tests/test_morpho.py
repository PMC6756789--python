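"""Morphometrics: lengths, straightness, angles, colocalization, particles."""

import numpy as np
import pytest

from doubletmech import (
    JunctionTrace,
    RoiImagePair,
    analyze_particles,
    angular_deviation,
    intensity_profile,
    junction_intensity_ratio,
    junction_length,
    make_coloc_pair,
    make_junction_series,
    pearson_roi,
    straightness,
)


class TestLengthAndStraightness:
    def test_two_point_segment(self):
        assert junction_length([(0, 0), (10, 0)]) == 10.0

    def test_three_unit_sides(self):
        poly = [(0, 0), (1, 0), (1, 1), (0, 1)]
        assert junction_length(poly) == pytest.approx(3.0)

    def test_random_polyline_matches_pairwise_sum(self, rng):
        pts = rng.normal(size=(50, 2)) * 10
        expected = sum(
            float(np.hypot(*(pts[i + 1] - pts[i]))) for i in range(49)
        )
        assert junction_length(pts) == pytest.approx(expected, abs=1e-12)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            junction_length([(0, 0)])

    def test_straight_segment_is_one(self):
        assert straightness([(0, 0), (5, 5), (10, 10)]) == pytest.approx(1.0)

    def test_semicircle_is_two_over_pi(self):
        t = np.linspace(0, np.pi, 1001)
        poly = np.stack([np.cos(t), np.sin(t)], axis=1)
        assert straightness(poly) == pytest.approx(2 / np.pi, abs=1e-3)

    def test_closed_loop_warns_and_returns_zero(self):
        square = [(0, 0), (1, 0), (1, 1), (0, 1), (0, 0)]
        with pytest.warns(UserWarning, match="closed"):
            assert straightness(square) == 0.0

    def test_invariant_under_similarity_transform(self, rng):
        pts = rng.normal(size=(20, 2))
        s0 = straightness(pts)
        phi = 0.7
        R = np.array([[np.cos(phi), -np.sin(phi)],
                      [np.sin(phi), np.cos(phi)]])
        transformed = 3.7 * (pts @ R.T) + np.array([11.0, -4.0])
        assert straightness(transformed) == pytest.approx(s0, rel=1e-12)

    def test_generator_waviness_matches_brute_force(self):
        poly = make_junction_series(30.0, 1.5, 0.0, 1, seed=2)[0]
        acc = np.linalg.norm(np.diff(poly, axis=0), axis=1).sum()
        chord = np.linalg.norm(poly[-1] - poly[0])
        assert straightness(poly) == pytest.approx(chord / acc, abs=1e-12)
        assert straightness(poly) < 1.0


class TestAngularDeviation:
    def _trace(self, frames, dt=10.0):
        return JunctionTrace([(i * dt, poly) for i, poly in enumerate(frames)])

    def test_rigid_series_zero(self):
        frames = make_junction_series(30.0, 0.5, 0.0, 6, seed=1)
        assert angular_deviation(self._trace(frames), 60.0) == pytest.approx(
            0.0, abs=1e-9)

    def test_constant_drift_mean(self):
        frames = make_junction_series(30.0, 0.0, 2.0, 6, seed=0)
        # deviations {0, 2, 4, 6, 8, 10} → mean 5
        assert angular_deviation(self._trace(frames), 60.0) == pytest.approx(
            5.0, abs=1e-9)

    def test_max_statistic(self):
        frames = make_junction_series(30.0, 0.0, 2.0, 6, seed=0)
        assert angular_deviation(self._trace(frames), 60.0,
                                 statistic="max") == pytest.approx(10.0)

    def test_180_rotation_wraps_to_zero(self):
        base = np.array([(0.0, 0.0), (30.0, 0.0)])
        trace = JunctionTrace([(0.0, base), (10.0, base[::-1])])
        assert angular_deviation(trace, 20.0) == pytest.approx(0.0, abs=1e-9)

    def test_window_restricts_frames(self):
        frames = make_junction_series(30.0, 0.0, 2.0, 10, seed=0)
        # frames at t ≤ 30 min: deviations {0, 2, 4, 6} → mean 3
        assert angular_deviation(self._trace(frames), 30.0) == pytest.approx(
            3.0, abs=1e-9)


class TestPearson:
    def test_identical_channels(self, rng):
        img = rng.normal(size=(32, 32)) + 10
        pair = RoiImagePair(img, img.copy(), np.ones((32, 32), bool))
        assert pearson_roi(pair) == pytest.approx(1.0, abs=1e-12)

    def test_inverted_channel(self, rng):
        img = rng.normal(size=(32, 32))
        pair = RoiImagePair(img, -img + 7.0, np.ones((32, 32), bool))
        assert pearson_roi(pair) == pytest.approx(-1.0, abs=1e-12)

    def test_constructed_correlation_recovered(self):
        a, b = make_coloc_pair(0.7, (128, 128), seed=4)
        pair = RoiImagePair(a, b, np.ones((128, 128), bool))
        assert pearson_roi(pair) == pytest.approx(0.7, abs=0.02)

    def test_roi_restriction_matters(self, rng):
        a = rng.normal(size=(32, 32))
        b = rng.normal(size=(32, 32))
        roi = np.zeros((32, 32), bool)
        roi[:8, :8] = True
        b[:8, :8] = a[:8, :8]  # identical only inside ROI
        pair = RoiImagePair(a, b, roi)
        assert pearson_roi(pair) == pytest.approx(1.0, abs=1e-12)

    def test_affine_gain_invariance(self, rng):
        a = rng.normal(size=(16, 16))
        b = rng.normal(size=(16, 16))
        roi = np.ones((16, 16), bool)
        r0 = pearson_roi(RoiImagePair(a, b, roi))
        r1 = pearson_roi(RoiImagePair(2.5 * a + 3, 0.5 * b - 7, roi))
        assert r1 == pytest.approx(r0, abs=1e-12)

    def test_zero_variance_signals_undefined(self):
        pair = RoiImagePair(np.ones((8, 8)), np.arange(64.0).reshape(8, 8),
                            np.ones((8, 8), bool))
        assert pearson_roi(pair) is None


class TestIntensityProfile:
    def test_constant_image_normalizes_to_one(self):
        img = np.full((32, 32), 7.0)
        prof = intensity_profile(img, [(2, 2), (28, 28)], n_samples=50)
        assert np.allclose(prof.normalized, 1.0)
        assert not prof.normalization_skipped

    def test_ramp_profile_increasing(self):
        img = np.tile(np.arange(64.0), (64, 1))
        prof = intensity_profile(img, [(0, 32), (63, 32)], n_samples=30)
        assert np.all(np.diff(prof.raw) > 0)
        assert prof.normalized[-1] == pytest.approx(1.0)

    def test_gaussian_stripe_matches_analytic(self):
        x = np.arange(128.0)
        stripe = np.exp(-((x - 64.0) ** 2) / (2 * 5.0**2))
        img = np.tile(stripe, (64, 1))
        prof = intensity_profile(img, [(20, 30), (108, 30)], n_samples=89)
        analytic = np.exp(-((prof.positions + 20.0 - 64.0) ** 2)
                          / (2 * 5.0**2))
        assert np.abs(prof.normalized - analytic / analytic.max()).max() < 1e-3

    def test_all_zero_samples_flagged(self):
        img = np.zeros((16, 16))
        prof = intensity_profile(img, [(1, 1), (10, 10)])
        assert prof.normalization_skipped

    def test_line_outside_bounds_rejected(self):
        with pytest.raises(ValueError, match="bounds"):
            intensity_profile(np.zeros((16, 16)), [(0, 0), (40, 2)])


class TestAnalyzeParticles:
    def _disks(self, centers, radius=10, shape=(96, 96)):
        Y, X = np.mgrid[: shape[0], : shape[1]]
        img = np.zeros(shape)
        for cx, cy in centers:
            img[(X - cx) ** 2 + (Y - cy) ** 2 <= radius**2] = 100.0
        return img

    def test_blank_image(self):
        count, areas = analyze_particles(np.zeros((32, 32)), threshold=0.0)
        assert count == 0 and areas == []

    def test_two_disks_area_recovered(self):
        img = self._disks([(25, 30), (70, 60)], radius=10)
        count, areas = analyze_particles(img, threshold=50.0,
                                         pixel_size=0.5)
        assert count == 2
        for area in areas:
            assert area == pytest.approx(np.pi * 5.0**2, rel=0.03)

    def test_bridged_disks_merge(self):
        img = self._disks([(30, 48), (60, 48)], radius=10)
        img[48, 30:60] = 100.0  # 1-px bridge
        count, _ = analyze_particles(img, threshold=50.0)
        assert count == 1

    def test_min_area_monotonicity(self):
        img = self._disks([(25, 30), (70, 60)], radius=10)
        img[5, 5] = 100.0  # single bright pixel
        counts = [
            analyze_particles(img, threshold=50.0, min_area=a)[0]
            for a in (0.0, 10.0, 1000.0)
        ]
        assert counts == sorted(counts, reverse=True)

    def test_otsu_threshold_option(self):
        img = self._disks([(40, 40)], radius=12)
        count, _ = analyze_particles(img, threshold="otsu")
        assert count == 1

    def test_threshold_outside_range_rejected(self):
        with pytest.raises(ValueError, match="range"):
            analyze_particles(np.zeros((8, 8)), threshold=5.0)


class TestIntensityRatio:
    def test_identical_channels_ratio_one(self, rng):
        img = rng.uniform(1, 10, size=(16, 16))
        pair = RoiImagePair(img, img.copy(), np.ones((16, 16), bool))
        assert junction_intensity_ratio(pair) == pytest.approx(1.0)

    def test_triple_intensity(self, rng):
        img = rng.uniform(1, 10, size=(16, 16))
        pair = RoiImagePair(3.0 * img, img, np.ones((16, 16), bool))
        assert junction_intensity_ratio(pair) == pytest.approx(3.0)

    def test_matches_two_pass_mean_quotient(self, rng):
        a = rng.uniform(0, 50, size=(20, 20))
        b = rng.uniform(1, 50, size=(20, 20))
        roi = rng.uniform(size=(20, 20)) > 0.5
        pair = RoiImagePair(a, b, roi)
        expected = a[roi].mean() / b[roi].mean()
        assert junction_intensity_ratio(pair) == pytest.approx(
            expected, abs=1e-12)

    def test_zero_denominator_signals_undefined(self):
        pair = RoiImagePair(np.ones((8, 8)), np.zeros((8, 8)),
                            np.ones((8, 8), bool))
        assert junction_intensity_ratio(pair) is None


class TestTraceValidation:
    def test_nonmonotonic_times_rejected(self):
        poly = np.array([(0.0, 0.0), (1.0, 0.0)])
        with pytest.raises(ValueError, match="increasing"):
            JunctionTrace([(0.0, poly), (0.0, poly)])
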