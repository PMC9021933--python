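"""Elliptic Fourier decomposition, power calibration and reconstruction."""

from __future__ import annotations

import numpy as np
import pytest

from fishmorph import (
    EFTCoefficients,
    FishParams,
    ShapeError,
    calibrate_harmonics,
    eft_forward,
    eft_inverse,
    generate_fish,
    harmonic_power,
    resample_outline,
)
from fishmorph.align import align_outlines
from fishmorph.efa import parameter_mean
from conftest import circle_outline, ellipse_outline
from _oracles import eft_dense_integration


class TestForward:
    def test_circle_first_harmonic(self):
        coeffs = eft_forward(circle_outline(5.0, 256), 8).harmonics
        a1, b1, c1, d1 = coeffs[0]
        assert a1 == pytest.approx(5.0, abs=1e-3)
        assert d1 == pytest.approx(5.0, abs=1e-3)
        assert abs(b1) < 1e-3 and abs(c1) < 1e-3
        assert np.abs(coeffs[1:]).max() < 1e-3

    def test_ellipse_chord_length_coefficients(self):
        # under chord-length parameterisation the (4, 2) ellipse has
        # a1 = 3.65668, d1 = 2.14591 (dense-integration oracle), not (4, 2)
        pts = ellipse_outline(4.0, 2.0).points
        ours = eft_forward(ellipse_outline(4.0, 2.0), 2).harmonics
        oracle = eft_dense_integration(pts, 2)
        np.testing.assert_allclose(ours, oracle, atol=1e-6)
        assert ours[0, 0] == pytest.approx(3.65668, abs=1e-3)
        assert ours[0, 3] == pytest.approx(2.14591, abs=1e-3)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_matches_dense_integration_on_random_polygon(self, seed):
        rng = np.random.default_rng(seed)
        # smooth random closed curve, 64 points
        theta = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        r = 2.0 + 0.5 * np.sin(3 * theta + rng.uniform(0, np.pi)) \
            + 0.2 * np.cos(5 * theta)
        from fishmorph.shapes import OutlineShape

        shape = OutlineShape(np.column_stack([r * np.cos(theta),
                                              r * np.sin(theta)]))
        ours = eft_forward(shape, 6).harmonics
        oracle = eft_dense_integration(shape.points, 6)
        np.testing.assert_allclose(ours, oracle, atol=1e-6)

    def test_translation_invariance(self):
        a = eft_forward(circle_outline(2.0, 128), 4).harmonics
        b = eft_forward(circle_outline(2.0, 128, center=(17.0, -4.0)), 4).harmonics
        np.testing.assert_allclose(a, b, atol=1e-12)


class TestPower:
    def test_circle_power(self):
        coeffs = eft_forward(circle_outline(5.0, 512), 8)
        profile = harmonic_power(coeffs)
        assert profile.power[0] == pytest.approx(25.0, abs=1e-3)
        assert profile.cumulative_fraction[0] >= 0.999

    def test_ellipse_power_from_its_own_coefficients(self):
        coeffs = eft_forward(ellipse_outline(4.0, 2.0, 512), 8)
        a1, b1, c1, d1 = coeffs.harmonics[0]
        expected = 0.5 * (a1 ** 2 + b1 ** 2 + c1 ** 2 + d1 ** 2)
        assert harmonic_power(coeffs).power[0] == pytest.approx(expected, rel=1e-12)

    def test_cumulative_fraction_monotone_ends_at_one(self, small_dataset):
        coeffs = eft_forward(resample_outline(small_dataset.outlines[0], 256), 20)
        cum = harmonic_power(coeffs).cumulative_fraction
        assert np.all(np.diff(cum) >= -1e-15)
        assert cum[-1] == pytest.approx(1.0, abs=0)

    def test_zero_coefficients_rejected(self):
        with pytest.raises(ShapeError, match="undefined|zero"):
            harmonic_power(EFTCoefficients(np.zeros((3, 4))))

    def test_parseval_stable_under_resampling_density(self):
        # on a smooth band-limited curve total power converges monotonically
        # (~n^-2) under density doubling; on a fish outline (fork corners)
        # it still varies < 1% for any density >= 128
        theta = np.linspace(0, 2 * np.pi, 4096, endpoint=False)
        r = 2.0 + 0.3 * np.sin(3 * theta) + 0.1 * np.cos(5 * theta)
        from fishmorph.shapes import OutlineShape

        smooth = OutlineShape(np.column_stack([r * np.cos(theta),
                                               r * np.sin(theta)]))
        totals = []
        for n in (128, 256, 512, 1024):
            coeffs = eft_forward(resample_outline(smooth, n), 30)
            totals.append(harmonic_power(coeffs).power.sum())
        diffs = np.abs(np.diff(totals)) / totals[-1]
        assert np.all(np.diff(diffs) < 0) and diffs[-1] < 5e-5

        shape, *_ = generate_fish(FishParams(noise_sd=0.0, seed=2),
                                  n_points=2048)
        fish_totals = [
            harmonic_power(eft_forward(resample_outline(shape, n), 30)).power.sum()
            for n in (128, 256, 512, 1024)
        ]
        assert np.ptp(fish_totals) / fish_totals[-1] < 0.01


class TestCalibration:
    def test_circles_need_one_harmonic(self):
        batch = [circle_outline(r, 256) for r in (1.0, 2.0, 3.0)]
        assert calibrate_harmonics(batch, threshold=0.99) == 1

    def test_threshold_monotonicity(self):
        batch = [circle_outline(r, 256) for r in (1.0, 2.0)]
        assert calibrate_harmonics(batch, 0.999) >= calibrate_harmonics(batch, 0.99)

    def test_matches_exhaustive_scan_on_synthetic_fish(self):
        rng = np.random.default_rng(1)
        shapes = []
        for i in range(20):
            s, *_ = generate_fish(FishParams(noise_sd=0.01, seed=0), rng=rng,
                                  id=str(i))
            shapes.append(s)
        aligned, _ = align_outlines(shapes)
        h_star = calibrate_harmonics(aligned, 0.99, h_max=32)
        profile = np.stack([
            harmonic_power(eft_forward(s, 32)).cumulative_fraction
            for s in aligned
        ]).mean(axis=0)
        scan = next(h for h in range(1, 33) if profile[h - 1] >= 0.99)
        assert h_star == scan

    def test_per_shape_at_least_mean(self):
        rng = np.random.default_rng(2)
        shapes = [generate_fish(FishParams(noise_sd=0.02, seed=0), rng=rng)[0]
                  for _ in range(8)]
        assert calibrate_harmonics(shapes, 0.99, per_shape=True) >= \
            calibrate_harmonics(shapes, 0.99)

    def test_bad_threshold_rejected(self):
        with pytest.raises(ShapeError, match="threshold"):
            calibrate_harmonics([circle_outline()], threshold=1.5)


class TestInverse:
    def test_circle_reconstruction_radius(self):
        coeffs = EFTCoefficients(np.array([[5.0, 0.0, 0.0, 5.0]]))
        pts = eft_inverse(coeffs, 64).points
        np.testing.assert_allclose(np.hypot(pts[:, 0], pts[:, 1]), 5.0, atol=1e-6)

    def test_zero_coefficients_flagged(self):
        with pytest.raises(ShapeError, match="zero"):
            eft_inverse(EFTCoefficients(np.zeros((2, 4))), 32)

    def test_too_few_points_rejected(self):
        with pytest.raises(ShapeError, match="n >= 8"):
            eft_inverse(EFTCoefficients(np.array([[1.0, 0, 0, 1.0]])), 7)

    def test_round_trip_on_synthetic_fish(self):
        shape, *_ = generate_fish(FishParams(noise_sd=0.005, seed=3), n_points=256)
        rec = eft_inverse(eft_forward(shape, 40), len(shape)).points
        orig = shape.points - parameter_mean(shape)
        err = np.linalg.norm(rec - orig, axis=1).mean()
        diag = np.hypot(*(shape.points.max(0) - shape.points.min(0)))
        assert err < 0.005 * diag

    def test_reconstruction_error_decreases_with_harmonics(self):
        rng = np.random.default_rng(4)
        errs = []
        shapes = [generate_fish(FishParams(noise_sd=0.01, seed=0), rng=rng,
                                n_points=256)[0] for _ in range(6)]
        for h in (2, 4, 8, 16, 32):
            tot = 0.0
            for s in shapes:
                rec = eft_inverse(eft_forward(s, h), len(s)).points
                tot += np.linalg.norm(rec - (s.points - parameter_mean(s)),
                                      axis=1).mean()
            errs.append(tot / len(shapes))
        assert all(b <= a + 1e-12 for a, b in zip(errs, errs[1:]))
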