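import numpy as np
import pytest

from conftest import as_bin, digital_ball, tube_z
from sinumorph.macrovessel import MeasurementWindow
from sinumorph.morphometry import (
    GranulometryCurve,
    granulometry_curve,
    local_thickness,
    minkowski_estimates,
    specific_length,
    trim_and_smooth,
    volume_density,
)
from sinumorph.phantom import PhantomSpec, place_disjoint_fibers
from sinumorph.volume_io import BinaryVolume


def full_window(shape, spacing=1.0):
    return MeasurementWindow(BinaryVolume(np.ones(shape, bool), spacing))


class TestVolumeDensity:
    def test_full_and_empty(self):
        W = full_window((8, 8, 8))
        assert volume_density(as_bin(np.ones((8, 8, 8), bool)), W) == 1.0
        assert volume_density(as_bin(np.zeros((8, 8, 8), bool)), W) == 0.0

    def test_monotone_in_structure(self, rng):
        W = full_window((12, 12, 12))
        m1 = rng.random((12, 12, 12)) < 0.3
        m2 = m1 | (rng.random((12, 12, 12)) < 0.2)
        assert volume_density(as_bin(m1), W) <= volume_density(as_bin(m2), W)

    def test_empty_window_errors(self):
        W = MeasurementWindow(BinaryVolume(np.zeros((4, 4, 4), bool), 1.0))
        with pytest.raises(ValueError):
            volume_density(as_bin(np.ones((4, 4, 4), bool)), W)


class TestSpecificLength:
    def test_zero_M_gives_zero(self):
        W = full_window((8, 8, 8))
        est = minkowski_estimates(as_bin(np.zeros((8, 8, 8), bool)), W)
        assert specific_length(est, W, 0.0) == 0.0

    def test_algebraic_identity(self, rng):
        """L_V * pi * V(W) * (1 - V_V) == M exactly."""
        mask = rng.random((16, 16, 16)) < 0.2
        X = as_bin(mask, 0.7)
        W = full_window(mask.shape, 0.7)
        est = minkowski_estimates(X, W)
        vv = volume_density(X, W)
        lv = specific_length(est, W, vv)
        assert lv * np.pi * W.volume * (1 - vv) == pytest.approx(est.M, rel=1e-12)

    def test_saturated_window_errors(self):
        W = full_window((6, 6, 6))
        est = minkowski_estimates(as_bin(np.ones((6, 6, 6), bool)), W)
        with pytest.raises(ValueError):
            specific_length(est, W, 1.0)

    def test_disjoint_fiber_length_recovery(self):
        """M/pi recovers total centerline length plus rounded-end
        corrections within 10% on disjoint fiber systems."""
        spec = PhantomSpec(seed=4, dims=(140, 140, 140), spacing=0.65)
        truth = place_disjoint_fibers(spec, 10)
        W = full_window(spec.dims, spec.spacing)
        est = minkowski_estimates(truth.sinusoid_mask, W)
        expected = truth.total_fiber_length_um + truth.end_correction_um
        assert est.M / np.pi == pytest.approx(expected, rel=0.10)


class TestLocalThickness:
    def test_single_ball_uniform_value(self):
        r = 6
        ball = digital_ball(r)
        th = local_thickness(as_bin(ball, 1.0))
        vals = th[ball]
        assert np.all(np.abs(vals - 2 * r) <= 1.0 + 1e-6)
        assert (th[~ball] == 0).all()

    def test_two_overlapping_balls_max_is_larger(self):
        n = 48
        g = np.mgrid[:n, :n, :n]
        small = ((g[0] - 16) ** 2 + (g[1] - 24) ** 2 + (g[2] - 24) ** 2) <= 5**2
        big = ((g[0] - 28) ** 2 + (g[1] - 24) ** 2 + (g[2] - 24) ** 2) <= 9**2
        th = local_thickness(as_bin(small | big, 1.0))
        assert abs(th.max() - 18) <= 1.0 + 1e-6

    def test_matches_exhaustive_inscribed_ball_oracle(self, rng):
        """Brute-force oracle on a small instance: for every ball centre c
        and radius r with ball(c, r) inside X, every covered voxel has
        thickness >= 2r; and the map never exceeds the oracle."""
        n = 24
        g = np.mgrid[:n, :n, :n]
        mask = (((g[0] - 8) ** 2 + (g[1] - 10) ** 2 + (g[2] - 10) ** 2) <= 36) | (
            ((g[0] - 16) ** 2 + (g[1] - 12) ** 2 + (g[2] - 12) ** 2) <= 16
        )
        th = local_thickness(as_bin(mask, 1.0))
        coords = np.argwhere(mask)
        oracle = np.zeros(mask.shape)
        from scipy.ndimage import distance_transform_edt

        edt = distance_transform_edt(mask)
        for c in coords:
            r = edt[tuple(c)] - 1e-9  # largest ball at c fully inside X
            d2 = ((coords - c) ** 2).sum(axis=1)
            covered = coords[d2 <= r * r]
            vals = 2 * r
            idx = tuple(covered.T)
            oracle[idx] = np.maximum(oracle[idx], vals)
        diff = np.abs(th[mask] - oracle[mask])
        assert diff.max() <= 1.0 + 1e-6  # one voxel of diameter discretization

    def test_long_cylinder_interior(self):
        r = 5
        mask = tube_z(32, 16, 16, r)
        th = local_thickness(as_bin(mask, 1.0))
        core = th[14:18, 14:18, 10:22]
        assert np.all(np.abs(core - 2 * r) <= 1.0 + 1e-6)


class TestGranulometry:
    def test_monodisperse_balls_single_bin(self):
        n = 64
        g = np.mgrid[:n, :n, :n]
        mask = np.zeros((n, n, n), bool)
        for c in [(12, 12, 12), (12, 40, 40), (40, 40, 12)]:
            mask |= ((g[0] - c[0]) ** 2 + (g[1] - c[1]) ** 2 + (g[2] - c[2]) ** 2) <= 36
        X = as_bin(mask, 1.0)
        th = local_thickness(X)
        curve = granulometry_curve(th, X)
        d_true = 12
        sel = np.abs(curve.bin_diameters - d_true) <= 1.0
        assert curve.weights[sel].sum() >= 0.95

    def test_two_populations_volume_ratio(self):
        n = 72
        g = np.mgrid[:n, :n, :n]
        mask = np.zeros((n, n, n), bool)
        r_small, r_big = 5, 10
        small_centers = [(12, 12, 12), (12, 12, 46), (12, 46, 12), (46, 12, 12),
                         (12, 46, 46), (46, 12, 46), (46, 46, 12), (46, 46, 46)]
        for c in small_centers:
            mask |= ((g[0] - c[0]) ** 2 + (g[1] - c[1]) ** 2 + (g[2] - c[2]) ** 2) <= r_small**2
        mask |= ((g[0] - 58) ** 2 + (g[1] - 58) ** 2 + (g[2] - 58) ** 2) <= r_big**2
        X = as_bin(mask, 1.0)
        curve = granulometry_curve(local_thickness(X), X)
        v_small = 8 * 4 / 3 * np.pi * r_small**3
        v_big = 4 / 3 * np.pi * r_big**3
        w_small = curve.weights[np.abs(curve.bin_diameters - 2 * r_small) <= 1.0].sum()
        w_big = curve.weights[np.abs(curve.bin_diameters - 2 * r_big) <= 1.0].sum()
        expect_small = v_small / (v_small + v_big)
        assert w_small == pytest.approx(expect_small, abs=0.05)
        assert w_big == pytest.approx(1 - expect_small, abs=0.05)

    def test_weights_sum_to_one(self, rng):
        mask = digital_ball(5)
        X = as_bin(mask, 0.5)
        curve = granulometry_curve(local_thickness(X), X)
        assert curve.weights.sum() == pytest.approx(1.0)

    def test_empty_structure_errors(self):
        X = as_bin(np.zeros((6, 6, 6), bool))
        with pytest.raises(ValueError):
            granulometry_curve(np.zeros((6, 6, 6)), X)


class TestTrimAndSmooth:
    def test_spurious_leading_bins_removed(self):
        d = np.arange(1.0, 13.0)
        w = np.array([0.10, 0.05, 0.02, 0.05, 0.15, 0.25, 0.20, 0.10, 0.05,
                      0.02, 0.008, 0.002])
        curve = GranulometryCurve(d, w / w.sum())
        out = trim_and_smooth(curve, spline_smoothing=0.0)
        assert out.bin_diameters[0] == 3.0  # first minimum at index 2
        assert out.weights.sum() == pytest.approx(1.0)

    def test_strictly_decreasing_curve_preserved(self):
        d = np.arange(1.0, 9.0)
        w = np.array([0.4, 0.25, 0.15, 0.1, 0.05, 0.03, 0.015, 0.005])
        out = trim_and_smooth(GranulometryCurve(d, w), spline_smoothing=0.0)
        assert out.bin_diameters[0] == 1.0  # no local minimum: no trimming
        np.testing.assert_allclose(out.weights, w / w.sum(), atol=1e-6)

    def test_output_normalized_and_nonnegative(self, rng):
        d = np.arange(1.0, 20.0)
        w = rng.random(19)
        out = trim_and_smooth(GranulometryCurve(d, w / w.sum()))
        assert out.weights.sum() == pytest.approx(1.0)
        assert (out.weights >= 0).all()
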