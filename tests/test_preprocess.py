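"""Smoothing, baseline estimation, RIP alignment and COW."""

import itertools

import numpy as np
import pytest
from scipy.signal import savgol_coeffs

from gcimstools.io import SampleMatrix
from gcimstools.preprocess import (PsalsaParams, SGParams, WarpFunction,
                                   align_drift_multiplicative,
                                   apply_warp_to_matrix, compute_tic,
                                   correct_baseline_matrix, cow_align,
                                   detect_rip_position, optimize_cow_params,
                                   psalsa_baseline, select_sg_params,
                                   sg_smooth)


class TestSavitzkyGolay:
    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            SGParams(4, 2)          # even window
        with pytest.raises(ValueError):
            SGParams(5, 5)          # degree >= window

    @pytest.mark.parametrize("n", [5, 11, 27])
    def test_quadratic_reproduced_exactly(self, n):
        x = np.linspace(-3, 5, 100)
        y = 2.0 - 0.7 * x + 0.3 * x ** 2
        np.testing.assert_allclose(sg_smooth(y, SGParams(n, 2)), y,
                                   atol=1e-9)

    def test_noise_variance_matches_kernel_energy(self):
        """Filtered white noise has variance  sigma^2 * sum(c_i^2)."""
        rng = np.random.default_rng(0)
        noise = rng.normal(size=200_000)
        params = SGParams(19, 2)
        out = sg_smooth(noise, params)
        expected = np.sum(savgol_coeffs(19, 2) ** 2)
        assert out.var() == pytest.approx(expected, rel=0.05)

    def test_too_short_signal_errors(self):
        with pytest.raises(ValueError, match="shorter"):
            sg_smooth(np.ones(5), SGParams(7, 2))


class TestSelectSGParams:
    def test_polynomial_reference_picks_largest_window(self):
        x = np.arange(200.0)
        y = 1 + x - 0.004 * x ** 2
        grid = [SGParams(n, 2) for n in range(5, 43, 2)]
        assert select_sg_params(y, grid).n == 41

    def test_matches_brute_force_on_narrow_gaussian(self):
        x = np.arange(300.0)
        y = 100 * np.exp(-0.5 * ((x - 150) / 3.0) ** 2)
        grid = [SGParams(n, 2) for n in range(5, 43, 2)]
        # brute force: strongest candidate with apex loss <= 1%
        feasible = [g for g in grid
                    if sg_smooth(y, g).max() >= 0.99 * y.max()]
        expected = max(feasible, key=lambda g: (g.n, -g.d))
        assert select_sg_params(y, grid, 0.01) == expected

    def test_reports_best_achievable_loss_on_failure(self):
        y = np.zeros(100)
        y[50] = 1.0  # delta spike: every smoother kills the apex
        grid = [SGParams(n, 2) for n in (11, 21)]
        with pytest.raises(ValueError, match="best achievable"):
            select_sg_params(y, grid, 0.01)


class TestPsalsa:
    def test_parameter_validation(self):
        with pytest.raises(ValueError):
            PsalsaParams(lam=-1)
        with pytest.raises(ValueError):
            PsalsaParams(p=1.5)

    def test_flat_zero_signal_gives_zero_baseline(self):
        z = psalsa_baseline(np.zeros(50), PsalsaParams())
        np.testing.assert_allclose(z, 0.0)

    def test_smooth_peakless_curve_is_followed(self):
        x = np.arange(600.0)
        y = 10 + 80 * np.exp(-x / 120) + 0.02 * x + 5 * np.sin(x / 150)
        z = psalsa_baseline(y, PsalsaParams(1e2, 5e-3, 50.0))
        assert np.abs(z - y).max() < 0.02 * (y.max() - y.min())

    def test_baseline_recovery_under_peaks(self):
        """RMSE to the true baseline stays below 5% of its range away
        from peak cores."""
        rng = np.random.default_rng(0)
        x = np.arange(600.0)
        base = 10 + 80 * np.exp(-x / 120) + 0.02 * x
        for rep in range(3):
            centers = rng.choice(np.arange(50, 550), 8, replace=False)
            sig = base + rng.normal(0, 1, 600)
            for c in centers:
                sig = sig + 300 * np.exp(-0.5 * ((x - c) / 4) ** 2)
            z = psalsa_baseline(sig, PsalsaParams(1e2, 5e-3, 50.0))
            away = np.all(np.abs(x[:, None] - centers[None, :]) > 16, axis=1)
            rmse = np.sqrt(np.mean((z - base)[away] ** 2))
            assert rmse < 0.05 * (base.max() - base.min())


class TestBaselineMatrix:
    def test_constant_baseline_rows_removed(self):
        x = np.arange(200.0)
        row = 30 + 20 * np.exp(-x / 40)
        grid = np.tile(row, (15, 1))
        m = SampleMatrix(grid, np.arange(15.0), np.arange(200.0))
        out = correct_baseline_matrix(m, PsalsaParams(1.0, 5e-3, 50.0),
                                      axis="drift")
        assert np.abs(out.intensities).max() < 0.02 * (row.max() - row.min())

    def test_zero_matrix_unchanged(self):
        m = SampleMatrix(np.zeros((10, 20)), np.arange(10.0), np.arange(20.0))
        out = correct_baseline_matrix(m, axis="retention")
        np.testing.assert_allclose(out.intensities, 0.0)

    def test_invalid_axis_rejected(self):
        m = SampleMatrix(np.zeros((4, 4)), np.arange(4.0), np.arange(4.0))
        with pytest.raises(ValueError, match="axis"):
            correct_baseline_matrix(m, axis="diagonal")


class TestRipAlignment:
    def _rip_matrix(self, center_ms=6.4, nr=30, nd=200):
        drift = 5.0 + 0.05 * np.arange(nd)
        spectrum = 1000 * np.exp(-0.5 * ((drift - center_ms) / 0.12) ** 2)
        return SampleMatrix(np.tile(spectrum, (nr, 1)), 1.0 * np.arange(nr), drift)

    def test_planted_rip_found_within_one_sample(self):
        m = self._rip_matrix(6.4)
        pos = detect_rip_position(m, (0.0, 29.0))
        assert pos == pytest.approx(6.4, abs=0.05)

    def test_subsample_refinement_on_off_grid_apex(self):
        m = self._rip_matrix(6.413)
        assert detect_rip_position(m, (0, 29)) == pytest.approx(6.413,
                                                                abs=0.01)

    def test_tallest_peak_wins_over_analyte(self):
        m = self._rip_matrix(6.4)
        drift = m.drift_axis
        m.intensities[:] += 300 * np.exp(-0.5 * ((drift - 9.0) / 0.2) ** 2)
        assert detect_rip_position(m, (0, 29)) == pytest.approx(6.4, abs=0.05)

    def test_window_outside_axis_errors(self):
        with pytest.raises(ValueError, match="no spectra"):
            detect_rip_position(self._rip_matrix(), (500.0, 600.0))

    def test_multiplicative_alignment_recovers_planted_scale(self):
        ref = self._rip_matrix(6.4)
        shifted = self._rip_matrix(6.4 * 1.02)
        own = detect_rip_position(shifted, (0, 29))
        aligned = align_drift_multiplicative(shifted, 6.4, own)
        apex_ref = np.argmax(ref.intensities[0])
        apex_ali = np.argmax(aligned.intensities[0])
        assert abs(int(apex_ref) - int(apex_ali)) <= 1

    def test_identity_when_rips_match(self):
        m = self._rip_matrix()
        out = align_drift_multiplicative(m, 6.4, 6.4)
        np.testing.assert_allclose(out.intensities, m.intensities, atol=1e-9)

    def test_zero_rows_stay_zero(self):
        m = self._rip_matrix()
        m.intensities[3] = 0.0
        out = align_drift_multiplicative(m, 6.4, 6.53)
        np.testing.assert_allclose(out.intensities[3], 0.0)


def test_tic_is_row_sum():
    m = SampleMatrix(np.ones((10, 5)), np.arange(10.0), np.arange(5.0))
    np.testing.assert_allclose(compute_tic(m), 5.0)


class TestCow:
    def _peaky(self, n=100, seed=3):
        rng = np.random.default_rng(seed)
        x = np.arange(float(n))
        sig = np.zeros(n)
        for a, c in zip(rng.uniform(100, 300, 4), (15, 40, 65, 88)):
            sig += a * np.exp(-0.5 * ((x - c) / 3.0) ** 2)
        return sig

    def test_identity_when_sample_equals_reference(self):
        ref = self._peaky()
        w = cow_align(ref, ref, 25, 5, segment_weights="uniform")
        np.testing.assert_allclose(w.sample_boundaries, w.ref_boundaries)
        assert w.total_correlation == pytest.approx(len(w.ref_boundaries) - 1,
                                                    abs=1e-6)

    def test_shifted_gaussian_realigned(self):
        x = np.arange(200.0)
        ref = 100 * np.exp(-0.5 * ((x - 90) / 6) ** 2)
        sample = 100 * np.exp(-0.5 * ((x - 94) / 6) ** 2)
        w = cow_align(sample, ref, 25, 10)
        warped = w.warp_signal(sample)
        corr = np.corrcoef(warped, ref)[0, 1]
        assert corr > 0.99

    @pytest.mark.parametrize("weights", ["uniform", "sd"])
    def test_dp_equals_exhaustive_enumeration(self, weights):
        """The dynamic program attains the global optimum found by brute
        force over all feasible boundary placements (N=100, I=25, t=5)."""
        rng = np.random.default_rng(3)
        n, I, t = 100, 25, 5
        for rep in range(3):
            ref = self._peaky(seed=rep)
            xs = np.arange(float(n))
            sample = np.interp(xs + rng.uniform(-3, 3), xs, ref) \
                + rng.normal(0, 2, n)
            w = cow_align(sample, ref, I, t, segment_weights=weights)

            n_seg = n // I
            ref_b = np.round(np.linspace(0, n - 1, n_seg + 1)).astype(int)

            def total(bounds):
                tot = 0.0
                for j in range(1, n_seg + 1):
                    L = ref_b[j] - ref_b[j - 1]
                    sl = bounds[j] - bounds[j - 1]
                    if sl < max(2, L - t) or sl > L + t:
                        return -np.inf
                    seg = sample[bounds[j - 1]:bounds[j] + 1]
                    res = np.interp(np.linspace(0, seg.size - 1, L + 1),
                                    np.arange(seg.size), seg)
                    rs = ref[ref_b[j - 1]:ref_b[j] + 1]
                    a = res - res.mean()
                    b = rs - rs.mean()
                    na, nb = np.linalg.norm(a), np.linalg.norm(b)
                    corr = 0.0 if na < 1e-12 or nb < 1e-12 else a @ b / (na * nb)
                    wgt = rs.std() if weights == "sd" else 1.0
                    tot += wgt * corr
                return tot

            ranges = [range(max(1, ref_b[j] - t), min(n - 2, ref_b[j] + t) + 1)
                      for j in range(1, n_seg)]
            best = max((total([0, *combo, n - 1]), [0, *combo, n - 1])
                       for combo in itertools.product(*ranges))
            assert w.total_correlation == pytest.approx(best[0], abs=1e-9)

    def test_slack_ge_segment_rejected(self):
        with pytest.raises(ValueError, match="slack"):
            cow_align(np.zeros(100), np.zeros(100), 10, 10)


class TestOptimizeCowParams:
    def test_planted_shift_needs_enough_slack(self):
        x = np.arange(150.0)
        ref = 100 * np.exp(-0.5 * ((x - 70) / 4) ** 2) \
            + 80 * np.exp(-0.5 * ((x - 120) / 4) ** 2)
        shifted = np.interp(x + 5, x, ref)
        assert optimize_cow_params([shifted], ref,
                                   [(25, 2), (25, 10)]) == (25, 10)

    def test_tie_break_prefers_smallest_grid_entry(self):
        ref = 100 * np.exp(-0.5 * ((np.arange(100.0) - 50) / 5) ** 2)
        assert optimize_cow_params([ref.copy()], ref,
                                   [(30, 5), (25, 5), (25, 10)]) == (25, 5)

    def test_empty_grid_errors(self):
        with pytest.raises(ValueError, match="empty"):
            optimize_cow_params([np.zeros(10)], np.zeros(10), [])


class TestApplyWarp:
    def test_identity_warp_is_identity(self):
        rng = np.random.default_rng(0)
        m = SampleMatrix(rng.normal(size=(50, 8)), np.arange(50.0),
                         np.arange(8.0))
        out = apply_warp_to_matrix(m, WarpFunction.identity(50))
        np.testing.assert_allclose(out.intensities, m.intensities)

    def test_constant_matrix_invariant_under_any_warp(self):
        m = SampleMatrix(np.full((60, 4), 3.14), np.arange(60.0),
                         np.arange(4.0))
        w = WarpFunction(np.array([0.0, 30.0, 59.0]),
                         np.array([0.0, 36.0, 59.0]), 60)
        np.testing.assert_allclose(
            apply_warp_to_matrix(m, w).intensities, 3.14)

    def test_length_mismatch_rejected(self):
        m = SampleMatrix(np.zeros((10, 3)), np.arange(10.0), np.arange(3.0))
        with pytest.raises(ValueError, match="length"):
            apply_warp_to_matrix(m, WarpFunction.identity(12))

    def test_warp_is_monotone_or_rejected(self):
        with pytest.raises(ValueError, match="monotone"):
            WarpFunction(np.array([0.0, 10.0, 20.0]),
                         np.array([0.0, 12.0, 8.0]), 21)
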