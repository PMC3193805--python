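"""RSI normalization, time-axis correction, voxel fitting, QC and summaries."""

import numpy as np
import pytest

from brixflow.kinetics import (
    DCESeries,
    RSICurve,
    REASON_BASELINE,
    compute_rsi,
    correct_time_axis,
    fit_roi,
    fit_voxel,
    grid_search_fit,
    qc_kep,
    summarize_roi,
)
from brixflow.model import brix_rsi


def make_series(signal, n_baseline=5, dt=0.2, nominal=3.0, actual=3.0, mask=None):
    signal = np.asarray(signal, dtype=float)
    n_frames = signal.shape[2]
    times = dt * (np.arange(n_frames) - (n_baseline - 1))
    if mask is None:
        mask = np.ones(signal.shape[:2], dtype=bool)
    return DCESeries(
        signal=signal,
        frame_times=times,
        n_baseline_frames=n_baseline,
        nominal_injection_duration=nominal,
        actual_injection_duration=actual,
        roi_mask=mask,
    )


class TestComputeRSI:
    def test_constant_signal_gives_zero_enhancement(self):
        series = make_series(np.full((2, 2, 20), 100.0))
        stack = compute_rsi(series)
        assert np.allclose(stack.rsi, 0.0)
        assert stack.rsi.shape == (2, 2, 15)
        assert np.all(stack.times > 0)

    def test_direct_value_and_noisy_baseline_mean(self):
        # baseline frames (98, 102, 100, 99, 101) average to 100
        sig = np.empty((1, 1, 6))
        sig[0, 0] = [98, 102, 100, 99, 101, 150]
        stack = compute_rsi(make_series(sig))
        assert stack.rsi[0, 0, 0] == pytest.approx(0.5)

    def test_zero_baseline_flagged_not_raised(self):
        sig = np.full((1, 2, 20), 100.0)
        sig[0, 1, :5] = 0.0
        stack = compute_rsi(make_series(sig))
        assert stack.valid_baseline[0, 0]
        assert not stack.valid_baseline[0, 1]
        assert np.all(np.isnan(stack.rsi[0, 1]))


class TestCorrectTimeAxis:
    @pytest.mark.parametrize(
        "actual,shift_min",
        [(3.0, 0.0), (9.0, 0.05), (1.0, -1.0 / 60.0)],
    )
    def test_post_times_shifted_by_half_deviation(self, actual, shift_min):
        series = make_series(np.full((1, 1, 20), 100.0), actual=actual)
        corrected = correct_time_axis(series)
        nb = series.n_baseline_frames
        np.testing.assert_allclose(
            corrected.frame_times[nb:], series.frame_times[nb:] + shift_min
        )
        np.testing.assert_array_equal(corrected.frame_times[:nb], series.frame_times[:nb])
        # idempotent: the corrected series carries actual == nominal
        again = correct_time_axis(corrected)
        np.testing.assert_array_equal(again.frame_times, corrected.frame_times)


class TestFitVoxel:
    def test_noiseless_recovery(self, post_times):
        y = brix_rsi(post_times, 1.5, 2.0, 0.2)
        fit = fit_voxel(RSICurve(times=post_times, rsi=y))
        assert fit.converged
        assert fit.A == pytest.approx(1.5, rel=1e-4)
        assert fit.k_ep == pytest.approx(2.0, rel=1e-4)
        assert fit.k_el == pytest.approx(0.2, rel=1e-4)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-10)

    def test_constant_zero_curve(self, post_times):
        fit = fit_voxel(RSICurve(times=post_times, rsi=np.zeros_like(post_times)))
        assert fit.A == 0.0
        assert np.isnan(fit.r_squared)

    def test_scale_consistency(self, post_times):
        """Scaling the curve scales A and leaves the rate constants alone."""
        y = brix_rsi(post_times, 1.2, 3.0, 0.25)
        for c in (0.5, 2.0, 7.0):
            fit = fit_voxel(RSICurve(times=post_times, rsi=c * y))
            assert fit.A == pytest.approx(c * 1.2, rel=1e-5)
            assert fit.k_ep == pytest.approx(3.0, rel=1e-5)
            assert fit.k_el == pytest.approx(0.25, rel=1e-5)

    def test_deterministic(self, post_times):
        y = brix_rsi(post_times, 1.0, 4.0, 0.3)
        y = y + np.random.default_rng(0).normal(0, 0.05, len(y))
        fits = [fit_voxel(RSICurve(times=post_times, rsi=y)) for _ in range(2)]
        assert fits[0] == fits[1]

    def test_too_few_points_rejected(self):
        t = np.arange(1, 6) * 0.2
        with pytest.raises(ValueError):
            fit_voxel(RSICurve(times=t, rsi=np.ones(5)))

    def test_grid_search_agrees_with_main_fitter(self, post_times):
        """Global grid search + Nelder-Mead refinement finds the same optimum."""
        rng = np.random.default_rng(42)
        for _ in range(5):
            A = rng.uniform(0.5, 3.0)
            k_ep = rng.uniform(0.5, 8.0)
            k_el = rng.uniform(0.05, 1.0)
            y = brix_rsi(post_times, A, k_ep, k_el)
            curve = RSICurve(times=post_times, rsi=y)
            main = fit_voxel(curve)
            oracle = grid_search_fit(curve, n_grid=25)
            assert main.residual_norm**2 == pytest.approx(
                oracle.residual_norm**2, abs=1e-6
            )
            for p in ("A", "k_ep", "k_el"):
                assert getattr(main, p) == pytest.approx(getattr(oracle, p), rel=1e-3)


class TestFitROI:
    def test_noiseless_roi_full_recovery(self, post_times):
        rng = np.random.default_rng(1)
        shape = (5, 5)
        A = rng.uniform(0.8, 2.0, shape)
        k_ep = rng.uniform(1.5, 5.0, shape)
        k_el = rng.uniform(0.1, 0.5, shape)
        n_frames = len(post_times) + 5
        sig = np.full(shape + (n_frames,), 500.0)
        for r in range(5):
            for c in range(5):
                sig[r, c, 5:] = 500.0 * (1 + brix_rsi(post_times, A[r, c], k_ep[r, c], k_el[r, c]))
        pmap = fit_roi(make_series(sig))
        assert pmap.evaluable
        assert pmap.excluded.sum() == 0
        assert np.nanmax(np.abs(pmap.A - A) / A) < 1e-4
        assert np.nanmax(np.abs(pmap.k_el - k_el) / k_el) < 1e-4

    def test_empty_roi_rejected(self):
        sig = np.full((2, 2, 20), 100.0)
        with pytest.raises(ValueError):
            fit_roi(make_series(sig, mask=np.zeros((2, 2), dtype=bool)))

    def test_zero_baseline_voxel_excluded_with_reason(self, post_times):
        n_frames = len(post_times) + 5
        sig = np.full((2, 2, n_frames), 300.0)
        for r in range(2):
            for c in range(2):
                sig[r, c, 5:] = 300.0 * (1 + brix_rsi(post_times, 1.0, 3.0, 0.2))
        sig[1, 1, :5] = 0.0
        pmap = fit_roi(make_series(sig))
        assert pmap.excluded.sum() == 1
        assert pmap.excluded[1, 1]
        assert pmap.reason[1, 1] == REASON_BASELINE


class TestQcKep:
    def _fitted_map(self, k_ep, k_el, post_times, shape=(3, 3)):
        n_frames = len(post_times) + 5
        sig = np.full(shape + (n_frames,), 400.0)
        curve = 400.0 * (1 + brix_rsi(post_times, 1.0, k_ep, k_el))
        sig[:, :, 5:] = curve
        return fit_roi(make_series(sig))

    def test_slow_exchange_well_sampled_is_reliable(self, post_times):
        # k_ep = 0.5/min puts the peak minutes out: ~20 frames on the upslope
        pmap = self._fitted_map(0.5, 0.1, post_times)
        assert qc_kep(pmap) is True

    def test_saturated_kep_is_unreliable(self, post_times):
        pmap = self._fitted_map(1.0, 0.2, post_times)
        pmap.at_bound[pmap.roi_mask, 1] = True
        assert qc_kep(pmap) is False

    def test_zero_threshold_flags_on_any_voxel(self, post_times):
        pmap = self._fitted_map(0.5, 0.1, post_times)
        pmap.at_bound[0, 0, 1] = True
        assert qc_kep(pmap, threshold=0.0) is False
        assert qc_kep(pmap, threshold=0.5) is True


class TestSummarizeROI:
    def _uniform_map(self, post_times, shape=(4, 4)):
        n_frames = len(post_times) + 5
        sig = np.full(shape + (n_frames,), 400.0)
        sig[:, :, 5:] = 400.0 * (1 + brix_rsi(post_times, 2.0, 3.0, 0.2))
        return fit_roi(make_series(sig))

    def test_uniform_map_mean_and_sem(self, post_times):
        summ = summarize_roi(self._uniform_map(post_times))
        assert summ.mean_A == pytest.approx(2.0, rel=1e-5)
        assert summ.sem_A == pytest.approx(0.0, abs=1e-6)
        assert summ.n_voxels == 16

    def test_mean_over_non_excluded_only(self, post_times):
        pmap = self._uniform_map(post_times)
        pmap.A[pmap.roi_mask] = 2.0
        half = np.zeros_like(pmap.excluded)
        half[:2] = True
        pmap.excluded = half
        pmap.A[half] = 99.0
        summ = summarize_roi(pmap)
        assert summ.mean_A == pytest.approx(2.0)
        assert summ.n_voxels == 8

    def test_matches_independent_tabulation(self, post_times):
        """ROI means equal hand-computed means of the exported voxel table."""
        rng = np.random.default_rng(3)
        shape = (5, 4)
        n_frames = len(post_times) + 5
        sig = np.full(shape + (n_frames,), 400.0)
        for r in range(shape[0]):
            for c in range(shape[1]):
                y = brix_rsi(post_times, rng.uniform(0.5, 2), rng.uniform(2, 4), rng.uniform(0.1, 0.4))
                sig[r, c, 5:] = 400.0 * (1 + y + rng.normal(0, 0.02, len(y)))
        pmap = fit_roi(make_series(sig))
        table = pmap.to_dataframe()
        usable = table[~table["excluded"]]
        summ = summarize_roi(pmap)
        assert summ.mean_A == pytest.approx(usable["A"].mean())
        assert summ.mean_k_el == pytest.approx(usable["k_el"].mean())

    def test_all_excluded_raises(self, post_times):
        pmap = self._uniform_map(post_times)
        pmap.excluded[:] = True
        with pytest.raises(ValueError):
            summarize_roi(pmap)
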