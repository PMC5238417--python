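"""Curve processing: IRF convolution, noise, gating, fitting, inversion."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import optimammo as om
from optimammo.curve_processing import (
    HomogeneousFit,
    TimeResolvedCurve,
    window_pathlength,
)
from optimammo.forward_model import PathlengthKernel


@pytest.fixture(scope="module")
def model_curve(props, geom):
    t = np.arange(5.0, 12000.0, 10.0)
    return TimeResolvedCurve(t, om.slab_transmittance(props, geom, t), 785)


class TestConvolveIrf:
    def test_single_bin_spike_is_identity(self, model_curve):
        spike = om.InstrumentResponse(
            TimeResolvedCurve(model_curve.time_bins[:1], np.array([1.0])), fwhm=0.0
        )
        out = om.convolve_irf(model_curve, spike)
        np.testing.assert_allclose(out.counts, model_curve.counts, rtol=1e-14)

    def test_total_counts_conserved(self, geom):
        # a strongly absorbing medium: the curve decays to nothing well
        # before the grid end, so no tail is truncated by the convolution
        t = np.arange(5.0, 12000.0, 10.0)
        fast = om.OpticalProperties(mua=0.3, musp=15.0)
        curve = TimeResolvedCurve(t, om.slab_transmittance(fast, geom, t))
        irf = om.gaussian_irf(460.0, curve.dt)
        out = om.convolve_irf(curve, irf)
        assert out.counts.sum() == pytest.approx(curve.counts.sum(), rel=1e-10)

    def test_first_moment_shifts_by_irf_mean(self, model_curve):
        irf = om.gaussian_irf(460.0, model_curve.dt)
        out = om.convolve_irf(model_curve, irf)
        t = model_curve.time_bins
        mean_in = np.average(t, weights=model_curve.counts)
        mean_out = np.average(t, weights=out.counts)
        irf_mean = np.average(irf.curve.time_bins, weights=irf.curve.counts)
        assert mean_out - mean_in == pytest.approx(irf_mean, abs=model_curve.dt / 2)

    def test_mismatched_bin_width_rejected(self, model_curve):
        irf = om.gaussian_irf(460.0, 7.0)
        with pytest.raises(ValueError):
            om.convolve_irf(model_curve, irf)


class TestPoissonNoise:
    def test_mean_matches_scaled_input(self, model_curve):
        reps = np.stack([
            om.add_poisson_noise(model_curve, 1e5, seed=s).counts for s in range(300)
        ])
        lam = model_curve.counts * (1e5 / model_curve.counts.sum())
        se = np.sqrt(np.maximum(lam, 1e-12) / reps.shape[0])
        big = lam > 5
        dev = np.abs(reps.mean(axis=0) - lam)[big] / se[big]
        assert np.mean(dev < 3) > 0.98

    def test_variance_close_to_mean(self, model_curve):
        reps = np.stack([
            om.add_poisson_noise(model_curve, 1e5, seed=s).counts for s in range(300)
        ])
        lam = model_curve.counts * (1e5 / model_curve.counts.sum())
        big = lam > 50
        ratio = reps.var(axis=0, ddof=1)[big] / lam[big]
        assert 0.8 < np.median(ratio) < 1.2

    def test_fixed_seed_bit_identical(self, model_curve):
        a = om.add_poisson_noise(model_curve, 1e5, seed=9)
        b = om.add_poisson_noise(model_curve, 1e5, seed=9)
        np.testing.assert_array_equal(a.counts, b.counts)

    def test_invalid_total_rejected(self, model_curve):
        with pytest.raises(ValueError):
            om.add_poisson_noise(model_curve, 0.0, seed=1)


class TestEqualCountWindows:
    def test_hand_worked_example_greedy_boundary(self):
        """counts [5,1,4,2,8] with K=2: cumulative 10 of 20 is reached at the
        third bin, so the first window is bins 0..2."""
        win = om.equal_count_windows(np.array([5.0, 1, 4, 2, 8]), 2)
        assert list(win.edges) == [0, 3, 5]
        assert list(win.totals) == [10.0, 10.0]

    def test_uniform_curve_gives_equal_width_windows(self):
        win = om.equal_count_windows(np.full(50, 7.0), 10)
        widths = np.diff(win.edges)
        assert np.all(widths == 5)
        assert np.allclose(win.totals, 35.0)

    def test_ten_windows_and_window_8_slice(self, model_curve):
        win = om.equal_count_windows(model_curve, 10)
        assert win.n_windows == 10
        sl = win.window_slice(8)
        total = model_curve.counts.sum()
        # greedy boundaries overshoot each target by at most one bin content
        max_bin = model_curve.counts.max()
        assert abs(model_curve.counts[sl].sum() - total / 10) <= 2 * max_bin
        # late window: starts after the curve peak
        assert sl.start > np.argmax(model_curve.counts)

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        counts=st.lists(st.integers(min_value=0, max_value=10_000), min_size=1, max_size=300),
        k=st.integers(min_value=1, max_value=10),
    )
    def test_split_mode_totals_within_one_count(self, counts, k):
        counts = np.asarray(counts, dtype=float)
        total = counts.sum()
        if total < k:
            return
        win = om.equal_count_windows(counts, k, split_bins=True)
        assert np.all(np.abs(win.totals - total / k) <= 1.0)
        assert win.edges[0] == 0.0 and win.edges[-1] == counts.size

    @settings(max_examples=200, derandomize=True, deadline=None)
    @given(
        counts=st.lists(st.integers(min_value=0, max_value=1000), min_size=2, max_size=200),
        k=st.integers(min_value=1, max_value=10),
    )
    def test_greedy_windows_partition_the_curve(self, counts, k):
        counts = np.asarray(counts, dtype=float)
        if counts.sum() < k:
            return
        win = om.equal_count_windows(counts, k)
        assert win.edges[0] == 0 and win.edges[-1] == counts.size
        assert np.all(np.diff(win.edges) >= 0)
        assert win.totals.sum() == pytest.approx(counts.sum())

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            om.equal_count_windows(np.zeros(5), 2)


class TestFitHomogeneous:
    def test_noise_free_round_trip(self, geom):
        t = np.arange(5.0, 12000.0, 10.0)
        truth = om.OpticalProperties(mua=0.08, musp=12.0)
        irf = om.gaussian_irf(600.0, 10.0)
        model = om.convolve_irf(
            TimeResolvedCurve(t, om.slab_transmittance(truth, geom, t)), irf
        )
        fit = om.fit_homogeneous(model, irf, geom)
        assert fit.converged
        assert fit.props.mua == pytest.approx(0.08, rel=1e-3)
        assert fit.props.musp == pytest.approx(12.0, rel=1e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_poisson_million_count_recovery(self, geom, seed):
        t = np.arange(5.0, 12000.0, 10.0)
        truth = om.OpticalProperties(mua=0.08, musp=12.0)
        irf = om.gaussian_irf(600.0, 10.0)
        model = om.convolve_irf(
            TimeResolvedCurve(t, om.slab_transmittance(truth, geom, t)), irf
        )
        noisy = om.add_poisson_noise(model, 1e6, seed=seed)
        fit = om.fit_homogeneous(noisy, irf, geom)
        assert fit.converged
        assert fit.props.mua == pytest.approx(0.08, rel=0.02)
        assert fit.props.musp == pytest.approx(12.0, rel=0.05)

    def test_pure_irf_curve_is_rejected(self, geom):
        t = np.arange(5.0, 12000.0, 10.0)
        irf = om.gaussian_irf(600.0, 10.0)
        sigma = 600.0 / 2.355
        pure = TimeResolvedCurve(t, 1e6 * np.exp(-0.5 * ((t - 1500.0) / sigma) ** 2))
        fit = om.fit_homogeneous(pure, irf, geom)
        assert not fit.converged
        assert fit.message

    def test_sparse_curve_rejected(self, geom):
        t = np.arange(5.0, 500.0, 10.0)
        irf = om.gaussian_irf(460.0, 10.0)
        with pytest.raises(ValueError):
            om.fit_homogeneous(TimeResolvedCurve(t, np.ones_like(t)), irf, geom)


class TestDeltaMuaEstimation:
    def test_identical_curves_give_zero(self):
        assert om.estimate_delta_mua(100.0, 100.0, 1.3) == 0.0

    def test_log_ratio_unit_case(self):
        assert om.estimate_delta_mua(100.0, 100.0 * np.e, 1.0) == pytest.approx(1.0)

    def test_positive_inputs_required(self):
        with pytest.raises(ValueError):
            om.estimate_delta_mua(0.0, 10.0, 1.0)
        with pytest.raises(ValueError):
            om.estimate_delta_mua(10.0, 10.0, 0.0)

    def test_closed_loop_constant_kernel_exact(self, props, geom):
        """With a window-constant kernel the gated inversion recovers the
        planted contrast to machine precision."""
        t = np.arange(5.0, 12000.0, 10.0)
        t0 = om.slab_transmittance(props, geom, t)
        l0 = 1.7
        kernel = PathlengthKernel(t, np.full_like(t, l0))
        dmua = 0.0432
        tp = t0 * np.exp(-dmua * kernel.l_of_t)
        win = om.equal_count_windows(t0, 10)
        sl = win.window_slice(8)
        lw = window_pathlength(kernel, t0, win, 8)
        est = om.estimate_delta_mua(tp[sl].sum(), t0[sl].sum(), lw)
        assert est == pytest.approx(dmua, rel=1e-10)

    def test_closed_loop_physical_kernel(self, props, geom):
        """With the physical (time-varying) kernel the count-weighted window
        average introduces only a tiny exponential-averaging bias."""
        t = np.arange(5.0, 12000.0, 10.0)
        pert = om.SphericalPerturbation(center=(0, 0, 2.0), radius=0.5, delta_mua=0.05)
        kernel = om.partial_pathlength(props, geom, pert, t, quadrature_order=8)
        t0 = om.slab_transmittance(props, geom, t)
        tp = t0 * np.exp(-0.05 * kernel.l_of_t)
        win = om.equal_count_windows(t0, 10)
        sl = win.window_slice(8)
        lw = window_pathlength(kernel, t0, win, 8)
        est = om.estimate_delta_mua(tp[sl].sum(), t0[sl].sum(), lw)
        assert est == pytest.approx(0.05, rel=1e-3)

    def test_estimator_bias_shrinks_with_counts(self, props, geom):
        """Consistency: the mean gated estimate approaches the truth as the
        photon budget grows."""
        t = np.arange(5.0, 12000.0, 10.0)
        pert = om.SphericalPerturbation(center=(0, 0, 2.0), radius=0.5, delta_mua=0.05)
        kernel = om.partial_pathlength(props, geom, pert, t, quadrature_order=8)
        t0 = om.slab_transmittance(props, geom, t)
        tp = t0 * np.exp(-0.05 * kernel.l_of_t)
        win = om.equal_count_windows(t0, 10)
        sl = win.window_slice(8)
        lw = window_pathlength(kernel, t0, win, 8)
        spreads = []
        for counts in (1e5, 1e6, 1e7):
            ref = TimeResolvedCurve(t, t0)
            les = TimeResolvedCurve(t, tp)
            ests = []
            for s in range(12):
                nref = om.add_poisson_noise(ref, counts, seed=s)
                nles = om.add_poisson_noise(les, counts, seed=1000 + s)
                ests.append(
                    om.estimate_delta_mua(nles.counts[sl].sum(), nref.counts[sl].sum(), lw)
                )
            spreads.append(np.abs(np.mean(ests) - 0.05) + np.std(ests))
        assert spreads[2] < spreads[0]

    def test_late_window_pathlength_exceeds_early(self, props, geom):
        """Late photons spend more path in a mid-slab inclusion: l averaged
        over window 8 exceeds window 2 on the default geometry."""
        t = np.arange(5.0, 12000.0, 10.0)
        pert = om.SphericalPerturbation(center=(0, 0, 2.0), radius=0.5)
        kernel = om.partial_pathlength(props, geom, pert, t, quadrature_order=8)
        t0 = om.slab_transmittance(props, geom, t)
        win = om.equal_count_windows(t0, 10)
        l8 = window_pathlength(kernel, t0, win, 8)
        l2 = window_pathlength(kernel, t0, win, 2)
        assert l8 > l2
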