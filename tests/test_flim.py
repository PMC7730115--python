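"""Decay model and fitting: forward-model oracles, recovery, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import flimchip as fc
from flimchip.flim import DecayHistogram, FitOptions


def simulate_pixel(alpha1, tau1, tau2, photons, irf, acq, rng, background=0.005):
    lam = fc.model_decay(alpha1, tau1, tau2, background, photons, irf, acq.time_grid_ps)
    return DecayHistogram(rng.poisson(lam), acq.bin_width_ps)


class TestModelDecay:
    def test_matches_oversampled_convolution_oracle(self, irf, acq):
        """Brute-force convolution on a 40x finer grid, re-binned, agrees
        to better than 0.5% of the peak per bin."""
        os = 40
        dt = acq.bin_width_ps
        tf = (np.arange(acq.n_time_bins * os) + 0.5) * dt / os
        sigma = 244.0 / (2 * np.sqrt(2 * np.log(2)))
        irf_fine = np.exp(-0.5 * ((tf - 1000.0) / sigma) ** 2)
        irf_fine /= irf_fine.sum()
        for a1, t1, t2 in [(0.7, 400, 2500), (1.0, 2100, 2101), (0.3, 300, 2300)]:
            decay = a1 * np.exp(-(tf - tf[0]) / t1) + (1 - a1) * np.exp(-(tf - tf[0]) / t2)
            ref = np.convolve(irf_fine, decay)[: tf.size].reshape(-1, os).sum(axis=1)
            ref = ref / ref.sum() * 1e5
            ours = fc.model_decay(a1, t1, t2, 0.0, 1e5, irf, acq.time_grid_ps)
            assert np.max(np.abs(ours - ref)) / ref.max() < 5e-3

    def test_delta_irf_gives_pure_exponential(self, acq):
        with pytest.warns(RuntimeWarning):
            delta = fc.make_irf(1.0, acq.bin_width_ps / 2, acq)
        t = acq.time_grid_ps
        out = fc.model_decay(1.0, 800.0, 2500.0, 0.0, 1000.0, delta, t)
        # proportional to e^(-t/tau) after the impulse bin (the impulse
        # bin itself only contains half a bin of decay)
        ratio = out[1:] / np.exp(-(t[1:] - t[0]) / 800.0)
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-6)

    def test_equal_lifetimes_degenerate_to_mono(self, irf, acq):
        t = acq.time_grid_ps
        bi = fc.model_decay(0.5, 1500.0, 1500.0, 2.0, 1e4, irf, t)
        mono = fc.model_decay(1.0, 1500.0, 3000.0, 2.0, 1e4, irf, t)  # tau2 weight 0
        np.testing.assert_allclose(bi, mono, rtol=1e-12)

    def test_amplitude_is_total_signal_photons(self, irf, acq):
        out = fc.model_decay(0.6, 400.0, 2500.0, 0.0, 12345.0, irf, acq.time_grid_ps)
        assert out.sum() == pytest.approx(12345.0)


class TestMeanLifetime:
    @pytest.mark.parametrize(
        "a1,a2,t1,t2,expected",
        [(0.5, 0.5, 500, 2500, 1500.0), (1.0, 0.0, 700, 2500, 700.0),
         (0.25, 0.75, 400, 2400, 1900.0)],
    )
    def test_weighted_sum(self, a1, a2, t1, t2, expected):
        assert fc.mean_lifetime(a1, a2, t1, t2) == pytest.approx(expected)

    def test_rejects_unnormalized_fractions(self):
        with pytest.raises(ValueError):
            fc.mean_lifetime(0.5, 0.6, 400, 2500)

    @given(
        a1=st.floats(0.0, 1.0),
        t1=st.floats(50.0, 1500.0),
        t2=st.floats(800.0, 6000.0),
    )
    @settings(derandomize=True, max_examples=50)
    def test_mean_lifetime_brackets_components(self, a1, t1, t2):
        tm = fc.mean_lifetime(a1, 1.0 - a1, t1, t2)
        assert min(t1, t2) - 1e-9 <= tm <= max(t1, t2) + 1e-9


class TestFitDecay:
    def test_mono_standard_recovered_within_three_percent(self, irf, acq):
        """The daily fluorescence standard: mono-exponential 2.1 ns decays
        at ~1e5 photons, fit with the single-exponential model."""
        rng = np.random.default_rng(42)
        taus = []
        for _ in range(7):
            hist = simulate_pixel(1.0, 2100.0, 2100.0, 1e5, irf, acq, rng, 0.01)
            res = fc.fit_decay(hist, irf, FitOptions(model="mono"))
            assert res.converged
            taus.append(res.tau_m_ps)
        assert abs(np.mean(taus) - 2100.0) / 2100.0 < 0.03

    def test_noiseless_biexponential_recovered_exactly(self, irf, acq):
        lam = fc.model_decay(0.7, 400.0, 2500.0, 0.0, 1e5, irf, acq.time_grid_ps)
        res = fc.fit_decay(DecayHistogram(lam, acq.bin_width_ps), irf, FitOptions())
        assert res.tau1_ps == pytest.approx(400.0, rel=1e-4)
        assert res.tau2_ps == pytest.approx(2500.0, rel=1e-4)
        assert res.alpha1 == pytest.approx(0.7, abs=1e-4)
        assert res.tau_m_ps == pytest.approx(1030.0, rel=1e-4)

    def test_parameter_recovery_bias_at_high_photons(self, irf, acq):
        """Over 50 simulated pixels at 1e5 photons: |bias| of tau_m < 3%
        and of alpha1 < 0.05 absolute versus programmed truth."""
        rng = np.random.default_rng(7)
        tms, a1s = [], []
        for _ in range(50):
            res = fc.fit_decay(
                simulate_pixel(0.7, 400.0, 2500.0, 1e5, irf, acq, rng), irf, FitOptions()
            )
            tms.append(res.tau_m_ps)
            a1s.append(res.alpha1)
        assert abs(np.mean(tms) - 1030.0) / 1030.0 < 0.03
        assert abs(np.mean(a1s) - 0.7) < 0.05

    def test_chi2_reduced_near_unity_when_model_correct(self, irf, acq):
        rng = np.random.default_rng(3)
        chi2 = [
            fc.fit_decay(
                simulate_pixel(0.7, 400.0, 2500.0, 1e4, irf, acq, rng), irf, FitOptions()
            ).chi2_reduced
            for _ in range(20)
        ]
        assert 0.7 < np.mean(chi2) < 1.5

    def test_nls_beats_coarse_grid_search(self, irf, acq):
        """Oracle: exhaustive coarse grid over (tau1, tau2) with amplitudes
        and background profiled by non-negative weighted least squares."""
        from scipy.optimize import nnls

        rng = np.random.default_rng(11)
        hist = simulate_pixel(0.7, 400.0, 2500.0, 1e4, irf, acq, rng)
        counts = hist.counts.astype(float)
        w = 1.0 / np.maximum(counts, 1.0)
        t = acq.time_grid_ps
        best = np.inf
        for tau1 in np.arange(200.0, 701.0, 50.0):
            for tau2 in np.arange(1800.0, 3201.0, 100.0):
                c1 = fc.model_decay(1.0, tau1, tau1, 0.0, 1.0, irf, t)
                c2 = fc.model_decay(1.0, tau2, tau2, 0.0, 1.0, irf, t)
                X = np.stack([c1, c2, np.ones_like(t) / t.size], axis=1)
                sw = np.sqrt(w)
                coef, _ = nnls(X * sw[:, None], counts * sw)
                chi2 = float(((X @ coef - counts) ** 2 * w).sum())
                best = min(best, chi2)
        res = fc.fit_decay(hist, irf, FitOptions())
        fit_chi2 = res.chi2_reduced * (counts.size - 5)
        assert fit_chi2 <= best + 1e-6

    def test_too_few_photons_returns_flagged_result(self, irf, acq):
        hist = DecayHistogram(np.ones(acq.n_time_bins), acq.bin_width_ps)
        res = fc.fit_decay(hist, irf, FitOptions(min_photons_per_fit=500))
        assert not res.fitted and not res.converged
        assert np.isnan(res.tau_m_ps)
        assert res.n_photons == acq.n_time_bins

    def test_result_invariants_on_random_pixels(self, irf, acq):
        rng = np.random.default_rng(19)
        for _ in range(10):
            a1 = rng.uniform(0.3, 0.9)
            t1 = rng.uniform(200, 800)
            t2 = rng.uniform(1500, 3500)
            res = fc.fit_decay(simulate_pixel(a1, t1, t2, 2e4, irf, acq, rng), irf)
            assert res.alpha1 + res.alpha2 == pytest.approx(1.0)
            assert res.tau1_ps <= res.tau2_ps
            assert res.tau1_ps - 1e-9 <= res.tau_m_ps <= res.tau2_ps + 1e-9
            assert res.C >= 0

    def test_mono_fit_matches_bi_fit_on_degenerate_decay(self, irf, acq):
        rng = np.random.default_rng(23)
        hist = simulate_pixel(0.5, 1400.0, 1400.0, 1e5, irf, acq, rng)
        mono = fc.fit_decay(hist, irf, FitOptions(model="mono"))
        bi = fc.fit_decay(hist, irf, FitOptions())
        assert bi.tau_m_ps == pytest.approx(mono.tau_m_ps, rel=0.02)


class TestFitImage:
    def test_single_cell_median_taum_recovered(self, small_geometry, irf):
        acq = fc.AcquisitionConfig(photons_per_bright_pixel=2000.0)
        scene = fc.generate_scene(
            fc.SceneConfig(density_label="low", geometry=small_geometry, seed=6, n_cells=1)
        )
        stack, _ = fc.render_flim_stack(scene, "NADPH", irf, acq, seed=8)
        maps = fc.fit_image(stack, irf, FitOptions())
        true_tm = scene.cells[0].channel_params["NADPH"].tau_m_ps
        est = np.nanmedian(maps["tau_m_ps"])
        assert abs(est - true_tm) / true_tm < 0.05

    def test_all_background_image_fully_masked(self, irf, acq):
        stack = np.random.default_rng(0).poisson(0.01, size=(acq.n_time_bins, 8, 8))
        maps = fc.fit_image(stack, irf, FitOptions())
        assert not maps["mask"].any()
        assert np.isnan(maps["tau_m_ps"]).all()

    def test_binning_recovers_pixels_below_threshold(self, small_geometry, irf):
        acq = fc.AcquisitionConfig(photons_per_bright_pixel=120.0)
        scene = fc.generate_scene(
            fc.SceneConfig(density_label="low", geometry=small_geometry, seed=6, n_cells=3)
        )
        stack, _ = fc.render_flim_stack(scene, "NADPH", irf, acq, seed=8)
        unbinned = fc.fit_image(stack, irf, FitOptions(binning_radius_px=0))
        binned = fc.fit_image(stack, irf, FitOptions(binning_radius_px=1))
        assert binned["mask"].sum() >= unbinned["mask"].sum()
        assert binned["mask"].sum() > 0

    def test_intensity_map_is_unbinned_total_photons(self, irf, acq):
        rng = np.random.default_rng(1)
        stack = rng.poisson(2.0, size=(acq.n_time_bins, 5, 5))
        maps = fc.fit_image(stack, irf, FitOptions())
        np.testing.assert_array_equal(maps["intensity"], stack.sum(axis=0))


class TestEstimateFwhm:
    def test_gaussian_sigma_conversion(self, acq):
        t = acq.time_grid_ps
        sigma = 103.6  # FWHM 244 ps
        samples = np.exp(-0.5 * ((t - 3000.0) / sigma) ** 2)
        est = fc.estimate_fwhm(samples, acq.bin_width_ps)
        assert abs(est - 244.0) <= acq.bin_width_ps

    def test_single_impulse_at_most_one_bin(self):
        s = np.zeros(64)
        s[30] = 5.0
        assert fc.estimate_fwhm(s, 10.0) <= 10.0

    @pytest.mark.parametrize("k", [2, 5, 11])
    def test_rectangular_pulse_width(self, k):
        s = np.zeros(64)
        s[20 : 20 + k] = 3.0
        assert abs(fc.estimate_fwhm(s, 10.0) - k * 10.0) <= 10.0

    def test_flat_input_rejected(self):
        with pytest.raises(ValueError):
            fc.estimate_fwhm(np.ones(32), 10.0)

    @given(
        fwhm=st.floats(150.0, 2000.0),
        center=st.floats(2000.0, 10000.0),
    )
    @settings(derandomize=True, max_examples=30)
    def test_fwhm_recovered_for_any_gaussian(self, fwhm, center, acq):
        t = acq.time_grid_ps
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
        samples = np.exp(-0.5 * ((t - center) / sigma) ** 2)
        est = fc.estimate_fwhm(samples, acq.bin_width_ps)
        assert abs(est - fwhm) <= acq.bin_width_ps
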