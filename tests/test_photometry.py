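"""Photometry: Gaussian scan-line fits, bleach-step detection and
calibration, bleaching correction, cluster sizing and rate fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from kymoquant.config import OpticsConfig
from kymoquant.photometry import (Calibration, ScanlineFit,
                                  bleach_correction_factor,
                                  bleach_step_amplitudes,
                                  calibrate_single_fluorophore,
                                  detect_bleach_steps, estimate_bleach_rate,
                                  estimate_cluster_size, fit_power_exponent,
                                  fit_profile, fit_scanline, measure_clusters)
from kymoquant.synthetic import (Kymograph, make_cascade_truth,
                                 make_static_cluster_truth, render_kymograph)


def _gauss_kymo(amplitude, n_lines=1, sd_nm=100.0, bg=0.0, noise_rng=None):
    """Kymograph whose every line is the same Gaussian profile (+ optional Poisson)."""
    x = (np.arange(54) + 0.5) * 0.075
    lam = amplitude * np.exp(-0.5 * ((x - 2.0) / (sd_nm * 1e-3)) ** 2) + bg
    field = np.tile(lam, (n_lines, 1))
    counts = noise_rng.poisson(field) if noise_rng is not None else np.round(field)
    return Kymograph(counts=counts, pixel_size=75.0, line_period=0.02)


class TestScanlineFit:
    def test_exact_gaussian_recovered(self):
        kymo = _gauss_kymo(600.0)  # integer rounding negligible at this height
        fit = fit_scanline(kymo, 0)
        assert fit.ok
        assert fit.amplitude == pytest.approx(600.0, abs=1.0)
        assert fit.center == pytest.approx(2.0, abs=1e-3)
        assert fit.width == pytest.approx(100.0, rel=0.02)

    def test_flat_background_gives_near_zero_amplitude(self):
        kymo = Kymograph(counts=np.full((1, 40), 7), pixel_size=75.0, line_period=0.02)
        fit = fit_scanline(kymo, 0)
        assert fit.amplitude == pytest.approx(0.0, abs=0.5)

    def test_noisy_bright_cluster_amplitude_within_2pct(self, rng):
        # 100-line average of a Poisson-noised amplitude-402 profile
        kymo = _gauss_kymo(402.0, n_lines=100, bg=0.5, noise_rng=rng)
        fit = fit_scanline(kymo, 50, row_band=100)
        assert fit.amplitude == pytest.approx(402.0, rel=0.02)

    def test_window_validation(self):
        kymo = _gauss_kymo(10.0)
        with pytest.raises(ValueError):
            fit_scanline(kymo, 0, window=(0, 3))
        with pytest.raises(ValueError):
            fit_scanline(kymo, 5)


class TestBleachSteps:
    def test_single_noiseless_drop_detected(self):
        trace = np.r_[np.full(60, 6.0), np.full(60, 4.5)]
        steps = detect_bleach_steps(trace, line_period=0.02)
        assert len(steps) == 1
        t, size = steps[0]
        assert size == pytest.approx(1.5, abs=1e-9)
        assert t == pytest.approx(60 * 0.02, abs=0.02)

    def test_constant_trace_has_no_steps(self):
        assert detect_bleach_steps(np.full(100, 5.0)) == []

    def test_short_trace_rejected(self):
        with pytest.raises(ValueError):
            detect_bleach_steps(np.ones(10))

    def test_four_fluorophore_cascade_recovers_step_size(self):
        # generator truth: 4 x 1.5-photon steps, Poisson noise
        optics = OpticsConfig(bleach_rate_at_reference=0.1)
        rng = np.random.default_rng(21)
        steps = []
        for _ in range(12):
            truth = make_cascade_truth(optics=optics)
            kymo = render_kymograph(truth, optics, seed=rng)
            steps.extend(bleach_step_amplitudes(kymo))
        assert len(steps) >= 30
        assert np.mean(steps) == pytest.approx(1.5, rel=0.15)


class TestCalibration:
    def test_nominal_calibration_values(self):
        cal = calibrate_single_fluorophore([1.5, 1.5, 1.5])
        assert cal.photons_per_fluor == 1.5
        assert cal.photons_per_tetramer == 6.0

    def test_mean_of_steps(self):
        cal = calibrate_single_fluorophore([1.0, 2.0])
        assert cal.photons_per_fluor == 1.5
        assert cal.n_steps_used == 2

    def test_no_steps_is_an_error(self):
        with pytest.raises(ValueError):
            calibrate_single_fluorophore([])

    @given(st.floats(min_value=1e-3, max_value=1e3, allow_nan=False))
    @settings(max_examples=50, deadline=None)
    def test_tetramer_identity_bit_exact(self, ppf):
        cal = Calibration(photons_per_fluor=ppf)
        assert cal.photons_per_tetramer == 4 * ppf


class TestBleachCorrection:
    def test_identity_at_time_zero(self, rng):
        kymo = _gauss_kymo(50.0, n_lines=40, bg=1.0, noise_rng=rng)
        assert bleach_correction_factor(kymo, 0.0) == 1.0

    def test_exponential_decay_gives_exponential_factor(self):
        k, dt = 0.1, 0.02
        t = np.arange(400) * dt
        lam = 1000.0 * np.exp(-k * t)
        counts = np.round(lam)[:, None] * np.ones((1, 10))
        kymo = Kymograph(counts=counts, pixel_size=75.0, line_period=dt)
        t_q = 4.0
        corr = bleach_correction_factor(kymo, t_q, band_lines=1)
        assert corr == pytest.approx(np.exp(k * t_q), rel=0.01)

    def test_constant_intensity_gives_unity_everywhere(self):
        kymo = Kymograph(counts=np.full((100, 10), 9), pixel_size=75.0, line_period=0.02)
        for t in (0.0, 0.5, 1.9):
            assert bleach_correction_factor(kymo, t) == 1.0


class TestClusterSize:
    def test_single_tetramer(self):
        cal = Calibration(photons_per_fluor=1.5)
        fit = ScanlineFit(6.0, 1.0, 100.0, 0.0, 0.0)
        assert estimate_cluster_size(fit, cal, 1.0).tetramers == pytest.approx(1.0)

    @pytest.mark.parametrize("amp,corr", [(402.0, 1.0), (201.0, 2.0)])
    def test_67_tetramer_worked_examples(self, amp, corr):
        cal = Calibration(photons_per_fluor=1.5)
        fit = ScanlineFit(amp, 1.0, 100.0, 0.0, 0.0)
        assert estimate_cluster_size(fit, cal, corr).tetramers == pytest.approx(67.0)

    @given(st.floats(0.1, 1e4), st.floats(1.0, 10.0))
    @settings(max_examples=50, deadline=None)
    def test_linear_in_amplitude_and_correction(self, amp, corr):
        cal = Calibration(photons_per_fluor=1.5)
        base = estimate_cluster_size(ScanlineFit(amp, 0, 100, 0, 0), cal, corr).tetramers
        double_amp = estimate_cluster_size(ScanlineFit(2 * amp, 0, 100, 0, 0), cal, corr).tetramers
        double_corr = estimate_cluster_size(ScanlineFit(amp, 0, 100, 0, 0), cal, 2 * corr).tetramers
        assert double_amp == pytest.approx(2 * base, rel=1e-12)
        assert double_corr == pytest.approx(2 * base, rel=1e-12)

    def test_correction_below_one_rejected(self):
        cal = Calibration(photons_per_fluor=1.5)
        with pytest.raises(ValueError):
            estimate_cluster_size(ScanlineFit(6, 0, 100, 0, 0), cal, 0.5)

    @pytest.mark.parametrize("size", [20, 67, 160])
    def test_known_cluster_sizes_recovered_within_10pct(self, size):
        # end-to-end photometric recovery, mean over 50 rendered clusters
        optics = OpticsConfig()
        cal = Calibration(photons_per_fluor=1.5)
        rng = np.random.default_rng(size)
        est = []
        for _ in range(10):
            truth = make_static_cluster_truth([size] * 5, duration=4.0,
                                              optics=optics, seed=rng)
            kymo = render_kymograph(truth, optics, seed=rng)
            est.extend(e.tetramers for e in measure_clusters(kymo, 0, cal))
        assert len(est) >= 50
        assert np.mean(est) == pytest.approx(size, rel=0.10)


class TestRates:
    def test_noiseless_decay_recovers_nominal_rate(self):
        k, dt = 5e-5, 10.0
        t = np.arange(1000) * dt
        lam = 2000.0 * np.exp(-k * t)
        kymo = Kymograph(counts=np.round(lam)[:, None] * np.ones((1, 5)),
                         pixel_size=75.0, line_period=dt)
        rate, flag = estimate_bleach_rate(kymo)
        assert flag == "ok"
        assert rate == pytest.approx(5e-5, rel=0.01)

    def test_constant_trace_flagged_non_decaying(self):
        kymo = Kymograph(counts=np.full((200, 5), 40), pixel_size=75.0, line_period=1.0)
        rate, flag = estimate_bleach_rate(kymo)
        assert rate == 0.0 and flag == "non_decaying"

    def test_power_exponent_worked_examples(self):
        p = np.array([2.0, 4.0, 8.0])
        assert fit_power_exponent(p**2, p) == pytest.approx(2.0, abs=1e-9)
        assert fit_power_exponent(3.0 * p, p) == pytest.approx(1.0, abs=1e-9)

    def test_power_exponent_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            fit_power_exponent([0.0, 1.0], [1.0, 2.0])

    def test_quadratic_power_dependence_from_generator(self):
        from kymoquant.recovery import recover_power_exponent
        out = recover_power_exponent(seed=3)
        assert out["exponent"] == pytest.approx(2.0, rel=0.10)
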