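"""Welch spectra, log-resampling, robust slope fitting, and band power."""

import numpy as np
import pytest
from scipy import signal

from aperiodic_net import spectral
from aperiodic_net.spectral import Spectrum, band_power, fit_slope, log_resample, welch_psd
from aperiodic_net.synthcohort import Oscillation, SyntheticTruth, generate_recording

from conftest import make_recording

SFREQ = 512.0


def power_law_spectrum(exponent, scale=1.0, fmax=256.0, n_channels=1):
    freqs = np.arange(0.0, fmax + 1)
    power = np.zeros_like(freqs)
    power[1:] = scale * freqs[1:] ** exponent
    power[0] = power[1]
    return Spectrum(
        freqs=freqs,
        power=np.tile(power, (n_channels, 1)),
        labels=[f"ch{i:02d}" for i in range(n_channels)],
    )


class TestWelch:
    def test_zero_signal_gives_zero_psd(self):
        spec = welch_psd(make_recording(np.zeros((10 * 512, 2))))
        assert np.all(spec.power == 0)

    def test_sinusoid_peak_at_10hz(self, sine_recording):
        spec = welch_psd(sine_recording)
        assert spec.freqs[np.argmax(spec.power[0])] == 10.0

    def test_white_noise_parseval(self, rng):
        x = rng.normal(0, 3.0, size=(180 * 512, 1))
        spec = welch_psd(make_recording(x))
        total = np.trapezoid(spec.power[0], spec.freqs)
        assert abs(total - 9.0) / 9.0 < 0.05

    def test_matches_scipy_welch(self, rng):
        """Independent oracle: scipy's Welch on a single whole-record segment."""
        x = rng.normal(size=(30 * 512, 3))
        spec = welch_psd(make_recording(x))
        f_ref, p_ref = signal.welch(
            x, fs=SFREQ, window="hamming", nperseg=512, noverlap=256, detrend=False, axis=0
        )
        np.testing.assert_allclose(spec.freqs, f_ref)
        np.testing.assert_allclose(spec.power, p_ref.T, rtol=1e-10)

    def test_windows_respect_segment_boundaries(self, rng):
        """Splitting a record into 3 clean segments barely changes the slope."""
        truth = SyntheticTruth(n_channels=1, duration=180, aperiodic_exponent=1.5, seed=7)
        rec = generate_recording(truth)
        n = rec.n_samples
        whole = fit_slope(welch_psd(rec)).slope
        rec_split = make_recording(
            rec.data, segments=[(0, n // 3), (n // 3, 2 * n // 3), (2 * n // 3, n)]
        )
        split = fit_slope(welch_psd(rec_split)).slope
        assert abs(whole[0] - split[0]) < 0.02

    def test_no_fitting_segment_errors(self):
        rec = make_recording(np.zeros((2048, 2)), segments=[(0, 100), (200, 400)])
        with pytest.raises(ValueError, match="window"):
            welch_psd(rec)


class TestLogResample:
    def test_power_law_is_exact(self):
        spec = power_law_spectrum(-2.0)
        grid, p = log_resample(spec)
        np.testing.assert_allclose(p[0], grid**-2.0, rtol=1e-12)

    def test_two_points_returns_endpoints(self):
        spec = power_law_spectrum(-1.0)
        grid, p = log_resample(spec, 2, 45, n_points=2)
        np.testing.assert_allclose(grid, [2.0, 45.0])
        np.testing.assert_allclose(p[0], [0.5, 1 / 45], rtol=1e-12)

    def test_resample_then_ols_recovers_analytic_slope(self):
        spec = power_law_spectrum(-1.3, scale=3.0)
        grid, p = log_resample(spec)
        slope = np.polyfit(np.log10(grid), np.log10(p[0]), 1)[0]
        assert abs(slope - (-1.3)) < 1e-9

    def test_nonpositive_fmin_errors(self):
        with pytest.raises(ValueError):
            log_resample(power_law_spectrum(-1.0), fmin=0.0)

    def test_raw_power_interpolation_variant(self):
        """Interpolating raw power reproduces on-grid values and stays positive."""
        spec = power_law_spectrum(-2.0)
        grid, p = log_resample(spec, 2, 32, n_points=5, interp_log_power=False)
        np.testing.assert_allclose(grid, [2, 4, 8, 16, 32])
        np.testing.assert_allclose(p[0], grid**-2.0, rtol=1e-12)  # grid hits integer bins
        _, p_dense = log_resample(spec, 2, 45, interp_log_power=False)
        assert np.all(p_dense > 0)


class TestFitSlope:
    def test_pure_power_law_exact(self):
        fit = fit_slope(power_law_spectrum(-2.0))
        assert abs(fit.slope[0] - (-2.0)) < 1e-9
        assert fit.excluded_mask.sum() == 0

    def test_gaussian_bump_excluded_and_slope_preserved(self):
        freqs = np.arange(0.0, 257)
        power = np.zeros_like(freqs)
        power[1:] = freqs[1:] ** -1.5
        power[0] = power[1]
        bump = 1.0 + 4.0 * np.exp(-((freqs - 10.0) ** 2) / (2 * 1.5**2))
        spec = Spectrum(freqs=freqs, power=(power * bump)[None, :], labels=["c"])
        fit = fit_slope(spec)
        assert abs(fit.slope[0] - (-1.5)) < 0.05
        in_bump = (fit.log_freqs >= 8) & (fit.log_freqs <= 12)
        assert fit.excluded_mask[0, in_bump].all()

    def test_scale_invariance(self):
        base = power_law_spectrum(-1.5)
        scaled = Spectrum(freqs=base.freqs, power=base.power * 1000, labels=base.labels)
        f0, f1 = fit_slope(base), fit_slope(scaled)
        assert abs(f0.slope[0] - f1.slope[0]) < 1e-9
        assert abs((f1.intercept[0] - f0.intercept[0]) - 3.0) < 1e-9

    def test_monotone_in_exponent(self):
        slopes = [fit_slope(power_law_spectrum(-b)).slope[0] for b in (0.5, 1.0, 1.5, 2.0, 2.5)]
        assert np.all(np.diff(slopes) < 0)

    def test_alpha_bump_robustness(self):
        """A x10 alpha bump moves the fitted slope by < 0.1."""
        truth_plain = SyntheticTruth(
            n_channels=1, duration=180, aperiodic_exponent=1.5, seed=11
        )
        truth_bump = SyntheticTruth(
            n_channels=1,
            duration=180,
            aperiodic_exponent=1.5,
            oscillations=[Oscillation(10.0, 1.5, 10.0, ("ch00",))],
            seed=11,
        )
        s_plain = fit_slope(welch_psd(generate_recording(truth_plain))).slope[0]
        s_bump = fit_slope(welch_psd(generate_recording(truth_bump))).slope[0]
        assert abs(s_plain - s_bump) < 0.1

    def test_nonpositive_power_errors(self):
        spec = power_law_spectrum(-1.0)
        spec.power[0, 20] = 0.0
        with pytest.raises(ValueError):
            fit_slope(spec)

    @pytest.mark.parametrize("beta", [1.0, 2.0])
    def test_recovery_on_synthetic_recordings(self, beta):
        """Fitted slope ~ -beta on realistic synthetic spectra with bumps."""
        errs = []
        for seed in range(5):
            truth = SyntheticTruth(
                n_channels=1,
                duration=180,
                aperiodic_exponent=beta,
                oscillations=[
                    Oscillation(10.0, 1.5, 4.0, ("ch00",)),
                    Oscillation(20.0, 2.0, 2.0, ("ch00",)),
                ],
                seed=100 + seed,
            )
            fit = fit_slope(welch_psd(generate_recording(truth)))
            errs.append(abs(fit.slope[0] - (-beta)))
        assert np.mean(errs) < 0.1


class TestBandPower:
    def test_aperiodic_only_residual_is_zero(self):
        spec = power_law_spectrum(-2.0)
        fit = fit_slope(spec)
        bp = band_power(spec, fit)
        assert abs(bp.residual[0]) < 1e-9

    def test_flat_psd_raw_power(self):
        spec = Spectrum(
            freqs=np.arange(0.0, 257), power=np.full((1, 257), 4.0), labels=["c"]
        )
        bp = band_power(spec, None)
        assert bp.raw[0] == 4.0

    def test_bump_residual_equals_mean_log_bump(self):
        freqs = np.arange(0.0, 257)
        power = np.zeros_like(freqs)
        power[1:] = freqs[1:] ** -2.0
        power[0] = power[1]
        bump = 1.0 + 3.0 * np.exp(-((freqs - 20.0) ** 2) / (2 * 2.0**2))
        spec = Spectrum(freqs=freqs, power=(power * bump)[None, :], labels=["c"])
        fit_ref = fit_slope(power_law_spectrum(-2.0))  # true aperiodic line
        bp = band_power(spec, fit_ref)
        in_band = (freqs >= 13) & (freqs <= 30)
        expected = np.log10(bump[in_band]).mean()
        assert abs(bp.residual[0] - expected) < 1e-9

    def test_band_edges_inclusive(self):
        spec = power_law_spectrum(-1.0)
        bp = band_power(spec, None, band=(13, 30))
        manual = spec.power[0, (spec.freqs >= 13) & (spec.freqs <= 30)]
        assert manual.size == 18
        assert bp.raw[0] == pytest.approx(manual.mean())

    def test_band_outside_spectrum_errors(self):
        with pytest.raises(ValueError):
            band_power(power_law_spectrum(-1.0), None, band=(300, 400))
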