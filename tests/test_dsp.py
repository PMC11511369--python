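"""Filter response, envelopes, averaged spectra, band levels, SNR spectra."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pestpulse.dsp import (
    BandSpec,
    DEFAULT_BAND,
    SpectrumEstimate,
    average_spectrum,
    band_level,
    bandpass_filter,
    butterworth_magnitude,
    hilbert_envelope,
    rms,
    snr_spectrum,
    spectrogram,
)
from pestpulse.exceptions import BandError, DegenerateSignalError, PestpulseError

RATE = 24000.0


def _sine(freq, amp=1.0, duration=2.0, rate=RATE):
    t = np.arange(int(duration * rate)) / rate
    return amp * np.sin(2 * np.pi * freq * t)


def _interior(x, frac=0.1):
    n = len(x)
    k = int(n * frac)
    return x[k : n - k]


def _reference_magnitude(f_hz: float, f1: float, f2: float, n: int) -> float:
    """Independent desk evaluation of the band-pass magnitude response."""
    w, w1, w2 = (2 * math.pi * v for v in (f_hz, f1, f2))
    x = (w1 * w2 - w * w) / (w * (w2 - w1))
    return 1.0 / math.sqrt(1.0 + x ** (2 * n))


class TestButterworthMagnitude:
    @pytest.mark.parametrize("order", [1, 2, 5, 10])
    def test_center_and_edge_identities(self, order):
        """Unity at the geometric center; 1/sqrt(2) at both edges, any order."""
        band = BandSpec(500.0, 6000.0, order)
        assert butterworth_magnitude(band.center, band) == pytest.approx(1.0, rel=1e-12)
        assert butterworth_magnitude(500.0, band) == pytest.approx(
            1 / math.sqrt(2), rel=1e-9
        )
        assert butterworth_magnitude(6000.0, band) == pytest.approx(
            1 / math.sqrt(2), rel=1e-9
        )

    @pytest.mark.parametrize("f", [100.0, 300.0, 1000.0, 3000.0, 8000.0, 20000.0])
    def test_matches_independent_evaluation(self, f):
        band = BandSpec(500.0, 6000.0, 10)
        assert butterworth_magnitude(f, band) == pytest.approx(
            _reference_magnitude(f, 500.0, 6000.0, 10), rel=1e-12
        )

    def test_limits_and_domain(self):
        band = DEFAULT_BAND
        assert butterworth_magnitude(0.0, band) == 0.0
        assert butterworth_magnitude(1e9, band) < 1e-12
        with pytest.raises(PestpulseError):
            butterworth_magnitude(-1.0, band)

    def test_band_validation(self):
        with pytest.raises(BandError):
            BandSpec(6000.0, 500.0)
        with pytest.raises(BandError):
            BandSpec(500.0, 6000.0, 0)


class TestBandpassFilter:
    def test_zero_in_zero_out(self):
        out = bandpass_filter(np.zeros(48000), RATE, DEFAULT_BAND)
        assert np.allclose(out, 0.0)

    @pytest.mark.parametrize("f", [800.0, 1200.0, 1732.05, 2500.0, 4000.0, 5000.0])
    def test_in_band_gain_matches_squared_magnitude(self, f):
        """Zero-phase two-pass gain equals the squared closed-form response."""
        out = bandpass_filter(_sine(f), RATE, DEFAULT_BAND)
        # sqrt(2)*RMS estimates sinusoid amplitude without phase-grid bias
        gain = math.sqrt(2) * rms(_interior(out))
        expected = butterworth_magnitude(f, DEFAULT_BAND) ** 2
        assert gain == pytest.approx(expected, rel=0.01)

    def test_out_of_band_rejection_exceeds_60db(self):
        out = bandpass_filter(_sine(50.0), RATE, DEFAULT_BAND)
        level = 20 * np.log10(np.max(np.abs(_interior(out))) + 1e-300)
        assert level < -60.0

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(BandError):
            bandpass_filter(np.zeros(48000), RATE, BandSpec(500.0, 13000.0))

    def test_too_short_signal_rejected(self):
        with pytest.raises(DegenerateSignalError):
            bandpass_filter(np.zeros(10), RATE, DEFAULT_BAND)


class TestHilbertEnvelope:
    def test_zero_signal_gives_zero_envelope(self):
        env = hilbert_envelope(np.zeros(48000), RATE)
        assert np.allclose(env.values, 0.0)

    def test_in_band_sinusoid_envelope_is_its_amplitude(self):
        """Analytic signal of a sinusoid has constant modulus = amplitude."""
        env = hilbert_envelope(_sine(2000.0, amp=0.8), RATE)
        inner = _interior(env.values)
        assert np.all(np.abs(inner - 0.8) < 0.008)

    def test_am_signal_envelope_tracks_modulation(self):
        t = np.arange(int(4 * RATE)) / RATE
        x = (1 + 0.5 * np.cos(2 * np.pi * 5 * t)) * np.sin(2 * np.pi * 2000 * t)
        env = hilbert_envelope(x, RATE)
        expected = np.abs(1 + 0.5 * np.cos(2 * np.pi * 5 * t))
        inner = slice(int(0.1 * len(t)), int(0.9 * len(t)))
        assert np.max(np.abs(env.values[inner] - expected[inner]) / expected[inner]) < 0.02

    def test_edge_guard_recorded(self):
        env = hilbert_envelope(np.zeros(48000), RATE)
        assert env.edge_guard == 1024
        assert env.interior.size == 48000 - 2048

    def test_empty_signal_rejected(self):
        with pytest.raises(DegenerateSignalError):
            hilbert_envelope(np.array([]), RATE)


class TestRms:
    def test_constant_is_its_magnitude(self):
        assert rms(np.full(10, 2.5)) == pytest.approx(2.5, rel=1e-12)
        assert rms(np.full(10, -2.5)) == pytest.approx(2.5, rel=1e-12)

    def test_hand_case(self):
        assert rms(np.array([3.0, 4.0])) == pytest.approx(math.sqrt(12.5), rel=1e-12)

    def test_unit_gaussian_monte_carlo(self, rng):
        assert rms(rng.standard_normal(10**6)) == pytest.approx(1.0, abs=0.01)

    def test_empty_rejected(self):
        with pytest.raises(DegenerateSignalError):
            rms(np.array([]))

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(deadline=None, max_examples=25)
    def test_positive_homogeneity(self, g):
        x = np.array([0.5, -1.5, 2.0, 0.0])
        assert rms(g * x) == pytest.approx(g * rms(x), rel=1e-9)


class TestAverageSpectrum:
    def test_peak_bin_at_sinusoid_frequency(self):
        spec = average_spectrum(_sine(1500.0, duration=4.0), RATE)
        assert abs(spec.freqs[np.argmax(spec.psd)] - 1500.0) <= spec.df / 2

    def test_psd_scales_with_amplitude_squared(self, rng):
        x = rng.standard_normal(50000)
        a, b = average_spectrum(x, RATE), average_spectrum(3.0 * x, RATE)
        np.testing.assert_allclose(b.psd, 9.0 * a.psd, rtol=1e-9)

    def test_white_noise_parseval_and_flatness(self, rng):
        """60 s of unit-variance noise: integral = variance, flat in band."""
        x = rng.standard_normal(int(60 * RATE))
        spec = average_spectrum(x, RATE)
        assert np.sum(spec.psd) * spec.df == pytest.approx(1.0, rel=0.05)
        band = spec.psd[(spec.freqs >= 500) & (spec.freqs <= 6000)]
        assert np.max(band) / np.min(band) < 1.5

    def test_window_metadata(self):
        spec = average_spectrum(_sine(1000.0), RATE)
        assert spec.window_size == 1024
        assert spec.window_kind == "blackmanharris"
        assert spec.n_segments == 1 + (48000 - 1024) // 512

    def test_short_signal_rejected(self):
        with pytest.raises(DegenerateSignalError):
            average_spectrum(np.zeros(512), RATE)


class TestSpectrogram:
    def test_silence_gives_zero_grid(self):
        _, _, sxx = spectrogram(np.zeros(48000), RATE)
        assert np.allclose(sxx, 0.0)

    def test_single_pulse_localized_in_time(self):
        x = np.zeros(int(60 * RATE))
        i0 = int(30 * RATE)
        t = np.arange(400) / RATE
        x[i0 : i0 + 400] = np.exp(-t / 0.005) * np.sin(2 * np.pi * 2500 * t)
        freqs, times, sxx = spectrogram(x, RATE)
        col_energy = np.sum(sxx**2, axis=0)
        assert abs(times[np.argmax(col_energy)] - 30.0) < 0.05

    def test_stationary_sinusoid_has_flat_row(self):
        freqs, times, sxx = spectrogram(_sine(3000.0, duration=4.0), RATE)
        row = sxx[np.argmin(np.abs(freqs - 3000.0))]
        assert np.max(row) / np.min(row) < 1.05


class TestBandLevel:
    def test_amplitude_doubling_adds_six_db(self, rng):
        x = rng.standard_normal(48000)
        a = band_level(average_spectrum(x, RATE), 500, 6000)
        b = band_level(average_spectrum(2 * x, RATE), 500, 6000)
        assert b - a == pytest.approx(20 * math.log10(2), abs=1e-9)

    def test_unit_noise_full_band_is_zero_db(self, rng):
        x = rng.standard_normal(int(60 * RATE))
        spec = average_spectrum(x, RATE)
        assert band_level(spec, 0.0, RATE / 2) == pytest.approx(0.0, abs=0.3)

    def test_half_of_flat_band_is_three_db_down(self):
        """On an idealized flat spectrum, halving the band halves the power."""
        freqs = np.arange(0.0, 1001.0)
        spec = SpectrumEstimate(freqs, np.ones_like(freqs), 1024, "blackmanharris", 1)
        full = band_level(spec, 0.5, 1000.5)
        half = band_level(spec, 0.5, 500.5)
        assert full - half == pytest.approx(10 * math.log10(2), abs=1e-9)

    def test_empty_band_rejected(self):
        spec = average_spectrum(_sine(1000.0), RATE)
        with pytest.raises(BandError):
            band_level(spec, 300.0, 300.01)


class TestSnrSpectrum:
    def test_identical_spectra_give_zero_db(self, rng):
        spec = average_spectrum(rng.standard_normal(48000), RATE)
        np.testing.assert_allclose(snr_spectrum(spec, spec), 0.0, atol=1e-12)

    def test_power_scaling_shifts_uniformly(self, rng):
        x = rng.standard_normal(48000)
        sig = average_spectrum(np.sqrt(10.0) * x, RATE)
        ref = average_spectrum(x, RATE)
        np.testing.assert_allclose(snr_spectrum(sig, ref), 10.0, atol=1e-9)

    def test_zero_reference_bin_flagged_not_fatal(self):
        freqs = np.array([0.0, 1.0, 2.0])
        sig = SpectrumEstimate(freqs, np.array([1.0, 1.0, 1.0]), 4, "boxcar", 1)
        ref = SpectrumEstimate(freqs, np.array([1.0, 0.0, 2.0]), 4, "boxcar", 1)
        out = snr_spectrum(sig, ref)
        assert np.isnan(out[1]) and np.isfinite(out[0]) and np.isfinite(out[2])

    def test_grid_mismatch_rejected(self, rng):
        a = average_spectrum(rng.standard_normal(48000), RATE, window_size=1024)
        b = average_spectrum(rng.standard_normal(48000), RATE, window_size=512)
        with pytest.raises(PestpulseError):
            snr_spectrum(a, b)


class TestInBandPulseSnr:
    def test_pulse_train_snr_concentrates_in_carrier_band(self, rng):
        """Pulses over noise lift the SNR spectrum inside the analysis band."""
        n = int(30 * RATE)
        noise = 0.01 * rng.standard_normal(n)
        x = noise.copy()
        for onset in np.arange(1.0, 29.0, 1.5):
            i0 = int(onset * RATE)
            t = np.arange(600) / RATE
            x[i0 : i0 + 600] += 0.5 * np.exp(-t / 0.008) * np.sin(2 * np.pi * 2500 * t)
        snr = snr_spectrum(
            average_spectrum(x, RATE), average_spectrum(noise, RATE)
        )
        freqs = average_spectrum(x, RATE).freqs
        in_band = snr[(freqs > 1500) & (freqs < 3500)]
        out_band = snr[(freqs > 9000) & (freqs < 11000)]
        assert np.median(in_band) > 3.0
        assert np.median(out_band) < 1.0
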