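"""Band-pass filtering, Hilbert envelopes, averaged spectra and band levels.

The analysis chain for insect vibro-acoustic pulses is: Butterworth
band-pass (default 500-6000 Hz, order 10) -> analytic-signal envelope ->
normalization -> pulse/energy metrics.  This module provides the filter, the
envelope, RMS, Welch-averaged power spectral densities with the 1024-sample
Blackman-Harris window, band-integrated levels in dB, and per-frequency SNR
spectra (signal PSD over reference PSD).

Filtering is zero-phase (forward-backward), so envelope peaks stay aligned
with pulse onsets; the effective magnitude response is the square of the
single-pass Butterworth response, putting the band edges at -6 dB.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .exceptions import BandError, DegenerateSignalError, PestpulseError

__all__ = [
    "BandSpec",
    "Envelope",
    "SpectrumEstimate",
    "DEFAULT_BAND",
    "EDGE_GUARD",
    "butterworth_magnitude",
    "bandpass_filter",
    "hilbert_envelope",
    "rms",
    "average_spectrum",
    "spectrogram",
    "band_level",
    "snr_spectrum",
]

#: Samples excluded at each end of an extracted envelope before any
#: downstream max/RMS: the discrete analytic signal and the filter
#: start-up are unreliable at the record boundaries.
EDGE_GUARD = 1024


@dataclass(frozen=True)
class BandSpec:
    """An analysis band for the Butterworth band-pass filter.

    Attributes
    ----------
    f_low, f_high
        Band edges in Hz (the -3 dB points of the single-pass response).
    order
        Filter order *n*: the exponent in the band-pass magnitude response
        ``M(w) = 1 / sqrt(1 + ((wc^2 - w^2) / (w * wd))^(2n))`` with center
        ``wc = sqrt(w1*w2)`` and width ``wd = w2 - w1``.
    """

    f_low: float
    f_high: float
    order: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.f_low < self.f_high:
            raise BandError(f"need 0 < f_low < f_high, got {self.f_low}, {self.f_high}")
        if self.order < 1:
            raise BandError(f"filter order must be >= 1, got {self.order}")

    @property
    def center(self) -> float:
        """Geometric center frequency sqrt(f_low * f_high) in Hz."""
        return float(np.sqrt(self.f_low * self.f_high))

    @property
    def width(self) -> float:
        return self.f_high - self.f_low

    def validate_rate(self, rate: float) -> None:
        if self.f_high >= rate / 2:
            raise BandError(
                f"band edge {self.f_high} Hz at or above Nyquist ({rate / 2} Hz)"
            )


#: Default analysis band: insect pulses carry most energy at 500-6000 Hz.
DEFAULT_BAND = BandSpec(500.0, 6000.0, 10)


@dataclass
class Envelope:
    """Instantaneous amplitude of a band-limited signal.

    ``edge_guard`` samples at each end are excluded by :attr:`interior`,
    which every downstream statistic uses.  Hand-constructed envelopes
    default to no guard.
    """

    values: np.ndarray
    rate: float
    band: BandSpec
    edge_guard: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.size == 0:
            raise DegenerateSignalError("empty envelope")
        if np.any(self.values < 0):
            raise PestpulseError("envelope values must be nonnegative")

    @property
    def interior(self) -> np.ndarray:
        """Envelope samples with the boundary guard stripped."""
        g = self.edge_guard
        return self.values[g : self.values.size - g] if g > 0 else self.values


@dataclass
class SpectrumEstimate:
    """One-sided averaged power spectral density.

    ``psd`` has units of (dimensionless amplitude)^2 per Hz, so integrating
    it over frequency recovers mean-square signal power (Parseval).
    """

    freqs: np.ndarray
    psd: np.ndarray
    window_size: int
    window_kind: str
    n_segments: int

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=np.float64)
        self.psd = np.asarray(self.psd, dtype=np.float64)
        if self.freqs.shape != self.psd.shape:
            raise PestpulseError("freqs and psd must have matching shapes")
        if np.any(self.psd < 0):
            raise PestpulseError("psd must be nonnegative")

    @property
    def df(self) -> float:
        return float(self.freqs[1] - self.freqs[0])


def butterworth_magnitude(f, band: BandSpec):
    """Closed-form single-pass Butterworth band-pass magnitude response.

    Evaluates ``M(w) = 1 / sqrt(1 + ((wc^2 - w^2)/(w*wd))^(2n))`` at
    ``w = 2*pi*f``.  Identities: M(center) = 1 and M(f_low) = M(f_high) =
    1/sqrt(2) for every order.  Accepts scalars or arrays; f must be >= 0.
    """
    f = np.asarray(f, dtype=np.float64)
    if np.any(f < 0):
        raise PestpulseError("frequency must be nonnegative")
    w = 2 * np.pi * f
    w1 = 2 * np.pi * band.f_low
    w2 = 2 * np.pi * band.f_high
    wc2 = w1 * w2
    wd = w2 - w1
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        x = (wc2 - w**2) / (w * wd)
        m = 1.0 / np.sqrt(1.0 + x ** (2 * band.order))
    m = np.where(w == 0, 0.0, m)
    m = np.where(np.isfinite(m), m, 0.0)  # overflow deep in the stopband -> 0
    return float(m) if m.ndim == 0 else m


def _design_sos(rate: float, band: BandSpec) -> np.ndarray:
    band.validate_rate(rate)
    return sps.butter(
        band.order, [band.f_low, band.f_high], btype="bandpass", fs=rate, output="sos"
    )


def bandpass_filter(x: np.ndarray, rate: float, band: BandSpec = DEFAULT_BAND) -> np.ndarray:
    """Zero-phase Butterworth band-pass.

    Applied forward and backward (second-order sections), so the effective
    gain is the squared single-pass magnitude and group delay cancels:
    envelope peaks keep their timing.  Output length equals input length.
    """
    x = np.asarray(x, dtype=np.float64)
    sos = _design_sos(rate, band)
    padlen = 3 * (2 * sos.shape[0] + 1)
    if x.ndim < 1 or x.shape[-1] <= padlen:
        raise DegenerateSignalError(
            f"signal of {x.shape[-1] if x.ndim else 0} samples shorter than "
            f"filter warm-up ({padlen + 1} samples)"
        )
    return sps.sosfiltfilt(sos, x, axis=-1)


def hilbert_envelope(
    x: np.ndarray,
    rate: float,
    band: BandSpec = DEFAULT_BAND,
    edge_guard: int = EDGE_GUARD,
) -> Envelope:
    """Band-pass filter ``x`` and return the analytic-signal envelope.

    The envelope is ``|x_bp + i*H{x_bp}|`` where H is the Hilbert transform
    of the band-pass-filtered signal: the instantaneous amplitude of the
    band-limited waveform.  For a pure in-band sinusoid of amplitude A the
    interior envelope is constant at A.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise DegenerateSignalError("empty signal")
    if not np.all(np.isfinite(x)):
        raise PestpulseError("signal contains non-finite samples")
    filtered = bandpass_filter(x, rate, band)
    env = np.abs(sps.hilbert(filtered))
    guard = int(min(edge_guard, x.size // 4))
    return Envelope(values=env, rate=rate, band=band, edge_guard=guard)


def rms(x: np.ndarray) -> float:
    """Root-mean-square sqrt(sum(x_i^2) / N)."""
    x = np.asarray(x, dtype=np.float64)
    if x.size == 0:
        raise DegenerateSignalError("RMS of empty sequence")
    return float(np.sqrt(np.mean(np.square(x))))


def average_spectrum(
    x: np.ndarray,
    rate: float,
    window_size: int = 1024,
    window_kind: str = "blackmanharris",
) -> SpectrumEstimate:
    """Welch-averaged one-sided PSD with 50% segment overlap.

    Defaults follow the analysis convention for 60 s records: 1024-sample
    Blackman-Harris window.  Each segment is mean-detrended before the FFT.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < window_size:
        raise DegenerateSignalError(
            f"signal of {x.size} samples shorter than one {window_size}-sample window"
        )
    noverlap = window_size // 2
    freqs, psd = sps.welch(
        x,
        fs=rate,
        window=sps.get_window(window_kind, window_size),
        nperseg=window_size,
        noverlap=noverlap,
        detrend="constant",
        scaling="density",
        return_onesided=True,
    )
    n_segments = 1 + (x.size - window_size) // (window_size - noverlap)
    return SpectrumEstimate(
        freqs=freqs,
        psd=psd,
        window_size=window_size,
        window_kind=window_kind,
        n_segments=n_segments,
    )


def spectrogram(
    x: np.ndarray,
    rate: float,
    window_size: int = 1024,
    window_kind: str = "blackmanharris",
):
    """Short-time magnitude spectrogram.

    Returns ``(freqs, times, magnitudes)`` with nonnegative magnitudes;
    squaring and averaging the columns is consistent with
    :func:`average_spectrum` up to the Welch normalization.
    """
    x = np.asarray(x, dtype=np.float64)
    if x.size < window_size:
        raise DegenerateSignalError(
            f"signal of {x.size} samples shorter than one {window_size}-sample window"
        )
    freqs, times, sxx = sps.spectrogram(
        x,
        fs=rate,
        window=sps.get_window(window_kind, window_size),
        nperseg=window_size,
        noverlap=window_size // 2,
        detrend="constant",
        mode="magnitude",
    )
    return freqs, times, sxx


def band_level(spec: SpectrumEstimate, f_low: float, f_high: float) -> float:
    """Band-integrated PSD level: ``10*log10(integral of psd over the band)``.

    The sound-pressure-level analogue for uncalibrated sensors; doubling the
    signal amplitude raises the level by 20*log10(2) ~ 6.02 dB.
    """
    if f_low >= f_high:
        raise BandError(f"need f_low < f_high, got {f_low}, {f_high}")
    mask = (spec.freqs >= f_low) & (spec.freqs <= f_high)
    if not np.any(mask):
        raise BandError(
            f"band [{f_low}, {f_high}] Hz contains no bins of the spectrum grid"
        )
    power = float(np.sum(spec.psd[mask]) * spec.df)
    if power <= 0:
        raise DegenerateSignalError(f"zero band power in [{f_low}, {f_high}] Hz")
    return float(10.0 * np.log10(power))


def snr_spectrum(
    signal_spec: SpectrumEstimate, reference_spec: SpectrumEstimate
) -> np.ndarray:
    """Per-frequency SNR in dB: ``10*log10(psd_signal / psd_reference)``.

    Bins where the reference PSD is zero are returned as NaN (undefined SNR)
    rather than raising.  Grids must match exactly.
    """
    if signal_spec.freqs.shape != reference_spec.freqs.shape or not np.allclose(
        signal_spec.freqs, reference_spec.freqs
    ):
        raise PestpulseError("SNR spectrum needs matching frequency grids")
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = 10.0 * np.log10(signal_spec.psd / reference_spec.psd)
    return np.where(reference_spec.psd > 0, ratio, np.nan)
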