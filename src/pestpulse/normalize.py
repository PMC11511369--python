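"""Noise-referenced envelope normalization.

Uncalibrated contact sensors report amplitudes in arbitrary units, so insect
pulse strength is expressed relative to the sensor's own noise floor.  Two
schemes are provided:

* **self-noise** -- divide the signal envelope by the RMS of the envelope of
  a matched reference recording captured with no insect present;
* **median** -- when no clean reference exists, treat every envelope sample
  strictly below the envelope median as noise and divide by the RMS of that
  below-median subset.

Both are invariant under a common amplitude gain applied to signal and
reference.  Note the two denominators are not numerically interchangeable:
for a Rayleigh-distributed noise envelope (Gaussian sensor noise) the
below-median RMS sits a fixed factor sqrt(1 - ln 2) ~ 0.554 (-5.13 dB)
below the full-envelope RMS, so median-normalized levels run systematically
higher by that constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dsp import BandSpec, Envelope, rms
from .exceptions import DegenerateSignalError, PestpulseError

__all__ = [
    "NormalizedEnvelope",
    "MEDIAN_SELF_NOISE_OFFSET_DB",
    "normalize_by_reference",
    "normalize_by_median",
]

#: Expected level of the median-method reference RMS relative to the
#: self-noise reference RMS for Gaussian sensor noise (Rayleigh envelope):
#: E[X^2 | X < median] / E[X^2] = 1 - ln 2, i.e.
#: 10*log10(1 - ln 2) ~ -5.13 dB.  See docs/methods.md for the derivation.
MEDIAN_SELF_NOISE_OFFSET_DB = float(10.0 * np.log10(1.0 - np.log(2.0)))


@dataclass
class NormalizedEnvelope:
    """A dimensionless envelope: raw envelope over a noise-reference RMS."""

    values: np.ndarray
    rate: float
    method: str  # "self_noise" | "median"
    reference_rms: float
    band: BandSpec

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.method not in ("self_noise", "median"):
            raise PestpulseError(f"unknown normalization method {self.method!r}")
        if not self.reference_rms > 0:
            raise DegenerateSignalError(
                f"reference RMS must be > 0, got {self.reference_rms}"
            )
        if self.values.size == 0:
            raise DegenerateSignalError("empty normalized envelope")


def normalize_by_reference(env: Envelope, ref_env: Envelope) -> NormalizedEnvelope:
    """Normalize an envelope by the RMS of a matched self-noise envelope.

    Both envelopes must come from the same band and rate.  Edge-guard
    regions of both are excluded.
    """
    if env.band != ref_env.band:
        raise PestpulseError(
            f"band mismatch: signal {env.band}, reference {ref_env.band}"
        )
    if env.rate != ref_env.rate:
        raise PestpulseError(
            f"rate mismatch: signal {env.rate} Hz, reference {ref_env.rate} Hz"
        )
    ref_rms = rms(ref_env.interior)
    if ref_rms <= 0:
        raise DegenerateSignalError("reference envelope has zero RMS")
    return NormalizedEnvelope(
        values=env.interior / ref_rms,
        rate=env.rate,
        method="self_noise",
        reference_rms=ref_rms,
        band=env.band,
    )


def normalize_by_median(env: Envelope) -> NormalizedEnvelope:
    """Normalize an envelope by the RMS of its below-median samples.

    The noise set is every interior envelope sample *strictly* below the
    interior median; ties at the median are excluded (measure-zero for
    continuous-valued envelopes).  Fails on constant envelopes, where the
    noise set is empty.
    """
    v = env.interior
    med = float(np.median(v))
    noise = v[v < med]
    if noise.size == 0:
        raise DegenerateSignalError(
            "degenerate envelope: no samples below the median (constant input?)"
        )
    ref_rms = rms(noise)
    if ref_rms <= 0:
        raise DegenerateSignalError("below-median noise subset has zero RMS")
    return NormalizedEnvelope(
        values=v / ref_rms,
        rate=env.rate,
        method="median",
        reference_rms=ref_rms,
        band=env.band,
    )
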