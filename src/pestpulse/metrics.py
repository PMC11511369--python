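"""Pulse-amplitude and spectral-energy detection metrics.

Two complementary signal-to-noise figures quantify insect activity in a
normalized record:

* **NSPA** (normalized strong-pulse amplitude): ``20*log10`` of the RMS of
  normalized-envelope samples lying between 50% and 90% of the record's
  envelope maximum.  Sensitive to sparse strong pulses.
* **NSEL** (normalized signal energy level): band-integrated PSD level of
  the signal minus that of the noise reference, in dB.  An averaged-energy
  measure, diluted when pulses are sparse -- on pulse-sparse records NSPA
  runs well above NSEL.

The channel with the highest NSPA is taken as the one closest to the
insect.  Batches of per-record results aggregate into per-(insect,
material) summary tables.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dsp import BandSpec, average_spectrum, band_level
from .exceptions import DegenerateSignalError, PestpulseError
from .normalize import NormalizedEnvelope

__all__ = [
    "MetricResult",
    "nspa",
    "qualifying_samples",
    "nsel",
    "best_channel",
    "summarize",
]

log = logging.getLogger(__name__)


@dataclass
class MetricResult:
    """Per-channel metric values with full provenance."""

    channel: int
    nspa_db: float | None
    nsel_db: float | None
    band: BandSpec
    method: str
    window_lo: float = 0.5
    window_hi: float = 0.9
    n_qualifying: int = 0
    reference_rms: float | None = None
    file: str | None = None
    insect: str | None = None
    material: str | None = None
    sensor: str | None = None
    status: str = "ok"
    error: str | None = None
    extra: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        """Flatten to a CSV/JSON-friendly record."""
        return {
            "file": self.file,
            "channel": self.channel,
            "insect": self.insect,
            "material": self.material,
            "sensor": self.sensor,
            "band_low": self.band.f_low,
            "band_high": self.band.f_high,
            "order": self.band.order,
            "method": self.method,
            "nspa_db": self.nspa_db,
            "nsel_db": self.nsel_db,
            "n_qualifying": self.n_qualifying,
            "reference_rms": self.reference_rms,
            "status": self.status,
            "error": self.error,
        }


def qualifying_samples(
    values: np.ndarray, window_lo: float = 0.5, window_hi: float = 0.9
) -> np.ndarray:
    """Envelope samples within the strong-pulse window [lo*max, hi*max].

    Both bounds are inclusive.  The window deliberately stops short of the
    maximum so a single extreme spike does not dominate the statistic.
    """
    if not 0 < window_lo < window_hi <= 1:
        raise PestpulseError(
            f"need 0 < window_lo < window_hi <= 1, got {window_lo}, {window_hi}"
        )
    values = np.asarray(values, dtype=np.float64)
    peak = float(np.max(values))
    if peak <= 0:
        raise DegenerateSignalError("all-zero envelope has no strong-pulse window")
    return values[(values >= window_lo * peak) & (values <= window_hi * peak)]


def nspa(
    nenv: NormalizedEnvelope, window_lo: float = 0.5, window_hi: float = 0.9
) -> float:
    """Normalized strong-pulse amplitude in dB.

    ``20*log10(RMS(Q))`` where Q are the normalized-envelope samples between
    ``window_lo`` and ``window_hi`` of the envelope maximum.  Raises
    :class:`DegenerateSignalError` when the window is empty (e.g. a constant
    envelope), never returns NaN.
    """
    q = qualifying_samples(nenv.values, window_lo, window_hi)
    if q.size == 0:
        raise DegenerateSignalError(
            "no envelope samples inside the strong-pulse window "
            f"[{window_lo:.2f}, {window_hi:.2f}] of the maximum"
        )
    return float(20.0 * np.log10(np.sqrt(np.mean(np.square(q)))))


def nsel(
    signal: np.ndarray,
    reference: np.ndarray,
    rate: float,
    f_low: float,
    f_high: float,
    window_size: int = 1024,
) -> float:
    """Normalized signal energy level in dB.

    Band-integrated PSD level of the signal minus that of the noise
    reference over ``[f_low, f_high]``; zero when the signal equals the
    reference.  PSDs are Welch-averaged (Blackman-Harris window).
    """
    sig_spec = average_spectrum(signal, rate, window_size=window_size)
    ref_spec = average_spectrum(reference, rate, window_size=window_size)
    return band_level(sig_spec, f_low, f_high) - band_level(ref_spec, f_low, f_high)


def best_channel(results: Sequence[MetricResult]) -> int:
    """Channel index with the highest NSPA; ties break to the lowest index.

    Channels with degenerate (missing) NSPA are excluded with a warning.
    """
    if not results:
        raise PestpulseError("best_channel needs at least one channel result")
    usable = [r for r in results if r.nspa_db is not None and np.isfinite(r.nspa_db)]
    skipped = [r.channel for r in results if r not in usable]
    if skipped:
        log.warning("best_channel: excluding degenerate channels %s", skipped)
    if not usable:
        raise DegenerateSignalError("no channel produced a finite NSPA")
    best = max(usable, key=lambda r: (r.nspa_db, -r.channel))
    return best.channel


def summarize(results: Iterable[MetricResult]) -> pd.DataFrame:
    """Aggregate labelled results into a per-(insect, material) table.

    Emits the arithmetic mean of the dB values plus the median and
    25th/75th percentiles (box-plot statistics), and the record count.
    Unlabelled fields group under ``"unknown"``; empty input yields an
    empty table.
    """
    rows = [r.to_row() for r in results if r.status == "ok"]
    if not rows:
        return pd.DataFrame()
    df = pd.DataFrame(rows)
    df["insect"] = df["insect"].fillna("unknown")
    df["material"] = df["material"].fillna("unknown")
    agg = df.groupby(["insect", "material"]).agg(
        nspa_mean=("nspa_db", "mean"),
        nspa_median=("nspa_db", "median"),
        nspa_q25=("nspa_db", lambda s: s.quantile(0.25)),
        nspa_q75=("nspa_db", lambda s: s.quantile(0.75)),
        nsel_mean=("nsel_db", "mean"),
        nsel_median=("nsel_db", "median"),
        nsel_q25=("nsel_db", lambda s: s.quantile(0.25)),
        nsel_q75=("nsel_db", lambda s: s.quantile(0.75)),
        n_records=("nspa_db", "size"),
    )
    return agg.reset_index()
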