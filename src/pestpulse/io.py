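"""Multi-channel WAV recording I/O.

A :class:`Recording` holds the sample matrix of one sensor capture together
with its sampling rate, per-channel roles (the stored-product detection rig
puts piezoelectric pickups on channels 0-3 and internal microphones on 4-7),
and free-form metadata labels (insect species, substrate material, sensor).

Integer PCM is normalized to the dimensionless range [-1, 1) by full-scale
division on read.  All downstream metrics are ratios against a noise
reference, so absolute gain never matters -- only consistency of the
convention does.
"""

from __future__ import annotations

import json
import wave
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.io import wavfile
from scipy.signal import resample_poly

from .exceptions import AudioFormatError, PestpulseError

__all__ = [
    "Recording",
    "CHANNEL_ROLES",
    "default_channel_roles",
    "read_recording",
    "write_recording",
    "segment",
]

#: Recognized channel roles.  The 8-channel detection-rig layout assigns
#: piezo pickups to channels 0-3 and internal microphones to 4-7; body
#: microphones (external noise sensing) are a separate role.
CHANNEL_ROLES = frozenset({"piezo_internal", "mic_internal", "mic_body", "unknown"})

_INT_FULL_SCALE = {np.dtype("int16"): 2.0**15, np.dtype("int32"): 2.0**31}


def default_channel_roles(n_channels: int) -> dict[int, str]:
    """Channel-role map for the standard 8-channel rig layout.

    Channels 0-3 are internal piezoelectric sensors, 4-7 internal
    microphones; anything beyond that is ``unknown``.
    """
    roles = {}
    for c in range(n_channels):
        if c < 4:
            roles[c] = "piezo_internal"
        elif c < 8:
            roles[c] = "mic_internal"
        else:
            roles[c] = "unknown"
    return roles


@dataclass
class Recording:
    """A multi-channel audio capture.

    Parameters
    ----------
    samples
        Array of shape ``(n_channels, n_samples)`` with dimensionless
        amplitudes (nominally within [-1, 1)).
    rate
        Sampling rate in Hz.
    roles
        Map channel index -> role string (see :data:`CHANNEL_ROLES`).
    meta
        Free-form labels (e.g. ``insect``, ``material``, ``sensor``).
    """

    samples: np.ndarray
    rate: float
    roles: dict[int, str] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=np.float64))
        if self.samples.ndim != 2 or self.samples.shape[1] == 0:
            raise PestpulseError("Recording needs a (n_channels, n_samples>0) matrix")
        if not (np.isfinite(self.rate) and self.rate > 0):
            raise PestpulseError(f"sampling rate must be finite and > 0, got {self.rate}")
        if not np.all(np.isfinite(self.samples)):
            raise PestpulseError("Recording contains non-finite samples")
        for c, role in self.roles.items():
            if role not in CHANNEL_ROLES:
                raise PestpulseError(f"unknown channel role {role!r} for channel {c}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        """Record length in seconds."""
        return self.n_samples / self.rate

    def channel(self, index: int) -> np.ndarray:
        return self.samples[index]


def _meta_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def read_recording(
    path: str | Path,
    channels: Sequence[int] | None = None,
    resample_to: float | None = None,
) -> Recording:
    """Read a WAV file into a :class:`Recording`.

    Integer PCM (16/24/32-bit) is divided by full scale so samples land in
    [-1, 1); IEEE-float files pass through unchanged.  A JSON sidecar
    ``<name>.wav.json`` with label metadata is loaded when present.

    Parameters
    ----------
    channels
        Optional channel indices to keep, preserved in the given order.
    resample_to
        If given, polyphase-resample every channel to this rate.  Off by
        default: recordings from foreign sensors are analyzed at native rate.
    """
    path = Path(path)
    if not path.exists():
        raise AudioFormatError(f"no such file: {path}")
    try:
        rate, data = wavfile.read(str(path))
    except Exception as exc:  # scipy raises bare ValueError on bad RIFF
        raise AudioFormatError(f"cannot read WAV file {path}: {exc}") from exc
    if data.size == 0:
        raise AudioFormatError(f"empty WAV file: {path}")

    data = np.atleast_2d(data.T if data.ndim == 2 else data)
    if data.dtype == np.uint8:  # 8-bit WAV is unsigned
        x = (data.astype(np.float64) - 128.0) / 128.0
    elif data.dtype in _INT_FULL_SCALE:
        x = data.astype(np.float64) / _INT_FULL_SCALE[data.dtype]
    elif np.issubdtype(data.dtype, np.floating):
        x = data.astype(np.float64)
    else:
        raise AudioFormatError(f"unsupported WAV sample format {data.dtype} in {path}")

    if channels is not None:
        channels = list(channels)
        bad = [c for c in channels if not 0 <= c < x.shape[0]]
        if bad:
            raise AudioFormatError(
                f"requested channels {bad} absent from {x.shape[0]}-channel file {path}"
            )
        x = x[channels]

    rate = float(rate)
    if resample_to is not None and resample_to != rate:
        frac = Fraction(resample_to / rate).limit_denominator(1000)
        x = resample_poly(x, frac.numerator, frac.denominator, axis=1)
        rate = float(resample_to)

    meta: dict = {}
    sidecar = _meta_sidecar(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())

    return Recording(
        samples=x,
        rate=rate,
        roles=default_channel_roles(x.shape[0]),
        meta=meta,
    )


def _write_pcm24(path: Path, rate: float, frames: np.ndarray) -> None:
    """Write 24-bit PCM via the stdlib wave module (scipy cannot write it)."""
    scaled = np.clip(np.round(frames * 2.0**23), -(2**23), 2**23 - 1).astype(np.int32)
    raw = scaled.astype("<i4").tobytes()
    # keep the low 3 of every 4 little-endian bytes
    buf = np.frombuffer(raw, dtype=np.uint8).reshape(-1, 4)[:, :3].tobytes()
    with wave.open(str(path), "wb") as w:
        w.setnchannels(frames.shape[1])
        w.setsampwidth(3)
        w.setframerate(int(round(rate)))
        w.writeframes(buf)


def write_recording(
    rec: Recording,
    path: str | Path,
    subtype: str = "FLOAT",
    write_meta: bool = True,
) -> None:
    """Write a :class:`Recording` as a WAV file.

    ``subtype`` is one of ``FLOAT`` (32-bit IEEE float, default), ``PCM_16``
    or ``PCM_24``.  Round-trip error through :func:`read_recording` is
    bounded by the format quantization step (2**-15 and 2**-23 respectively
    for the PCM subtypes).  Metadata is stored in a JSON sidecar.
    """
    path = Path(path)
    frames = rec.samples.T  # (n_samples, n_channels)
    try:
        if subtype == "FLOAT":
            wavfile.write(str(path), int(round(rec.rate)), frames.astype(np.float32))
        elif subtype == "PCM_16":
            scaled = np.clip(np.round(frames * 2.0**15), -(2**15), 2**15 - 1)
            wavfile.write(str(path), int(round(rec.rate)), scaled.astype(np.int16))
        elif subtype == "PCM_24":
            _write_pcm24(path, rec.rate, frames)
        else:
            raise AudioFormatError(f"unsupported write subtype {subtype!r}")
    except OSError as exc:
        raise AudioFormatError(f"cannot write {path}: {exc}") from exc
    if write_meta and rec.meta:
        _meta_sidecar(path).write_text(json.dumps(rec.meta, indent=1, sort_keys=True))


def segment(rec: Recording, t_start: float, t_stop: float) -> Recording:
    """Cut the half-open time window ``[t_start, t_stop)`` from all channels.

    The returned length is ``round((t_stop - t_start) * rate)`` samples, so
    adjacent segments partition the original sample sequence exactly.
    """
    if t_start >= t_stop:
        raise PestpulseError(f"t_start ({t_start}) must be < t_stop ({t_stop})")
    i0 = int(round(t_start * rec.rate))
    n = int(round((t_stop - t_start) * rec.rate))
    if i0 < 0 or i0 + n > rec.n_samples:
        raise PestpulseError(
            f"segment [{t_start}, {t_stop}) s outside recording of "
            f"{rec.duration:.3f} s"
        )
    return Recording(
        samples=rec.samples[:, i0 : i0 + n].copy(),
        rate=rec.rate,
        roles=dict(rec.roles),
        meta=dict(rec.meta),
    )
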