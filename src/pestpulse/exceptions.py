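"""Exception hierarchy for pestpulse."""


class PestpulseError(Exception):
    """Base class for all pestpulse errors."""


class AudioFormatError(PestpulseError):
    """Unreadable, empty, or unsupported audio container/encoding."""


class BandError(PestpulseError):
    """Analysis band invalid for the sampling rate (e.g. edge at or above Nyquist)."""


class DegenerateSignalError(PestpulseError):
    """A signal too short, constant, or silent for the requested operation."""
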