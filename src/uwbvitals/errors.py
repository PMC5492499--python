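"""Exception hierarchy shared across the package."""


class UwbVitalsError(Exception):
    """Base class for all package-specific errors."""


class FrameParseError(UwbVitalsError):
    """A frame file could not be parsed; the message names the offending row."""


class ConfigError(UwbVitalsError):
    """Missing or invalid configuration (unknown keys, bad metadata, ...)."""


class DimensionError(UwbVitalsError):
    """Vector/matrix length mismatch between a frame and a clutter state."""


class SingularityError(UwbVitalsError):
    """A design matrix was rank deficient where full rank is required."""


class StateError(UwbVitalsError):
    """Detector/clutter state machine was asked for something its history
    cannot provide (e.g. freezing further back than the buffer holds)."""


class ReconstructionError(UwbVitalsError):
    """Vital-signal reconstruction cannot proceed (no segmentable candidates
    or empty candidate set -- the 'motion too large' condition)."""
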