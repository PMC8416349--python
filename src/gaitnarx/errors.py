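"""Exception hierarchy shared across the package."""


class GaitNarxError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(GaitNarxError, ValueError):
    """Invalid configuration value (condition label, grid, interval, ...)."""


class RateError(GaitNarxError, ValueError):
    """A series was supplied at an unexpected sample rate."""


class LengthError(GaitNarxError, ValueError):
    """A series is too short (or degenerate) for the requested operation."""


class EventError(GaitNarxError, ValueError):
    """Required gait events are missing or unresolvable."""


class StructureError(GaitNarxError, ValueError):
    """Array shapes inconsistent with the network configuration."""


class NumericError(GaitNarxError, FloatingPointError):
    """Non-finite values encountered where finite ones are required."""


class DegenerateRangeError(GaitNarxError, ValueError):
    """A channel is constant where a non-degenerate min/max range is needed."""


class FoldError(GaitNarxError, ValueError):
    """Session cannot support the requested trial-blocked fold layout."""


class TrainingError(GaitNarxError, RuntimeError):
    """Training failed irrecoverably (e.g. every restart diverged)."""


class DataError(GaitNarxError, ValueError):
    """On-disk trial data violates the documented schema."""
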