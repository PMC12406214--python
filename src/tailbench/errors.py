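"""Exception types shared across the package."""


class TailbenchError(Exception):
    """Base class for package errors."""


class ConfigError(TailbenchError):
    """Invalid configuration; message names the offending field."""

    def __init__(self, field: str, message: str):
        self.field = field
        super().__init__(f"{field}: {message}")


class SchemaError(TailbenchError):
    """A tabular file does not conform to its declared schema."""


class SignalTooShortError(TailbenchError):
    """Read shorter than the minimum state durations."""


class InsufficientReadsError(TailbenchError):
    """Fewer observations than the statistic requires."""


class UnboundedPeakError(TailbenchError):
    """Density never falls below half of the main peak within the grid."""
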