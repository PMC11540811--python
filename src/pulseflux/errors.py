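"""Exception hierarchy.

Every error raised on purpose by this package derives from :class:`PulsefluxError`
so callers can catch pipeline failures without masking programming errors.
"""


class PulsefluxError(Exception):
    """Base class for all pulseflux errors."""


class ConfigurationError(PulsefluxError):
    """A configuration value is invalid; the message names the offending field."""


class ParameterError(PulsefluxError):
    """An operation was called with arguments outside its documented domain."""


class RecordingParseError(PulsefluxError):
    """A recording file is malformed.

    ``line`` is the 1-based line number of the offending row when known.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class PulseDetectionError(PulsefluxError):
    """No cardiac periodicity could be found in a signal."""


class DegeneratePulseError(PulsefluxError):
    """A pulse window is too short (or otherwise unusable) for feature extraction."""


class DegenerateRegressorError(PulsefluxError):
    """The independent variable has zero variance; the slope is undefined."""


class DataError(PulsefluxError):
    """Input data violate a physical expectation (e.g. non-positive mean perfusion)."""


class InputTooShortError(PulsefluxError):
    """Fewer pulses are available than the requested window length."""


class ValidationError(PulsefluxError):
    """A tabular input failed field validation; the message names row and field."""
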