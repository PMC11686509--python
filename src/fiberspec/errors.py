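"""Exception hierarchy shared across the package."""


class FiberspecError(Exception):
    """Base class for all package errors."""


class RangeError(FiberspecError, ValueError):
    """A biomarker value or ratio lies outside the admissible range."""


class ConfigError(FiberspecError, ValueError):
    """Invalid or inconsistent configuration."""


class ParameterError(FiberspecError, ValueError):
    """Invalid operation parameter (window sizes, fractions, ...)."""


class InputError(FiberspecError, ValueError):
    """Malformed or incomplete input data."""


class FitError(FiberspecError, RuntimeError):
    """A curve fit was degenerate or failed to converge."""


class CalibrationRequiredError(FiberspecError, RuntimeError):
    """An operation needs a calibration reference that is missing."""


class StateError(FiberspecError, RuntimeError):
    """Operation applied in an invalid object state (e.g. double correction)."""


class FormatError(FiberspecError, ValueError):
    """A file does not conform to the spectra/feature CSV or JSON dialect."""
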