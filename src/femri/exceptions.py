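"""Exception hierarchy shared across the pipeline stages."""


class FemriError(Exception):
    """Base class for all package errors."""


class ConfigurationError(FemriError, ValueError):
    """A phantom or run configuration violates its invariants."""


class InputError(FemriError, ValueError):
    """An input raster, table or parameter is malformed."""


class StateError(FemriError, RuntimeError):
    """An operation was called before a required prior step (e.g. stratification)."""


class DegenerateDesignError(FemriError, ValueError):
    """A regression design has no spread (all standards at one concentration)."""


class CalibrationError(FemriError, ValueError):
    """A fitted calibration is physically inadmissible (non-positive slope)."""


class UndefinedFrequencyError(FemriError, ZeroDivisionError):
    """A frequency was requested over an empty denominator population."""


class RasterIOError(FemriError, IOError):
    """Raster file could not be read or written; message carries the path."""


class PipelineError(FemriError, RuntimeError):
    """A pipeline stage failed; message names the stage."""
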