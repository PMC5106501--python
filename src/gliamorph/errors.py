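"""Exception hierarchy.

Every error raised by the package derives from :class:`GliamorphError` so
callers can catch pipeline failures with a single handler while still
distinguishing configuration mistakes from runtime measurement problems.
"""


class GliamorphError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GliamorphError):
    """Unknown preset, malformed config file, or inconsistent experiment setup."""


class ParameterError(GliamorphError):
    """A numeric parameter is outside its valid range."""


class FormatError(GliamorphError):
    """An input raster or file has an unsupported layout (e.g. multichannel)."""


class GenerationError(GliamorphError):
    """The synthetic generator could not satisfy the requested geometry."""


class CalibrationError(GliamorphError):
    """Density calibration could not reach the coverage target."""


class MeasurementError(GliamorphError):
    """A measurement is undefined for the given input (e.g. empty mask)."""


class UndefinedMeasureError(MeasurementError):
    """A ratio measurement has an empty denominator (e.g. empty region)."""


class SamplingError(GliamorphError):
    """Systematic sampling produced no usable frames."""


class DesignError(GliamorphError):
    """A sampling design is internally inconsistent (e.g. overlapping frames)."""


class InputError(GliamorphError):
    """A statistics-stage input table violates its contract."""
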