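"""Exception hierarchy for the wingpol pipeline.

Every anticipated failure mode maps to a distinct subclass so callers can
distinguish bad files from bad geometry from degenerate statistics.
"""


class WingpolError(Exception):
    """Base class for all wingpol-specific errors."""


class FormatError(WingpolError):
    """A file could not be read or violates the single-channel raster contract."""


class GeometryError(WingpolError):
    """Masks disagree in shape, or a region/cell has no usable pixels."""


class SpecError(WingpolError, ValueError):
    """A simulation or analysis parameter set is invalid."""


class ProtocolError(WingpolError):
    """A time-series is missing a required reference group or frame."""


class DegenerateDataError(WingpolError):
    """A statistic is undefined on the given data (e.g. zero variance)."""


class FitError(WingpolError):
    """A curve fit failed to converge from every starting point."""


class InsufficientSamplesError(WingpolError):
    """Too few boundary samples to evaluate the polarity statistic."""
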