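"""Exception hierarchy for the videba pipeline.

Every stage raises a subclass of :class:`VidebaError` so that the CLI can
abort with the stage name and a readable message instead of a traceback.
"""


class VidebaError(Exception):
    """Base class for all pipeline errors."""


class FormatError(VidebaError):
    """A file could not be parsed (malformed header, wrong shape, ...)."""


class ValidationError(VidebaError):
    """Parsed data violates an invariant (non-monotone time, bad window, ...)."""


class CalibrationError(VidebaError):
    """DLT calibration failed (too few points, degenerate geometry)."""


class ProjectionError(VidebaError):
    """A 3D point cannot be projected (denominator ~ 0)."""


class TriangulationError(VidebaError):
    """Stereo triangulation is degenerate for a sample."""


class InsufficientDataError(VidebaError):
    """A window or segment holds too few samples for the requested statistic."""


class FitError(VidebaError):
    """A statistical fit failed to converge or is undefined."""
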