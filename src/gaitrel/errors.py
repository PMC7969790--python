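"""Exception hierarchy.

Every error raised by the package derives from :class:`GaitrelError` so callers
can catch one base class; parameter/design problems additionally derive from
``ValueError``.
"""


class GaitrelError(Exception):
    """Base class for all package errors."""


class ParameterError(GaitrelError, ValueError):
    """An argument violates a precondition (negative sd, out-of-range percent, ...)."""


class DesignError(GaitrelError, ValueError):
    """A study table or design is malformed (unbalanced, duplicate ids, ...)."""


class CalibrationError(GaitrelError):
    """Standstill calibration failed (window too short, degenerate gravity vector)."""


class SegmentationError(GaitrelError):
    """Stride segmentation could not find at least two cycle events."""


class SelectionError(GaitrelError):
    """No window of steady strides satisfying the minimum-stride rule exists."""


class EventDetectionError(GaitrelError):
    """A pro/retraction event could not be located (flat cycle)."""


class PhaseError(GaitrelError):
    """Limb phasing is undefined (zero-variance cycle)."""


class UndefinedVarianceError(GaitrelError):
    """ICC/VPC requested with zero total variance."""
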