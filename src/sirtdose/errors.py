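"""Exception hierarchy for the dosimetry pipeline.

Every stage raises a subclass of :class:`SirtDoseError` so callers can
distinguish pipeline failures from programming errors.
"""


class SirtDoseError(Exception):
    """Base class for all package errors."""


class GridAlignmentError(SirtDoseError):
    """Two volumes do not live on the same voxel grid."""


class GeometryError(SirtDoseError):
    """Invalid or degenerate spatial configuration (e.g. tumor outside liver)."""


class DimensionalityError(SirtDoseError):
    """A volume on disk or in memory is not a 3D scalar field."""


class MetadataError(SirtDoseError):
    """Required spatial metadata (spacing, affine) missing or invalid."""


class CalibrationError(SirtDoseError):
    """Relative calibration impossible (e.g. zero counts in the region)."""


class ContourError(SirtDoseError):
    """Empty or inconsistent contour where a nonempty one is required."""


class ParameterError(SirtDoseError):
    """Out-of-range user parameter."""


class InsufficientDataError(SirtDoseError):
    """Too few observations for a statistical procedure."""


class CohortError(SirtDoseError):
    """Invalid synthetic-cohort request."""
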