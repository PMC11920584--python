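"""Exception hierarchy for rootcarve.

All package-specific failures derive from :class:`RootcarveError` so callers
(and the CLI) can distinguish validation problems from runtime/data problems.
"""


class RootcarveError(Exception):
    """Base class for all rootcarve errors."""


class ValidationError(RootcarveError, ValueError):
    """Invalid configuration or arguments detected before any computation."""


class InsufficientCorrespondencesError(ValidationError):
    """Fewer than four 3D-2D marker correspondences were supplied to PnP."""


class DegenerateGeometryError(RootcarveError):
    """Input geometry admits no unique solution (e.g. collinear points)."""


class UndefinedProjectionError(RootcarveError):
    """A world point coincides with the camera center."""


class ConstantImageError(RootcarveError):
    """Otsu thresholding needs at least two distinct intensity values."""


class InvalidThresholdError(ValidationError):
    """Hysteresis thresholds violate 0 <= low <= high."""


class InvalidSceneGeometryError(ValidationError):
    """Scene geometry is inconsistent (e.g. camera inside the canister)."""


class NoEvidenceError(ValidationError):
    """Carving was requested with zero views."""


class AlignmentError(ValidationError):
    """Per-view grids (silhouette vs. ray field) have inconsistent shapes."""


class UndefinedDensityError(RootcarveError):
    """Density is undefined because the reconstructed volume is missing/zero."""


class EmptyModelError(RootcarveError):
    """An operation that needs occupied voxels was called on an empty model."""


class GridMemoryError(RootcarveError):
    """A dense voxel grid would exceed the configured cell cap."""
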