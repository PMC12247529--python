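"""Exception types raised across the pipeline.

All are subclasses of built-in exception categories so that callers who do
not care about the distinction can catch ``ValueError`` / ``RuntimeError``.
"""


class DimensionalityError(ValueError):
    """Image does not have exactly three spatial dimensions."""


class GeometryError(ValueError):
    """Voxel grids or affines of paired images do not agree."""


class DegenerateInputError(ValueError):
    """Input carries no usable signal (e.g. constant image, empty brain mask)."""


class ConfigurationError(ValueError):
    """Requested operation is inconsistent with the provided configuration."""


class UndefinedMetricError(ValueError):
    """Metric is mathematically undefined for the given inputs (0/0)."""


class ZeroVarianceError(ValueError):
    """A statistic requiring spread was asked of zero-variance data."""


class InsufficientDataError(ValueError):
    """Fewer observations than the statistic requires."""


class LesionPlacementError(RuntimeError):
    """Phantom generator could not place a lesion inside the brain."""


class SegmenterUnavailableError(RuntimeError):
    """An external segmentation backend is not installed."""
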