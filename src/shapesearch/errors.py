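"""Exception hierarchy for shapesearch."""


class ShapeSearchError(Exception):
    """Base class for all shapesearch errors."""


class MapFormatError(ShapeSearchError):
    """An MRC file is unreadable or has an invalid header field."""


class DegenerateMapError(ShapeSearchError):
    """A density map has zero total mass or is otherwise unusable."""


class ImplausibleVolumeError(ShapeSearchError):
    """A volume rescale would require an implausibly large blow-up."""


class InfeasibleFitError(ShapeSearchError):
    """Requested mixture size exceeds the number of occupied voxels."""


class NumericalDegeneracyError(ShapeSearchError):
    """A covariance matrix is singular or numerically degenerate."""


class DegenerateProjectionError(ShapeSearchError):
    """Projection of an empty map was requested."""


class UndefinedCorrelationError(ShapeSearchError):
    """Correlation of a constant (zero-variance) image is undefined."""


class DegenerateRowError(ShapeSearchError):
    """A CC row is constant, so its Z-scores are undefined."""


class InsufficientLibraryError(ShapeSearchError):
    """Fewer than two library models: final scores are undefined."""


class DegenerateGeometryError(ShapeSearchError):
    """A distance matrix admits no positive-eigenvalue embedding."""


class DegenerateProfileError(ShapeSearchError):
    """A model's CC profile is constant, so PCC is undefined."""


class OutOfBoxError(ShapeSearchError):
    """A synthetic shape does not fit inside its simulation box."""
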