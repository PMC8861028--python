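"""Exception hierarchy.

Every error raised by the package derives from :class:`TarsalCTError`, so
callers can catch one type at a pipeline boundary and still discriminate
below it.
"""


class TarsalCTError(Exception):
    """Base class for all package errors."""


class FormatError(TarsalCTError):
    """A file could not be parsed in the declared image format."""


class MetadataError(TarsalCTError):
    """Required metadata (voxel spacing) is absent and no override was given."""


class ValidationError(TarsalCTError):
    """Tabular input violates the cohort schema; carries offending rows."""

    def __init__(self, message, rows=None):
        super().__init__(message)
        self.rows = rows if rows is not None else []


class GeometryError(TarsalCTError):
    """A phantom ellipsoid does not fit inside the voxel grid."""


class RangeError(TarsalCTError):
    """A numeric argument is outside its documented range."""


class DegenerateInputError(TarsalCTError):
    """Too little foreground to define an orientation."""


class AmbiguousAxisError(TarsalCTError):
    """The foreground is too isotropic for a principal axis to be meaningful."""


class LandmarkError(TarsalCTError):
    """No bone landmark could be located along the slice axis."""


class ThresholdError(TarsalCTError):
    """Histogram too degenerate to suggest a segmentation threshold."""


class ContractError(TarsalCTError):
    """Arguments violate an inter-argument contract (e.g. shape mismatch)."""


class DesignError(TarsalCTError):
    """The cohort design cannot support the requested statistical test."""


class SingularFitError(TarsalCTError):
    """A regression design matrix is singular (e.g. constant predictor)."""
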