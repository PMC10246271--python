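"""Exception types shared across the package."""


class FCMarkerError(ValueError):
    """Base class for all package-specific errors."""


class InvalidAtlasError(FCMarkerError):
    """Atlas definition is unusable (too few ROIs, missing labels, ...)."""


class EdgeIndexError(FCMarkerError, IndexError):
    """An (i, j) ROI pair does not address a valid upper-triangle edge."""


class AlignmentError(FCMarkerError):
    """Participant table and connectivity matrix do not describe the same subjects."""


class DataValidationError(FCMarkerError):
    """A dataset violates a structural invariant (non-finite values, bad codes, ...)."""


class QualityError(FCMarkerError):
    """Too little usable data survives a quality-control step."""


class ConfigError(FCMarkerError):
    """A simulation or pipeline configuration is internally inconsistent."""


class DimensionError(FCMarkerError):
    """Edge dimensionality of a model and a dataset do not match."""
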