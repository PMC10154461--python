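"""Exception hierarchy shared across the pipeline.

Exit-code mapping for the CLI: ConfigError -> 2, any DataError -> 3.
"""


class RimshrinkError(Exception):
    """Base class for all package errors."""


class ConfigError(RimshrinkError):
    """Invalid configuration value or unknown policy name."""


class DataError(RimshrinkError):
    """Invalid or inconsistent input data."""


class GeometryError(DataError):
    """Volume/mask shape or spacing mismatch."""


class HeaderError(DataError):
    """Unusable volume header (e.g. non-positive voxel spacing)."""


class EmptyROIError(DataError):
    """A mask or derived ROI contains no foreground voxels."""

    def __init__(self, message, case_id=None, method=None):
        detail = message
        if case_id is not None:
            detail += f" [case_id={case_id}]"
        if method is not None:
            detail += f" [method={method}]"
        super().__init__(detail)
        self.case_id = case_id
        self.method = method


class VocabularyError(DataError):
    """Label outside the accepted two-class vocabulary."""


class IntegrityError(DataError):
    """Duplicate keys or malformed tabular input."""


class AlignmentError(DataError):
    """Two tables do not share the required case set."""


class InsufficientDataError(DataError):
    """Too few cases/pairs for the requested computation."""
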