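"""Exception hierarchy for cineshear."""


class CineShearError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CineShearError):
    """Invalid acquisition / analysis configuration."""


class OutOfDomainError(CineShearError):
    """A requested position lies outside the physical domain (lumen or grid)."""


class SegmentationError(CineShearError):
    """Lumen segmentation failed (degenerate features, collapsed contour, ...)."""


class FormatError(CineShearError):
    """On-disk container is malformed or misses required metadata."""

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        self.field = field
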