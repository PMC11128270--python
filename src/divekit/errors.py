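"""Exception hierarchy shared across the package."""


class DivekitError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DivekitError, ValueError):
    """A configuration value violates its documented constraints."""


class FormatError(DivekitError, ValueError):
    """An input file does not conform to the expected layout."""


class IntegrityError(DivekitError, ValueError):
    """Data are structurally valid but internally inconsistent."""


class ValidationError(DivekitError, ValueError):
    """A domain object violates its invariants."""


class OutOfRangeError(DivekitError, ValueError):
    """A query falls outside the supported span of the data."""


class GridMismatchError(DivekitError, ValueError):
    """Two gridded fields that must share a grid do not."""


class InsufficientDataError(DivekitError, ValueError):
    """Too few observations to perform the requested computation."""


class UnsupportedCRSError(DivekitError, ValueError):
    """A raster is not in an unprojected geographic coordinate system."""
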