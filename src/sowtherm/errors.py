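"""Exception hierarchy shared across the package.

All errors derive from :class:`SowthermError` so callers (and the CLI) can
catch package failures uniformly; each subclass also derives from the
closest builtin so plain ``except ValueError`` keeps working.
"""


class SowthermError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SowthermError, ValueError):
    """An invalid configuration value; the message names the field."""


class FormatError(SowthermError, ValueError):
    """A malformed input file; the message carries the offending line."""


class GeometryError(SowthermError, ValueError):
    """A region specification that does not fit the pixel grid."""


class ShapeMismatchError(SowthermError, ValueError):
    """Two pixel grids (or feature tables) with incompatible shapes."""


class EmptyRegionError(SowthermError, ValueError):
    """A mask selecting no usable pixels."""


class DomainError(SowthermError, ValueError):
    """Arguments outside the mathematical domain of an operation."""
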