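"""Exception hierarchy shared across the package."""


class StromaQuantError(Exception):
    """Base class for all package-specific failures."""


class UnsupportedFormatError(StromaQuantError):
    """Raised for image files of a bit depth or layout the reader does not accept."""


class ConfigError(StromaQuantError):
    """Raised when a configuration violates its invariants."""


class InsufficientDataError(StromaQuantError):
    """Raised when an operation is asked for a result that is undefined at the given n."""


class PlacementError(StromaQuantError):
    """Raised when synthetic objects cannot be placed without overlap."""
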