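"""Exception types shared across the package."""


class AmyloidscopeError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(AmyloidscopeError, ValueError):
    """Invalid parameter combination in a config or distribution spec."""


class PackingError(AmyloidscopeError, RuntimeError):
    """Sphere/cube placement could not satisfy the requested packing.

    Carries ``achieved`` (objects placed before giving up) and ``requested``.
    """

    def __init__(self, message: str, achieved: int, requested: int):
        super().__init__(message)
        self.achieved = achieved
        self.requested = requested


class FormatError(AmyloidscopeError, ValueError):
    """Malformed on-disk artifact (e.g. ragged TIFF stack, missing sidecar)."""


class SchemaError(AmyloidscopeError, ValueError):
    """Table or report does not match the expected column/key schema."""


class DegenerateInputError(AmyloidscopeError, ValueError):
    """Input is structurally valid but degenerate for the requested operation
    (e.g. a constant image passed to Otsu thresholding)."""
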