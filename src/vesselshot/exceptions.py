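"""Exception types shared across the package."""


class VesselshotError(ValueError):
    """Base class for all package-specific errors."""


class ParameterError(VesselshotError):
    """An operation received an invalid parameter value."""


class ShapeError(VesselshotError):
    """Array arguments have incompatible or unexpected shapes."""


class SizeError(VesselshotError):
    """An image is too small for the requested operation."""


class ConsistencyError(VesselshotError):
    """Related arguments disagree (counts, positions, class ids)."""


class SamplingError(VesselshotError):
    """An episode cannot be sampled from the given class library."""


class MissingAnnotationError(VesselshotError):
    """An image was supplied without its vessel or field-of-view mask."""


class ConfigurationError(VesselshotError):
    """An experiment configuration is invalid."""
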