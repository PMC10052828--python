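"""Exception hierarchy shared across the package."""


class IsletDeconError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(IsletDeconError):
    """A configuration object is structurally invalid or incomplete."""


class ValidationError(IsletDeconError, ValueError):
    """Input data violate a documented precondition."""


class FormatError(IsletDeconError):
    """An on-disk file does not conform to the expected format."""


class LowSupportWarning(UserWarning):
    """Too few observations to fit; the item is skipped, not failed."""
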