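"""Exception hierarchy shared across the package."""


class DigDiveError(Exception):
    """Base class for all package errors."""


class FormatError(DigDiveError):
    """A file does not conform to the expected on-disk format."""


class ValidationError(DigDiveError):
    """Input data violate a documented invariant or precondition."""


class ConfigError(DigDiveError):
    """A configuration value is missing, unknown or inconsistent."""


class NoMinimumError(DigDiveError):
    """The depth density has no strict local minimum below its mean.

    Raised by the dive-threshold search instead of silently falling back
    to a default; callers that have a configured fallback must apply it
    explicitly.
    """
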