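"""Exception types shared across the package."""


class FFNetError(Exception):
    """Base class for all package errors."""


class ValidationError(FFNetError, ValueError):
    """Input data violates a structural invariant (names the offending row/column)."""


class ConfigurationError(FFNetError, ValueError):
    """A configuration object or option is invalid."""
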