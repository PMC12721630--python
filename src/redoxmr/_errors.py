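"""Exception types shared across the package."""


class RedoxMrError(Exception):
    """Base class for package errors."""


class ConfigurationError(RedoxMrError):
    """A simulation or pipeline configuration is invalid."""


class DataError(RedoxMrError):
    """Input data violate a precondition (shape, sign, missingness)."""


class FitError(RedoxMrError):
    """A model fit is undefined, degenerate or non-identifiable."""
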