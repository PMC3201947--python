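"""Exception hierarchy shared across the package."""


class PathgwasError(Exception):
    """Base class for all package errors."""


class ValidationError(PathgwasError, ValueError):
    """Input data violates a documented invariant (bad row, bad value)."""


class ConfigurationError(PathgwasError, ValueError):
    """Run configuration is inconsistent (missing column, unknown code)."""
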