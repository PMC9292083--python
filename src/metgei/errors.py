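"""Exception types shared across the package."""


class MetError(Exception):
    """Base class for all package errors."""


class SchemaError(MetError):
    """A required column is missing or unmappable in an input file."""


class ValidationError(MetError):
    """Input data violate a structural invariant (duplicates, bad ranges)."""


class ConfigError(MetError):
    """A simulation or run configuration is internally inconsistent."""


class FitError(MetError):
    """A model fit failed or did not converge."""
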