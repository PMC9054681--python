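"""Exception hierarchy shared across the package.

Exit-code mapping used by the CLI: ValidationError family -> 1,
ComputationError family -> 2.
"""


class NeuromirError(Exception):
    """Base class for all package errors."""


class ValidationError(NeuromirError):
    """Malformed or contract-violating input data or configuration."""


class SchemaError(ValidationError):
    """A required column or field is missing or has the wrong type."""


class ConfigError(ValidationError):
    """A simulation or run configuration violates its invariants."""


class DataError(ValidationError):
    """Input data violate a statistical precondition (e.g. absent outcome level)."""


class ComputationError(NeuromirError):
    """A numerical procedure could not produce a valid result."""


class FitError(ComputationError):
    """Model fitting failed to converge or the design is degenerate."""


class RankDeficiencyError(FitError):
    """The model design matrix is rank deficient (collinear terms)."""
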