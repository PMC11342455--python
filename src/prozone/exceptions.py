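"""Exception hierarchy shared across the package."""


class ProzoneError(Exception):
    """Base class for all package-specific errors."""


class DomainError(ProzoneError, ValueError):
    """An argument lies outside the mathematical domain of a model."""


class ValidationError(ProzoneError, ValueError):
    """A parameter set or configuration violates its invariants."""


class InsufficientDataError(ProzoneError, ValueError):
    """Too few doses / replicates / points for the requested operation."""


class OrderingError(ProzoneError, ValueError):
    """Quantities supplied in an order that contradicts their definition."""


class SchemaError(ProzoneError, ValueError):
    """An input table is missing required columns."""


class ParseError(ProzoneError, ValueError):
    """A cell of an input table could not be interpreted."""


class ConfigurationError(ProzoneError, ValueError):
    """A simulation or analysis configuration is incomplete."""
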