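"""Exception hierarchy shared across the package."""


class FlexbanditError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(FlexbanditError):
    """A required column or field is missing or mis-typed."""


class ValidationError(FlexbanditError):
    """Input data violates a structural invariant (reported with row context)."""


class StructureError(FlexbanditError):
    """Events have the wrong shape for the requested conversion."""


class ConfigurationError(FlexbanditError):
    """A parameter object violates its own invariants."""


class InsufficientDataError(FlexbanditError):
    """Too few observations to evaluate the requested rule."""


class DegenerateInputError(FlexbanditError):
    """Statistic undefined for this input (e.g. constant ranks)."""
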