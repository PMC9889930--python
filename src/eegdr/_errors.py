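"""Exception hierarchy shared across the toolkit."""


class EegdrError(Exception):
    """Base class for all toolkit errors."""


class ValidationError(EegdrError):
    """Input data violates a structural invariant (shape, range, finiteness)."""


class ParameterError(EegdrError):
    """A caller-supplied parameter is outside its admissible range."""


class SchemaError(EegdrError):
    """Tabular inputs do not match the expected column/feature schema."""


class EstimationError(EegdrError):
    """A statistic could not be estimated from the data provided."""


class DegenerateInputError(EegdrError):
    """The input is formally valid but degenerate for this operation
    (e.g. zero variance where a moment ratio is required)."""
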