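"""Exception types shared across the package."""


class IatdynError(Exception):
    """Base class for all package-specific errors."""


class SchemaError(IatdynError):
    """An input table does not match the documented column schema."""


class StructuralError(IatdynError):
    """A dataset or model specification violates a structural invariant."""


class ParameterError(IatdynError, ValueError):
    """A numeric parameter is outside its admissible domain."""


class RequirementError(IatdynError):
    """A model stage needs a column or term the input does not carry."""


class DegenerateInputError(IatdynError):
    """The requested statistic is undefined for this input (e.g. zero SD)."""


class ComparisonError(IatdynError):
    """Two fits cannot be compared (mismatched trial sets)."""


class ConvergenceWarning(UserWarning):
    """An optimizer or sampler finished without meeting its tolerance."""
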