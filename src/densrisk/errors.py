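"""Exception hierarchy shared across the pipeline."""


class DensriskError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(DensriskError, ValueError):
    """An invalid field in a generator or pipeline configuration.

    The message names the offending field.
    """


class DomainError(DensriskError, ValueError):
    """A value outside the mathematical domain of an operation
    (e.g. non-positive density under a log transform)."""


class InputError(DensriskError, ValueError):
    """Structurally invalid input to an analysis step
    (wrong rows, non-nested models, degenerate outcome, ...)."""


class EmptyInputError(InputError):
    """An operation received an empty table or array."""


class SchemaError(DensriskError, ValueError):
    """A participant file does not match the documented column schema."""


class FitError(DensriskError, RuntimeError):
    """A model fit failed to converge or was ill-posed (e.g. separation)."""


class UnderdeterminedFitError(FitError):
    """Fewer observations than basis/design dimension."""


class StateError(DensriskError, RuntimeError):
    """An object was used before it reached the required state."""


class PipelineStageError(DensriskError, RuntimeError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, original: Exception):
        self.stage = stage
        self.original = original
        super().__init__(f"pipeline stage '{stage}' failed: {original}")
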