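"""Exception hierarchy shared across the pipeline stages."""


class StrollpipeError(Exception):
    """Base class for all pipeline errors."""


class InvalidArgumentError(StrollpipeError, ValueError):
    """An argument violates a stated precondition."""


class TooShortError(StrollpipeError):
    """The signal is shorter than the operation requires."""


class InsufficientGaitError(StrollpipeError):
    """Too few strides were detected to compute stride-level statistics."""


class UndefinedFeatureError(StrollpipeError):
    """A degenerate input makes one or more features undefined.

    Carries the names of the affected features.
    """

    def __init__(self, names, message=None):
        self.names = list(names)
        super().__init__(message or f"features undefined for this input: {self.names}")


class MissingSideError(StrollpipeError):
    """Events are available for one foot only."""


class ConstantFeatureError(StrollpipeError):
    """A feature column has zero variance and cannot be standardized."""


class SchemaError(StrollpipeError):
    """A table is missing required columns."""


class UndefinedCorrelationError(StrollpipeError):
    """A correlation involves a constant variable."""


class InsufficientPairsError(StrollpipeError):
    """Fewer than two complete test-retest pairs."""


class ContractViolationError(StrollpipeError):
    """An operation received an epoch whose label violates its contract."""


class InvalidComparisonError(StrollpipeError):
    """Model fits are not defined on identical rows."""


class NoZuptWarning(UserWarning):
    """No stance interval found in a gait-labelled epoch."""
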