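"""Exception hierarchy shared across the package."""


class StenoshearError(Exception):
    """Base class for all package errors."""


class InvalidGeometryError(StenoshearError):
    """Degenerate or malformed geometric input (too few points, zero length,
    vanishing tangent)."""


class InsufficientSamplesError(InvalidGeometryError):
    """Too few samples to estimate derivatives."""


class DegenerateChordError(InvalidGeometryError):
    """Chord length is zero (closed or self-returning curve)."""


class ConstraintInfeasibleError(StenoshearError):
    """Rejection sampling exhausted its retry budget.

    Carries the name of the descriptor bound that was violated last.
    """

    def __init__(self, message: str, violated: str | None = None):
        super().__init__(message)
        self.violated = violated


class ValidationError(StenoshearError):
    """A parameter fell outside its documented range."""


class LesionOverlapError(ValidationError):
    """Two stenoses are closer than the minimum throat separation."""


class ShapeError(StenoshearError):
    """Array dimensions do not match the documented contract."""


class DegenerateStatisticsError(StenoshearError):
    """Normalization statistics are degenerate (zero variance)."""


class CorrelationUndefinedError(StenoshearError):
    """Pearson correlation undefined because one input has zero variance."""


class StateError(StenoshearError):
    """Operation called before its prerequisites were fitted/built."""


class PipelineStageError(StenoshearError):
    """A pipeline stage is missing its upstream artifacts."""
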