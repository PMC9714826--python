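"""Exception hierarchy for the pipeline."""


class StrokelocError(Exception):
    """Base class for all package errors."""


class FormatError(StrokelocError):
    """Unreadable, corrupt or unsupported input file."""


class GeometryError(StrokelocError):
    """Inconsistent shapes, degenerate hulls or invalid transforms."""


class ParameterError(StrokelocError):
    """Invalid user-supplied parameter value."""


class TrainingError(StrokelocError):
    """Training preconditions violated (e.g. single-class labels)."""


class StateError(StrokelocError):
    """Model used before training or with a mismatched configuration."""


class DependencyError(StrokelocError):
    """A required intermediate product is missing."""


class PhantomSpecError(StrokelocError):
    """A synthetic phantom specification violates its own invariants."""
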