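"""Exception hierarchy shared across the package.

All domain-validation failures derive from :class:`DomainError` (a
``ValueError``) so callers can catch one type for bad physical inputs.
"""


class DomainError(ValueError):
    """An argument is outside its physically meaningful domain."""


class GeometricInconsistencyError(DomainError):
    """More barbed ends per area than the filament length density allows."""


class ConfigurationError(ValueError):
    """A configuration table/file is inconsistent or incomplete."""


class NonIdentifiableError(ValueError):
    """The data cannot constrain the requested parameter (e.g. a single load)."""


class InsufficientDataError(ValueError):
    """Too few samples for the requested estimate."""


class TimeOrderingError(ValueError):
    """A time axis is not strictly increasing."""


class SchemaError(ValueError):
    """A CSV table is missing required columns or has malformed values."""


class NormalizationError(ValueError):
    """A normalization reference is zero or missing."""


class FitFailureError(RuntimeError):
    """Nonlinear fit failed to converge; carries the best attempt found."""

    def __init__(self, message, best=None):
        super().__init__(message)
        self.best = best


class DegenerateFitError(FitFailureError):
    """The data admit no finite decay constant (e.g. constant response)."""


class FitRejectionError(RuntimeError):
    """A per-track fit was rejected; ``reason`` is a short machine code."""

    def __init__(self, reason, message=None):
        super().__init__(message or f"track fit rejected: {reason}")
        self.reason = reason


class PhaseSeparationError(RuntimeError):
    """Fast (FRET) and slow (bleaching) phases could not be separated."""


class StationarityWarning(UserWarning):
    """A requested averaging window shows a significant trend."""
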