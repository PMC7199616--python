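"""Typed exceptions raised across the package."""


class FracwellError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(FracwellError, ValueError):
    """A model parameter violates its invariant (e.g. non-positive mass)."""


class InvalidInputError(FracwellError, ValueError):
    """An operation received structurally invalid input (wrong shape, empty list...)."""


class OutOfRangeError(FracwellError, ValueError):
    """A value lies outside the admissible range (e.g. energy above the barrier)."""


class NoSubBarrierStateError(FracwellError, RuntimeError):
    """No sub-barrier eigenstate of the requested parity exists for this geometry."""

    def __init__(self, parity: str, message: str | None = None):
        self.parity = parity
        super().__init__(message or f"no sub-barrier {parity} state found")


class MatchingInconsistencyError(FracwellError, RuntimeError):
    """The requested energy does not satisfy the interface matching system."""


class DegenerateFieldError(FracwellError, RuntimeError):
    """A field is node-dominated; logarithmic derivatives are not meaningful."""


class PropagationFailureError(FracwellError, RuntimeError):
    """Time propagation violated its norm-conservation contract."""


class InfinitePeriodError(FracwellError, ZeroDivisionError):
    """The doublet is degenerate; the tunneling oscillation period diverges."""


class ConfigurationError(FracwellError, ValueError):
    """A run configuration is incomplete or self-contradictory."""
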