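"""Exception hierarchy shared across the package."""


class ErythroplanError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(ErythroplanError, ValueError):
    """A model or patient parameter violates its admissible range."""


class InvalidControlError(ErythroplanError, ValueError):
    """A control value lies outside [0, 1]."""


class ScheduleMismatchError(ErythroplanError, ValueError):
    """A schedule does not align with the simulation/calendar grid."""


class DivergenceError(InvalidParameterError):
    """The PV steady state does not exist (unbounded growth)."""


class CapacityExceededError(ErythroplanError, RuntimeError):
    """Continuous withdrawal at full capacity cannot hold the upper bound."""


class EstimationError(ErythroplanError, RuntimeError):
    """Parameter estimation could not be carried out."""


class SolverFailureError(ErythroplanError, RuntimeError):
    """An optimization backend failed to converge."""


class InsufficientDataError(ErythroplanError, ValueError):
    """Too few records for the requested statistic."""


class MemoryBudgetError(ErythroplanError, MemoryError):
    """A tabulation would exceed the configured memory cap."""
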