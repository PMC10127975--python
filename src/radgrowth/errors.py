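"""Exception hierarchy shared across the package."""


class RadGrowthError(Exception):
    """Base class for all package-specific errors."""


class DomainError(RadGrowthError, ValueError):
    """An input value lies outside the mathematical domain of an operation."""


class ConfigurationError(RadGrowthError, ValueError):
    """A parameter set is inconsistent or incomplete for the requested model."""


class ProtocolError(RadGrowthError, ValueError):
    """A treatment protocol violates its structural invariants."""


class IntegrationError(RadGrowthError, RuntimeError):
    """Numerical integration produced a non-finite state."""

    def __init__(self, message: str, step_index: int | None = None):
        super().__init__(message)
        self.step_index = step_index


class UnsupportedCombinationError(RadGrowthError, ValueError):
    """A solver/model pairing that is mathematically unsound was requested."""


class DirectionError(RadGrowthError, ValueError):
    """A perturbation would leave the admissible parameter domain."""


class InsufficientDataError(RadGrowthError, ValueError):
    """Too few data points for the requested statistic."""


class ValidationError(RadGrowthError, ValueError):
    """Malformed external input (file contents, table rows)."""
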