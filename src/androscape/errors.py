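"""Exception hierarchy for androscape."""


class AndroscapeError(Exception):
    """Base class for all androscape errors."""


class InvalidParameterError(AndroscapeError, ValueError):
    """A parameter value violates its documented constraints."""


class InvalidInputError(AndroscapeError, ValueError):
    """A runtime input (state, series, table) violates its contract."""


class IntegrationError(AndroscapeError, RuntimeError):
    """The ODE solver failed to produce a trajectory."""


class SteadyStateError(AndroscapeError, RuntimeError):
    """Steady-state solve failed to converge; carries the residual norm."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class DataError(AndroscapeError, ValueError):
    """A dataset is empty, malformed, or insufficient for the operation."""


class FitError(AndroscapeError, RuntimeError):
    """A least-squares fit failed to converge."""


class ConfigError(AndroscapeError, ValueError):
    """Configuration file is missing, malformed, or out of range."""

    def __init__(self, message: str, key: str | None = None):
        super().__init__(f"{key}: {message}" if key else message)
        self.key = key
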