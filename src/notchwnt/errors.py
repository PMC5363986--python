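"""Exception types shared across the package."""


class NotchWntError(Exception):
    """Base class for all package-specific errors."""


class ParameterError(NotchWntError, ValueError):
    """A model parameter violates its admissible range."""


class InputError(NotchWntError, ValueError):
    """A runtime input (concentration, stimulus, grid) is invalid."""


class GraphError(NotchWntError, KeyError):
    """A cell-graph lookup or consistency check failed."""


class FittingError(NotchWntError, RuntimeError):
    """The calibration routine could not evaluate or improve the objective."""

    def __init__(self, message: str, parameter: str | None = None):
        super().__init__(message)
        self.parameter = parameter


class SteadyStateError(NotchWntError, RuntimeError):
    """No admissible steady state could be located."""


class IntegrationError(NotchWntError, RuntimeError):
    """The ODE solver failed; carries the last accepted state and time."""

    def __init__(self, message: str, t_last: float | None = None, y_last=None):
        super().__init__(message)
        self.t_last = t_last
        self.y_last = y_last
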