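"""Exception hierarchy for vfokit."""


class VfokitError(Exception):
    """Base class for all vfokit errors."""


class InvalidStateError(VfokitError):
    """A state vector or parameter set contains non-finite values."""


class IntegrationFailureError(VfokitError):
    """An ODE/PDE integration diverged or could not be completed.

    Attributes
    ----------
    last_valid_time : float or None
        The last time at which the solution was still finite.
    """

    def __init__(self, message, last_valid_time=None, history=None):
        super().__init__(message)
        self.last_valid_time = last_valid_time
        self.history = history


class ConfigurationError(VfokitError):
    """An invalid solver or model configuration (e.g. CFL violation)."""


class GridMismatchError(VfokitError):
    """Two series/fields live on incompatible grids."""


class DegenerateSignalError(VfokitError):
    """A signal is degenerate for the requested operation (e.g. zero variance)."""


class NoPeriodicityError(VfokitError):
    """No periodicity could be detected in a signal."""


class UndefinedRatioError(VfokitError):
    """An entrainment ratio is undefined (a fold has no section crossings)."""
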