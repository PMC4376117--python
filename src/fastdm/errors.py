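"""Exception types shared across the package."""


class FastDmError(Exception):
    """Base class for all errors raised by this package."""


class ControlFileError(FastDmError):
    """A control file is malformed or internally inconsistent."""


class DataFileError(FastDmError):
    """A data file cannot be parsed; the message names the offending line."""


class TrialMinimumError(FastDmError):
    """A condition has too few trials for the chosen optimization criterion."""


class EstimationError(FastDmError):
    """The estimation procedure cannot be carried out on the given data."""


class ConvergenceError(FastDmError):
    """A numerical routine failed to reach its accuracy target.

    Attributes
    ----------
    residual : float or None
        Achieved residual when the routine gave up.
    """

    def __init__(self, message, residual=None):
        super().__init__(message)
        self.residual = residual
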