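"""Exception hierarchy for the mars package."""


class MarsError(Exception):
    """Base class for all mars errors."""


class InvalidParameterError(MarsError, ValueError):
    """A model or sampler parameter is outside its admissible range."""


class InvalidInputError(MarsError, ValueError):
    """Input data violates a documented precondition."""


class NumericalError(MarsError, ArithmeticError):
    """A numerically invalid intermediate (non-PD covariance, non-finite result)."""


class CalibrationError(MarsError, RuntimeError):
    """Threshold calibration is impossible at the requested settings."""


class PanelMismatchError(MarsError, ValueError):
    """A null panel does not match the locus it is being applied to."""


class ParseError(MarsError, ValueError):
    """A file could not be parsed."""
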