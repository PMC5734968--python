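"""Exception hierarchy for the registration pipeline."""


class RegistrationError(Exception):
    """Base class for all errors raised by meshffd."""


class ValidationError(RegistrationError, ValueError):
    """An input violates a documented precondition."""


class OutOfBoundsError(RegistrationError):
    """A sample point falls outside the image domain."""


class DegeneracyError(RegistrationError):
    """A geometric configuration is rank deficient (e.g. collinear points)."""


class InsufficientFeaturesError(RegistrationError):
    """Fewer than the minimum number of feature matches were found."""


class EstimationFailureError(RegistrationError):
    """Robust model estimation found no consensus set."""
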