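"""Exception hierarchy for hillmuscle."""


class HillMuscleError(Exception):
    """Base class for all package-specific errors."""


class DomainError(HillMuscleError, ValueError):
    """An argument lies outside the physical domain of an operation."""


class SingularRateError(HillMuscleError):
    """The damper coefficient vanished, leaving the contraction rate undefined.

    Happens when R_PDE = 0 and the transmitted force is zero: the internal
    node then has no damping and its velocity is unbounded.  Set R_PDE > 0.
    """


class ProtocolError(HillMuscleError):
    """A virtual experiment did not satisfy its protocol (e.g. the isometric
    phase failed to converge within the allotted time)."""


class UndefinedKappaError(HillMuscleError):
    """The serial-to-total velocity ratio is undefined because the total
    contraction velocity is (numerically) zero."""


class FitError(HillMuscleError):
    """Nonlinear least squares failed to converge.  Carries the initial
    guess so the user can restart from a better point."""

    def __init__(self, message, initial_guess=None):
        super().__init__(message)
        self.initial_guess = initial_guess


class StateError(HillMuscleError):
    """A dynamical state is inconsistent (e.g. no real root of the
    contraction-rate balance).  Carries a diagnostic dump."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class CatalogError(HillMuscleError):
    """The packaged muscle catalogue failed its integrity check."""


class ConfigError(HillMuscleError, ValueError):
    """A run configuration is malformed.  Carries the offending field path."""

    def __init__(self, message, field_path=None):
        super().__init__(message)
        self.field_path = field_path
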