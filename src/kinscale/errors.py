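"""Exception hierarchy shared by all pipeline stages."""


class KinscaleError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(KinscaleError, ValueError):
    """A value violates a domain-type invariant (e.g. non-positive K_M)."""


class SchemaError(KinscaleError, ValueError):
    """An input table is missing a mandatory column or is malformed."""


class DomainError(KinscaleError, ValueError):
    """An argument lies outside the mathematical domain of an operation."""


class NoSignalError(KinscaleError):
    """All measured rates are zero; kinetic parameters are unidentifiable."""


class ConvergenceError(KinscaleError):
    """Nonlinear fit failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_iterate=None):
        super().__init__(message)
        self.last_iterate = last_iterate


class InsufficientDataError(KinscaleError, ValueError):
    """Fewer points than the minimum a regression requires."""


class DegenerateDesignError(KinscaleError, ValueError):
    """Zero variance in the regressor; the design matrix is singular."""
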