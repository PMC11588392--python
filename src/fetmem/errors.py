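"""Exception hierarchy shared by all fetmem modules."""


class FetmemError(Exception):
    """Base class for all package errors."""


class ParameterError(FetmemError, ValueError):
    """A material or geometric parameter violates its physical constraints."""


class KinematicsError(FetmemError, ValueError):
    """A deformation state is inadmissible (e.g. det F <= 0)."""


class ValidationError(FetmemError, ValueError):
    """Input data (curves, files, windows) failed validation."""


class SolverError(FetmemError, RuntimeError):
    """A nonlinear solve failed to converge.

    Attributes carry diagnostics for the caller (last converged load level,
    residual norm) so continuation drivers can react.
    """

    def __init__(self, message, *, last_converged=None, residual=None):
        super().__init__(message)
        self.last_converged = last_converged
        self.residual = residual


class StabilityControlError(SolverError):
    """The fiber-energy stability control fired (g3 above its cap, or the
    exponential energy overflowed). Continuation drivers respond by retrying
    with a smaller load increment."""

    def __init__(self, message, *, g3=None, cap=None, **kw):
        super().__init__(message, **kw)
        self.g3 = g3
        self.cap = cap
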