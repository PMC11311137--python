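"""Exception hierarchy shared by all analysis stages."""


class NucleokinError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(NucleokinError, ValueError):
    """Input violates a documented invariant (wrong range, shape, or order)."""


class DomainError(NucleokinError, ValueError):
    """Mathematically invalid argument for an operation (e.g. log of <= 0)."""


class ConvergenceError(NucleokinError, RuntimeError):
    """An iterative solver failed to reach its tolerance."""

    def __init__(self, message: str, residual: float | None = None):
        super().__init__(message)
        self.residual = residual


class RegimeNotFoundError(NucleokinError, RuntimeError):
    """No contiguous window of the kinetic data satisfied the linearity rule."""

    def __init__(self, message: str, best_r2: float | None = None):
        super().__init__(message)
        self.best_r2 = best_r2


class InsufficientDataError(NucleokinError, ValueError):
    """Too few observations for the requested fit."""
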