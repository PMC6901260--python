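"""Exception hierarchy shared by all modules."""

from __future__ import annotations


class TxnKineticsError(Exception):
    """Base class for all package errors."""


class ConfigurationError(TxnKineticsError):
    """A parameter, preset name or run configuration is invalid."""


class GeneValidationError(TxnKineticsError):
    """A gene model violates one or more geometric invariants."""

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__("invalid gene model: " + "; ".join(self.violations))


class DataError(TxnKineticsError):
    """An input table or trace is malformed or physically impossible."""


class FitError(TxnKineticsError):
    """A curve fit failed; carries best-effort parameters when available."""

    def __init__(self, message: str, best=None, residuals=None):
        self.best = best
        self.residuals = residuals
        super().__init__(message)


class NonConvergenceError(TxnKineticsError):
    """Steady state was not reached within the step budget."""

    def __init__(self, message: str, window_means=None):
        self.window_means = window_means
        super().__init__(message)


class UnsupportedRegimeError(TxnKineticsError):
    """An analytic result was requested outside its regime of validity."""
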