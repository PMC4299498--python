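"""Exception hierarchy.

ValidationError maps to CLI exit code 2, NumericalError to 3.
"""


class RnapAllocError(Exception):
    """Base class for all package errors."""


class ValidationError(RnapAllocError, ValueError):
    """Invalid inputs: bad specs, missing columns, unknown species."""


class NumericalError(RnapAllocError, RuntimeError):
    """Solver or integrator failure, with diagnostics in the message."""


class UndefinedShareError(ValidationError):
    """All sigma-fragment totals are zero; shares are undefined."""


class UndefinedFoldError(ValidationError):
    """Reporter-only activity is not positive; fold induction undefined."""


class InsufficientDataError(ValidationError):
    """Too few induction points to constrain the fit."""


class DegenerateFitError(ValidationError):
    """Regression input is degenerate (e.g. all-zero reference activities)."""


class InfeasibleTargetError(ValidationError):
    """Target activity cannot be reached by tuning alpha expression."""
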