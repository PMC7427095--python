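"""Exception hierarchy shared across the package.

Exit-code mapping used by the command-line layer: :class:`InputError` maps
to exit code 2, :class:`FitConvergenceError` to exit code 3.
"""


class OptobindError(Exception):
    """Base class for all package errors."""


class InputError(OptobindError, ValueError):
    """Invalid user input: bad file, bad column, non-physical parameter."""


class UndefinedAffinityError(OptobindError, ZeroDivisionError):
    """K_d is undefined because the on-rate is zero."""


class FitConvergenceError(OptobindError, RuntimeError):
    """No restart of the global fit converged.

    Carries per-restart diagnostics so the failure can be inspected rather
    than silently returning a best-so-far parameter set.
    """

    def __init__(self, message: str, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or []


class BootstrapError(OptobindError, RuntimeError):
    """Too many bootstrap replicates failed to refit."""

    def __init__(self, message: str, n_failed: int = 0, n_total: int = 0):
        super().__init__(message)
        self.n_failed = n_failed
        self.n_total = n_total
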