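"""Exception hierarchy.

Input/domain problems derive from :class:`InputError` (CLI exit code 2),
solver and model failures from :class:`SolverError` (exit code 3).
"""


class CrpenError(Exception):
    """Base class for all package-specific errors."""


class InputError(CrpenError, ValueError):
    """Invalid user input: bad domain values, malformed files, bad geometry."""


class ParameterError(InputError):
    """Physically inadmissible model parameters (D <= 0, K < 1, ...)."""


class DomainError(InputError):
    """Query outside the model domain (negative time or depth, bad level)."""


class DegenerateProfileError(InputError):
    """Profile has no saturated plateau above background; nothing to normalize."""


class NotYetPenetratedError(InputError):
    """Requested intensity level is never crossed by the profile."""


class InsufficientDataError(InputError):
    """Too few usable points to fit."""


class SolverError(CrpenError, RuntimeError):
    """Root-finding or estimation failure."""


class NoSolutionError(SolverError):
    """The two-contour system has no root in the search bracket."""


class InconsistentDataError(SolverError):
    """The solve produced physically inadmissible parameters (K < 1)."""
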