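"""Exception hierarchy.

Every error raised by the library derives from :class:`EquispecError` so
callers (and the CLI) can catch the whole family at once.
"""


class EquispecError(Exception):
    """Base class for all equispec errors."""


class InvalidModelError(EquispecError):
    """An equilibrium model violates its invariants (duplicate stoichiometry,
    non-finite log beta, bare-component species, missing pKw, ...)."""


class InvalidConditionError(EquispecError):
    """Conditions are out of domain (negative totals, nothing to solve)."""


class SolverFailureError(EquispecError):
    """The mass-balance Newton iteration did not converge."""

    def __init__(self, message: str, worst_residual: float | None = None):
        super().__init__(message)
        self.worst_residual = worst_residual


class ThresholdNotReachedError(EquispecError):
    """A species fraction never reaches the requested threshold in the
    search bracket; carries the maximum fraction that was attained."""

    def __init__(self, message: str, max_fraction: float | None = None):
        super().__init__(message)
        self.max_fraction = max_fraction


class NoCrossoverError(EquispecError):
    """Two species concentrations never cross inside the search bracket."""


class DegenerateCurveError(EquispecError):
    """A titration curve is unusable (flat EMF, empty window, duplicate
    volumes, no equivalence bracket)."""


class CurveParseError(EquispecError):
    """A curve or model file failed validation; carries the offending line."""

    def __init__(self, message: str, line: int | None = None):
        super().__init__(message if line is None else f"line {line}: {message}")
        self.line = line
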