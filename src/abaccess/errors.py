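"""Exception hierarchy shared across the pipeline stages.

Exit-code mapping used by the CLI: :class:`InputError` subclasses map to
exit code 1 (bad inputs, schema violations, infeasible configuration),
:class:`NumericalError` subclasses to exit code 2 (degenerate statistics,
non-convergence, disqualified hyperparameter searches).
"""


class AbaccessError(Exception):
    """Base class for all package errors."""


class InputError(AbaccessError):
    """Invalid input data, schema, or configuration."""


class ParameterError(InputError):
    """A parameter value outside its documented domain."""


class InvalidRecordError(InputError):
    """A county/tract record violating its invariants (e.g. zero population)."""


class SchemaError(InputError):
    """A delimited-text input missing required columns."""

    def __init__(self, path: str, missing: list[str]):
        self.path = path
        self.missing = list(missing)
        super().__init__(f"{path}: missing required column(s): {', '.join(self.missing)}")


class NoProviderError(InputError):
    """No active facility available when computing nearest distances."""


class NumericalError(AbaccessError):
    """A numerical failure during model fitting or diagnostics."""


class ConstantInputError(NumericalError):
    """Moran's I requested for a constant vector: the statistic is undefined."""


class DegenerateHullError(NumericalError):
    """Fewer than three non-collinear points: the convex hull is degenerate."""


class ConvergenceError(NumericalError):
    """IRLS failed to converge within the iteration budget."""


class SelectionError(NumericalError):
    """Every hyperparameter grid point was disqualified."""
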