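"""Exception hierarchy for sprint F-v profiling."""


class SprintFVError(Exception):
    """Base class for all package errors."""


class InvalidInputError(SprintFVError, ValueError):
    """An argument violates a physical or structural precondition."""


class NoMovementError(SprintFVError):
    """No sprint onset could be detected in a radar trace."""


class InsufficientDataError(SprintFVError):
    """Too few samples remain after trimming to support a fit."""


class InsufficientTrialsError(SprintFVError):
    """Fewer than two trials available for an athlete-session aggregate."""


class FitFailureError(SprintFVError):
    """Nonlinear least squares did not converge.

    Carries solver diagnostics in ``diagnostics``.
    """

    def __init__(self, message: str, diagnostics: dict | None = None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class ModelDegenerateError(SprintFVError):
    """A fitted model is degenerate (vanishing MSS or tau)."""


class DegenerateStatisticError(SprintFVError):
    """A statistic is undefined on the given data (e.g. zero variance).

    ``detail`` may carry the exactly-known quantity (e.g. a constant change).
    """

    def __init__(self, message: str, detail: dict | None = None):
        super().__init__(message)
        self.detail = detail or {}


class IncompleteDesignError(SprintFVError):
    """A study frame is missing a required session or group cell."""


class ConfigError(SprintFVError):
    """A study or cohort configuration is internally inconsistent."""


class ValidationError(SprintFVError):
    """An input file failed structural validation; message names offending rows."""
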