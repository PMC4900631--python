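"""Exception hierarchy shared across the package."""


class FisofusError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(FisofusError):
    """A user-supplied configuration is structurally invalid (missing
    columns, infeasible generator settings, bad parameter ranges)."""


class ValidationError(FisofusError):
    """Input data violate a documented invariant; carries row context
    where available."""

    def __init__(self, message: str, rows: list | None = None):
        super().__init__(message)
        self.rows = rows or []


class InsufficientDataError(FisofusError):
    """Too few observations to compute the requested quantity."""


class EstimationError(FisofusError):
    """An estimator could not produce a defined result (e.g. all hulls
    degenerate, zero-mean coefficient of variation)."""
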