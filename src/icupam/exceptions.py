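"""Exception hierarchy shared across the package."""


class IcupamError(Exception):
    """Base class for all package-specific errors."""


class ConfigError(IcupamError):
    """Invalid simulation or analysis configuration."""


class SchemaError(IcupamError):
    """Malformed input table (missing columns, bad values); message lists offending rows."""


class MissingIntakeError(IcupamError):
    """A diet day required by the model is absent and may not be silently filled."""


class ExclusionError(IcupamError):
    """Patient violates the cohort inclusion criteria (e.g. follow-up <= 4 days)."""


class ConvergenceError(IcupamError):
    """Penalized IRLS failed to converge; carries the deviance trace."""

    def __init__(self, message, trace=None):
        super().__init__(message)
        self.trace = list(trace) if trace is not None else []
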