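"""Exception hierarchy shared across the package."""


class FieldPmfError(Exception):
    """Base class for all package errors."""


class ParseError(FieldPmfError):
    """A structure or series file could not be parsed."""


class FormatError(FieldPmfError):
    """Parsed data violates a format invariant (e.g. non-monotonic times)."""


class MissingChargeError(FieldPmfError):
    """An atom could not be resolved against the supplied charge table."""


class InsufficientDataError(FieldPmfError):
    """Too few samples remain for the requested statistic."""


class SingularityError(FieldPmfError):
    """An environment charge (numerically) coincides with the field probe."""


class DegenerateAxisError(FieldPmfError):
    """The two atoms defining a reaction axis are coincident."""


class UndefinedCorrelationError(FieldPmfError):
    """A constant series makes the Pearson correlation undefined."""


class ConvergenceError(FieldPmfError):
    """Self-consistent iteration failed to reach tolerance."""


class BootstrapFailureError(FieldPmfError):
    """Too many bootstrap replicates failed to converge."""


class NoBarrierError(FieldPmfError):
    """A free-energy profile has no interior maximum."""


class FitError(FieldPmfError):
    """A least-squares design is rank deficient or under-determined."""


class InfeasibleScheduleError(FieldPmfError):
    """A prescribed field cannot be realised at the generator geometry."""


class InconclusiveResultError(FieldPmfError):
    """All committor shots timed out before committing to a basin."""


class ConfigError(FieldPmfError):
    """A run configuration failed validation; message lists all violations."""
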