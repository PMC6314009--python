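"""Exception hierarchy; exit codes are used by the CLI."""


class SymptomNetError(Exception):
    """Base class for all package errors."""

    exit_code = 1


class ConfigError(SymptomNetError):
    """Invalid configuration or unusable parameter combination."""

    exit_code = 2


class DataError(SymptomNetError):
    """Input data violate a precondition (bad categories, too few rows, ...)."""

    exit_code = 3


class EstimationError(SymptomNetError):
    """A statistical procedure could not produce a valid result."""

    exit_code = 4


class ConvergenceError(EstimationError):
    """An iterative solver ran out of iterations."""

    exit_code = 5
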