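"""Exception hierarchy shared across the package."""


class GradlabError(Exception):
    """Base class for all package errors."""


class UsageError(GradlabError, ValueError):
    """Invalid argument or precondition violation."""


class DataError(GradlabError, ValueError):
    """Malformed or incomplete input data (missing genes, bad rows...)."""


class NumericalError(GradlabError, ArithmeticError):
    """A solver produced an unusable result (instability, divergence)."""


class CalibrationError(GradlabError, ValueError):
    """A synthetic-data calibration target is infeasible."""


class ConfigError(GradlabError, ValueError):
    """Configuration file fails schema validation."""
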