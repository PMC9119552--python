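"""Exception types shared across the package."""


class CompselError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CompselError, ValueError):
    """A simulation, scenario, or policy configuration is invalid."""


class InvalidValueError(CompselError, ValueError):
    """A numeric input violates its contract (e.g. probability outside [0, 1])."""


class InfeasiblePolicyError(CompselError):
    """An admissions policy cannot be satisfied (e.g. cutoff leaves too few survivors)."""


class UndefinedMetricError(CompselError):
    """A summary statistic is undefined for the given inputs (e.g. empty acceptance)."""
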