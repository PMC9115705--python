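"""Exception hierarchy shared across the package."""


class RVEnergeticsError(Exception):
    """Base class for all package errors."""


class InvalidInputError(RVEnergeticsError):
    """A signal or table violates a structural precondition (non-finite
    samples, mismatched time bases, malformed columns)."""


class InvalidArgumentError(RVEnergeticsError, ValueError):
    """A scalar argument is outside its documented domain."""


class InsufficientDataError(RVEnergeticsError):
    """Too few cycles / records to carry out the requested operation."""


class DegenerateProfileError(RVEnergeticsError):
    """Flow-profile calibration impossible (non-positive mean of the
    unit-amplitude profile)."""


class DegenerateDesignError(RVEnergeticsError):
    """Regression design matrix has no variance in the predictor."""


class RankDeficiencyError(RVEnergeticsError):
    """Within-group covariance is singular; drop a dependent variable."""


class UndefinedEfficiencyError(RVEnergeticsError):
    """Efficiency requested for a breakdown with zero total power."""


class InvalidSpecError(RVEnergeticsError):
    """A synthetic-cohort spec is infeasible (e.g. empty truncation
    support)."""
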