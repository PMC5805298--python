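"""Exception hierarchy shared across the package."""


class QtSalvageError(Exception):
    """Base class for all package-specific errors."""


class InvalidParameterError(QtSalvageError, ValueError):
    """A simulation or analysis parameter violates its stated constraints."""


class InsufficientSignalError(QtSalvageError):
    """Fewer than two detectable beats; baseline cannot be estimated."""


class LeadUnmeasurableError(QtSalvageError):
    """No T wave detectable above the noise band in this lead."""


class MissingLeadsError(QtSalvageError):
    """A required lead group (anterior or inferior) has no measurable lead."""


class InsufficientSeriesError(QtSalvageError):
    """Fewer than two timepoints available for a timecourse summary."""


class UndefinedMsiError(QtSalvageError, ZeroDivisionError):
    """Salvage index requested with zero area at risk."""


class DegenerateTestError(QtSalvageError):
    """A test statistic is undefined for this input (e.g. zero variance)."""


class RankDeficiencyError(QtSalvageError):
    """Collinear design matrix; carries the offending column names."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(f"design matrix is rank deficient; offending columns: {self.columns}")


class SeparationError(QtSalvageError):
    """Complete (or quasi-complete) separation in a logistic model."""


class SingleClassError(QtSalvageError):
    """Binary outcome contains only one class."""
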