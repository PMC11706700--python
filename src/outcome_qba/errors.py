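"""Exception hierarchy for the QBA pipeline.

Every stage raises a subclass of :class:`QBAError` so callers can catch
pipeline failures distinctly from programming errors.
"""


class QBAError(Exception):
    """Base class for all package errors."""


class UnderpoweredConfigError(QBAError):
    """Synthetic-cohort config expected to yield < 1 cause-specific case per arm."""


class ContractViolationError(QBAError):
    """An operation was called with inputs violating its documented contract."""


class ElicitationError(QBAError):
    """No beta distribution matches the requested quantile triple.

    Carries the best-achieved quantiles so the caller can judge how far off
    the fit is.
    """

    def __init__(self, message, achieved=None, shapes=None):
        super().__init__(message)
        self.achieved = achieved
        self.shapes = shapes


class DegenerateTableError(QBAError):
    """A 2x2 table cannot be formed or used (empty arm, zero cell)."""


class NonIdentifiableCorrectionError(QBAError):
    """Se + Sp <= 1: the misclassification correction is not identifiable."""


class NegativeCellError(QBAError):
    """A bias correction produced a non-positive cell count."""

    def __init__(self, message, cells=None):
        super().__init__(message)
        self.cells = cells or []


class TrimmingError(QBAError):
    """Propensity-score common support is empty."""


class FittingError(QBAError):
    """A regression model failed to converge or separated."""


class AnalysisFailureError(QBAError):
    """A Monte Carlo analysis retained no iterations."""

    def __init__(self, message, discard_fraction=None):
        super().__init__(message)
        self.discard_fraction = discard_fraction
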