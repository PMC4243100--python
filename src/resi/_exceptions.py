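"""Exception types shared across the package."""


class ResiError(Exception):
    """Base class for all package errors."""


class DatasetValidationError(ResiError):
    """An ExpressionDataset invariant is violated."""

    def __init__(self, violations):
        self.violations = list(violations)
        super().__init__("; ".join(self.violations))


class UnsupportedTaskError(ResiError):
    """The label has a number of levels other than two (only binary tasks are supported)."""


class ParseError(ResiError):
    """A delimited input file could not be parsed."""


class InsufficientInstancesError(ResiError):
    """Too few instances for the requested neighbourhood size (requires n >= k + 1)."""


class NoRelevantFeaturesError(ResiError):
    """Every feature was filtered out as irrelevant.

    Carries the best relevance score observed so the caller can see how far
    the data fell short of the threshold.
    """

    def __init__(self, message, best_score=None):
        super().__init__(message)
        self.best_score = best_score
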