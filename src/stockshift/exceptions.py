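"""Exception hierarchy for stockshift.

All errors raised deliberately by the package derive from :class:`StockshiftError`
so callers can catch package failures without swallowing programming errors.
"""


class StockshiftError(Exception):
    """Base class for all stockshift errors."""


class FormatError(StockshiftError, ValueError):
    """A file or table does not have the expected layout (e.g. missing column)."""


class ValidationError(StockshiftError, ValueError):
    """Input data violate a structural invariant (year gaps, negative SSB, ...)."""


class EmptyDatasetError(StockshiftError, ValueError):
    """An operation produced or received a dataset with no usable observations."""


class InputError(StockshiftError, ValueError):
    """An operation received arguments outside its contract."""


class FitError(StockshiftError, RuntimeError):
    """A model fit failed to converge or was degenerate beyond recovery."""

    def __init__(self, message, best_attempt=None):
        super().__init__(message)
        self.best_attempt = best_attempt


class ComparisonError(StockshiftError, RuntimeError):
    """All candidate models failed during a model comparison."""


class ThresholdSearchError(StockshiftError, RuntimeError):
    """No admissible candidate threshold remained in a threshold search."""


class DecisionError(StockshiftError, RuntimeError):
    """A decision procedure could not be completed (e.g. too many failed folds)."""


class ConfigurationError(StockshiftError, ValueError):
    """The pipeline configuration is inconsistent with the requested analysis."""
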