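"""Exception hierarchy for itemrel."""


class ItemrelError(Exception):
    """Base class for all itemrel errors."""


class DataValidationError(ItemrelError):
    """Input data violate a structural requirement (shape, range, missingness)."""


class ParseError(DataValidationError):
    """A cell in an input file could not be parsed as an integer score."""


class MissingValueError(DataValidationError):
    """An input file contains an empty or missing cell."""


class DegenerateItemError(ItemrelError):
    """An item has zero variance, so its reliability is undefined."""


class InsufficientItemsError(ItemrelError):
    """The method needs more items than the data provide."""


class CollinearityError(ItemrelError):
    """The inter-item covariance matrix (excluding the target item) is singular."""


class ConvergenceError(ItemrelError):
    """No EM start converged; carries per-start diagnostics."""

    def __init__(self, message, diagnostics=None):
        super().__init__(message)
        self.diagnostics = diagnostics or {}


class CriterionError(ItemrelError):
    """The criterion score for method CA is unusable (zero variance or alpha <= 0)."""


class UndefinedIndexError(ItemrelError):
    """An item index (e.g., scalability) is undefined for these data."""


class InvalidConditionError(ItemrelError):
    """A simulation condition violates its constraints (e.g., non-increasing locations)."""
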