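"""Method CA: correction for attenuation with a rest-score criterion.

The estimate for item i is ``corr(Xi, Y)^2 / alpha_Y`` where Y defaults to
the rest score ``R(i) = X - Xi`` and ``alpha_Y`` is coefficient alpha of the
J-1 remaining items.  True scores of item and criterion are assumed to
correlate perfectly.  Estimates may exceed 1 and are never clipped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import ItemScoreMatrix, ReliabilityReport, total_and_rest_scores
from .exceptions import (
    CriterionError,
    DataValidationError,
    DegenerateItemError,
    InsufficientItemsError,
)

__all__ = ["CriterionSpec", "coefficient_alpha", "ca_reliability"]


@dataclass(frozen=True)
class CriterionSpec:
    """Criterion choice for method CA.

    ``mode="rest_score"`` uses R(i) with alpha of the remaining items;
    ``mode="external_column"`` needs a criterion vector of length N and its
    reliability in (0, 1].
    """

    mode: str = "rest_score"
    criterion: np.ndarray = None
    reliability: float = None

    def __post_init__(self):
        if self.mode not in ("rest_score", "external_column"):
            raise DataValidationError(f"unknown criterion mode {self.mode!r}")
        if self.mode == "external_column":
            if self.criterion is None:
                raise DataValidationError("external criterion vector is required")
            if self.reliability is None or not 0 < self.reliability <= 1:
                raise DataValidationError(
                    "external criterion needs a supplied reliability in (0, 1]"
                )
            object.__setattr__(
                self, "criterion", np.asarray(self.criterion, dtype=float)
            )


def coefficient_alpha(data) -> float:
    """Cronbach's coefficient alpha: (J/(J-1)) (1 - sum var_i / var_X)."""
    scores = data.scores if isinstance(data, ItemScoreMatrix) else np.asarray(data)
    n, j = scores.shape
    if j < 2:
        raise InsufficientItemsError("coefficient alpha needs at least 2 items")
    total_var = scores.sum(axis=1).var(ddof=1)
    if not total_var > 0:
        raise DegenerateItemError("total score has zero variance")
    item_var = scores.var(axis=0, ddof=1).sum()
    return float(j / (j - 1) * (1.0 - item_var / total_var))


def _corr(a, b) -> float:
    va = a.var(ddof=1)
    vb = b.var(ddof=1)
    if not (va > 0 and vb > 0):
        raise DegenerateItemError("correlation undefined: zero variance")
    return float(np.cov(a, b, ddof=1)[0, 1] / np.sqrt(va * vb))


def ca_reliability(
    data: ItemScoreMatrix, criterion: CriterionSpec = None
) -> ReliabilityReport:
    """Item-score reliability by the correction for attenuation."""
    criterion = criterion or CriterionSpec()
    estimates = np.empty(data.n_items)
    if criterion.mode == "rest_score":
        if data.n_items < 3:
            raise InsufficientItemsError(
                "rest-score criterion needs J >= 3 (alpha of the rest needs "
                ">= 2 items)"
            )
        for i in range(data.n_items):
            _, rest = total_and_rest_scores(data, i)
            if not rest.var(ddof=1) > 0:
                raise CriterionError(
                    f"rest score for item {data.item_labels[i]} has zero variance"
                )
            alpha_rest = coefficient_alpha(data.drop_item(i))
            if alpha_rest <= 0:
                raise CriterionError(
                    f"alpha of the rest score for item {data.item_labels[i]} "
                    f"is {alpha_rest:.4f} <= 0; denominator invalid"
                )
            estimates[i] = _corr(data.scores[:, i].astype(float), rest.astype(float)) ** 2 / alpha_rest
        settings = {"criterion": "rest_score", "reliability_source": "alpha"}
    else:
        y = criterion.criterion
        if y.shape != (data.n_persons,):
            raise DataValidationError(
                "criterion vector length must equal the number of persons"
            )
        if not y.var(ddof=1) > 0:
            raise CriterionError("external criterion has zero variance")
        for i in range(data.n_items):
            estimates[i] = (
                _corr(data.scores[:, i].astype(float), y) ** 2
                / criterion.reliability
            )
        settings = {
            "criterion": "external_column",
            "reliability_source": "user_supplied",
            "criterion_reliability": criterion.reliability,
        }
    return ReliabilityReport(
        method="CA",
        estimates=estimates,
        settings=settings,
        item_labels=list(data.item_labels),
    )
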