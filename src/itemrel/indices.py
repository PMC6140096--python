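"""Comparison item indices: corrected item-rest correlation and scalability Hi.

Hi relates the summed covariances of an item with the other items to the
maximum those covariances could attain given the two marginal distributions
(the comonotone rearrangement), so it corrects the association for the
items' marginals.  Both indices carry the conventional >= .3 rule-of-thumb
flag in reports.
"""

from __future__ import annotations

import numpy as np

from .data import ItemScoreMatrix
from .exceptions import DegenerateItemError, InsufficientItemsError, UndefinedIndexError

__all__ = ["item_rest_correlation", "scalability_Hi", "item_indices"]

THRESHOLD = 0.3


def item_rest_correlation(data: ItemScoreMatrix, item: int) -> float:
    """Product-moment correlation of item i with its rest score R(i)."""
    x = data.scores[:, item].astype(float)
    rest = data.scores.sum(axis=1) - data.scores[:, item]
    if not (x.var(ddof=1) > 0 and rest.var(ddof=1) > 0):
        raise DegenerateItemError(
            f"item-rest correlation undefined for item {data.item_labels[item]}: "
            "zero variance"
        )
    return float(np.corrcoef(x, rest)[0, 1])


def _max_covariance(a: np.ndarray, b: np.ndarray) -> float:
    # comonotone rearrangement: sorting both margins attains the maximum
    # covariance compatible with the two marginal distributions
    return float(np.cov(np.sort(a), np.sort(b), ddof=1)[0, 1])


def scalability_Hi(data: ItemScoreMatrix, item: int) -> float:
    """Mokken item scalability coefficient Hi."""
    if data.n_items < 2:
        raise InsufficientItemsError("Hi needs at least 2 items")
    x = data.scores[:, item].astype(float)
    num = 0.0
    den = 0.0
    for j in range(data.n_items):
        if j == item:
            continue
        other = data.scores[:, j].astype(float)
        num += float(np.cov(x, other, ddof=1)[0, 1])
        den += _max_covariance(x, other)
    if not den > 0:
        raise UndefinedIndexError(
            f"maximum covariance is zero for item {data.item_labels[item]}; "
            "Hi undefined"
        )
    return num / den


def item_indices(data: ItemScoreMatrix) -> list:
    """Per-item report rows with rule-of-thumb flags (threshold .3)."""
    rows = []
    for i in range(data.n_items):
        r = item_rest_correlation(data, i)
        hi = scalability_Hi(data, i)
        rows.append(
            {
                "item": data.item_labels[i],
                "mean": float(data.scores[:, i].mean()),
                "item_rest_correlation": r,
                "item_rest_flag": bool(r >= THRESHOLD),
                "scalability_Hi": hi,
                "scalability_flag": bool(hi >= THRESHOLD),
            }
        )
    return rows
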