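"""Guttman's lambda-6 adapted to a single item.

``lambda6_i`` is the squared multiple correlation of item i regressed on the
remaining J-1 items: ``sigma_i' Sigma_ii^{-1} sigma_i / var(Xi)``, where
``Sigma_ii`` is the inter-item covariance matrix without item i and
``sigma_i`` the covariances of item i with the rest.  It embeds in the
cumulative-probability framework via the flat approximation
``pi~_xy = sigma_i' Sigma_ii^{-1} sigma_i / m^2 + pi_x pi_y``, which routed
through :func:`itemrel.ctt.reliability_from_approximation` reproduces
``lambda6_i`` exactly; :func:`lambda6_all` asserts that identity on every run.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ctt import estimate_cumulative_tables, reliability_from_approximation
from .data import ItemScoreMatrix, ReliabilityReport
from .exceptions import (
    CollinearityError,
    DegenerateItemError,
    InsufficientItemsError,
)

__all__ = ["InterItemCovariance", "lambda6_item", "lambda6_all"]

_COND_LIMIT = 1e12


@dataclass(frozen=True)
class InterItemCovariance:
    """Full J x J inter-item covariance matrix (denominator N-1)."""

    matrix: np.ndarray
    item_labels: list = None

    def __post_init__(self):
        mat = np.asarray(self.matrix, dtype=float)
        if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
            raise ValueError("covariance matrix must be square")
        if not np.allclose(mat, mat.T, atol=1e-10):
            raise ValueError("covariance matrix must be symmetric")
        labels = self.item_labels or [f"V{k + 1}" for k in range(mat.shape[0])]
        mat.setflags(write=False)
        object.__setattr__(self, "matrix", mat)
        object.__setattr__(self, "item_labels", list(labels))

    @classmethod
    def from_data(cls, data: ItemScoreMatrix) -> "InterItemCovariance":
        if data.n_items < 2:
            raise InsufficientItemsError("need at least 2 items for covariances")
        return cls(np.cov(data.scores, rowvar=False, ddof=1), list(data.item_labels))

    @property
    def n_items(self) -> int:
        return self.matrix.shape[0]

    def partition(self, item: int):
        """Return ``(Sigma_ii, sigma_i)`` excluding the target item."""
        rest = [k for k in range(self.n_items) if k != item]
        sub = self.matrix[np.ix_(rest, rest)]
        vec = self.matrix[rest, item]
        return sub, vec


def lambda6_item(cov: InterItemCovariance, item: int) -> float:
    """lambda6 for one item: its squared multiple correlation on the rest."""
    variance = cov.matrix[item, item]
    if not variance > 0:
        raise DegenerateItemError(
            f"item {cov.item_labels[item]} has zero variance"
        )
    sub, vec = cov.partition(item)
    cond = np.linalg.cond(sub)
    if not np.isfinite(cond) or cond > _COND_LIMIT:
        rest_labels = [lab for k, lab in enumerate(cov.item_labels) if k != item]
        # name the items loading on the near-null eigenvector
        w, v = np.linalg.eigh(sub)
        null_vec = np.abs(v[:, 0])
        involved = [
            lab
            for lab, load in zip(rest_labels, null_vec)
            if load > 0.1 * null_vec.max()
        ]
        raise CollinearityError(
            f"covariance matrix excluding item {cov.item_labels[item]} is "
            f"(near-)singular (cond={cond:.3g}); dependent items: "
            + ", ".join(involved)
        )
    explained = float(vec @ np.linalg.solve(sub, vec))
    return explained / float(variance)


def lambda6_test_score(data: ItemScoreMatrix) -> float:
    """Guttman's lambda6 for the *test* score: 1 - sum(eps_i^2) / var(X).

    Internal utility; the per-item variant is the headline method.
    """
    cov = InterItemCovariance.from_data(data)
    eps = 0.0
    for i in range(data.n_items):
        sub, vec = cov.partition(i)
        eps += cov.matrix[i, i] - float(vec @ np.linalg.solve(sub, vec))
    total_var = data.scores.sum(axis=1).var(ddof=1)
    return 1.0 - eps / total_var


def lambda6_all(data: ItemScoreMatrix) -> ReliabilityReport:
    """lambda6 for every item, with the framework-route consistency check."""
    if data.n_items < 2:
        raise InsufficientItemsError("method lambda6 needs at least 2 items")
    cov = InterItemCovariance.from_data(data)
    tables = estimate_cumulative_tables(data)
    estimates = np.empty(data.n_items)
    for i in range(data.n_items):
        direct = lambda6_item(cov, i)
        # internal consistency: route the flat approximation through the
        # framework assembly; the two must agree to machine precision
        sub, vec = cov.partition(i)
        explained = float(vec @ np.linalg.solve(sub, vec))
        marginal = tables.marginal[i, 1:]
        approx = explained / data.m**2 + np.outer(marginal, marginal)
        framework = reliability_from_approximation(
            approx, marginal, cov.matrix[i, i]
        )
        if abs(framework - direct) > 1e-9 * max(1.0, abs(direct)):
            raise AssertionError(
                f"framework route {framework!r} != direct route {direct!r} "
                f"for item {data.item_labels[i]}"
            )
        estimates[i] = direct
    return ReliabilityReport(
        method="LAMBDA6",
        estimates=estimates,
        settings={},
        item_labels=list(data.item_labels),
    )
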