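"""Cumulative-probability framework for item-score reliability.

Everything here is classical test theory on a single administration.  For
item scores ``x, y = 0..m`` the marginal cumulative probability is
``pi_x(i) = P(Xi >= x)`` and the joint cumulative probability for two items is
``pi_x(i),y(j) = P(Xi >= x, Xj >= y)``.  Item-score reliability is

    rho_ii' = sum_x sum_y [pi_x(i),y(i') - pi_x(i) pi_y(i)] / var(Xi)

where ``i'`` denotes an independent repetition of item ``i``.  The joint
probabilities over repetitions are unobservable; every estimator in this
package is a rule for approximating them, after which
:func:`reliability_from_approximation` assembles the reliability.

The ordered P(++) matrix arranges all ``J*m`` item steps ``(i, x)`` by
ascending marginal cumulative probability; same-item cells are unobservable.
Its complement, the P(--) matrix, holds ``P(Xi < x, Xj < y)``.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from .data import ItemScoreMatrix
from .exceptions import DataValidationError, DegenerateItemError

__all__ = [
    "CumulativeTables",
    "PPlusMatrix",
    "estimate_cumulative_tables",
    "order_item_steps",
    "build_pplus",
    "reliability_from_approximation",
]


@dataclass(frozen=True)
class CumulativeTables:
    """Sample (or supplied) cumulative probabilities and item variances.

    Attributes
    ----------
    marginal : ndarray of shape (J, m+1)
        ``marginal[i, x] = P(Xi >= x)``; column 0 is identically 1.
    joint : ndarray of shape (J, J, m, m)
        ``joint[i, j, x-1, y-1] = P(Xi >= x, Xj >= y)`` for scores
        ``x, y = 1..m``.  Same-item entries ``joint[i, i]`` refer to a single
        administration (not a repetition) and may be NaN when the tables are
        constructed from published pairwise values only.
    item_variances : ndarray of shape (J,)
        Sample variances of the item scores (denominator N-1).
    """

    marginal: np.ndarray
    joint: np.ndarray
    item_variances: np.ndarray
    item_labels: list = None

    def __post_init__(self):
        marginal = np.asarray(self.marginal, dtype=float)
        joint = np.asarray(self.joint, dtype=float)
        variances = np.asarray(self.item_variances, dtype=float)
        j, m_plus_1 = marginal.shape
        m = m_plus_1 - 1
        if m < 1:
            raise DataValidationError("marginal table needs columns for x=0..m, m>=1")
        if joint.shape != (j, j, m, m):
            raise DataValidationError(
                f"joint table shape {joint.shape} != {(j, j, m, m)}"
            )
        if not np.allclose(marginal[:, 0], 1.0):
            raise DataValidationError("pi_0(i) must equal 1 for every item")
        if np.any(np.diff(marginal, axis=1) > 1e-12):
            raise DataValidationError("marginal rows must be nonincreasing in x")
        labels = self.item_labels or [f"V{k + 1}" for k in range(j)]
        for arr in (marginal, joint, variances):
            arr.setflags(write=False)
        object.__setattr__(self, "marginal", marginal)
        object.__setattr__(self, "joint", joint)
        object.__setattr__(self, "item_variances", variances)
        object.__setattr__(self, "item_labels", list(labels))

    @property
    def n_items(self) -> int:
        return self.marginal.shape[0]

    @property
    def m(self) -> int:
        return self.marginal.shape[1] - 1


def estimate_cumulative_tables(data: ItemScoreMatrix) -> CumulativeTables:
    """Estimate all marginal and pairwise-joint cumulative proportions.

    Proportions use denominator ``N``; item variances use ``N - 1``.
    """
    scores = data.scores
    n, j = scores.shape
    m = data.m
    # indicator cube: geq[p, i, x-1] = 1{X_pi >= x}, x = 1..m
    geq = scores[:, :, None] >= np.arange(1, m + 1)[None, None, :]
    geq = geq.astype(float)
    marginal = np.concatenate([np.ones((j, 1)), geq.mean(axis=0).reshape(j, m)], axis=1)
    joint = np.einsum("nix,njy->ijxy", geq, geq) / n
    variances = scores.var(axis=0, ddof=1)
    return CumulativeTables(marginal, joint, variances, list(data.item_labels))


def order_item_steps(tables: CumulativeTables):
    """Order the ``J*m`` item steps ``(i, x)`` by ascending ``pi_x(i)``.

    Ties are broken deterministically by (item index, descending score
    category).  Returns a list of ``(item, x)`` pairs.
    """
    steps = [
        (i, x)
        for i in range(tables.n_items)
        for x in range(1, tables.m + 1)
    ]
    return sorted(steps, key=lambda s: (tables.marginal[s[0], s[1]], s[0], -s[1]))


@dataclass(frozen=True)
class PPlusMatrix:
    """Ordered P(++) matrix with its P(--) complement.

    ``values[r, c]`` holds ``pi_x(i),y(j)`` for the r-th and c-th ordered item
    steps; same-item cells are unobservable and stored as NaN, with
    ``observable`` False.  ``complement[r, c] = P(Xi < x, Xj < y)``.
    Published reports index cells 1-based via :meth:`cell`.
    """

    steps: list
    marginals: np.ndarray
    values: np.ndarray
    observable: np.ndarray
    complement: np.ndarray
    item_labels: list

    @property
    def size(self) -> int:
        return len(self.steps)

    @property
    def step_labels(self):
        return [f"pi{x}({self.item_labels[i]})" for i, x in self.steps]

    def cell(self, row: int, col: int) -> float:
        """1-based cell accessor matching published (row, column) reports."""
        return float(self.values[row - 1, col - 1])

    def monotonicity_violations(self, tol: float = 1e-12) -> int:
        """Count observable adjacent pairs that decrease along a row or column.

        Under the double monotonicity model rows and columns are
        nondecreasing; sample matrices may violate this.  Diagnostic only --
        no correction is ever applied.
        """
        count = 0
        v, obs = self.values, self.observable
        for mat, mask in ((v, obs), (v.T, obs.T)):
            both = mask[:, 1:] & mask[:, :-1]
            count += int(np.sum((mat[:, 1:] - mat[:, :-1] < -tol) & both))
        return count

    def to_csv(self, path_or_buf=None, float_format: str = "%.4f"):
        """Dump the matrix with ordered step labels and NA for unobservable cells."""
        buf = io.StringIO()
        labels = self.step_labels
        buf.write("," + ",".join(labels) + "\n")
        for r in range(self.size):
            cells = [
                (float_format % self.values[r, c]) if self.observable[r, c] else "NA"
                for c in range(self.size)
            ]
            buf.write(labels[r] + "," + ",".join(cells) + "\n")
        text = buf.getvalue()
        if path_or_buf is None:
            return text
        if hasattr(path_or_buf, "write"):
            path_or_buf.write(text)
        else:
            with open(path_or_buf, "w", encoding="utf-8") as fh:
                fh.write(text)
        return None


def build_pplus(tables: CumulativeTables, order=None) -> PPlusMatrix:
    """Assemble the ordered P(++) matrix and its P(--) complement.

    The complement is derived cellwise as
    ``P(Xi < x, Xj < y) = 1 - pi_x(i) - pi_y(j) + pi_x(i),y(j)``.
    """
    if order is None:
        order = order_item_steps(tables)
    size = len(order)
    marginals = np.array([tables.marginal[i, x] for i, x in order])
    values = np.full((size, size), np.nan)
    observable = np.zeros((size, size), dtype=bool)
    for r, (i, x) in enumerate(order):
        for c, (jj, y) in enumerate(order):
            if i == jj:
                continue
            values[r, c] = tables.joint[i, jj, x - 1, y - 1]
            observable[r, c] = True
    complement = 1.0 - marginals[:, None] - marginals[None, :] + values
    return PPlusMatrix(
        steps=list(order),
        marginals=marginals,
        values=values,
        observable=observable,
        complement=complement,
        item_labels=list(tables.item_labels),
    )


def reliability_from_approximation(approx, marginal, item_variance) -> float:
    """Assemble an item-score reliability from an approximation table.

    Parameters
    ----------
    approx : ndarray of shape (m, m)
        Approximation of the same-item joint cumulative probabilities
        ``pi_x(i),y(i')`` for ``x, y = 1..m``.
    marginal : ndarray of shape (m,)
        Marginal cumulative probabilities ``pi_x(i)`` for ``x = 1..m``.
    item_variance : float
        Variance of the item score (must be positive).

    Returns
    -------
    float
        ``sum_xy [approx_xy - pi_x pi_y] / item_variance``, not clipped to
        [0, 1].
    """
    approx = np.asarray(approx, dtype=float)
    marginal = np.asarray(marginal, dtype=float)
    if approx.shape != (marginal.size, marginal.size):
        raise DataValidationError(
            f"approximation table shape {approx.shape} does not match "
            f"m={marginal.size}"
        )
    if not item_variance > 0:
        raise DegenerateItemError(
            f"item variance must be positive, got {item_variance}"
        )
    return float((approx - np.outer(marginal, marginal)).sum() / item_variance)
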