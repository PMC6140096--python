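"""Method MS: neighbor-based approximation of same-item joint probabilities.

Each unobservable same-item cell of the ordered P(++) matrix is replaced by
the mean of at most eight neighbor-based approximations.  Candidate
generation is isolated in :func:`candidate_values` so the scheme can be
swapped without touching anything else.  Three schemes are provided:

``"ratio"`` (default)
    Each of the up to four observable orthogonal neighbors contributes two
    candidates: its P(++) value rescaled by the ratio of the target to the
    neighbor marginal (``v * p_target / p_neighbor``), and its P(--)
    complement value rescaled by the corresponding complement-marginal ratio
    and mapped back to the P(++) scale.  Four neighbors x two matrices gives
    the "at most eight" approximations; a cell and its mirror draw on the
    same neighbors by symmetry.  The marginal-ratio correction removes the
    boundary bias a raw neighbor copy would have for the most extreme item
    steps.

``"pp"``
    The observable orthogonal neighbor values themselves, averaged raw.

``"pp_mm"``
    Raw P(++) neighbor values plus raw P(--) neighbor values mapped back via
    ``pi = q + p_row + p_col - 1``.

All three draw on the same source cells: for the published worked example
the cell of ``pi_1(1),2(1')`` at (8,2) has no lower neighbor and draws on
exactly the proportions at cells (8,1), (7,2) and (8,3), i.e. {.32, .51,
.70} (:func:`source_proportions`).
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass

import numpy as np

from .ctt import (
    CumulativeTables,
    PPlusMatrix,
    build_pplus,
    estimate_cumulative_tables,
    reliability_from_approximation,
)
from .data import ItemScoreMatrix, ReliabilityReport
from .exceptions import DegenerateItemError, InsufficientItemsError

__all__ = [
    "MSApproximation",
    "Candidate",
    "candidate_values",
    "source_proportions",
    "ms_approximate",
    "ms_reliability",
]

SCHEMES = ("ratio", "pp", "pp_mm")

_NEIGHBOR_OFFSETS = ((-1, 0), (1, 0), (0, -1), (0, 1))

_EPS = 1e-12

#: one candidate approximation: its value, the neighbor cell it draws on
#: (0-based row/col in the ordered matrix), and which matrix it came from
#: ("pp" for P(++), "mm" for the P(--) complement).
Candidate = namedtuple("Candidate", ["value", "row", "col", "matrix"])


def _neighbors(pplus: PPlusMatrix, row: int, col: int):
    size = pplus.size
    for dr, dc in _NEIGHBOR_OFFSETS:
        r, c = row + dr, col + dc
        if 0 <= r < size and 0 <= c < size and pplus.observable[r, c]:
            yield r, c, bool(dr)


def candidate_values(pplus: PPlusMatrix, row: int, col: int, scheme: str = "ratio"):
    """Candidate approximations for the unobservable cell (row, col), 0-based.

    Returns a list of :class:`Candidate`; empty when no neighbor is
    observable.  Candidates whose rescaling denominator vanishes are skipped.
    """
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")
    p = pplus.marginals
    out = []
    for r, c, row_step in _neighbors(pplus, row, col):
        value = float(pplus.values[r, c])
        comp = float(pplus.complement[r, c])
        # the neighbor differs from the target in exactly one marginal
        p_target = p[row] if row_step else p[col]
        p_neigh = p[r] if row_step else p[c]
        if scheme == "pp":
            out.append(Candidate(value, r, c, "pp"))
        elif scheme == "pp_mm":
            out.append(Candidate(value, r, c, "pp"))
            out.append(Candidate(comp + p[row] + p[col] - 1.0, r, c, "mm"))
        else:  # ratio
            if p_neigh > _EPS:
                out.append(Candidate(value * p_target / p_neigh, r, c, "pp"))
            if 1.0 - p_neigh > _EPS:
                scaled = comp * (1.0 - p_target) / (1.0 - p_neigh)
                out.append(Candidate(scaled + p[row] + p[col] - 1.0, r, c, "mm"))
    return out


def source_proportions(pplus: PPlusMatrix, row: int, col: int, scheme: str = "ratio"):
    """The set of observable P(++) proportions a cell's candidates draw on."""
    return {
        round(float(pplus.values[cand.row, cand.col]), 12)
        for cand in candidate_values(pplus, row, col, scheme)
    }


@dataclass(frozen=True)
class MSApproximation:
    """Per-item m x m tables of approximated same-item joint probabilities.

    ``tables[i][x-1, y-1]`` approximates ``pi_x(i),y(i')``; ``candidates``
    maps ``(item, x, y)`` to the :class:`Candidate` list actually averaged.
    """

    tables: dict
    candidates: dict
    scheme: str


def ms_approximate(
    pplus: PPlusMatrix, tables: CumulativeTables = None, scheme: str = "ratio"
) -> MSApproximation:
    """Approximate every unobservable same-item cell of the P(++) matrix.

    When a neighbor is unavailable (border rows/columns, or an adjacent
    same-item cell), only the available candidates are averaged.  If no
    candidate at all is available (pathological tiny inputs) the independence
    value ``pi_x(i) * pi_y(i)`` is used and a warning is emitted.
    """
    items = sorted({i for i, _ in pplus.steps})
    if len(items) < 2:
        raise InsufficientItemsError(
            "method MS needs at least 2 items to supply neighbor candidates"
        )
    m = max(x for _, x in pplus.steps)
    position = {step: idx for idx, step in enumerate(pplus.steps)}
    out_tables = {}
    out_candidates = {}
    for i in items:
        table = np.empty((m, m))
        for x in range(1, m + 1):
            for y in range(1, m + 1):
                r, c = position[(i, x)], position[(i, y)]
                cands = candidate_values(pplus, r, c, scheme=scheme)
                if cands:
                    value = float(np.mean([cand.value for cand in cands]))
                else:
                    value = float(pplus.marginals[r] * pplus.marginals[c])
                    warnings.warn(
                        f"no neighbor candidate for item {i}, cell "
                        f"(x={x}, y={y}); falling back to independence",
                        stacklevel=2,
                    )
                table[x - 1, y - 1] = min(1.0, max(0.0, value))
                out_candidates[(i, x, y)] = cands
        out_tables[i] = table
    return MSApproximation(tables=out_tables, candidates=out_candidates, scheme=scheme)


def ms_reliability(data: ItemScoreMatrix, scheme: str = "ratio") -> ReliabilityReport:
    """Item-score reliability by method MS (deterministic)."""
    if data.n_items < 2:
        raise InsufficientItemsError("method MS needs at least 2 items")
    tables = estimate_cumulative_tables(data)
    for i, v in enumerate(tables.item_variances):
        if not v > 0:
            raise DegenerateItemError(
                f"item {data.item_labels[i]} has zero variance"
            )
    pplus = build_pplus(tables)
    approx = ms_approximate(pplus, tables, scheme=scheme)
    estimates = np.array(
        [
            reliability_from_approximation(
                approx.tables[i],
                tables.marginal[i, 1:],
                tables.item_variances[i],
            )
            for i in range(data.n_items)
        ]
    )
    return ReliabilityReport(
        method="MS",
        estimates=estimates,
        settings={"scheme": scheme},
        item_labels=list(data.item_labels),
    )
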