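"""Core data types and file I/O for person x item score matrices.

The universal input of every estimator in this package is an
:class:`ItemScoreMatrix`: an ``N x J`` integer matrix with entries in
``{0, ..., m}``, one row per person, one column per item.  All items share a
single maximum category score ``m``; mixed-format tests are out of scope.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    DataValidationError,
    MissingValueError,
    ParseError,
)

__all__ = [
    "ItemScoreMatrix",
    "ReliabilityReport",
    "read_scores",
    "write_scores",
    "total_and_rest_scores",
]


@dataclass(frozen=True)
class ItemScoreMatrix:
    """Validated person x item integer score matrix.

    Parameters
    ----------
    scores : ndarray of shape (N, J)
        Integer item scores, each in ``{0, ..., m}``.
    m : int
        Maximum category score, shared by all items.
    item_labels : list of str
        One identifier per item (defaults to ``"V1" .. "VJ"``).
    """

    scores: np.ndarray
    m: int
    item_labels: list = field(default=None)

    def __post_init__(self):
        scores = np.asarray(self.scores)
        if scores.ndim != 2:
            raise DataValidationError("scores must be a 2-D person x item matrix")
        if not np.issubdtype(scores.dtype, np.integer):
            if np.issubdtype(scores.dtype, np.floating) and np.all(
                np.isfinite(scores)
            ) and np.all(scores == np.round(scores)):
                scores = scores.astype(np.int64)
            else:
                raise DataValidationError("scores must be integers")
        else:
            scores = scores.astype(np.int64)
        n, j = scores.shape
        if n < 2:
            raise DataValidationError(f"need at least 2 persons, got N={n}")
        if j < 1:
            raise DataValidationError("need at least 1 item")
        if self.m < 1:
            raise DataValidationError(f"maximum score m must be >= 1, got m={self.m}")
        if scores.min() < 0:
            raise DataValidationError("negative scores are not allowed")
        if scores.max() > self.m:
            raise DataValidationError(
                f"score {scores.max()} exceeds declared maximum m={self.m}"
            )
        labels = self.item_labels
        if labels is None:
            labels = [f"V{k + 1}" for k in range(j)]
        labels = [str(x) for x in labels]
        if len(labels) != j:
            raise DataValidationError(
                f"{len(labels)} item labels for {j} items"
            )
        scores.setflags(write=False)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "item_labels", labels)

    @property
    def n_persons(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    @classmethod
    def from_array(cls, scores, m=None, item_labels=None, shift_to_zero=False):
        """Build a matrix from an array, inferring ``m`` from the observed maximum.

        Scores are required to start at 0; pass ``shift_to_zero=True`` to
        rebase inputs whose overall minimum exceeds 0.
        """
        arr = np.asarray(scores)
        if arr.size and arr.min() > 0:
            if shift_to_zero:
                arr = arr - arr.min()
            else:
                raise DataValidationError(
                    "scores must start at 0 (observed minimum is "
                    f"{arr.min()}); use shift_to_zero to rebase"
                )
        if m is None:
            m = int(arr.max()) if arr.size else 0
            if m < 1:
                raise DataValidationError(
                    "cannot infer m: all observed scores are 0; declare m explicitly"
                )
        return cls(arr, int(m), item_labels)

    def drop_item(self, item: int) -> "ItemScoreMatrix":
        """Return a copy without column ``item`` (labels preserved)."""
        keep = [k for k in range(self.n_items) if k != item]
        return ItemScoreMatrix(
            self.scores[:, keep], self.m, [self.item_labels[k] for k in keep]
        )


@dataclass
class ReliabilityReport:
    """Per-item reliability estimates produced by one method.

    ``estimates`` are raw (unclipped) real numbers, one per item.  For
    stochastic methods (LCRC) ``settings`` always records the seed.
    """

    method: str
    estimates: np.ndarray
    settings: dict
    item_labels: list = None

    def __post_init__(self):
        if self.method not in {"MS", "LAMBDA6", "LCRC", "CA"}:
            raise ValueError(f"unknown method {self.method!r}")
        self.estimates = np.asarray(self.estimates, dtype=float)
        if self.estimates.ndim != 1:
            raise ValueError("estimates must be a vector with one value per item")
        if self.item_labels is not None and len(self.item_labels) != len(
            self.estimates
        ):
            raise ValueError("item_labels length does not match estimates")
        if self.method == "LCRC" and "seed" not in self.settings:
            raise ValueError("LCRC reports must record the seed in settings")

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "settings": _jsonable(self.settings),
            "item_labels": self.item_labels,
            "estimates": [float(v) for v in self.estimates],
        }

    def to_json(self, path=None, indent=2):
        text = json.dumps(self.to_dict(), indent=indent)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def read_scores(
    path,
    delimiter: str = ",",
    header: bool = False,
    m: int = None,
    shift_to_zero: bool = False,
) -> ItemScoreMatrix:
    """Read an item-score matrix from a delimited text file.

    One row per person, one column per item, integer cells, optional single
    header row with item labels.  ``m`` is inferred as the observed maximum
    unless given.

    Raises
    ------
    ParseError
        If a cell does not parse as an integer (names the row and column).
    MissingValueError
        If a cell is empty or a common NA marker.
    DataValidationError
        For negative scores, ragged rows, or scores not starting at 0.
    """
    na_markers = {"", "NA", "N/A", "NAN", "NULL", "."}
    rows = []
    labels = None
    with open(path, "r", encoding="utf-8", newline="") as fh:
        reader = csv.reader(fh, delimiter=delimiter)
        for lineno, record in enumerate(reader, start=1):
            if not record or all(not c.strip() for c in record):
                continue
            if header and labels is None:
                labels = [c.strip() for c in record]
                continue
            parsed = []
            for colno, cell in enumerate(record, start=1):
                text = cell.strip()
                if text.upper() in na_markers:
                    raise MissingValueError(
                        f"missing value at row {lineno}, column {colno} of {path}"
                    )
                try:
                    value = int(text)
                except ValueError:
                    raise ParseError(
                        f"non-integer cell {text!r} at row {lineno}, "
                        f"column {colno} of {path}"
                    ) from None
                parsed.append(value)
            rows.append(parsed)
    if not rows:
        raise DataValidationError(f"no data rows in {path}")
    widths = {len(r) for r in rows}
    if len(widths) != 1:
        raise DataValidationError(f"ragged rows in {path}: widths {sorted(widths)}")
    arr = np.array(rows, dtype=np.int64)
    if arr.min() < 0:
        raise DataValidationError(f"negative score in {path}")
    if labels is not None and len(labels) != arr.shape[1]:
        raise DataValidationError(
            f"header has {len(labels)} fields for {arr.shape[1]} columns"
        )
    return ItemScoreMatrix.from_array(
        arr, m=m, item_labels=labels, shift_to_zero=shift_to_zero
    )


def write_scores(data: ItemScoreMatrix, path, delimiter: str = ",", header: bool = False):
    """Write a matrix in the format accepted by :func:`read_scores`."""
    with open(path, "w", encoding="utf-8", newline="") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        if header:
            writer.writerow(data.item_labels)
        writer.writerows(data.scores.tolist())


def total_and_rest_scores(data: ItemScoreMatrix, item: int):
    """Return ``(X, R(i))``: the test score and the rest score for one item.

    ``X`` is the per-person row sum of all item scores and
    ``R(i) = X - Xi`` elementwise.
    """
    if not 0 <= item < data.n_items:
        raise IndexError(f"item index {item} out of range [0, {data.n_items})")
    total = data.scores.sum(axis=1)
    rest = total - data.scores[:, item]
    return total, rest
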