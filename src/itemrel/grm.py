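"""Multidimensional graded response model simulator.

Item scores are generated from

    P(Xi >= x | theta) = logistic( sum_q alpha_iq (theta_q - delta_ix) ),

with ``theta`` multivariate standard normal with a given correlation matrix.
Six named condition presets mirror the simulation design they were taken
from:

=============  ====  ===  ===  ======  =========================================
name              J    m    Q       N  deviation from the standard condition
=============  ====  ===  ===  ======  =========================================
standard          6    1    1   1,000  --
polytomous        6    4    1   1,000  five ordered categories
unequal_alpha     6    1    1   1,000  discriminations alternate 0.5 / 2
two_dim           6    1    2   1,000  loadings alternate dimensions, corr .5
long_test        18    1    1   1,000  standard items copied twice (3 blocks)
small_n           6    1    1     200  sample size 200
=============  ====  ===  ===  ======  =========================================

The population item-score reliability of a condition is approximated by
Monte Carlo: for a large set of simulees the conditional expected item score
``T_i = sum_x P(Xi >= x | theta)`` is computed exactly and its variance is
divided by the variance of the sampled item scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import expit

from .data import ItemScoreMatrix
from .exceptions import InvalidConditionError

__all__ = [
    "GRMCondition",
    "condition",
    "CONDITION_NAMES",
    "grm_cumulative",
    "cumulative_probs",
    "simulate_dataset",
    "population_item_reliability",
]

_STANDARD_DELTAS = np.linspace(-1.5, 1.5, 6)


@dataclass(frozen=True)
class GRMCondition:
    """One simulation condition of the graded response model.

    ``discrimination`` is J x Q, ``location`` is J x m with strictly
    increasing rows, ``theta_correlation`` is a Q x Q correlation matrix.
    """

    name: str
    n_persons: int
    discrimination: np.ndarray
    location: np.ndarray
    theta_correlation: np.ndarray = None
    replications: int = 1000

    def __post_init__(self):
        disc = np.atleast_2d(np.asarray(self.discrimination, dtype=float))
        loc = np.atleast_2d(np.asarray(self.location, dtype=float))
        if disc.shape[0] != loc.shape[0]:
            raise InvalidConditionError(
                "discrimination and location must agree on the number of items"
            )
        corr = self.theta_correlation
        if corr is None:
            corr = np.eye(disc.shape[1])
        corr = np.atleast_2d(np.asarray(corr, dtype=float))
        if corr.shape != (disc.shape[1], disc.shape[1]):
            raise InvalidConditionError("theta correlation must be Q x Q")
        if not np.allclose(np.diag(corr), 1.0) or not np.allclose(corr, corr.T):
            raise InvalidConditionError(
                "theta correlation must be symmetric with unit diagonal"
            )
        if np.any(np.linalg.eigvalsh(corr) <= 0):
            raise InvalidConditionError("theta correlation must be positive definite")
        if loc.shape[1] > 1 and np.any(np.diff(loc, axis=1) <= 0):
            raise InvalidConditionError(
                "location parameters must be strictly increasing within item"
            )
        if self.n_persons < 2:
            raise InvalidConditionError("need at least 2 simulees")
        for arr in (disc, loc, corr):
            arr.setflags(write=False)
        object.__setattr__(self, "discrimination", disc)
        object.__setattr__(self, "location", loc)
        object.__setattr__(self, "theta_correlation", corr)

    @property
    def n_items(self) -> int:
        return self.discrimination.shape[0]

    @property
    def n_dims(self) -> int:
        return self.discrimination.shape[1]

    @property
    def m(self) -> int:
        return self.location.shape[1]

    def item_strata(self) -> list:
        """Per-item stratum labels used in stratified study reports.

        Items are labelled by discrimination level when discriminations
        differ (``low_alpha`` / ``high_alpha``) and by dominant dimension
        when Q > 1 (``theta1`` ...); otherwise ``all``.
        """
        disc = self.discrimination
        if self.n_dims > 1:
            return [f"theta{int(np.argmax(np.abs(row))) + 1}" for row in disc]
        levels = np.unique(disc)
        if levels.size > 1:
            mid = levels.mean()
            return ["high_alpha" if a > mid else "low_alpha" for a in disc[:, 0]]
        return ["all"] * self.n_items


def _polytomous_locations() -> np.ndarray:
    first = np.array([-3.0, -2.4, -1.8, -1.2, -0.6, 0.0])
    return first[:, None] + np.arange(4)[None, :] * 1.0


_PRESETS = {}


def _register(name, **kwargs):
    _PRESETS[name] = kwargs


_register(
    "standard",
    n_persons=1000,
    discrimination=np.ones((6, 1)),
    location=_STANDARD_DELTAS[:, None],
)
_register(
    "polytomous",
    n_persons=1000,
    discrimination=np.ones((6, 1)),
    location=_polytomous_locations(),
)
_register(
    "unequal_alpha",
    n_persons=1000,
    discrimination=np.array([[0.5], [2.0], [0.5], [2.0], [0.5], [2.0]]),
    location=_STANDARD_DELTAS[:, None],
)
_register(
    "two_dim",
    n_persons=1000,
    discrimination=np.array(
        [[1.0, 0.0], [0.0, 1.0], [1.0, 0.0], [0.0, 1.0], [1.0, 0.0], [0.0, 1.0]]
    ),
    location=_STANDARD_DELTAS[:, None],
    theta_correlation=np.array([[1.0, 0.5], [0.5, 1.0]]),
)
_register(
    "long_test",
    n_persons=1000,
    discrimination=np.ones((18, 1)),
    location=np.tile(_STANDARD_DELTAS, 3)[:, None],
)
_register(
    "small_n",
    n_persons=200,
    discrimination=np.ones((6, 1)),
    location=_STANDARD_DELTAS[:, None],
)

CONDITION_NAMES = tuple(_PRESETS)


def condition(preset, **overrides) -> GRMCondition:
    """Return a preset condition (by name), optionally overriding fields."""
    if isinstance(preset, GRMCondition):
        return replace(preset, **overrides) if overrides else preset
    if preset not in _PRESETS:
        raise InvalidConditionError(
            f"unknown condition {preset!r}; choose from {CONDITION_NAMES}"
        )
    spec = dict(_PRESETS[preset])
    spec.update(overrides)
    spec.setdefault("name", preset)
    return GRMCondition(**spec)


def grm_cumulative(theta, alpha_row, delta) -> float:
    """``P(Xi >= x | theta)`` for one item step: the logistic of
    ``sum_q alpha_q (theta_q - delta)``."""
    theta = np.atleast_1d(np.asarray(theta, dtype=float))
    alpha_row = np.atleast_1d(np.asarray(alpha_row, dtype=float))
    return float(expit(np.sum(alpha_row * (theta - delta))))


def cumulative_probs(cond: GRMCondition, theta: np.ndarray) -> np.ndarray:
    """``P(Xi >= x | theta)`` for all simulees/items/steps: shape (n, J, m)."""
    theta = np.atleast_2d(theta)
    lin = theta @ cond.discrimination.T  # (n, J)
    alpha_sum = cond.discrimination.sum(axis=1)  # (J,)
    pred = lin[:, :, None] - cond.location[None, :, :] * alpha_sum[None, :, None]
    return expit(pred)


def draw_theta(cond: GRMCondition, n: int, rng) -> np.ndarray:
    """Draw n latent vectors from the Q-variate standard normal with the
    condition's correlation matrix (Cholesky factorization)."""
    z = rng.standard_normal((n, cond.n_dims))
    chol = np.linalg.cholesky(cond.theta_correlation)
    return z @ chol.T


def _sample_scores(cum, rng) -> np.ndarray:
    # score >= x  iff  u < P(Xi >= x | theta); one uniform per person/item
    u = rng.random(cum.shape[:2])
    return (u[:, :, None] < cum).sum(axis=2)


def simulate_dataset(cond: GRMCondition, seed=None) -> ItemScoreMatrix:
    """Draw one N x J data set from the condition (bit-reproducible given seed)."""
    rng = np.random.default_rng(seed)
    theta = draw_theta(cond, cond.n_persons, rng)
    cum = cumulative_probs(cond, theta)
    scores = _sample_scores(cum, rng)
    return ItemScoreMatrix(scores, cond.m)


def population_item_reliability(
    cond: GRMCondition, n_simulees: int = 1_000_000, seed=None, chunk: int = 200_000
) -> np.ndarray:
    """Monte-Carlo population item-score reliability, one value per item.

    ``Var(T_i) / Var(X_i)`` over ``n_simulees`` draws, where
    ``T_i = sum_x P(Xi >= x | theta)`` uses exact model probabilities and
    ``X_i`` are sampled item scores.  Chunked to bound memory.
    """
    if n_simulees < 10_000:
        raise InvalidConditionError("need at least 10^4 simulees")
    rng = np.random.default_rng(seed)
    j = cond.n_items
    sums = np.zeros((4, j))  # sum T, sum T^2, sum X, sum X^2
    done = 0
    while done < n_simulees:
        size = min(chunk, n_simulees - done)
        theta = draw_theta(cond, size, rng)
        cum = cumulative_probs(cond, theta)
        t = cum.sum(axis=2)
        x = _sample_scores(cum, rng).astype(float)
        sums[0] += t.sum(axis=0)
        sums[1] += (t**2).sum(axis=0)
        sums[2] += x.sum(axis=0)
        sums[3] += (x**2).sum(axis=0)
        done += size
    var_t = sums[1] / done - (sums[0] / done) ** 2
    var_x = sums[3] / done - (sums[2] / done) ** 2
    return var_t / var_x
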