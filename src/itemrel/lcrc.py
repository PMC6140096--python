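"""Latent class reliability coefficient (method LCRC).

An unconstrained latent class model with K classes,

    P(X1=x1, ..., XJ=xJ) = sum_k P(xi=k) prod_j P(Xj=xj | xi=k),

is fitted by EM from multiple random starts.  The fitted parameters imply the
same-item joint cumulative probabilities over independent repetitions,

    pi~_x(i),y(i') = sum_{u>=x} sum_{v>=y} sum_k P(xi=k) P(Xi=u|k) P(Xi=v|k),

which are inserted into the reliability assembly together with the *sample*
marginals and variances.

Implementation notes
--------------------
* EM runs on the unique response patterns and is vectorized across all random
  starts simultaneously, which makes 25 starts barely more expensive than one.
* Class-conditional probabilities are initialized from uniform Dirichlet
  draws; convergence is declared when the relative log-likelihood change
  drops below ``tol`` (default 1e-8), with a hard cap of ``max_iter``
  iterations.
* The log-likelihood is monitored for monotonicity; EM guarantees it never
  decreases, so a drop beyond 1e-10 raises.
* Label switching needs no correction: the joint approximation is invariant
  under class permutation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .ctt import estimate_cumulative_tables, reliability_from_approximation
from .data import ItemScoreMatrix, ReliabilityReport
from .exceptions import ConvergenceError, DataValidationError, DegenerateItemError

__all__ = [
    "LatentClassModel",
    "fit_lcm",
    "lcrc_joint_approx",
    "lcrc_reliability",
    "model_item_reliability",
]

_LOG_FLOOR = 1e-300


@dataclass(frozen=True)
class LatentClassModel:
    """Fitted (or specified) unconstrained latent class model.

    Attributes
    ----------
    weights : ndarray of shape (K,)
        Class probabilities ``P(xi = k)``.
    response : ndarray of shape (K, J, m+1)
        Conditional category probabilities ``P(Xi = x | xi = k)``.
    """

    weights: np.ndarray
    response: np.ndarray
    loglik: float = np.nan
    n_starts: int = 0
    seed: object = None
    converged: bool = True
    n_iter: int = 0
    loglik_history: np.ndarray = field(default=None, repr=False)
    start_logliks: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        weights = np.asarray(self.weights, dtype=float)
        response = np.asarray(self.response, dtype=float)
        if weights.ndim != 1:
            raise DataValidationError("weights must be a vector over classes")
        if response.ndim != 3 or response.shape[0] != weights.size:
            raise DataValidationError("response must have shape (K, J, m+1)")
        if np.any(weights < -1e-12) or abs(weights.sum() - 1.0) > 1e-8:
            raise DataValidationError("class weights must be a probability vector")
        if np.any(response < -1e-12) or np.any(
            np.abs(response.sum(axis=2) - 1.0) > 1e-8
        ):
            raise DataValidationError(
                "each response row must be a probability vector over categories"
            )
        weights.setflags(write=False)
        response.setflags(write=False)
        object.__setattr__(self, "weights", weights)
        object.__setattr__(self, "response", response)

    @property
    def n_classes(self) -> int:
        return self.weights.size

    @property
    def n_items(self) -> int:
        return self.response.shape[1]

    @property
    def m(self) -> int:
        return self.response.shape[2] - 1

    @classmethod
    def dichotomous(cls, weights, success_probs, n_items: int = 1) -> "LatentClassModel":
        """Build a model of ``n_items`` identical dichotomous items from
        per-class success probabilities (convenience for worked examples)."""
        weights = np.asarray(weights, dtype=float)
        p = np.asarray(success_probs, dtype=float)
        per_class = np.stack([1 - p, p], axis=-1)  # (K, 2)
        response = np.repeat(per_class[:, None, :], n_items, axis=1)
        return cls(weights=weights, response=response)

    def n_parameters(self) -> int:
        k, j, mp1 = self.response.shape
        return (k - 1) + k * j * (mp1 - 1)

    def bic(self, n: int) -> float:
        return -2.0 * self.loglik + self.n_parameters() * np.log(n)

    def marginal_cumulative(self, item: int) -> np.ndarray:
        """Model-implied ``P(Xi >= x)`` for x = 1..m."""
        cum = np.cumsum(self.response[:, item, ::-1], axis=1)[:, ::-1]
        return self.weights @ cum[:, 1:]

    def category_probs(self, item: int) -> np.ndarray:
        """Model-implied ``P(Xi = x)`` for x = 0..m."""
        return self.weights @ self.response[:, item, :]


def _batched_em(onehot, counts, K, weights, response, tol, max_iter):
    """Run EM for all starts at once on unique-pattern data.

    Returns (weights, response, loglik, n_iter, converged, history).
    Shapes: onehot (P, J, C); weights (S, K); response (S, K, J, C).
    """
    n = counts.sum()
    S = weights.shape[0]
    prev = np.full(S, -np.inf)
    converged = np.zeros(S, dtype=bool)
    n_iter = np.zeros(S, dtype=int)
    history = []
    for it in range(1, max_iter + 1):
        logresp = np.log(np.clip(response, _LOG_FLOOR, None))
        logw = np.log(np.clip(weights, _LOG_FLOOR, None))
        # log P(pattern p | class k), per start: (S, P, K)
        cls_ll = np.einsum("pjc,skjc->spk", onehot, logresp)
        logjoint = logw[:, None, :] + cls_ll
        top = logjoint.max(axis=2, keepdims=True)
        lse = top[:, :, 0] + np.log(
            np.exp(logjoint - top).sum(axis=2)
        )
        loglik = lse @ counts
        history.append(loglik)
        # EM never decreases the log-likelihood; tolerate float noise only
        if np.any(loglik < prev - 1e-10 * np.maximum(1.0, np.abs(prev))):
            raise AssertionError("EM log-likelihood decreased beyond tolerance")
        rel = np.abs(loglik - prev) / np.maximum(np.abs(loglik), 1.0)
        newly = (~converged) & (rel < tol)
        n_iter[newly] = it
        converged |= newly
        prev = loglik
        if converged.all():
            break
        z = np.exp(logjoint - lse[:, :, None])  # posterior (S, P, K)
        nk = np.einsum("spk,p->sk", z, counts)
        weights = nk / n
        num = np.einsum("spk,p,pjc->skjc", z, counts, onehot)
        safe = np.maximum(nk, _LOG_FLOOR)
        response = num / safe[:, :, None, None]
        # an emptied class keeps weight 0 and a uniform response row
        empty = nk <= 0
        if empty.any():
            response[empty] = 1.0 / onehot.shape[2]
    n_iter[~converged] = max_iter
    return weights, response, prev, n_iter, converged, np.array(history)


def fit_lcm(
    data: ItemScoreMatrix,
    K: int,
    n_starts: int = 25,
    seed=None,
    *,
    tol: float = 1e-8,
    max_iter: int = 2000,
) -> LatentClassModel:
    """Fit an unconstrained LCM by EM, best of ``n_starts`` random starts.

    Reproducible given ``seed``.  Raises :class:`ConvergenceError` only when
    every start fails to converge; emits an identifiability warning when K
    exceeds the number of distinct response patterns.
    """
    if K < 1:
        raise DataValidationError(f"K must be >= 1, got {K}")
    if data.n_persons <= K:
        raise DataValidationError(
            f"need more persons than classes (N={data.n_persons}, K={K})"
        )
    patterns, counts = np.unique(data.scores, axis=0, return_counts=True)
    if K > patterns.shape[0]:
        warnings.warn(
            f"K={K} exceeds the {patterns.shape[0]} distinct response "
            "patterns; the model is not identifiable",
            stacklevel=2,
        )
    C = data.m + 1
    onehot = (patterns[:, :, None] == np.arange(C)).astype(float)
    counts = counts.astype(float)
    rng = np.random.default_rng(seed)
    weights0 = rng.dirichlet(np.ones(K), size=n_starts)
    response0 = rng.dirichlet(np.ones(C), size=(n_starts, K, data.n_items))
    weights, response, loglik, n_iter, converged, history = _batched_em(
        onehot, counts, K, weights0, response0, tol, max_iter
    )
    if not converged.any():
        raise ConvergenceError(
            f"no EM start converged within {max_iter} iterations",
            diagnostics={"final_loglik": loglik, "n_iter": n_iter},
        )
    best = int(np.argmax(loglik))
    w = np.clip(weights[best], 0.0, None)
    w = w / w.sum()
    r = np.clip(response[best], 0.0, None)
    r = r / r.sum(axis=2, keepdims=True)
    return LatentClassModel(
        weights=w,
        response=r,
        loglik=float(loglik[best]),
        n_starts=n_starts,
        seed=seed,
        converged=bool(converged[best]),
        n_iter=int(n_iter[best]),
        loglik_history=history[:, best],
        start_logliks=loglik.copy(),
    )


def lcrc_joint_approx(model: LatentClassModel, item: int) -> np.ndarray:
    """Model-implied m x m table of ``pi~_x(i),y(i')`` for x, y = 1..m.

    For a single class this reduces exactly to the product of marginals
    (independence); the table is symmetric and nonincreasing in x and y.
    """
    m = model.m
    # cumulative P(Xi >= x | k) for x = 1..m, per class: (K, m)
    cum = np.cumsum(model.response[:, item, ::-1], axis=1)[:, ::-1][:, 1:]
    return np.einsum("k,kx,ky->xy", model.weights, cum, cum)


def model_item_reliability(model: LatentClassModel, item: int) -> float:
    """Item-score reliability implied by the model parameters alone.

    Uses the model-implied marginals and the model-implied item-score
    variance (population form).  For dichotomous items this is
    ``(pi~_11' - pi_1^2) / (pi_1 (1 - pi_1))``.
    """
    approx = lcrc_joint_approx(model, item)
    marginal = model.marginal_cumulative(item)
    probs = model.category_probs(item)
    x = np.arange(model.m + 1)
    variance = float(probs @ x**2 - (probs @ x) ** 2)
    return reliability_from_approximation(approx, marginal, variance)


def select_classes_bic(
    data: ItemScoreMatrix, k_max: int = 5, n_starts: int = 25, seed=None, **em_kwargs
):
    """Fit K = 1..k_max and return ``(best_model, bic_table)`` by minimum BIC."""
    seq = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    seeds = seq.spawn(k_max)
    models = []
    table = []
    for k in range(1, k_max + 1):
        model = fit_lcm(data, k, n_starts=n_starts, seed=seeds[k - 1], **em_kwargs)
        models.append(model)
        table.append({"K": k, "loglik": model.loglik, "bic": model.bic(data.n_persons)})
    best = int(np.argmin([row["bic"] for row in table]))
    return models[best], table


def lcrc_reliability(
    data: ItemScoreMatrix,
    K="bic",
    n_starts: int = 25,
    seed=None,
    k_max: int = 5,
    **em_kwargs,
) -> ReliabilityReport:
    """Item-score reliability by method LCRC.

    ``K`` is either an integer number of classes or ``"bic"`` (fit K=1..k_max,
    keep the minimum-BIC model).  The fitted model supplies the joint
    approximation; marginals and variances come from the sample.
    """
    bic_table = None
    if K == "bic":
        model, bic_table = select_classes_bic(
            data, k_max=k_max, n_starts=n_starts, seed=seed, **em_kwargs
        )
    else:
        model = fit_lcm(data, int(K), n_starts=n_starts, seed=seed, **em_kwargs)
    tables = estimate_cumulative_tables(data)
    estimates = np.empty(data.n_items)
    for i in range(data.n_items):
        if not tables.item_variances[i] > 0:
            raise DegenerateItemError(f"item {data.item_labels[i]} has zero variance")
        estimates[i] = reliability_from_approximation(
            lcrc_joint_approx(model, i),
            tables.marginal[i, 1:],
            tables.item_variances[i],
        )
    settings = {
        "K": model.n_classes,
        "selection": "bic" if K == "bic" else "fixed",
        "n_starts": n_starts,
        "seed": _seed_repr(seed),
        "loglik": model.loglik,
        "converged": model.converged,
    }
    if bic_table is not None:
        settings["bic_table"] = bic_table
    return ReliabilityReport(
        method="LCRC",
        estimates=estimates,
        settings=settings,
        item_labels=list(data.item_labels),
    )


def _seed_repr(seed):
    if seed is None or isinstance(seed, (int, np.integer)):
        return None if seed is None else int(seed)
    if isinstance(seed, np.random.SeedSequence):
        return list(map(int, seed.entropy if np.iterable(seed.entropy) else [seed.entropy]))
    return repr(seed)
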