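"""Bias/variability study harness.

Runs the reliability estimators over replicated simulated data sets and
summarizes, per (condition, method), the pooled differences
``estimate - population value`` across items and replications by median
bias, IQR, and percentage of boxplot outliers (beyond 1.5 x IQR from the
quartiles).

Two quartile conventions are supported, because outlier percentages are
sensitive to them: ``"tukey"`` (hinges, the convention of the boxplot
implementations the published figures typically come from) and ``"linear"``
(linearly interpolated quantiles, numpy's default).

Seed policy: one master seed per study; per-condition and per-replication
child streams are spawned deterministically, so any condition can be rerun
in isolation and the whole study is bit-reproducible.
"""

from __future__ import annotations

import json
import math
from collections import namedtuple
from dataclasses import dataclass, field

import numpy as np

from .ca import ca_reliability
from .exceptions import ItemrelError
from .grm import GRMCondition, condition, population_item_reliability, simulate_dataset
from .lambda6 import lambda6_all
from .lcrc import lcrc_reliability
from .ms import ms_reliability

__all__ = ["Summary", "summarize", "StudyResult", "run_study", "METHODS"]

Summary = namedtuple("Summary", ["median_bias", "iqr", "pct_outliers"])

_QUARTILE_CONVENTIONS = ("tukey", "linear")


def _tukey_hinges(sorted_x: np.ndarray):
    n = sorted_x.size
    d = (math.floor((n + 1) / 2) + 1) / 2  # 1-based hinge position
    lo = int(math.floor(d)) - 1
    frac = d - math.floor(d)
    q1 = sorted_x[lo] + frac * (sorted_x[min(lo + 1, n - 1)] - sorted_x[lo])
    hi = int(math.floor(n + 1 - d)) - 1
    frac_hi = (n + 1 - d) - math.floor(n + 1 - d)
    q3 = sorted_x[hi] + frac_hi * (sorted_x[min(hi + 1, n - 1)] - sorted_x[hi])
    return float(q1), float(q3)


def quartiles(x, convention: str = "tukey"):
    """First and third quartile under the requested convention."""
    if convention not in _QUARTILE_CONVENTIONS:
        raise ValueError(
            f"unknown quartile convention {convention!r}; "
            f"choose from {_QUARTILE_CONVENTIONS}"
        )
    xs = np.sort(np.asarray(x, dtype=float).ravel())
    if xs.size == 0:
        raise ValueError("empty vector")
    if convention == "tukey":
        return _tukey_hinges(xs)
    q1, q3 = np.percentile(xs, [25, 75])
    return float(q1), float(q3)


def summarize(differences, convention: str = "tukey") -> Summary:
    """Median bias, IQR, and percentage of boxplot outliers of a vector.

    Outliers lie outside ``[Q1 - 1.5 IQR, Q3 + 1.5 IQR]``.
    """
    x = np.asarray(differences, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty vector")
    q1, q3 = quartiles(x, convention)
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    pct = 100.0 * np.mean((x < lo) | (x > hi))
    return Summary(float(np.median(x)), float(iqr), float(pct))


@dataclass
class StudyResult:
    """Raw pooled differences and bookkeeping for one study run."""

    differences: dict  # condition -> method -> (R_ok, J) array
    population: dict  # condition -> (J,) array
    item_strata: dict  # condition -> list of per-item labels
    failures: list
    seed: object
    settings: dict = field(default_factory=dict)

    def pooled(self, cond_name: str, method: str) -> np.ndarray:
        """Differences pooled across replications and items (flat vector)."""
        return self.differences[cond_name][method].ravel()

    def summary_rows(self, convention: str = "tukey") -> list:
        """Fig-1-style summary rows, pooled and stratified where applicable."""
        rows = []
        for cond_name, per_method in self.differences.items():
            strata = np.array(self.item_strata[cond_name])
            for method, diffs in per_method.items():
                groups = [("pooled", slice(None))]
                if len(set(strata)) > 1:
                    groups += [(s, strata == s) for s in sorted(set(strata))]
                for label, sel in groups:
                    vec = diffs[:, sel].ravel()
                    s = summarize(vec, convention)
                    rows.append(
                        {
                            "condition": cond_name,
                            "method": method,
                            "stratum": label,
                            "median_bias": s.median_bias,
                            "iqr": s.iqr,
                            "pct_outliers": s.pct_outliers,
                            "n": int(vec.size),
                        }
                    )
        return rows

    def to_json(self, path=None, convention: str = "tukey", indent=2):
        payload = {
            "seed": self.seed,
            "settings": self.settings,
            "population": {k: v.tolist() for k, v in self.population.items()},
            "item_strata": self.item_strata,
            "failures": self.failures,
            "summary": self.summary_rows(convention),
            "differences": {
                c: {m: d.tolist() for m, d in per.items()}
                for c, per in self.differences.items()
            },
        }
        text = json.dumps(payload, indent=indent)
        if path is not None:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text + "\n")
        return text


def _estimate(method, data, lcrc_opts, seed_seq):
    if method == "MS":
        return ms_reliability(data)
    if method == "LAMBDA6":
        return lambda6_all(data)
    if method == "CA":
        return ca_reliability(data)
    if method == "LCRC":
        return lcrc_reliability(data, seed=seed_seq, **lcrc_opts)
    raise ValueError(f"unknown method {method!r}")


METHODS = ("MS", "LAMBDA6", "LCRC", "CA")


def run_study(
    conditions,
    methods=("MS", "LAMBDA6", "CA"),
    replications: int = 1000,
    seed=None,
    lcrc_opts: dict = None,
    population_simulees: int = 1_000_000,
    progress=None,
) -> StudyResult:
    """Simulate, estimate, and difference against the population reliability.

    Parameters
    ----------
    conditions : sequence of condition names or :class:`GRMCondition`
    methods : subset of ``("MS", "LAMBDA6", "LCRC", "CA")``
    replications : data sets per condition
    seed : master seed (int or SeedSequence)
    lcrc_opts : forwarded to :func:`itemrel.lcrc.lcrc_reliability`
        (e.g. ``{"K": "bic", "n_starts": 25}``)
    population_simulees : Monte-Carlo size for the population value,
        computed once per condition with a dedicated child stream.

    Per-replication estimator failures are recorded in ``failures`` and the
    replication is dropped for that method only, never silently.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods {sorted(unknown)}")
    lcrc_opts = dict(lcrc_opts or {})
    lcrc_opts.setdefault("K", "bic")
    conds = [condition(c) for c in conditions]
    master = np.random.SeedSequence(seed)
    cond_seqs = master.spawn(len(conds))
    differences = {}
    population = {}
    strata = {}
    failures = []
    for cond_obj, cond_seq in zip(conds, cond_seqs):
        streams = cond_seq.spawn(replications + 1)
        pop_rho = population_item_reliability(
            cond_obj, n_simulees=population_simulees, seed=streams[0]
        )
        population[cond_obj.name] = pop_rho
        strata[cond_obj.name] = cond_obj.item_strata()
        per_method = {mth: [] for mth in methods}
        for r in range(replications):
            sim_seq, est_seq = streams[r + 1].spawn(2)
            data = simulate_dataset(cond_obj, seed=sim_seq)
            for mth in methods:
                try:
                    report = _estimate(mth, data, lcrc_opts, est_seq)
                except ItemrelError as err:
                    failures.append(
                        {
                            "condition": cond_obj.name,
                            "replication": r,
                            "method": mth,
                            "error": f"{type(err).__name__}: {err}",
                        }
                    )
                    continue
                per_method[mth].append(report.estimates - pop_rho)
            if progress is not None:
                progress(cond_obj.name, r)
        differences[cond_obj.name] = {
            mth: np.array(rows).reshape(len(rows), cond_obj.n_items)
            for mth, rows in per_method.items()
        }
    return StudyResult(
        differences=differences,
        population=population,
        item_strata=strata,
        failures=failures,
        seed=seed if seed is None or isinstance(seed, int) else repr(seed),
        settings={
            "methods": list(methods),
            "replications": replications,
            "lcrc": {k: (v if not isinstance(v, np.random.SeedSequence) else repr(v)) for k, v in lcrc_opts.items()},
            "population_simulees": population_simulees,
        },
    )
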