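"""Decomposable BIC scoring of discrete Bayesian-network structures.

The score of a DAG G on an N-row fully observed cohort is

    BIC(G) = 2 L - k ln N,
    L      = sum over rows and variables of ln Pr{X_i | pa(X_i)},

with Pr estimated by maximum likelihood on the same cohort, and
k = sum_i (r_i - 1) * prod_{p in pa(i)} r_p the free-parameter count
(r denotes state counts).  Natural logarithms throughout; L is reported in
nats.  The score decomposes per family (child, parents), which the scorer
caches aggressively for greedy search.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import log, prod

import numpy as np

from .cohort import CohortTable
from .graph import PDAG


@dataclass
class ScoreValue:
    """Total log-likelihood, parameter count, sample size and BIC."""

    L: float
    k: int
    N: int

    @property
    def bic(self) -> float:
        return 2.0 * self.L - self.k * log(self.N)


class BICScorer:
    """Cached family-wise BIC scorer over one fully observed cohort."""

    def __init__(self, cohort: CohortTable):
        if not cohort.is_fully_observed():
            raise ValueError("BIC scoring requires a fully observed cohort")
        self.cohort = cohort
        self.N = cohort.n
        self.names = cohort.columns
        self.index = {n: i for i, n in enumerate(self.names)}
        self.cards = np.array([v.n_states for v in cohort.schema])
        self._data = cohort.values
        self._cache: dict[tuple[str, tuple[str, ...]], tuple[float, int]] = {}

    def family(self, child: str, parents) -> tuple[float, int]:
        """(log-likelihood contribution, parameter count) of one family."""
        parents = tuple(sorted(parents))
        key = (child, parents)
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        ci = self.index[child]
        r = int(self.cards[ci])
        if parents:
            pidx = [self.index[p] for p in parents]
            pcards = self.cards[pidx]
            cfg = np.ravel_multi_index(
                self._data[:, pidx].T, pcards
            )
            joint = np.ravel_multi_index(
                (cfg, self._data[:, ci]), (int(np.prod(pcards)), r)
            )
            njoint = np.bincount(joint, minlength=int(np.prod(pcards)) * r)
            njoint = njoint.reshape(-1, r)
            ncfg = njoint.sum(axis=1)
            nz = njoint > 0
            rows = np.nonzero(nz)[0]  # parent-config index of each nonzero cell
            vals = njoint[nz].astype(float)
            ll = float((vals * (np.log(vals) - np.log(ncfg[rows]))).sum())
            q = int(np.prod(pcards))
        else:
            counts = np.bincount(self._data[:, ci], minlength=r).astype(float)
            nzc = counts > 0
            ll = float((counts[nzc] * (np.log(counts[nzc]) - log(self.N))).sum())
            q = 1
        k = (r - 1) * q
        self._cache[key] = (ll, k)
        return ll, k

    def score_parent_map(self, parent_map: dict[str, set[str]]) -> ScoreValue:
        L = 0.0
        k = 0
        for child in self.names:
            ll, kk = self.family(child, parent_map.get(child, ()))
            L += ll
            k += kk
        return ScoreValue(L, k, self.N)

    def delta_insert(self, parent_map, child: str, parent: str) -> float:
        """BIC change from adding parent -> child."""
        old = parent_map.get(child, set())
        l0, k0 = self.family(child, old)
        l1, k1 = self.family(child, old | {parent})
        return 2.0 * (l1 - l0) - (k1 - k0) * log(self.N)

    def delta_delete(self, parent_map, child: str, parent: str) -> float:
        """BIC change from removing parent -> child."""
        old = parent_map.get(child, set())
        l0, k0 = self.family(child, old)
        l1, k1 = self.family(child, old - {parent})
        return 2.0 * (l1 - l0) - (k1 - k0) * log(self.N)


def score_bic(graph: PDAG, cohort: CohortTable) -> ScoreValue:
    """BIC of a PDAG, scored on a consistent DAG extension.

    Score-equivalence of the BIC makes the choice of extension immaterial.
    """
    dag = graph if graph.is_dag() else graph.consistent_extension()
    parent_map = {v: dag.parents(v) for v in cohort.columns}
    return BICScorer(cohort).score_parent_map(parent_map)
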