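"""Causal networks: a DAG with conditional probability tables.

Parameters are posterior means under a symmetric Dirichlet prior
(``prior_strength`` pseudo-counts per CPT row, split evenly across child
states), so ``prior_strength -> 0`` recovers maximum likelihood and every
fitted probability is strictly positive for ``prior_strength > 0``.
Inference is exact variable elimination with a min-fill ordering; the
do-operator clamps a node and severs its incoming edges (truncated
factorization).
"""

from __future__ import annotations

import json
from functools import reduce

import numpy as np

from .cohort import CohortTable
from .graph import GraphError, PDAG


class Factor:
    """Dense non-negative table over a tuple of named discrete variables."""

    __slots__ = ("vars", "table")

    def __init__(self, vars_, table):
        self.vars = tuple(vars_)
        self.table = np.asarray(table, dtype=float)
        assert self.table.ndim == len(self.vars)

    def multiply(self, other: "Factor") -> "Factor":
        all_vars = list(self.vars) + [v for v in other.vars if v not in self.vars]
        a = self._broadcast(all_vars)
        b = other._broadcast(all_vars)
        return Factor(all_vars, a * b)

    def _broadcast(self, all_vars) -> np.ndarray:
        # transpose own axes into ascending target order, then add singleton
        # axes for variables this factor does not mention
        src = [all_vars.index(v) for v in self.vars]
        order = np.argsort(src)
        t = np.transpose(self.table, axes=order)
        shape = [1] * len(all_vars)
        for pos, ax in enumerate(sorted(src)):
            shape[ax] = t.shape[pos]
        return t.reshape(shape)

    def marginalize(self, var: str) -> "Factor":
        ax = self.vars.index(var)
        return Factor(
            self.vars[:ax] + self.vars[ax + 1 :], self.table.sum(axis=ax)
        )

    def reduce_evidence(self, var: str, state: int) -> "Factor":
        ax = self.vars.index(var)
        return Factor(
            self.vars[:ax] + self.vars[ax + 1 :],
            np.take(self.table, state, axis=ax),
        )


class ZeroSupportError(ValueError):
    """Evidence configuration has probability zero under the network."""


class CausalNetwork:
    """Directed acyclic graph plus CPTs over discrete variables.

    Attributes
    ----------
    nodes : list of str, topologically ordered.
    parents : dict node -> ordered tuple of parent names.
    cards : dict node -> state count.
    cpts : dict node -> ndarray of shape (*parent cards, card); rows
        (fixed parent configuration) sum to 1.
    """

    def __init__(self, parents, cards, cpts, prior_strength=None):
        import networkx as nx

        self.parents = {v: tuple(ps) for v, ps in parents.items()}
        self.cards = dict(cards)
        self.cpts = {v: np.asarray(t, dtype=float) for v, t in cpts.items()}
        self.prior_strength = prior_strength
        g = nx.DiGraph()
        g.add_nodes_from(self.parents)
        for v, ps in self.parents.items():
            g.add_edges_from((p, v) for p in ps)
        if not nx.is_directed_acyclic_graph(g):
            raise GraphError("network structure contains a directed cycle")
        self.nodes = list(nx.topological_sort(g))
        self._graph = g
        for v in self.nodes:
            t = self.cpts[v]
            want = tuple(self.cards[p] for p in self.parents[v]) + (self.cards[v],)
            if t.shape != want:
                raise ValueError(f"CPT shape mismatch for {v}: {t.shape} != {want}")
            if not np.allclose(t.sum(axis=-1), 1.0, atol=1e-9):
                raise ValueError(f"CPT rows of {v} do not sum to 1")

    # ------------------------------------------------------------ structure
    def children(self, v: str) -> set[str]:
        return set(self._graph.successors(v))

    def markov_boundary(self, node: str) -> set[str]:
        """Parents, children and children's other parents of ``node``."""
        if node not in self.parents:
            raise KeyError(node)
        mb = set(self.parents[node]) | self.children(node)
        for c in self.children(node):
            mb |= set(self.parents[c])
        mb.discard(node)
        return mb

    def aligned_cpt(self, v: str) -> np.ndarray:
        """CPT of ``v`` with parent axes in sorted-name order (the layout
        :func:`fit_parameters` produces), for cross-network comparison."""
        ps = self.parents[v]
        order = tuple(sorted(range(len(ps)), key=lambda i: ps[i]))
        return np.transpose(self.cpts[v], axes=order + (len(ps),))

    def to_pdag(self) -> PDAG:
        return PDAG(
            self.nodes,
            {(p, v) for v, ps in self.parents.items() for p in ps},
        )

    def is_descendant(self, node: str, of: str) -> bool:
        import networkx as nx

        return node in nx.descendants(self._graph, of)

    # ------------------------------------------------------------ inference
    def factors(self) -> list[Factor]:
        return [
            Factor(self.parents[v] + (v,), self.cpts[v]) for v in self.nodes
        ]

    def infer(self, target: str, evidence: dict[str, int] | None = None) -> np.ndarray:
        """Exact posterior distribution of ``target`` given ``evidence``.

        Variable elimination with min-fill ordering over the hidden
        variables.  Raises :class:`ZeroSupportError` if the evidence has
        zero probability.
        """
        evidence = dict(evidence or {})
        if target in evidence:
            raise ValueError("cannot condition on the inference target")
        for v, s in evidence.items():
            if not (0 <= s < self.cards[v]):
                raise ValueError(f"state {s} out of range for {v}")
        factors = []
        for f in self.factors():
            for v, s in evidence.items():
                if v in f.vars:
                    f = f.reduce_evidence(v, s)
            factors.append(f)
        hidden = [
            v for v in self.nodes if v != target and v not in evidence
        ]
        for v in _min_fill_order(factors, hidden):
            related = [f for f in factors if v in f.vars]
            if not related:
                continue
            factors = [f for f in factors if v not in f.vars]
            prod = reduce(Factor.multiply, related)
            factors.append(prod.marginalize(v))
        result = reduce(
            Factor.multiply, [f for f in factors if target in f.vars]
        )
        # factors not mentioning the target have been fully reduced to scalars
        scalar = 1.0
        for f in factors:
            if target not in f.vars:
                scalar *= float(f.table.sum()) if f.vars else float(f.table)
        table = result.table
        if table.sum() * scalar <= 0:
            raise ZeroSupportError("evidence has zero probability")
        return table / table.sum()

    def joint_table(self) -> Factor:
        """Full joint distribution (enumeration oracle; small networks only)."""
        return reduce(Factor.multiply, self.factors())

    # ---------------------------------------------------------- intervention
    def intervene(self, node: str, state: int) -> "CausalNetwork":
        """Mutilated network under do(node = state): incoming edges removed,
        node clamped to a point mass."""
        if not (0 <= state < self.cards[node]):
            raise ValueError(f"state {state} out of range for {node}")
        parents = dict(self.parents)
        cpts = dict(self.cpts)
        parents[node] = ()
        point = np.zeros(self.cards[node])
        point[state] = 1.0
        cpts[node] = point
        return CausalNetwork(parents, self.cards, cpts, self.prior_strength)

    # ------------------------------------------------------------- sampling
    def sample(self, n: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
        """Ancestral sampling in topological order."""
        out: dict[str, np.ndarray] = {}
        for v in self.nodes:
            ps = self.parents[v]
            cpt = self.cpts[v]
            if not ps:
                probs = np.broadcast_to(cpt, (n, self.cards[v]))
            else:
                idx = tuple(out[p] for p in ps)
                probs = cpt[idx]
            u = rng.random((n, 1))
            out[v] = (probs.cumsum(axis=1) < u).sum(axis=1).astype(np.int64)
        return out

    # -------------------------------------------------------- serialization
    def to_json(self, path=None) -> str:
        doc = {
            "prior_strength": self.prior_strength,
            "nodes": self.nodes,
            "cards": self.cards,
            "parents": {v: list(ps) for v, ps in self.parents.items()},
            "cpts": {v: self.cpts[v].tolist() for v in self.nodes},
        }
        s = json.dumps(doc)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s)
        return s

    @classmethod
    def from_json(cls, source) -> "CausalNetwork":
        if isinstance(source, str) and source.lstrip().startswith("{"):
            doc = json.loads(source)
        else:
            with open(source) as fh:
                doc = json.load(fh)
        return cls(
            doc["parents"], doc["cards"], doc["cpts"], doc.get("prior_strength")
        )


def _min_fill_order(factors: list[Factor], hidden: list[str]) -> list[str]:
    """Greedy min-fill elimination ordering (ties lexicographic)."""
    cliques = [set(f.vars) for f in factors]
    order = []
    hidden = set(hidden)
    while hidden:
        best = None
        for v in sorted(hidden):
            nb = set()
            for c in cliques:
                if v in c:
                    nb |= c
            nb.discard(v)
            fill = sum(
                1
                for a, b in _pairs(sorted(nb))
                if not any(a in c and b in c for c in cliques)
            )
            if best is None or fill < best[0]:
                best = (fill, v, nb)
        _, v, nb = best
        order.append(v)
        hidden.discard(v)
        cliques = [c for c in cliques if v not in c]
        cliques.append(nb)
    return order


def _pairs(xs):
    from itertools import combinations

    return combinations(xs, 2)


def fit_parameters(
    dag: PDAG, cohort: CohortTable, prior_strength: float = 1.0
) -> CausalNetwork:
    """Bayesian CPT estimation on a fully directed DAG.

    Each CPT cell is the symmetric-Dirichlet posterior mean
    ``(count + prior_strength / r) / (config count + prior_strength)`` with
    r the child's state count; an unobserved parent configuration yields a
    uniform row.
    """
    if dag.undirected:
        raise GraphError("fit_parameters requires a fully directed DAG")
    if not cohort.is_fully_observed():
        raise ValueError("parameter fitting requires a fully observed cohort")
    if set(dag.nodes) != set(cohort.columns):
        raise ValueError("DAG nodes must match cohort variables")
    cards = {v.name: v.n_states for v in cohort.schema}
    parents = {v: tuple(sorted(dag.parents(v))) for v in dag.nodes}
    cpts = {}
    for v in dag.nodes:
        ps = parents[v]
        r = cards[v]
        shape = tuple(cards[p] for p in ps) + (r,)
        counts = np.zeros(shape)
        idx = tuple(cohort.column(p) for p in ps) + (cohort.column(v),)
        np.add.at(counts, idx, 1.0)
        num = counts + (prior_strength / r if prior_strength > 0 else 0.0)
        den = counts.sum(axis=-1, keepdims=True) + prior_strength
        if prior_strength == 0:
            with np.errstate(invalid="ignore", divide="ignore"):
                cpt = np.where(den > 0, num / np.maximum(den, 1e-300), 1.0 / r)
        else:
            cpt = num / den
        cpts[v] = cpt
    return CausalNetwork(parents, cards, cpts, prior_strength)
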