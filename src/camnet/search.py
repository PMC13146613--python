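"""Greedy equivalence search of the Markov equivalence class under
knowledge constraints.

The search is score-based on the decomposable BIC (2L - k ln N) and runs
directly over equivalence classes (CPDAGs), alternating

* a forward phase applying the best admissible Insert(x, y, T) operator —
  connect a non-adjacent pair, optionally directing a set T of y's
  undirected neighbours into y — until no insertion improves the score, and
* a backward phase applying the best Delete(x, y, H) operator until no
  deletion improves the score,

with operator validity (clique and semi-directed-path conditions) and score
deltas evaluated on the equivalence class itself, so that collider
configurations are scored correctly rather than through an arbitrary DAG
representative.  After every operator the graph is re-closed to a CPDAG
(consistent extension + pattern + Meek rules).  Knowledge constraints act
as hard filters: Insert(x, y, ·) is never considered when x -> y is
forbidden, and constraint-forced orientations are propagated on the final
CPDAG.  Tie-breaks on equal score improvement are lexicographic by
(child, parent) for reproducibility.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np

from .cohort import CohortTable
from .constraints import ConstraintSet
from .graph import PDAG
from .scoring import BICScorer

_EPS = 1e-9
_MAX_T = 3  # cap on |T| / |H| subset size per operator


def _is_clique(g: PDAG, nodes) -> bool:
    return all(g.has_adjacency(a, b) for a, b in combinations(sorted(nodes), 2))


def _semi_directed_blocked(g: PDAG, y: str, x: str, blocked: set[str]) -> bool:
    """True iff every semi-directed path y -> ... -> x passes through
    ``blocked``."""
    stack, seen = [y], {y}
    while stack:
        v = stack.pop()
        for w in g.children(v) | g.undirected_neighbors(v):
            if w in seen or w in blocked:
                continue
            if w == x:
                return False
            seen.add(w)
            stack.append(w)
    return True


def _subsets(items, max_size):
    items = sorted(items)
    yield ()
    for k in range(1, min(len(items), max_size) + 1):
        yield from combinations(items, k)


def _best_insert(g: PDAG, scorer: BICScorer, constraints):
    best = None
    names = sorted(g.nodes)
    for y in names:
        pa_y = g.parents(y)
        n_y = g.undirected_neighbors(y)
        for x in names:
            if x == y or g.has_adjacency(x, y):
                continue
            if constraints is not None and not constraints.is_allowed(x, y):
                continue
            na = {w for w in n_y if g.has_adjacency(w, x)}
            t_pool = n_y - na
            for T in _subsets(t_pool, _MAX_T):
                cond = na | set(T)
                if not _is_clique(g, cond):
                    continue
                if not _semi_directed_blocked(g, y, x, cond):
                    continue
                base = tuple(cond | pa_y)
                l0, k0 = scorer.family(y, base)
                l1, k1 = scorer.family(y, base + (x,))
                delta = 2.0 * (l1 - l0) - (k1 - k0) * np.log(scorer.N)
                key = (-delta, y, x, T)
                if delta > _EPS and (best is None or key < best[0]):
                    best = (key, x, y, T)
    return best


def _best_delete(g: PDAG, scorer: BICScorer):
    best = None
    pairs = sorted(
        {(a, b) for a, b in g.directed}
        | {(a, b) for a, b in g.undirected}
        | {(b, a) for a, b in g.undirected}
    )
    for x, y in pairs:
        pa_y = g.parents(y)
        na = {
            w
            for w in g.undirected_neighbors(y)
            if g.has_adjacency(w, x) and w != x
        }
        for H in _subsets(na, _MAX_T):
            keep = na - set(H)
            if not _is_clique(g, keep):
                continue
            base = tuple(keep | (pa_y - {x}))
            l0, k0 = scorer.family(y, tuple(set(base) | {x}))
            l1, k1 = scorer.family(y, base)
            delta = 2.0 * (l1 - l0) - (k1 - k0) * np.log(scorer.N)
            key = (-delta, y, x, H)
            if delta > _EPS and (best is None or key < best[0]):
                best = (key, x, y, H)
    return best


def _apply_insert(g: PDAG, x: str, y: str, T) -> PDAG:
    g = g.copy()
    g.add_directed(x, y)
    for t in T:
        g.orient(t, y)
    return _reclose(g)


def _apply_delete(g: PDAG, x: str, y: str, H) -> PDAG:
    g = g.copy()
    g.remove_edge(x, y)
    for h in H:
        if h in g.undirected_neighbors(y):
            g.orient(y, h)
        if h in g.undirected_neighbors(x):
            g.orient(x, h)
    return _reclose(g)


def _reclose(g: PDAG) -> PDAG:
    """Re-close a post-operator PDAG to the CPDAG of its extension."""
    return PDAG.from_dag(g.consistent_extension())


def search_mec(
    cohort: CohortTable,
    constraints: ConstraintSet | None = None,
    use_rule4: bool = False,
) -> PDAG:
    """Constrained greedy equivalence search returning a CPDAG.

    Parameters
    ----------
    cohort : CohortTable
        Fully observed discrete cohort.
    constraints : ConstraintSet, optional
        Forbidden ordered pairs; an edge violating them is never scored.
    use_rule4 : bool
        Enable the standard fourth orientation rule when propagating
        constraint-forced orientations (off by default).
    """
    names = cohort.columns
    if len(names) < 2:
        raise ValueError("need at least two variables")
    scorer = BICScorer(cohort)
    g = PDAG(names)
    improved = True
    while improved:
        improved = False
        while True:
            best = _best_insert(g, scorer, constraints)
            if best is None:
                break
            _, x, y, T = best
            g = _apply_insert(g, x, y, T)
            improved = True
        while True:
            best = _best_delete(g, scorer)
            if best is None:
                break
            _, x, y, H = best
            g = _apply_delete(g, x, y, H)
            improved = True
    if constraints is not None:
        g = _apply_constraint_orientations(g, constraints, use_rule4)
    return g


def _apply_constraint_orientations(
    cpdag: PDAG, constraints: ConstraintSet, use_rule4: bool
) -> PDAG:
    """Orient reversible edges whose opposite direction is forbidden, then
    re-close under Meek's rules, to fixpoint."""
    g = cpdag
    changed = True
    while changed:
        changed = False
        for a, b in sorted(g.undirected):
            fwd = constraints.is_allowed(a, b)
            bwd = constraints.is_allowed(b, a)
            if fwd and not bwd:
                g = g.copy()
                g.orient(a, b)
                changed = True
            elif bwd and not fwd:
                g = g.copy()
                g.orient(b, a)
                changed = True
            if changed:
                g = g.apply_meek_rules(use_rule4=use_rule4)
                break
    return g


def enumerate_dags(names: list[str]):
    """Yield every DAG over ``names`` as a parent map (brute force; use only
    for small oracles, <=5 variables)."""
    from itertools import product

    pairs = list(combinations(sorted(names), 2))
    for choice in product((0, 1, 2), repeat=len(pairs)):
        parent_map: dict[str, set[str]] = {v: set() for v in names}
        edges = []
        for (a, b), c in zip(pairs, choice):
            if c == 1:
                edges.append((a, b))
            elif c == 2:
                edges.append((b, a))
        g = PDAG(names, edges)
        if g.has_directed_cycle():
            continue
        for p, c in edges:
            parent_map[c].add(p)
        yield parent_map


def exhaustive_best_dag(
    cohort: CohortTable, constraints: ConstraintSet | None = None
) -> PDAG:
    """Argmax of the BIC over all DAGs (oracle for tiny problems).

    Ties are broken toward the first DAG in enumeration order, which — by
    score equivalence — still pins down a unique CPDAG.
    """
    scorer = BICScorer(cohort)
    best_score, best_map = -np.inf, None
    for parent_map in enumerate_dags(cohort.columns):
        if constraints is not None:
            ok = all(
                constraints.is_allowed(p, c)
                for c, ps in parent_map.items()
                for p in ps
            )
            if not ok:
                continue
        s = scorer.score_parent_map(parent_map).bic
        if s > best_score + _EPS:
            best_score, best_map = s, parent_map
    dag = PDAG(
        cohort.columns,
        {(p, c) for c, ps in best_map.items() for p in ps},
    )
    return PDAG.from_dag(dag)
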