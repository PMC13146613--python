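"""Causal direction identification by discrete additive-noise regression.

For an undirected MEC edge X—Y the model Y = f(X) + eps with eps independent
of X is fitted by discrete regression: f is a table over the states of X,
initialised at the conditional mode and iteratively updated to minimise the
dependence DM between X and the integer residual Y - f(X).  DM is the
negative p-value of the Pearson chi-square independence test, so a *less
negative* DM means more independent residuals.  A direction is accepted when
its residuals pass the independence test and the orientation introduces no
new v-structure or cycle in the equivalence class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import CohortTable
from .graph import PDAG, _key


@dataclass
class DiscreteRegressionFit:
    """Fitted regression table, residuals and the residual-independence test."""

    f: dict[int, int]
    residuals: np.ndarray
    p_indep: float
    iterations: int
    dm_history: list[float]  # DM after initialisation and after each sweep

    @property
    def dm(self) -> float:
        return -self.p_indep


@dataclass
class DirectionDecision:
    """Outcome of direction identification for one undirected edge."""

    edge: tuple[str, str]
    outcome: str  # "oriented" | "unresolved"
    reason: str  # sem_identified | forced_by_structure | both_fail | structure_conflict
    direction: tuple[str, str] | None = None
    p_values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.outcome == "oriented" and self.direction is None:
            raise ValueError("oriented decision must carry a direction")


def independence_pvalue(x: np.ndarray, resid: np.ndarray) -> float:
    """Pearson chi-square p-value for X vs residual, pooling sparse levels.

    Residual levels (columns) whose expected count falls below 5 are merged
    into an adjacent level before testing; a constant residual is perfectly
    independent (p = 1).
    """
    xs, xi = np.unique(x, return_inverse=True)
    rs, ri = np.unique(resid, return_inverse=True)
    if len(rs) < 2 or len(xs) < 2:
        return 1.0
    table = np.zeros((len(xs), len(rs)))
    np.add.at(table, (xi, ri), 1.0)
    # pool sparse residual columns into their neighbor
    while table.shape[1] > 2:
        n = table.sum()
        expected = np.outer(table.sum(1), table.sum(0)) / n
        if expected.min() >= 5:
            break
        j = int(np.argmin(table.sum(0)))
        k = j - 1 if j > 0 else j + 1
        table[:, k] += table[:, j]
        table = np.delete(table, j, axis=1)
    if table.shape[1] < 2:
        return 1.0
    _, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(p)


def fit_discrete_regression(
    x: np.ndarray,
    y: np.ndarray,
    alpha: float = 0.05,
    max_iter: int = 25,
) -> DiscreteRegressionFit:
    """Fit f: state(X) -> state(Y) minimising residual dependence.

    Starts from the conditional-mode table f0(x_i) = argmax_y n(x_i, y)
    (ties to the smallest y), then sweeps the states of X, replacing f(x_i)
    by the candidate y that minimises DM; candidates range over all observed
    states of Y.  Stops when the residuals pass the chi-square independence
    test at ``alpha`` or f stabilises.
    """
    x = np.asarray(x)
    y = np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    xstates = np.unique(x)
    if len(xstates) < 2:
        raise ValueError("constant regressor: cannot fit discrete regression")
    ystates = np.unique(y)

    # f0: conditional mode, ties -> smallest y
    f = {}
    for xi in xstates:
        counts = np.array([(y[x == xi] == yv).sum() for yv in ystates])
        f[int(xi)] = int(ystates[int(np.argmax(counts))])

    fx = np.array([f[int(v)] for v in x])
    p = independence_pvalue(x, y - fx)
    history = [-p]
    iterations = 0
    while p <= alpha and iterations < max_iter:
        iterations += 1
        changed = False
        for xi in xstates:
            sel = x == xi
            best_y, best_dm = f[int(xi)], -p
            for yv in ystates:
                if int(yv) == f[int(xi)]:
                    continue
                fx_try = fx.copy()
                fx_try[sel] = yv
                dm = -independence_pvalue(x, y - fx_try)
                if dm < best_dm - 1e-15 or (
                    dm == best_dm and int(yv) < best_y
                ):
                    best_y, best_dm = int(yv), dm
            if best_y != f[int(xi)]:
                f[int(xi)] = best_y
                fx[sel] = best_y
                p = -best_dm
                changed = True
        p = independence_pvalue(x, y - fx)
        history.append(-p)
        if not changed:
            break
    return DiscreteRegressionFit(f, y - fx, float(p), iterations, history)


def _orientation_valid(mec: PDAG, a: str, b: str) -> bool:
    """Would orienting a→b avoid any new v-structure and any cycle?"""
    for w in mec.parents(b):
        if w != a and not mec.has_adjacency(w, a):
            return False  # new collider w→b←a
    return not mec.creates_cycle(a, b)


def identify_direction(
    edge: tuple[str, str],
    mec: PDAG,
    cohort: CohortTable,
    alpha: float = 0.05,
) -> DirectionDecision:
    """Decide the orientation of one undirected MEC edge.

    Candidate orientations that would create a new v-structure or a cycle
    are discarded.  A single surviving candidate is confirmed (with veto) by
    the additive-noise residual test; when both survive, a direction is
    accepted only if exactly one of the two fits yields independent
    residuals.
    """
    u, v = edge
    if _key(u, v) not in mec.undirected:
        raise ValueError(f"{u}—{v} is not an undirected edge of the MEC")
    candidates = [
        (a, b) for a, b in ((u, v), (v, u)) if _orientation_valid(mec, a, b)
    ]
    key = _key(u, v)
    if not candidates:
        return DirectionDecision(key, "unresolved", "structure_conflict")

    pvals = {}
    for a, b in candidates:
        fit = fit_discrete_regression(
            cohort.column(a), cohort.column(b), alpha=alpha
        )
        pvals[f"{a}->{b}"] = fit.p_indep
    passed = [c for c in candidates if pvals[f"{c[0]}->{c[1]}"] > alpha]

    if len(candidates) == 1:
        if passed:
            return DirectionDecision(
                key, "oriented", "forced_by_structure", candidates[0], pvals
            )
        return DirectionDecision(key, "unresolved", "both_fail", None, pvals)
    if len(passed) == 1:
        return DirectionDecision(key, "oriented", "sem_identified", passed[0], pvals)
    return DirectionDecision(key, "unresolved", "both_fail", None, pvals)


def orient_all(
    mec: PDAG, cohort: CohortTable, alpha: float = 0.05, use_rule4: bool = False
) -> tuple[PDAG, list[DirectionDecision]]:
    """Run direction identification over all undirected edges.

    Edges are visited in lexicographic order; after each pass the Meek rules
    are re-applied, and passes repeat until no further edge is oriented.
    Returns the updated graph and the final decision per edge.
    """
    g = mec.copy()
    decisions: dict[tuple[str, str], DirectionDecision] = {}
    changed = True
    while changed:
        changed = False
        for edge in sorted(g.undirected):
            d = identify_direction(edge, g, cohort, alpha=alpha)
            decisions[edge] = d
            if d.outcome == "oriented":
                g.orient(*d.direction)
                changed = True
        if changed:
            g = g.apply_meek_rules(use_rule4=use_rule4)
    return g, list(decisions.values())
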