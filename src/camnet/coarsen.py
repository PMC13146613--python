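"""Network coarse-graining: absorb unresolvable edges into macro variables.

When neither orientation of an undirected edge is admissible (bidirectional
coupling or a hidden confounder), the incident variables are merged into a
macro variable whose state space is the Cartesian product of the member
state spaces.  Edges between members and outside nodes are re-attached to
the macro node with their original direction; the contraction must create
no cycle and no v-structure absent from the input graph.  The member set is
the smallest valid superset of the edge's endpoints (breadth-first search
ordered by size, then lexicographically).
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .cohort import CohortTable
from .graph import GraphError, PDAG, _key
from .schema import Schema, VariableSpec


@dataclass
class MacroVariable:
    """A coarse-grained node over >=2 member variables.

    Macro states enumerate member-state tuples in row-major order over the
    member list, i.e. state = ravel_multi_index(member_states, member_cards).
    """

    name: str
    members: list[str]
    member_cards: list[int]

    @property
    def n_states(self) -> int:
        return int(np.prod(self.member_cards))

    def encode(self, member_states) -> int:
        return int(np.ravel_multi_index(tuple(member_states), self.member_cards))

    def decode(self, state: int) -> tuple[int, ...]:
        return tuple(int(v) for v in np.unravel_index(state, self.member_cards))

    def state_labels(self) -> list[str]:
        labels = []
        for s in range(self.n_states):
            combo = self.decode(s)
            labels.append(
                "&".join(f"{m}={v}" for m, v in zip(self.members, combo))
            )
        return labels


def macro_name(members) -> str:
    return "+".join(sorted(members))


def _contract(graph: PDAG, members: set[str], name: str) -> PDAG:
    """Contract ``members`` into one node; raises GraphError on conflicting
    inherited edge directions."""
    g = PDAG([n for n in graph.nodes if n not in members] + [name])
    rel: dict[str, set[str]] = {}
    for a, b in graph.directed:
        ain, bin_ = a in members, b in members
        if ain and bin_:
            continue
        if not ain and not bin_:
            g.directed.add((a, b))
        elif ain:
            rel.setdefault(b, set()).add("out")
        else:
            rel.setdefault(a, set()).add("in")
    for a, b in graph.undirected:
        ain, bin_ = a in members, b in members
        if ain and bin_:
            continue
        if not ain and not bin_:
            g.undirected.add(_key(a, b))
        else:
            z = b if ain else a
            rel.setdefault(z, set()).add("und")
    for z, kinds in rel.items():
        if len(kinds) > 1:
            raise GraphError(
                f"conflicting inherited edges between {name} and {z}"
            )
        kind = next(iter(kinds))
        if kind == "out":
            g.directed.add((name, z))
        elif kind == "in":
            g.directed.add((z, name))
        else:
            g.undirected.add(_key(name, z))
    return g


def _new_v_structures(original: PDAG, contracted: PDAG, members: set[str]) -> bool:
    """True if the contracted graph has a v-structure with no counterpart
    among the original nodes."""
    orig_vs = original.v_structures()

    def had_original(x: str, z: str, y: str) -> bool:
        xs = members if x not in original._nodeset else {x}
        zs = members if z not in original._nodeset else {z}
        ys = members if y not in original._nodeset else {y}
        for xo in xs:
            for zo in zs:
                for yo in ys:
                    if (min(xo, yo), zo, max(xo, yo)) in orig_vs:
                        return True
        return False

    return any(not had_original(x, z, y) for x, z, y in contracted.v_structures())


def _contraction_valid(graph: PDAG, members: set[str], name: str):
    try:
        g = _contract(graph, members, name)
    except GraphError:
        return None
    if g.has_directed_cycle():
        return None
    if _new_v_structures(graph, g, members):
        return None
    return g


def _search_member_set(graph: PDAG, seed_members: set[str], max_candidates=2000):
    """Smallest valid superset of ``seed_members`` whose contraction is
    admissible; BFS ordered by size then lexicographic."""
    from heapq import heappop, heappush

    start = tuple(sorted(seed_members))
    heap = [(len(start), start)]
    seen = {start}
    tried = 0
    while heap and tried < max_candidates:
        _, cand = heappop(heap)
        tried += 1
        members = set(cand)
        g = _contraction_valid(graph, members, macro_name(members))
        if g is not None:
            return members, g
        frontier = set()
        for m in members:
            frontier |= graph.adjacencies(m)
        for z in sorted(frontier - members):
            nxt = tuple(sorted(members | {z}))
            if nxt not in seen:
                seen.add(nxt)
                heappush(heap, (len(nxt), nxt))
    raise GraphError("no admissible macro-variable member set found")


def coarse_grain(
    graph: PDAG, unresolved, cards: dict[str, int]
) -> tuple[PDAG, list[MacroVariable]]:
    """Replace every unresolved undirected edge by a macro variable.

    Parameters
    ----------
    graph : PDAG
        Oriented equivalence class still containing undirected edges.
    unresolved : iterable of (str, str)
        Edges whose direction could not be identified; must be undirected
        edges of ``graph``.  Overlapping member sets merge into one macro.
    cards : dict
        State count per (micro) variable, needed to size macro state spaces.

    Returns
    -------
    (PDAG, list of MacroVariable)
    """
    todo = {_key(a, b) for a, b in unresolved}
    for e in todo:
        if e not in graph.undirected:
            raise ValueError(f"unresolved edge {e} is not undirected in graph")
    g = graph.copy()
    membership: dict[str, list[str]] = {}  # macro node -> flattened members
    while todo:
        a, b = sorted(todo)[0]
        members, g2 = _search_member_set(g, {a, b})
        # flatten members that are themselves macro nodes
        flat: list[str] = []
        for m in sorted(members):
            flat.extend(membership.pop(m, [m]))
        name = macro_name(members)
        membership[name] = flat
        g = g2
        # retarget remaining unresolved edges onto the macro node
        todo = {
            _key(
                name if x in members else x,
                name if y in members else y,
            )
            for x, y in todo
            if not (x in members and y in members)
        }
    macros = []
    for name, flat in membership.items():
        mv = MacroVariable(macro_name(flat), flat, [cards[m] for m in flat])
        if mv.name != name:
            # rename contracted node to the flattened canonical name
            g = _rename_node(g, name, mv.name)
        macros.append(mv)
    return g, macros


def _rename_node(g: PDAG, old: str, new: str) -> PDAG:
    def r(x):
        return new if x == old else x

    return PDAG(
        [r(n) for n in g.nodes],
        {(r(a), r(b)) for a, b in g.directed},
        {(r(a), r(b)) for a, b in g.undirected},
    )


def recode_cohort(cohort: CohortTable, macros: list[MacroVariable]) -> CohortTable:
    """Replace member columns by macro columns (row-major state encoding).

    A macro cell is missing iff any member cell is missing.  The macro
    column takes the position of its first member; its schema category is
    inherited from that member.
    """
    if not macros:
        return cohort
    by_member = {}
    for mv in macros:
        for m in mv.members:
            if m not in cohort.schema:
                raise ValueError(f"macro member {m!r} absent from cohort")
            by_member[m] = mv
    new_specs: list[VariableSpec] = []
    emitted = set()
    for spec in cohort.schema:
        mv = by_member.get(spec.name)
        if mv is None:
            new_specs.append(spec)
        elif mv.name not in emitted:
            emitted.add(mv.name)
            new_specs.append(
                VariableSpec(
                    name=mv.name,
                    category=spec.category,
                    states=mv.state_labels(),
                    long_name=f"macro variable over {', '.join(mv.members)}",
                )
            )
    schema = Schema(new_specs)
    n = cohort.n
    values = np.zeros((n, len(new_specs)), dtype=np.int64)
    missing = np.zeros((n, len(new_specs)), dtype=bool)
    for j, spec in enumerate(new_specs):
        mv = next((m for m in macros if m.name == spec.name), None)
        if mv is None:
            values[:, j] = cohort.column(spec.name)
            missing[:, j] = cohort.column_missing(spec.name)
        else:
            cols = np.stack([cohort.column(m) for m in mv.members])
            miss = np.stack([cohort.column_missing(m) for m in mv.members])
            anymiss = miss.any(axis=0)
            enc = np.ravel_multi_index(
                np.where(miss, 0, cols), mv.member_cards
            )
            values[:, j] = np.where(anymiss, 0, enc)
            missing[:, j] = anymiss
    return CohortTable(schema, values, missing)
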