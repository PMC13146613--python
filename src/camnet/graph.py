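"""Partially directed graphs (CPDAG/MEC representation) and orientation rules.

A :class:`PDAG` holds directed edges (compelled causal arrows) and undirected
edges (orientations not identifiable from conditional independence).  The
module implements:

* Meek's orientation-propagation rules (the three classic rules; the fourth
  is available behind a flag but off by default),
* the CPDAG of a DAG (v-structures + Meek closure),
* a consistent DAG extension of a PDAG (Dor & Tarsi style),
* edge-list TSV and GraphML serialization.
"""

from __future__ import annotations

from itertools import combinations

import networkx as nx


class GraphError(ValueError):
    pass


def _key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


class PDAG:
    """Graph with directed and undirected edges over named nodes."""

    def __init__(self, nodes=(), directed=(), undirected=()):
        self.nodes: list[str] = list(nodes)
        self._nodeset = set(self.nodes)
        self.directed: set[tuple[str, str]] = set()
        self.undirected: set[tuple[str, str]] = set()
        for a, b in directed:
            self.add_directed(a, b)
        for a, b in undirected:
            self.add_undirected(a, b)

    # ------------------------------------------------------------- mutation
    def _check(self, a: str, b: str) -> None:
        if a == b:
            raise GraphError(f"self-loop on {a}")
        for x in (a, b):
            if x not in self._nodeset:
                self.nodes.append(x)
                self._nodeset.add(x)

    def add_directed(self, a: str, b: str) -> None:
        self._check(a, b)
        if self.has_adjacency(a, b) and (a, b) not in self.directed:
            raise GraphError(f"edge {a},{b} already present")
        self.directed.add((a, b))

    def add_undirected(self, a: str, b: str) -> None:
        self._check(a, b)
        if self.has_adjacency(a, b) and _key(a, b) not in self.undirected:
            raise GraphError(f"edge {a},{b} already present")
        self.undirected.add(_key(a, b))

    def remove_edge(self, a: str, b: str) -> None:
        self.directed.discard((a, b))
        self.directed.discard((b, a))
        self.undirected.discard(_key(a, b))

    def orient(self, a: str, b: str) -> None:
        """Turn the undirected edge a—b into a→b."""
        if _key(a, b) not in self.undirected:
            raise GraphError(f"{a}—{b} is not undirected")
        self.undirected.discard(_key(a, b))
        self.directed.add((a, b))

    # -------------------------------------------------------------- queries
    def has_adjacency(self, a: str, b: str) -> bool:
        return (
            (a, b) in self.directed
            or (b, a) in self.directed
            or _key(a, b) in self.undirected
        )

    def parents(self, v: str) -> set[str]:
        return {a for a, b in self.directed if b == v}

    def children(self, v: str) -> set[str]:
        return {b for a, b in self.directed if a == v}

    def undirected_neighbors(self, v: str) -> set[str]:
        return {
            (a if b == v else b)
            for a, b in self.undirected
            if v in (a, b)
        }

    def adjacencies(self, v: str) -> set[str]:
        return self.parents(v) | self.children(v) | self.undirected_neighbors(v)

    @property
    def n_edges(self) -> int:
        return len(self.directed) + len(self.undirected)

    def copy(self) -> "PDAG":
        return PDAG(self.nodes, self.directed, self.undirected)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, PDAG)
            and set(self.nodes) == set(other.nodes)
            and self.directed == other.directed
            and self.undirected == other.undirected
        )

    def __repr__(self) -> str:
        return (
            f"PDAG({len(self.nodes)} nodes, {len(self.directed)} directed, "
            f"{len(self.undirected)} undirected)"
        )

    # ------------------------------------------------------------ structure
    def directed_graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.directed)
        return g

    def has_directed_cycle(self) -> bool:
        return not nx.is_directed_acyclic_graph(self.directed_graph())

    def creates_cycle(self, a: str, b: str) -> bool:
        """Would adding a→b close a directed cycle?"""
        if a not in self._nodeset or b not in self._nodeset:
            return False
        return nx.has_path(self.directed_graph(), b, a)

    def v_structures(self) -> set[tuple[str, str, str]]:
        """All colliders x→z←y with x, y non-adjacent, as (min(x,y), z, max(x,y))."""
        out = set()
        for z in self.nodes:
            for x, y in combinations(sorted(self.parents(z)), 2):
                if not self.has_adjacency(x, y):
                    out.add((x, z, y))
        return out

    def is_dag(self) -> bool:
        return not self.undirected and not self.has_directed_cycle()

    # ----------------------------------------------------------- Meek rules
    def apply_meek_rules(self, use_rule4: bool = False, rng=None) -> "PDAG":
        """Return the closure under Meek's orientation rules (in place on a copy).

        Rule 1: a→b, b—c, a and c non-adjacent  =>  b→c.
        Rule 2: a→b, b→c, a—c                   =>  a→c.
        Rule 3: a→b, a→c, b—c, b→d, c—d         =>  c→d.
        Rule 4 (optional, off by default): the standard fourth propagation
        rule, needed only in the presence of background knowledge.
        """
        g = self.copy()
        changed = True
        while changed:
            changed = False
            edges = sorted(g.undirected)
            if rng is not None:
                rng.shuffle(edges)
            for a, b in edges:
                for x, y in ((a, b), (b, a)):
                    if g._meek_applies(x, y, use_rule4):
                        g.orient(x, y)
                        changed = True
                        break
                if changed:
                    break
        return g

    def _meek_applies(self, b: str, c: str, use_rule4: bool) -> bool:
        """Should the undirected edge b—c be oriented b→c under some rule?"""
        # Rule 1: exists a→b with a, c non-adjacent.
        for a in self.parents(b):
            if a != c and not self.has_adjacency(a, c):
                return True
        # Rule 2: exists a directed path b→x→c; c→b would close a cycle.
        for x in self.children(b):
            if c in self.children(x):
                return True
        # Rule 3 (printed form): exists a, w with a→w, a→b, w—b, w→c;
        # orienting c→b would force a new v-structure at b.
        for a in self.parents(b):
            for w in self.children(a):
                if (
                    w not in (b, c)
                    and _key(w, b) in self.undirected
                    and (w, c) in self.directed
                ):
                    return True
        if use_rule4:
            # Standard rule 4: b—w, w→x, x→c, b adjacent to x, w,c non-adjacent.
            for w in self.undirected_neighbors(b):
                if w == c:
                    continue
                for x in self.children(w):
                    if (
                        x != b
                        and (x, c) in self.directed
                        and self.has_adjacency(b, x)
                        and not self.has_adjacency(w, c)
                    ):
                        return True
        return False

    # -------------------------------------------------------- CPDAG helpers
    @classmethod
    def from_dag(cls, dag: "PDAG | nx.DiGraph") -> "PDAG":
        """The CPDAG (pattern) of a DAG: v-structures kept directed, the
        remaining edges undirected, then the Meek closure."""
        if isinstance(dag, nx.DiGraph):
            d = cls(dag.nodes, dag.edges)
        else:
            d = dag
        if d.undirected or d.has_directed_cycle():
            raise GraphError("from_dag requires a DAG")
        vs = d.v_structures()
        compelled = set()
        for x, z, y in vs:
            compelled.add((x, z))
            compelled.add((y, z))
        skeleton = cls(d.nodes)
        for a, b in d.directed:
            if (a, b) in compelled:
                if _key(a, b) in skeleton.undirected:
                    skeleton.undirected.discard(_key(a, b))
                skeleton.directed.add((a, b))
            elif not skeleton.has_adjacency(a, b):
                skeleton.add_undirected(a, b)
        return skeleton.apply_meek_rules()

    def consistent_extension(self) -> "PDAG":
        """Orient all undirected edges into a DAG without new v-structures
        or cycles (Dor & Tarsi).  Raises if none exists."""
        g = self.copy()
        out = PDAG(self.nodes, self.directed)
        while g.undirected or g.directed:
            progressed = False
            for x in sorted(g.nodes):
                if g.children(x):
                    continue
                nbrs = g.undirected_neighbors(x)
                adj = g.adjacencies(x)
                # every undirected neighbor must be adjacent to all of x's
                # other adjacencies (so orienting into x creates no collider)
                if all(
                    all(g.has_adjacency(y, z) for z in adj - {y})
                    for y in nbrs
                ):
                    for y in nbrs:
                        out.directed.add((y, x))
                    for y in list(adj):
                        g.remove_edge(x, y)
                        g.remove_edge(y, x)
                    g.nodes.remove(x)
                    g._nodeset.discard(x)
                    progressed = True
                    break
            if not progressed:
                raise GraphError("PDAG admits no consistent extension")
        if out.has_directed_cycle():
            raise GraphError("extension produced a cycle")
        return out

    # -------------------------------------------------------------- file IO
    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("source\ttarget\ttype\n")
            for a, b in sorted(self.directed):
                fh.write(f"{a}\t{b}\tdirected\n")
            for a, b in sorted(self.undirected):
                fh.write(f"{a}\t{b}\tundirected\n")

    @classmethod
    def from_tsv(cls, path, nodes=()) -> "PDAG":
        g = cls(nodes)
        with open(path) as fh:
            header = fh.readline().strip().split("\t")
            if header != ["source", "target", "type"]:
                raise GraphError(f"unexpected edge-list header: {header}")
            for line in fh:
                if not line.strip():
                    continue
                a, b, kind = line.rstrip("\n").split("\t")
                if kind == "directed":
                    g.add_directed(a, b)
                elif kind == "undirected":
                    g.add_undirected(a, b)
                else:
                    raise GraphError(f"unknown edge type {kind!r}")
        return g

    def to_graphml(self, path) -> None:
        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for a, b in self.directed:
            g.add_edge(a, b, kind="directed")
        for a, b in self.undirected:
            g.add_edge(a, b, kind="undirected")
        nx.write_graphml(g, path)
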