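"""Pattern graphs (CPDAGs) and the DAG/PDAG conversions the equivalence search needs.

A pattern (completed partially directed acyclic graph) represents a Markov
equivalence class of DAGs: compelled edges are directed, reversible edges
undirected. A DAG's pattern is obtained by directing exactly the edges of its
v-structures (colliders a->c<-b with a, b non-adjacent) and closing under the
Meek orientation rules; a PDAG produced by a search operator is re-completed by
extending it to a consistent DAG (Dor-Tarsi) and re-deriving that DAG's pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations
from typing import Iterable, Iterator, Sequence

import networkx as nx


class GraphError(ValueError):
    pass


class PDAG:
    """Mixed graph over nodes 0..n-1 with directed and undirected edges."""

    __slots__ = ("n", "parents", "children", "undirected")

    def __init__(self, n: int):
        self.n = n
        self.parents: list[set[int]] = [set() for _ in range(n)]
        self.children: list[set[int]] = [set() for _ in range(n)]
        self.undirected: list[set[int]] = [set() for _ in range(n)]

    def copy(self) -> "PDAG":
        g = PDAG(self.n)
        g.parents = [set(s) for s in self.parents]
        g.children = [set(s) for s in self.children]
        g.undirected = [set(s) for s in self.undirected]
        return g

    # -- edge mutation -----------------------------------------------------
    def add_directed(self, u: int, v: int) -> None:
        self.children[u].add(v)
        self.parents[v].add(u)

    def add_undirected(self, u: int, v: int) -> None:
        self.undirected[u].add(v)
        self.undirected[v].add(u)

    def remove_all(self, u: int, v: int) -> None:
        self.children[u].discard(v)
        self.parents[v].discard(u)
        self.children[v].discard(u)
        self.parents[u].discard(v)
        self.undirected[u].discard(v)
        self.undirected[v].discard(u)

    def orient(self, u: int, v: int) -> None:
        """Turn the undirected edge u-v into u->v."""
        self.undirected[u].discard(v)
        self.undirected[v].discard(u)
        self.add_directed(u, v)

    # -- queries -----------------------------------------------------------
    def adjacent(self, u: int, v: int) -> bool:
        return v in self.children[u] or v in self.parents[u] or v in self.undirected[u]

    def neighbors(self, u: int) -> set[int]:
        return self.children[u] | self.parents[u] | self.undirected[u]

    def directed_edges(self) -> list[tuple[int, int]]:
        return [(u, v) for u in range(self.n) for v in sorted(self.children[u])]

    def undirected_edges(self) -> list[tuple[int, int]]:
        return [
            (u, v) for u in range(self.n) for v in sorted(self.undirected[u]) if u < v
        ]

    def is_clique(self, nodes: Iterable[int]) -> bool:
        nodes = list(nodes)
        return all(self.adjacent(a, b) for a, b in combinations(nodes, 2))

    def has_directed_cycle(self) -> bool:
        color = [0] * self.n  # 0 white, 1 grey, 2 black

        def visit(u: int) -> bool:
            color[u] = 1
            for v in self.children[u]:
                if color[v] == 1 or (color[v] == 0 and visit(v)):
                    return True
            color[u] = 2
            return False

        return any(color[u] == 0 and visit(u) for u in range(self.n))

    def has_semi_directed_path(self, src: int, dst: int, blocked: set[int]) -> bool:
        """Path src ~> dst following directed (forward) or undirected edges,
        avoiding ``blocked`` as interior/endpoint nodes."""
        if src == dst:
            return True
        seen = {src}
        stack = [src]
        while stack:
            u = stack.pop()
            for v in self.children[u] | self.undirected[u]:
                if v == dst:
                    return True
                if v not in seen and v not in blocked:
                    seen.add(v)
                    stack.append(v)
        return False


def meek_closure(g: PDAG) -> PDAG:
    """Apply the Meek orientation rules until fixpoint (in place; returns g).

    R1: a->b, b-c, a,c non-adjacent        => b->c
    R2: a->b->c, a-c                       => a->c
    R3: a-b, a-c, a-d, c->b, d->b, c#d     => a->b

    Rules 1-3 are complete for patterns whose directed edges come from
    v-structures (no background knowledge), which is the only way this
    function is reached.
    """
    changed = True
    while changed:
        changed = False
        for b in range(g.n):
            for c in list(g.undirected[b]):
                # R1
                if any(a != c and not g.adjacent(a, c) for a in g.parents[b]):
                    g.orient(b, c)
                    changed = True
                    continue
                # R2: b->...->c with b-c : orient b->c
                if any(k in g.parents[c] for k in g.children[b]):
                    g.orient(b, c)
                    changed = True
                    continue
                # R3: b-c; b has undirected neighbors d1,d2 nonadjacent, both ->c
                nb = [d for d in g.undirected[b] if d != c and d in g.parents[c]]
                if any(
                    not g.adjacent(d1, d2) for d1, d2 in combinations(nb, 2)
                ):
                    g.orient(b, c)
                    changed = True
                    continue
    return g


def dag_to_cpdag(dag: PDAG) -> PDAG:
    """Pattern of a DAG: v-structure edges directed, the rest undirected,
    closed under the Meek rules."""
    if dag.undirected_edges():
        raise GraphError("expected a fully directed DAG")
    if dag.has_directed_cycle():
        raise GraphError("graph has a directed cycle")
    pattern = PDAG(dag.n)
    compelled: set[tuple[int, int]] = set()
    for c in range(dag.n):
        for a, b in combinations(sorted(dag.parents[c]), 2):
            if not dag.adjacent(a, b):
                compelled.add((a, c))
                compelled.add((b, c))
    for u, v in dag.directed_edges():
        if (u, v) in compelled:
            pattern.add_directed(u, v)
        else:
            pattern.add_undirected(u, v)
    return meek_closure(pattern)


def pdag_to_dag(pdag: PDAG) -> PDAG:
    """A consistent DAG extension of a PDAG (Dor & Tarsi 1992).

    Raises GraphError when no consistent extension exists.
    """
    g = pdag.copy()
    dag = PDAG(pdag.n)
    for u, v in pdag.directed_edges():
        dag.add_directed(u, v)
    remaining = set(range(pdag.n))
    while remaining:
        for x in sorted(remaining):
            if g.children[x] & remaining:
                continue  # not a sink in the directed part
            und = g.undirected[x] & remaining
            others = (g.neighbors(x) & remaining) - {x}
            if all(g.adjacent(y, z) for y in und for z in others if y != z):
                for y in und:
                    dag.add_directed(y, x)
                for y in list(g.neighbors(x) & remaining):
                    g.remove_all(x, y)
                remaining.discard(x)
                break
        else:
            raise GraphError("PDAG admits no consistent DAG extension")
    return dag


def complete_pdag(pdag: PDAG) -> PDAG:
    """Re-complete a PDAG into the CPDAG of its consistent extensions."""
    return dag_to_cpdag(pdag_to_dag(pdag))


def all_dags(n: int) -> Iterator[PDAG]:
    """Every labelled DAG on n nodes (25 for n=3), by brute-force enumeration."""
    pairs = list(combinations(range(n), 2))
    states = [0, 1, 2]  # none, u->v, v->u

    def build(assignment: Sequence[int]) -> PDAG | None:
        g = PDAG(n)
        for (u, v), s in zip(pairs, assignment):
            if s == 1:
                g.add_directed(u, v)
            elif s == 2:
                g.add_directed(v, u)
        return None if g.has_directed_cycle() else g

    def rec(i: int, acc: list[int]) -> Iterator[PDAG]:
        if i == len(pairs):
            g = build(acc)
            if g is not None:
                yield g
            return
        for s in states:
            yield from rec(i + 1, acc + [s])

    yield from rec(0, [])


@dataclass
class PatternGraph:
    """A labelled CPDAG with per-edge non-Gaussian orientation confidence.

    ``orientation_measure`` maps a directed edge (u, v) to a signed scalar:
    positive values favoured u->v. Edges directed by the equivalence search
    itself (compelled edges) carry no measure.
    """

    vertices: tuple[str, ...]
    directed_edges: set[tuple[str, str]] = field(default_factory=set)
    undirected_edges: set[tuple[str, str]] = field(default_factory=set)
    orientation_measure: dict[tuple[str, str], float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.undirected_edges = {tuple(sorted(e)) for e in self.undirected_edges}
        dpairs = {frozenset(e) for e in self.directed_edges}
        upairs = {frozenset(e) for e in self.undirected_edges}
        if dpairs & upairs:
            raise GraphError("an edge cannot be both directed and undirected")
        if self.to_pdag().has_directed_cycle():
            raise GraphError("directed subgraph contains a cycle")

    # -- conversions -------------------------------------------------------
    def index(self) -> dict[str, int]:
        return {v: i for i, v in enumerate(self.vertices)}

    def to_pdag(self) -> PDAG:
        idx = self.index()
        g = PDAG(len(self.vertices))
        for u, v in self.directed_edges:
            g.add_directed(idx[u], idx[v])
        for u, v in self.undirected_edges:
            g.add_undirected(idx[u], idx[v])
        return g

    @classmethod
    def from_pdag(cls, g: PDAG, vertices: Sequence[str]) -> "PatternGraph":
        names = tuple(vertices)
        return cls(
            vertices=names,
            directed_edges={(names[u], names[v]) for u, v in g.directed_edges()},
            undirected_edges={(names[u], names[v]) for u, v in g.undirected_edges()},
        )

    # -- queries -----------------------------------------------------------
    def skeleton(self) -> set[frozenset[str]]:
        return {frozenset(e) for e in self.directed_edges} | {
            frozenset(e) for e in self.undirected_edges
        }

    def n_edges(self) -> int:
        return len(self.directed_edges) + len(self.undirected_edges)

    def to_networkx(self) -> nx.DiGraph:
        """Directed edges as arcs, undirected edges as reciprocal arc pairs."""
        g = nx.DiGraph()
        g.add_nodes_from(self.vertices)
        for u, v in sorted(self.directed_edges):
            g.add_edge(u, v, kind="directed",
                       measure=self.orientation_measure.get((u, v)))
        for u, v in sorted(self.undirected_edges):
            g.add_edge(u, v, kind="undirected")
            g.add_edge(v, u, kind="undirected")
        return g

    def to_dot(self, name: str = "pattern") -> str:
        lines = [f"digraph {name} {{"]
        for v in self.vertices:
            lines.append(f'  "{v}";')
        for u, v in sorted(self.directed_edges):
            lines.append(f'  "{u}" -> "{v}";')
        for u, v in sorted(self.undirected_edges):
            lines.append(f'  "{u}" -> "{v}" [dir=none];')
        lines.append("}")
        return "\n".join(lines) + "\n"
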