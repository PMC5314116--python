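"""Greedy equivalence search (GES) over CPDAGs, single- and multi-subject.

GES starts from the empty graph and greedily applies the best valid
single-edge insertion over Markov equivalence classes while the (minimized)
BIC strictly decreases, then greedily deletes edges, and returns the completed
pattern. Candidate moves are the Chickering insert/delete operators with their
validity tests; after every accepted move the PDAG is re-completed via a
consistent DAG extension. The multi-subject variant scores each candidate by
the arithmetic mean of per-subject BIC, each subject with its own sample size,
yielding one group-level pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np

from .graphs import PDAG, PatternGraph, complete_pdag
from .scores import LocalScorer, ROITimeSeriesSet, TimeSeriesError

_EPS = 1e-10  # a move must beat this to count as a strict improvement


@dataclass
class SearchStep:
    phase: str  # forward | backward
    operator: str  # insert | delete
    edge: tuple[str, str]
    delta: float


@dataclass
class SearchTrace:
    steps: list[SearchStep] = field(default_factory=list)

    def record(self, phase: str, operator: str, edge: tuple[str, str], delta: float) -> None:
        self.steps.append(SearchStep(phase, operator, edge, delta))


def _subsets(items: list[int]):
    for r in range(len(items) + 1):
        yield from (frozenset(c) for c in combinations(items, r))


def _best_insert(g: PDAG, scorer: LocalScorer):
    """Best valid Insert(x, y, T): returns (delta, x, y, T) or None.

    Validity (Chickering 2002): NA_yx | T is a clique and every semi-directed
    path from y to x crosses NA_yx | T. Ties broken by (x, y) label order.
    """
    best = None
    for y in range(g.n):
        pa_y = frozenset(g.parents[y])
        na_all = g.undirected[y]
        for x in range(g.n):
            if x == y or g.adjacent(x, y):
                continue
            na_yx = {z for z in na_all if g.adjacent(z, x)}
            t0 = sorted(z for z in na_all if not g.adjacent(z, x))
            for t in _subsets(t0):
                block = na_yx | t
                if not g.is_clique(block):
                    continue
                if g.has_semi_directed_path(y, x, block):
                    continue
                delta = scorer.delta(y, pa_y | block, x)
                key = (delta, x, y, tuple(sorted(t)))
                if best is None or key < best:
                    best = key
    if best is None or best[0] >= -_EPS:
        return None
    delta, x, y, t = best
    return delta, x, y, frozenset(t)


def _best_delete(g: PDAG, scorer: LocalScorer):
    """Best valid Delete(x, y, H): returns (delta, x, y, H) or None.

    Defined for x->y or x-y; valid when NA_yx \\ H is a clique.
    """
    best = None
    for y in range(g.n):
        pa_y = frozenset(g.parents[y])
        for x in range(g.n):
            if x == y:
                continue
            if y not in g.children[x] and y not in g.undirected[x]:
                continue
            na_yx = sorted(z for z in g.undirected[y] if g.adjacent(z, x) and z != x)
            for h in _subsets(na_yx):
                keep = frozenset(na_yx) - h
                if not g.is_clique(keep):
                    continue
                base = (pa_y | keep) - {x}
                delta = scorer.local(y, base) - scorer.local(y, base | {x})
                key = (delta, x, y, tuple(sorted(h)))
                if best is None or key < best:
                    best = key
    if best is None or best[0] >= -_EPS:
        return None
    delta, x, y, h = best
    return delta, x, y, frozenset(h)


def _apply_insert(g: PDAG, x: int, y: int, t: frozenset[int]) -> PDAG:
    g = g.copy()
    g.add_directed(x, y)
    for z in t:
        g.orient(z, y)
    return complete_pdag(g)


def _apply_delete(g: PDAG, x: int, y: int, h: frozenset[int]) -> PDAG:
    g = g.copy()
    g.remove_all(x, y)
    for z in h:
        if z in g.undirected[y]:
            g.orient(y, z)
        if z in g.undirected[x]:
            g.orient(x, z)
    return complete_pdag(g)


def _search(scorer: LocalScorer, labels: tuple[str, ...]) -> tuple[PatternGraph, SearchTrace]:
    g = PDAG(len(labels))
    trace = SearchTrace()
    while True:  # forward: greedy insertions
        move = _best_insert(g, scorer)
        if move is None:
            break
        delta, x, y, t = move
        g = _apply_insert(g, x, y, t)
        trace.record("forward", "insert", (labels[x], labels[y]), delta)
    while True:  # backward: greedy deletions
        move = _best_delete(g, scorer)
        if move is None:
            break
        delta, x, y, h = move
        g = _apply_delete(g, x, y, h)
        trace.record("backward", "delete", (labels[x], labels[y]), delta)
    return PatternGraph.from_pdag(g, labels), trace


def ges_search(data: np.ndarray | ROITimeSeriesSet,
               labels: tuple[str, ...] | None = None) -> tuple[PatternGraph, SearchTrace]:
    """GES on a single dataset (T x R matrix or a one-subject set).

    Deterministic for fixed input: candidate ties are broken by label order.
    """
    if isinstance(data, np.ndarray):
        arr = np.asarray(data, float)
        if labels is None:
            labels = tuple(f"v{i}" for i in range(arr.shape[1]))
        data = ROITimeSeriesSet([("s0", arr)], labels)
    elif len(data.subjects) != 1:
        raise TimeSeriesError("ges_search expects one subject; use images_search for several")
    scorer = LocalScorer(data)
    return _search(scorer, data.region_labels)


def images_search(data: ROITimeSeriesSet) -> tuple[PatternGraph, SearchTrace]:
    """Multi-subject GES: candidates scored by the mean per-subject BIC."""
    scorer = LocalScorer(data)
    return _search(scorer, data.region_labels)
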