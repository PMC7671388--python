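"""Quartet amalgamation into a supertree by recursive good/bad-edge cuts.

Every quartet topology ab|cd over the current taxon set contributes six edges
to a multigraph: *good* edges (a,b) and (c,d) between paired taxa, and *bad*
edges on the four cross pairs.  At each recursion level the taxon set is
bipartitioned so as to minimise ``(good edges cut + 1) / (bad edges cut + 1)``
over all single-taxon splits plus seeded hill-climbed random bipartitions;
each cut becomes a split of the final (topology-only) tree.  When recursing
into one side, quartets with exactly one taxon on the far side keep their
information by mapping that taxon to a placeholder leaf representing the
entire far side.
"""

from __future__ import annotations

import itertools
import logging
from typing import Iterable, Sequence

import numpy as np

from .quartet_ml import QuartetResult
from .treeops import PhyloTree, parse_newick

__all__ = ["QuartetGraph", "build_graph", "find_cut", "build_supertree"]

logger = logging.getLogger(__name__)

Split = tuple[tuple, tuple]  # ((a, b), (c, d)) labels


class _Rest:
    """Placeholder leaf standing for everything outside the current subproblem."""

    __slots__ = ("tag",)
    _counter = itertools.count()

    def __init__(self):
        self.tag = next(_Rest._counter)

    def __repr__(self):
        return f"<rest:{self.tag}>"


def _as_split(q) -> Split:
    if isinstance(q, QuartetResult):
        if q.best_split is None:
            raise ValueError("cannot embed an inconclusive quartet")
        return q.best_split
    (a, b), (c, d) = q
    return ((a, b), (c, d))


class QuartetGraph:
    """Good/bad edge weights over a taxon set, accumulated from quartets."""

    def __init__(self, taxa: Sequence):
        self.taxa = list(taxa)
        self._pos = {t: i for i, t in enumerate(self.taxa)}
        n = len(self.taxa)
        self.good = np.zeros((n, n))
        self.bad = np.zeros((n, n))
        self.n_quartets = 0

    def add_quartet(self, split: Split) -> None:
        (a, b), (c, d) = split
        p = self._pos
        ia, ib, ic, id_ = p[a], p[b], p[c], p[d]
        for i, j in ((ia, ib), (ic, id_)):
            self.good[i, j] += 1
            self.good[j, i] += 1
        for i, j in ((ia, ic), (ia, id_), (ib, ic), (ib, id_)):
            self.bad[i, j] += 1
            self.bad[j, i] += 1
        self.n_quartets += 1

    def good_weight(self, a, b) -> float:
        return float(self.good[self._pos[a], self._pos[b]])

    def bad_weight(self, a, b) -> float:
        return float(self.bad[self._pos[a], self._pos[b]])


def build_graph(quartets: Iterable, taxa: Sequence) -> QuartetGraph:
    """Accumulate the six-edge embedding of every quartet lying inside *taxa*."""
    g = QuartetGraph(taxa)
    inside = set(taxa)
    for q in quartets:
        (a, b), (c, d) = _as_split(q)
        if {a, b, c, d} <= inside:
            g.add_quartet(((a, b), (c, d)))
    return g


def _cut_weights(graph: QuartetGraph, side: np.ndarray) -> tuple[float, float]:
    mask = side[:, None] != side[None, :]
    return float(graph.good[mask].sum() / 2), float(graph.bad[mask].sum() / 2)


def _objective(good_cut: float, bad_cut: float) -> float:
    return (good_cut + 1.0) / (bad_cut + 1.0)


def _hill_climb(graph: QuartetGraph, side: np.ndarray) -> tuple[np.ndarray, float, float, float]:
    n = len(side)
    good_cut, bad_cut = _cut_weights(graph, side)
    obj = _objective(good_cut, bad_cut)
    improved = True
    while improved:
        improved = False
        for i in range(n):
            # moving i across the cut must keep both sides nonempty
            same = int(side.sum()) if side[i] else n - int(side.sum())
            if same <= 1:
                continue
            delta_good = graph.good[i, side == side[i]].sum() - graph.good[i, side != side[i]].sum()
            delta_bad = graph.bad[i, side == side[i]].sum() - graph.bad[i, side != side[i]].sum()
            new_obj = _objective(good_cut + delta_good, bad_cut + delta_bad)
            if new_obj < obj - 1e-12:
                side = side.copy()
                side[i] = ~side[i]
                good_cut += delta_good
                bad_cut += delta_bad
                obj = new_obj
                improved = True
    return side, obj, good_cut, bad_cut


def find_cut(
    graph: QuartetGraph,
    seed: int | np.random.Generator | None = 0,
    restarts: int = 50,
    return_weights: bool = False,
):
    """Best bipartition of the graph's taxa under the good/bad cut ratio.

    Candidates: every single-taxon split, plus ``restarts`` random
    bipartitions refined by single-taxon moves.  Deterministic given the seed.
    """
    n = len(graph.taxa)
    if n < 2:
        raise ValueError("cannot cut fewer than two taxa")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    best = None  # (obj, good_cut, bad_cut, side)
    for i in range(n):
        side = np.zeros(n, dtype=bool)
        side[i] = True
        g, b = _cut_weights(graph, side)
        cand = (_objective(g, b), g, b, side)
        if best is None or cand[0] < best[0]:
            best = cand
    if n > 2:
        for _ in range(restarts):
            side = rng.integers(0, 2, size=n).astype(bool)
            if side.all() or not side.any():
                side[rng.integers(n)] = not side[rng.integers(n)]
                if side.all() or not side.any():
                    continue
            side, obj, g, b = _hill_climb(graph, side)
            if obj < best[0]:
                best = (obj, g, b, side)
    obj, good_cut, bad_cut, side = best
    a = frozenset(t for t, s in zip(graph.taxa, side) if s)
    b = frozenset(t for t, s in zip(graph.taxa, side) if not s)
    if return_weights:
        return (a, b), good_cut, bad_cut
    return (a, b)


def _project_quartets(quartets: list[Split], inside: frozenset, rest) -> list[Split]:
    """Quartets restricted to one side of a cut; a single outside taxon is
    mapped to the placeholder leaf, quartets with two or more outside taxa are
    dropped."""
    out = []
    for (a, b), (c, d) in quartets:
        members = [a, b, c, d]
        n_out = sum(1 for t in members if t not in inside)
        if n_out == 0:
            out.append(((a, b), (c, d)))
        elif n_out == 1:
            mapped = [t if t in inside else rest for t in members]
            out.append(((mapped[0], mapped[1]), (mapped[2], mapped[3])))
    return out


class _Node:
    __slots__ = ("label", "children")

    def __init__(self, label=None, children=None):
        self.label = label
        self.children = children or []


def _solve(taxa: frozenset, quartets: list[Split], rng: np.random.Generator, restarts: int) -> _Node:
    """Unrooted tree over *taxa* represented as a rooted node structure
    (rooting is arbitrary and collapsed at serialisation)."""
    taxa_list = sorted(taxa, key=repr)
    if len(taxa_list) <= 3:
        if len(taxa_list) == 1:
            return _Node(label=taxa_list[0])
        return _Node(children=[_Node(label=t) for t in taxa_list])
    graph = build_graph(quartets, taxa_list)
    if graph.n_quartets == 0:
        return _Node(children=[_Node(label=t) for t in taxa_list])
    (a, b), good_cut, bad_cut = find_cut(
        graph, seed=np.random.default_rng(rng.integers(2**63)), restarts=restarts, return_weights=True
    )
    if bad_cut == 0 and good_cut > 0:
        # the quartets give no usable signal for this set: multifurcate
        return _Node(children=[_Node(label=t) for t in taxa_list])
    ra, rb = _Rest(), _Rest()
    sub_a = _solve(a | {ra}, _project_quartets(quartets, a, ra), rng, restarts)
    sub_b = _solve(b | {rb}, _project_quartets(quartets, b, rb), rng, restarts)
    return _Node(children=[_strip_rest(sub_a, ra), _strip_rest(sub_b, rb)])


def _strip_rest(node: _Node, rest) -> _Node:
    """Remove the placeholder leaf and reroot the subtree at its attachment
    point (the placeholder may sit anywhere in the rooted representation)."""
    adj: dict[_Node, list[_Node]] = {}

    def walk(n: _Node) -> None:
        adj.setdefault(n, [])
        for c in n.children:
            adj[n].append(c)
            adj.setdefault(c, []).append(n)
            walk(c)

    walk(node)
    rest_node = next(n for n in adj if n.label is rest)
    anchor = adj[rest_node][0]

    def rebuild(n: _Node, parent: _Node | None) -> _Node:
        if n.label is not None:
            return _Node(label=n.label)
        kids = [rebuild(c, n) for c in adj[n] if c is not parent and c is not rest_node]
        if len(kids) == 1:
            return kids[0]
        return _Node(children=kids)

    return rebuild(anchor, None)


def _to_newick(node: _Node) -> str:
    if node.label is not None:
        return _escape(str(node.label))
    return "(" + ",".join(_to_newick(c) for c in node.children) + ")"


def _escape(label: str) -> str:
    if any(ch in label for ch in "(),:;[] '\t\n"):
        return "'" + label.replace("'", "''") + "'"
    return label


def build_supertree(
    quartets: Iterable,
    taxa: Sequence | None = None,
    seed: int | np.random.Generator | None = 0,
    restarts: int = 50,
) -> PhyloTree:
    """Amalgamate quartet topologies into one unrooted topology-only tree.

    ``quartets`` may be ``QuartetResult`` objects (conclusive ones are used,
    inconclusive ones skipped) or raw ``((a,b),(c,d))`` splits.  Taxa that
    appear in no quartet are attached at the root with a warning.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    splits: list[Split] = []
    for q in quartets:
        if isinstance(q, QuartetResult) and q.inconclusive:
            continue
        splits.append(_as_split(q))
    seen = set()
    for (a, b), (c, d) in splits:
        seen.update((a, b, c, d))
    if taxa is None:
        taxa_set = frozenset(seen)
    else:
        taxa_set = frozenset(taxa)
    if len(taxa_set) < 4:
        raise ValueError("a supertree needs at least four taxa")
    orphans = sorted(taxa_set - seen)
    if orphans:
        logger.warning("taxa in no quartet, attached at the root: %s", orphans)
    core = taxa_set - set(orphans)
    if len(core) < 4:
        root = _Node(children=[_Node(label=t) for t in sorted(taxa_set)])
    else:
        root = _solve(frozenset(core), splits, rng, restarts)
        if root.label is not None:
            root = _Node(children=[root])
        for t in orphans:
            root.children.append(_Node(label=t))
    return parse_newick(_to_newick(root) + ";")
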