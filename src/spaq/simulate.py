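"""Sequence-evolution simulator: random trees, substitutions, optional indels.

Stands in for external genome simulators in tests and benchmarks: sample a
random binary tree, evolve a root sequence along it under JC or GTR (branch
lengths in expected substitutions per site), optionally sprinkle indels, and
emit one DNA sequence per leaf.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .quartet_ml import GTRParams
from .spaced_words import NUCLEOTIDES
from .treeops import PhyloTree, parse_newick

__all__ = ["SimulationConfig", "random_tree", "evolve"]


@dataclass
class SimulationConfig:
    n_taxa: int = 8
    sequence_length: int = 10_000
    model: str = "JC"  # "JC" or "GTR"
    gtr: GTRParams | None = None
    indel_rate: float = 0.0  # events per site per unit branch length
    indel_mean_length: float = 3.0
    seed: int | None = 0

    def __post_init__(self):
        if self.n_taxa < 4:
            raise ValueError("need at least four taxa")
        if self.sequence_length < 1:
            raise ValueError("sequence length must be positive")
        if self.model not in ("JC", "GTR"):
            raise ValueError(f"unknown model {self.model!r}")
        if self.indel_rate < 0 or self.indel_mean_length < 1:
            raise ValueError("invalid indel parameters")

    def params(self) -> GTRParams:
        if self.model == "JC" or self.gtr is None:
            return GTRParams()
        return self.gtr


def random_tree(
    n_taxa: int,
    seed: int | np.random.Generator | None = 0,
    branch_length_law: Callable[[np.random.Generator], float] | None = None,
    labels: list[str] | None = None,
) -> PhyloTree:
    """Random unrooted binary topology by sequential random joins.

    Starts from the 3-leaf star and attaches each further taxon to a uniformly
    chosen edge; branch lengths are drawn i.i.d. from ``branch_length_law``
    (default: exponential with mean 0.1).  Deterministic per seed.
    """
    if n_taxa < 3:
        raise ValueError("need at least three taxa")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if branch_length_law is None:
        branch_length_law = lambda r: float(r.exponential(0.1))
    if labels is None:
        labels = [f"t{i+1}" for i in range(n_taxa)]
    if len(labels) != n_taxa:
        raise ValueError("label count must equal n_taxa")

    # adjacency over node ids; leaves 0..n-1, internal nodes appended
    nxt = [n_taxa]  # next internal node id
    edges: list[list[int]] = [[0, n_taxa], [1, n_taxa], [2, n_taxa]]
    nxt[0] += 1
    for leaf in range(3, n_taxa):
        ei = int(rng.integers(len(edges)))
        u, v = edges[ei]
        mid = nxt[0]
        nxt[0] += 1
        edges[ei] = [u, mid]
        edges.append([mid, v])
        edges.append([leaf, mid])

    adj: dict[int, list[int]] = {}
    lengths: dict[frozenset, float] = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
        lengths[frozenset((u, v))] = branch_length_law(rng)

    def newick(u: int, parent: int | None) -> str:
        kids = [k for k in adj[u] if k != parent]
        if not kids:
            name = labels[u]
            return f"{name}:{lengths[frozenset((u, parent))]:.10f}"
        inner = ",".join(newick(k, u) for k in kids)
        if parent is None:
            return f"({inner})"
        return f"({inner}):{lengths[frozenset((u, parent))]:.10f}"

    return parse_newick(newick(n_taxa, None) + ";")


def _transition(q_eig, t: float) -> np.ndarray:
    lam, right, left = q_eig
    p = right @ np.diag(np.exp(lam * t)) @ left
    p = np.clip(p, 0.0, None)
    return p / p.sum(axis=1, keepdims=True)


def _eig(params: GTRParams):
    q = params.rate_matrix()
    pi = np.asarray(params.base_freqs)
    sq = np.sqrt(pi)
    sym = (q * sq[:, None]) / sq[None, :]  # D^{1/2} Q D^{-1/2}
    lam, u = np.linalg.eigh((sym + sym.T) / 2.0)
    return lam, u / sq[:, None], (u * sq[:, None]).T


def _sample_states(p_rows: np.ndarray, parent: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(p_rows, axis=1)
    u = rng.random(len(parent))
    return (u[:, None] > cum[parent]).sum(axis=1).astype(np.int8)


def _apply_indels(seq: np.ndarray, t: float, cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    n_events = rng.poisson(cfg.indel_rate * t * len(seq))
    p_geom = 1.0 / cfg.indel_mean_length
    for _ in range(n_events):
        length = int(rng.geometric(p_geom))
        pos = int(rng.integers(len(seq) + 1))
        if rng.random() < 0.5:  # insertion
            ins = rng.integers(0, 4, size=length).astype(np.int8)
            seq = np.concatenate([seq[:pos], ins, seq[pos:]])
        elif len(seq) > length:  # deletion
            seq = np.concatenate([seq[:pos], seq[pos + length :]])
    return seq


def evolve(tree: PhyloTree, config: SimulationConfig) -> dict[str, str]:
    """Evolve a stationary root sequence down *tree*; returns taxon -> DNA."""
    rng = np.random.default_rng(config.seed)
    params = config.params()
    pi = np.asarray(params.base_freqs)
    q_eig = _eig(params)

    root = tree.dendropy_tree.seed_node
    root_seq = rng.choice(4, size=config.sequence_length, p=pi).astype(np.int8)
    out: dict[str, str] = {}
    stack = [(root, root_seq)]
    while stack:
        node, seq = stack.pop()
        kids = node.child_nodes()
        if not kids:
            out[node.taxon.label] = "".join(NUCLEOTIDES[c] for c in seq)
            continue
        for child in kids:
            t = child.edge.length or 0.0
            if t > 0:
                p = _transition(q_eig, t)
                child_seq = _sample_states(p, seq, rng)
            else:
                child_seq = seq.copy()
            if config.indel_rate > 0 and t > 0:
                child_seq = _apply_indels(child_seq, t, config, rng)
            stack.append((child, child_seq))
    return out
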