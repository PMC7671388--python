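"""Newick parsing/writing and Robinson-Foulds comparison (dendropy-backed)."""

from __future__ import annotations

import dendropy

__all__ = ["PhyloTree", "TreeParseError", "parse_newick", "write_newick", "rf_distance"]


class TreeParseError(ValueError):
    pass


class PhyloTree:
    """An unrooted leaf-labelled tree, thin wrapper over a dendropy tree."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(labels) != len(set(labels)):
            raise TreeParseError("duplicate leaf labels")

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def leaf_labels(self) -> frozenset:
        return frozenset(l.taxon.label for l in self._tree.leaf_node_iter())

    def bipartitions(self) -> set[frozenset]:
        """Nontrivial bipartitions, each as the side not containing the
        lexicographically smallest leaf label."""
        labels = self.leaf_labels
        if not labels:
            return set()
        ref = min(labels)
        splits = set()
        for edge in self._tree.preorder_edge_iter():
            if edge.head_node is None or edge.tail_node is None:
                continue
            side = frozenset(
                l.taxon.label for l in edge.head_node.leaf_iter()
            )
            if ref in side:
                side = labels - side
            if 2 <= len(side) <= len(labels) - 2:
                splits.add(side)
        return splits

    def __str__(self) -> str:
        return write_newick(self)


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string; rooted inputs are unrooted by collapsing a
    degree-2 root."""
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        raise TreeParseError(f"malformed Newick: {exc}") from exc
    if tree.seed_node is None or not any(tree.leaf_node_iter()):
        raise TreeParseError("empty tree")
    if len(tree.seed_node.child_nodes()) == 2 and sum(1 for _ in tree.leaf_node_iter()) > 2:
        tree.deroot()
    tree.is_rooted = False
    return PhyloTree(tree)


def write_newick(tree: PhyloTree) -> str:
    s = tree.dendropy_tree.as_string(
        schema="newick",
        suppress_rooting=True,
        unquoted_underscores=True,
    )
    return s.strip()


def rf_distance(t1: PhyloTree, t2: PhyloTree) -> tuple[int, float]:
    """Robinson-Foulds distance between two trees on the same leaf set.

    Returns (absolute, normalized): the symmetric-difference count of
    nontrivial bipartitions, and that count divided by the total number of
    nontrivial bipartitions present in the two trees (0.0 when both are
    stars).
    """
    if t1.leaf_labels != t2.leaf_labels:
        raise ValueError("trees must have identical leaf sets")
    b1, b2 = t1.bipartitions(), t2.bipartitions()
    absolute = len(b1 ^ b2)
    denom = len(b1) + len(b2)
    return absolute, (absolute / denom if denom else 0.0)
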