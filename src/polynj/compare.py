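"""Topology comparison utilities (bipartitions, Robinson-Foulds)."""

from __future__ import annotations

from .treeio import TreeNode

__all__ = ["bipartitions", "rf_distance", "contains_bipartitions"]


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Nontrivial leaf bipartitions of the unrooted version of ``tree``.

    Each split is represented by the side not containing the
    lexicographically smallest leaf, so rooted and unrooted encodings of
    the same topology agree.
    """
    all_leaves = tree.leaf_set()
    if len(all_leaves) < 4:
        return set()
    ref = min(all_leaves)
    splits: set[frozenset] = set()
    for node in tree.iter_postorder():
        if node.is_leaf() or node.parent is None:
            continue
        side = node.leaf_set()
        if len(side) < 2 or len(all_leaves) - len(side) < 2:
            continue
        if ref in side:
            side = all_leaves - side
        splits.add(side)
    return splits


def rf_distance(a: TreeNode, b: TreeNode) -> int:
    """Robinson-Foulds distance (unrooted, same leaf set required)."""
    if a.leaf_set() != b.leaf_set():
        raise ValueError("trees must share a leaf set for RF comparison")
    return len(bipartitions(a) ^ bipartitions(b))


def contains_bipartitions(container: TreeNode, contained: TreeNode) -> bool:
    """True if every nontrivial split of ``contained`` occurs in ``container``."""
    return bipartitions(contained) <= bipartitions(container)
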