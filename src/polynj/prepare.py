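"""Prepare a gene tree for polytomy resolution.

Contract weakly supported internal branches (creating polytomies),
enumerate candidate rootings of an unrooted tree on its edges, and list
the polytomies of a rooted multifurcating tree in bottom-up order.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .treeio import TreeError, TreeNode

__all__ = [
    "Polytomy",
    "contract_low_support",
    "enumerate_rootings",
    "extract_polytomies",
    "is_unrooted",
]


@dataclass
class Polytomy:
    """A node with >= 3 children, each child a resolved subtree or leaf."""

    node: TreeNode

    @property
    def children(self) -> list[TreeNode]:
        return self.node.children

    def __len__(self) -> int:
        return len(self.node.children)


def contract_low_support(
    tree: TreeNode,
    threshold: float,
    missing_support: float = 1.0,
) -> TreeNode:
    """Return a copy of ``tree`` with internal branches of support
    strictly below ``threshold`` contracted.

    Leaf branches are never contracted.  Branches without a support value
    are treated as having support ``missing_support`` (default: kept).
    Contraction keeps ties: support exactly equal to the threshold
    survives.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    root = tree.copy()
    for node in list(root.iter_postorder()):
        if node.is_leaf() or node.parent is None:
            continue
        support = node.support if node.support is not None else missing_support
        if support < threshold:
            parent = node.parent
            pos = parent.children.index(node)
            parent.children[pos:pos + 1] = node.children
            for child in node.children:
                child.parent = parent
            node.children = []
            node.parent = None
    return root


def is_unrooted(tree: TreeNode) -> bool:
    """A tree whose root has 3+ children is treated as unrooted."""
    return len(tree.children) != 2 and not tree.is_leaf()


# -- rooting ----------------------------------------------------------------

def _unrooted_graph(tree: TreeNode):
    """Adjacency-list view of a tree, read as unrooted.

    A rooted binary top (root with exactly two children) is suppressed,
    merging its two incident edges into one (lengths added, support taken
    from whichever side carries one).
    """
    adj: dict[int, list[tuple[int, dict]]] = {}
    payload: dict[int, TreeNode] = {}
    counter = [0]

    def new_vertex(node: Optional[TreeNode] = None) -> int:
        vid = counter[0]
        counter[0] += 1
        adj[vid] = []
        if node is not None:
            payload[vid] = node
        return vid

    def connect(u: int, v: int, data: dict) -> None:
        adj[u].append((v, data))
        adj[v].append((u, data))

    def build(node: TreeNode) -> int:
        vid = new_vertex(node if node.is_leaf() else None)
        if not node.is_leaf():
            payload[vid] = TreeNode(node.name)
        for child in node.children:
            cid = build(child)
            connect(vid, cid, {"support": child.support, "length": child.length})
        return vid

    if len(tree.children) == 2 and not tree.is_leaf():
        left, right = tree.children
        lid, rid = build(left), build(right)
        length = None
        if left.length is not None or right.length is not None:
            length = (left.length or 0.0) + (right.length or 0.0)
        support = left.support if left.support is not None else right.support
        connect(lid, rid, {"support": support, "length": length})
    else:
        build(tree)
    return adj, payload


def _root_on_edge(adj, payload, u: int, v: int, edge_data: dict) -> TreeNode:
    """Build a rooted tree with the root subdividing edge (u, v)."""

    def grow(vid: int, parent_vid: int, data: dict) -> TreeNode:
        src = payload[vid]
        node = TreeNode(src.name, data.get("support"), data.get("length"))
        for nbr, nbr_data in adj[vid]:
            if nbr != parent_vid:
                node.add_child(grow(nbr, vid, nbr_data))
        return node

    half = dict(edge_data)
    if half.get("length") is not None:
        half = {**half, "length": half["length"] / 2.0}
    root = TreeNode()
    root.add_child(grow(u, v, half))
    root.add_child(grow(v, u, half))
    return root


def enumerate_rootings(tree: TreeNode) -> list[TreeNode]:
    """One rooted candidate per edge of the unrooted version of ``tree``.

    For a binary tree with n leaves this yields 2n - 3 candidates.
    Candidates are ordered deterministically (edge discovery order).
    """
    n_leaves = sum(1 for _ in tree.iter_leaves())
    if n_leaves < 3:
        raise TreeError("rooting enumeration needs at least 3 leaves")
    adj, payload = _unrooted_graph(tree)
    seen = set()
    edges = []
    for u in sorted(adj):
        for v, data in adj[u]:
            key = (min(u, v), max(u, v))
            if key not in seen:
                seen.add(key)
                edges.append((u, v, data))
    return [_root_on_edge(adj, payload, u, v, data) for u, v, data in edges]


def extract_polytomies(tree: TreeNode) -> list[Polytomy]:
    """Polytomies of ``tree`` in bottom-up (postorder) order.

    Resolving them in the returned order never encounters an unresolved
    polytomy inside a child subtree.
    """
    return [Polytomy(n) for n in tree.iter_postorder() if len(n.children) >= 3]
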