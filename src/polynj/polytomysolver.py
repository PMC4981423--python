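"""Duplication/loss-minimizing polytomy resolution (dynamic program).

``build_table`` computes, for every node ``s`` of (a subtree of) the
species tree and every integer ``k``, the minimal weighted
duplication+loss cost ``M(s, k)`` of a resolution with ``k`` gene
lineages entering ``s``.  ``backtrack_count_vectors`` enumerates the
optimal count vectors (lineages entering each species node), and
``brute_force_resolutions`` is the exhaustive oracle the table is
validated against.

The naive O(|S| K^2) table is used deliberately; inputs are desk-scale
and correctness is anchored to the brute-force oracle.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterator, Mapping, Optional

import numpy as np

from .reconcile import CostScheme, SpeciesIndex, reconcile
from .treeio import TreeNode

__all__ = [
    "DPTable",
    "leaf_cost",
    "adjust_cost",
    "build_table",
    "optimal_cost",
    "backtrack_count_vectors",
    "brute_force_resolutions",
    "enumerate_topologies",
    "SolverError",
]


class SolverError(RuntimeError):
    pass


def adjust_cost(k: int, v: int, costs: CostScheme) -> float:
    """Cost of adjusting k entering lineages to v present copies:
    duplications if v > k, losses if v < k (never both)."""
    if v >= k:
        return costs.dup * (v - k)
    return costs.loss * (k - v)


def leaf_cost(m_s: int, k: int, costs: CostScheme) -> float:
    """M at a species node with multiplicity ``m_s`` and no descendant
    polytomy children: duplications up to m_s, or losses down to it."""
    if m_s < 0 or k < 0:
        raise ValueError("counts must be nonnegative")
    return adjust_cost(k, m_s, costs)


@dataclass
class DPTable:
    root: TreeNode
    index: SpeciesIndex
    costs: CostScheme
    K: int
    mult: dict[TreeNode, int]
    M: dict[TreeNode, np.ndarray] = field(default_factory=dict)
    children_of: dict[TreeNode, tuple[TreeNode, TreeNode]] = field(default_factory=dict)

    def multiplicity(self, s: TreeNode) -> int:
        return self.mult.get(s, 0)


def _subtree_postorder(root: TreeNode) -> list[TreeNode]:
    return list(root.iter_postorder())


def build_table(
    species_root: TreeNode,
    mult: Mapping[TreeNode, int],
    costs: CostScheme = CostScheme(),
    K: Optional[int] = None,
) -> DPTable:
    """Build the cost table over the species subtree rooted at
    ``species_root``.

    ``mult[s]`` is the number of polytomy children whose root maps exactly
    to ``s``.  ``K`` bounds the copy numbers considered; the total child
    count (the default) provably suffices, and a boundary guard raises if
    a chosen optimum ever touches ``K``.
    """
    total = sum(mult.values())
    if total < 1:
        raise ValueError("polytomy must contain at least one gene")
    if K is None:
        # a resolution never needs more simultaneous lineages than there
        # are polytomy children; +1 margin lets the boundary guard in the
        # backtrack distinguish a true optimum from a truncated one
        K = total + 1
    if K < total:
        raise ValueError(f"K={K} smaller than the number of polytomy children {total}")
    index = SpeciesIndex(species_root)
    table = DPTable(species_root, index, costs, K, dict(mult))
    subtree_total: dict[TreeNode, int] = {}
    for s in _subtree_postorder(species_root):
        m_s = table.multiplicity(s)
        subtree_total[s] = m_s + sum(subtree_total[c] for c in s.children)
        row = np.empty(K + 1)
        # k = 0 means no lineage ever enters s: feasible (at zero cost) only
        # when the subtree holds no polytomy child; a "duplication from
        # nothing" must never be priced in.
        row[0] = 0.0 if subtree_total[s] == 0 else math.inf
        if s.is_leaf():
            for k in range(1, K + 1):
                row[k] = leaf_cost(m_s, k, costs)
        else:
            left, right = s.children
            table.children_of[s] = (left, right)
            ml, mr = table.M[left], table.M[right]
            for k in range(1, K + 1):
                best = math.inf
                for v in range(m_s, K + 1):
                    cand = adjust_cost(k, v, costs) + ml[v - m_s] + mr[v - m_s]
                    if cand < best:
                        best = cand
                row[k] = best
        table.M[s] = row
    return table


def optimal_cost(table: DPTable) -> float:
    """Minimal reconciliation cost of a resolution: M(root, 1)."""
    return float(table.M[table.root][1])


def _optimal_choices(table: DPTable, s: TreeNode, k: int, tol: float = 1e-9) -> list[int]:
    """All copy numbers v attaining M(s, k) at an internal node, ascending."""
    m_s = table.multiplicity(s)
    left, right = table.children_of[s]
    ml, mr = table.M[left], table.M[right]
    target = table.M[s][k]
    out = []
    hi = 0 if k == 0 else table.K  # no copies may appear below an empty entry
    for v in range(m_s, hi + 1):
        cand = adjust_cost(k, v, table.costs) + ml[v - m_s] + mr[v - m_s]
        if cand <= target + tol:
            out.append(v)
    if out and out == [table.K] and table.K > table.multiplicity(s):
        # the only optimum sits on the boundary: K was too small
        raise SolverError(f"copy-number bound K={table.K} too small")
    return out


def _iter_vectors(table: DPTable, s: TreeNode, k: int) -> Iterator[dict[TreeNode, int]]:
    if s.is_leaf() or s not in table.children_of:
        yield {s: k}
        return
    left, right = table.children_of[s]
    m_s = table.multiplicity(s)
    for v in _optimal_choices(table, s, k):
        for lv in _iter_vectors(table, left, v - m_s):
            for rv in _iter_vectors(table, right, v - m_s):
                yield {s: k, **lv, **rv}


def backtrack_count_vectors(
    table: DPTable, limit: Optional[int] = None
) -> list[dict[TreeNode, int]]:
    """Enumerate optimal count vectors, smallest copy number first.

    Each vector maps every species node of the table's subtree to the
    number of lineages entering it; all satisfy sibling equality and
    V[root] = 1, and each attains M(root, 1).  At most ``limit`` vectors
    are returned (all of them when ``limit`` is None).
    """
    gen = _iter_vectors(table, table.root, 1)
    if limit is None:
        return list(gen)
    if limit < 1:
        raise ValueError("limit must be >= 1")
    return list(itertools.islice(gen, limit))


# ---------------------------------------------------------------------------
# Brute-force oracle
# ---------------------------------------------------------------------------

def enumerate_topologies(labels: list[str]) -> Iterator[TreeNode]:
    """All (2n-3)!! rooted binary topologies over ``labels``."""
    if not labels:
        raise ValueError("need at least one label")

    def build(i: int, tree: TreeNode) -> Iterator[TreeNode]:
        if i == len(labels):
            yield tree.copy()
            return
        leaf = TreeNode(labels[i])
        # insert above every node, including the root
        for node in list(tree.iter_preorder()):
            joint = TreeNode()
            parent = node.parent
            if parent is None:
                joint.add_child(node)
                joint.add_child(leaf)
                yield from build(i + 1, joint)
                joint.children = []
                node.parent = None
            else:
                pos = parent.children.index(node)
                parent.children[pos] = joint
                joint.parent = parent
                joint.add_child(node)
                joint.add_child(leaf)
                yield from build(i + 1, tree)
                joint.children = []
                parent.children[pos] = node
                node.parent = parent
            leaf.parent = None

    yield from build(1, TreeNode(labels[0]))


def brute_force_resolutions(
    child_images: list[TreeNode],
    species_root: TreeNode,
    costs: CostScheme = CostScheme(),
    max_children: int = 8,
) -> tuple[float, list[TreeNode]]:
    """Exhaustively score every rooted binary resolution of a polytomy.

    ``child_images`` gives, per polytomy child, the species node its root
    maps to (all within the subtree of ``species_root``).  Each candidate
    topology is scored by LCA reconciliation, plus one loss per species
    edge on the path from ``species_root`` down to the candidate root's
    image (the completion a fixed entry point at the subtree root implies).

    Returns the minimal cost and every topology attaining it, with leaves
    labelled ``c0..c{n-1}`` in the order of ``child_images``.
    """
    n = len(child_images)
    if n > max_children:
        raise ValueError(f"brute force limited to {max_children} children, got {n}")
    index = SpeciesIndex(species_root)
    leaf_map = {f"c{i}": img for i, img in enumerate(child_images)}
    labels = [f"c{i}" for i in range(n)]
    best = math.inf
    winners: list[TreeNode] = []
    tol = 1e-9
    for tree in enumerate_topologies(labels):
        rec = reconcile(tree, index, leaf_map)
        depth_gap = index.depth[rec.mapping[tree]] - index.depth[species_root]
        score = rec.cost(costs) + costs.loss * depth_gap
        if score < best - tol:
            best = score
            winners = [tree]
        elif score <= best + tol:
            winners.append(tree)
    return best, winners
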