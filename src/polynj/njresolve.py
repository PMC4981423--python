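"""Resolve a polytomy into a binary subtree guided by a count vector.

The species tree is processed bottom-up.  At each internal species node,
lineages from the two child pools are first joined by speciations, the
pair minimizing the Neighbor-Joining criterion

    Q(x, y) = (n - 2) D(x, y) - sum_{t != x} D(x, t) - sum_{t != y} D(y, t)

being joined next; surplus copies are then reduced by duplication joins
(same criterion, within the pool) and deficits are padded with artificial
loss nodes at infinite distance.  Distances to a joined node follow the
NJ reduction D(r, t) = (D(x, t) + D(y, t) - D(x, y)) / 2, except that a
loss partner simply hands over the real partner's distances.

The Q sums run over the local candidate pool (the union of the two child
pools for speciations, the single pool for duplications), restricted to
real nodes; this is the convention under which the single-species case
collapses exactly to classical Neighbor-Joining.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional

from .treeio import INF, DistanceMatrix, TreeNode

__all__ = [
    "Point",
    "MetricSpace",
    "ResolutionError",
    "Resolution",
    "q_score",
    "metric_space_from_matrix",
    "resolve_polytomy",
]


class ResolutionError(RuntimeError):
    pass


@dataclass
class Point:
    """A live element of the evolving metric space."""

    idx: int
    tree: TreeNode
    species: TreeNode
    is_loss: bool = False

    @property
    def leafset(self) -> frozenset:
        return self.tree.leaf_set()


class MetricSpace:
    """The evolving set of joinable nodes with pairwise distances.

    Loss nodes sit at infinite distance from everything; distances between
    real nodes stay symmetric with zero self-distance.
    """

    def __init__(self):
        self.points: dict[int, Point] = {}
        self.D: dict[int, dict[int, float]] = {}
        self._next = 0
        self.join_count = 0
        self.loss_count = 0

    def __len__(self) -> int:
        return len(self.points)

    def _new_idx(self) -> int:
        idx = self._next
        self._next += 1
        return idx

    def distance(self, x: int, y: int) -> float:
        if x == y:
            return 0.0
        if self.points[x].is_loss or self.points[y].is_loss:
            return INF
        return self.D[x][y]

    def add_point(
        self,
        tree: TreeNode,
        species: TreeNode,
        row: Optional[Mapping[int, float]] = None,
        is_loss: bool = False,
    ) -> Point:
        idx = self._new_idx()
        point = Point(idx, tree, species, is_loss)
        self.points[idx] = point
        self.D[idx] = {}
        if not is_loss:
            if row is None:
                row = {}
            for other, d in row.items():
                if other in self.points and not self.points[other].is_loss:
                    self.D[idx][other] = d
                    self.D[other][idx] = d
        return point

    def add_loss(self, species: TreeNode) -> Point:
        stub = TreeNode()
        stub.event = "loss-stub"
        stub.species = species
        point = self.add_point(stub, species, is_loss=True)
        stub.name = f"__loss_{point.idx}"
        self.loss_count += 1
        return point

    def remove(self, idx: int) -> None:
        del self.points[idx]
        for other in self.D.pop(idx, {}):
            self.D[other].pop(idx, None)

    def join(self, x: int, y: int, species: TreeNode) -> Point:
        """Join points x and y into a new node mapped to ``species``."""
        px, py = self.points[x], self.points[y]
        tree = TreeNode()
        tree.add_child(px.tree)
        tree.add_child(py.tree)
        tree.species = species
        row: dict[int, float] = {}
        if not (px.is_loss and py.is_loss):
            dxy = self.distance(x, y)
            for t, pt in self.points.items():
                if t in (x, y) or pt.is_loss:
                    continue
                if px.is_loss:
                    row[t] = self.D[y][t]
                elif py.is_loss:
                    row[t] = self.D[x][t]
                else:
                    row[t] = 0.5 * (self.D[x][t] + self.D[y][t] - dxy)
        self.remove(x)
        self.remove(y)
        self.join_count += 1
        return self.add_point(tree, species, row, is_loss=px.is_loss and py.is_loss)

    def collapse(self, members: list[int], tree: TreeNode, species: TreeNode) -> Point:
        """Replace ``members`` by one point whose row is their mean row
        (surrogate for a pre-resolved, supported clade)."""
        reals = [i for i in members if not self.points[i].is_loss]
        if not reals:
            raise ResolutionError("cannot collapse a group with no real members")
        if len(reals) == 1 and len(members) == 1:
            point = self.points[reals[0]]
            point.tree = tree
            point.species = species
            return point
        row: dict[int, float] = {}
        for t, pt in self.points.items():
            if t in members or pt.is_loss:
                continue
            row[t] = sum(self.D[i][t] for i in reals) / len(reals)
        for i in members:
            self.remove(i)
        return self.add_point(tree, species, row)

    def copy(self, tree_map: Optional[Mapping[TreeNode, TreeNode]] = None) -> "MetricSpace":
        """Clone the space; ``tree_map`` rebinds point payloads to copied
        gene-tree nodes."""
        clone = MetricSpace.__new__(MetricSpace)
        clone.points = {}
        for idx, p in self.points.items():
            tree = tree_map.get(p.tree, p.tree) if tree_map else p.tree
            clone.points[idx] = Point(idx, tree, p.species, p.is_loss)
        clone.D = {i: dict(row) for i, row in self.D.items()}
        clone._next = self._next
        clone.join_count = self.join_count
        clone.loss_count = self.loss_count
        return clone


def q_score(ms: MetricSpace, pool: Iterable[int], x: int, y: int) -> float:
    """The NJ selection criterion over the candidate ``pool``."""
    pool = list(pool)
    n = len(pool)
    if x == y:
        raise ValueError("q_score needs two distinct points")
    dxy = ms.distance(x, y)
    if dxy == INF:
        return INF
    sx = sum(ms.distance(x, t) for t in pool if t != x)
    sy = sum(ms.distance(y, t) for t in pool if t != y)
    return (n - 2) * dxy - sx - sy


def _split_real(ms: MetricSpace, pool: list[int]) -> tuple[list[int], list[int]]:
    reals = [i for i in pool if not ms.points[i].is_loss]
    losses = [i for i in pool if ms.points[i].is_loss]
    return reals, losses


def _pick_cross(ms: MetricSpace, pool_l: list[int], pool_r: list[int]) -> tuple[int, int]:
    reals_l, losses_l = _split_real(ms, pool_l)
    reals_r, losses_r = _split_real(ms, pool_r)
    if reals_l and reals_r:
        pool = reals_l + [i for i in reals_r if i not in reals_l]
        best = None
        best_key = None
        for x in reals_l:
            for y in reals_r:
                if x == y:
                    continue
                key = (q_score(ms, pool, x, y), x, y)
                if best_key is None or key < best_key:
                    best_key = key
                    best = (x, y)
        return best
    if reals_l:
        return min(reals_l), min(losses_r)
    if reals_r:
        return min(losses_l), min(reals_r)
    return min(pool_l), min(pool_r)


def _pick_within(ms: MetricSpace, pool: list[int]) -> tuple[int, int]:
    reals, losses = _split_real(ms, pool)
    if len(reals) >= 2:
        best = None
        best_key = None
        for x, y in itertools.combinations(sorted(reals), 2):
            key = (q_score(ms, reals, x, y), x, y)
            if best_key is None or key < best_key:
                best_key = key
                best = (x, y)
        return best
    if len(reals) == 1:
        return reals[0], min(losses)
    return tuple(sorted(losses)[:2])


def metric_space_from_matrix(
    dm: DistanceMatrix,
    children: Iterable[tuple[TreeNode, TreeNode]],
) -> tuple[MetricSpace, dict[TreeNode, list[int]]]:
    """Seed a metric space from polytomy leaf children and a matrix.

    ``children`` yields (leaf subtree, species node) pairs; every leaf
    name must be a label of ``dm``.  Returns the space and the per-species
    pools E(s).
    """
    ms = MetricSpace()
    pools: dict[TreeNode, list[int]] = {}
    label_of: dict[int, str] = {}
    for tree, species in children:
        if tree.name is None:
            raise ResolutionError(
                "metric_space_from_matrix only seeds leaf children; use "
                "MetricSpace.collapse for resolved subtrees"
            )
        row = {
            idx: dm.get(tree.name, label_of[idx])
            for idx in label_of
        }
        point = ms.add_point(tree, species, row)
        label_of[point.idx] = tree.name
        pools.setdefault(species, []).append(point.idx)
    return ms, pools


@dataclass
class Resolution:
    """Outcome of resolving one polytomy."""

    root: Point
    joins: int
    stubs: int
    real_leaves: int

    @property
    def tree(self) -> TreeNode:
        return self.root.tree


def resolve_polytomy(
    species_root: TreeNode,
    count_vector: Mapping[TreeNode, int],
    ms: MetricSpace,
    pools: dict[TreeNode, list[int]],
) -> Resolution:
    """Resolve the polytomy whose children populate ``pools`` into a
    single binary subtree realizing ``count_vector``.

    ``count_vector`` must satisfy sibling equality and put one lineage at
    ``species_root``.  Loss stubs remain in the returned working tree (the
    caller prunes them from user-facing output).
    """
    v_root = count_vector.get(species_root, 0)
    if v_root != 1:
        raise ResolutionError(f"count vector must have 1 lineage at the root, got {v_root}")
    real_leaves = sum(
        0 if ms.points[i].is_loss else 1 for pool in pools.values() for i in pool
    )
    joins0, stubs0 = ms.join_count, ms.loss_count
    for s in species_root.iter_postorder():
        pool_s = pools.setdefault(s, [])
        if s.children:
            sl, sr = s.children
            n = count_vector.get(sl, 0)
            if n != count_vector.get(sr, 0):
                raise ResolutionError("count vector violates sibling equality")
            pool_l = pools.setdefault(sl, [])
            pool_r = pools.setdefault(sr, [])
            for _ in range(n):
                if not pool_l or not pool_r:
                    raise ResolutionError("count vector infeasible: empty candidate set")
                x, y = _pick_cross(ms, pool_l, pool_r)
                point = ms.join(x, y, s)
                pool_l.remove(x)
                pool_r.remove(y)
                pool_s.append(point.idx)
        k = count_vector.get(s, 0)
        while len(pool_s) > k:
            if len(pool_s) < 2:
                raise ResolutionError("count vector infeasible: empty candidate set")
            x, y = _pick_within(ms, pool_s)
            point = ms.join(x, y, s)
            pool_s.remove(x)
            pool_s.remove(y)
            pool_s.append(point.idx)
        while len(pool_s) < k:
            point = ms.add_loss(s)
            pool_s.append(point.idx)
    top = pools[species_root]
    if len(top) != 1:
        raise ResolutionError("resolution did not converge to a single lineage")
    root = ms.points[top[0]]
    return Resolution(
        root=root,
        joins=ms.join_count - joins0,
        stubs=ms.loss_count - stubs0,
        real_leaves=real_leaves,
    )
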