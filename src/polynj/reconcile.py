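"""LCA reconciliation of a gene tree with a species tree.

Maps every gene-tree node to a species-tree node (leaves by the supplied
binding, internal nodes to the LCA of their children's images), labels
internal nodes as duplications or speciations, counts losses per
species-tree branch via the edge-subdivision construction, and derives
ancestral gene contents (number of gene lineages entering each species
node).  Losses are attributed to the species-tree branch of the lineage
that went missing, which is what per-branch genome-wide tallies need.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional

from .treeio import TreeNode

__all__ = [
    "CostScheme",
    "SpeciesIndex",
    "Reconciliation",
    "lca_map",
    "annotate_events",
    "count_losses",
    "gene_content",
    "reconcile",
    "branch_tally",
    "tally_table",
]


@dataclass(frozen=True)
class CostScheme:
    """Weights for duplication and loss events (both finite, not both 0)."""

    dup: float = 1.0
    loss: float = 1.0

    def __post_init__(self):
        if self.dup < 0 or self.loss < 0:
            raise ValueError("event costs must be nonnegative")
        if self.dup == 0 and self.loss == 0:
            raise ValueError("duplication and loss costs cannot both be zero")


class SpeciesIndex:
    """Depth/parent index over a species tree with O(depth) LCA queries."""

    def __init__(self, root: TreeNode):
        self.root = root
        self.nodes = list(root.iter_postorder())
        self.depth: dict[TreeNode, int] = {}
        self.order: dict[TreeNode, int] = {n: i for i, n in enumerate(self.nodes)}
        # the given root anchors depth 0 even when it is a subtree of a
        # larger species tree
        for node in root.iter_preorder():
            self.depth[node] = 0 if node is root else self.depth[node.parent] + 1
        self.by_label: dict[str, TreeNode] = {}
        for node in self.nodes:
            if node.name:
                self.by_label[node.name] = node

    def lca(self, a: TreeNode, b: TreeNode) -> TreeNode:
        da, db = self.depth[a], self.depth[b]
        while da > db:
            a = a.parent
            da -= 1
        while db > da:
            b = b.parent
            db -= 1
        while a is not b:
            a, b = a.parent, b.parent
        return a

    def sibling(self, node: TreeNode) -> TreeNode:
        p = node.parent
        return p.children[0] if p.children[1] is node else p.children[1]

    def branch_id(self, node: TreeNode) -> str:
        """Stable identifier for the branch above ``node``."""
        if node.name:
            return node.name
        return f"n{self.order[node]}"


@dataclass
class Reconciliation:
    """A reconciled gene tree: node images, events, loss placement, cost."""

    gene_tree: TreeNode
    index: SpeciesIndex
    mapping: dict[TreeNode, TreeNode]
    events: dict[TreeNode, str] = field(default_factory=dict)
    losses: dict[TreeNode, int] = field(default_factory=dict)

    @property
    def species_tree(self) -> TreeNode:
        return self.index.root

    def duplications(self) -> list[TreeNode]:
        return [n for n, e in self.events.items() if e == "duplication"]

    def dup_count(self) -> int:
        return len(self.duplications())

    def loss_count(self) -> int:
        return sum(self.losses.values())

    def cost(self, costs: CostScheme = CostScheme()) -> float:
        return costs.dup * self.dup_count() + costs.loss * self.loss_count()


def _resolve_leaf_image(value, index: SpeciesIndex) -> TreeNode:
    if isinstance(value, TreeNode):
        return value
    try:
        return index.by_label[value]
    except KeyError:
        raise ValueError(f"species label {value!r} not found in species tree") from None


def lca_map(
    gene_tree: TreeNode,
    species_index: SpeciesIndex | TreeNode,
    leaf_map: Mapping[str, object],
) -> Reconciliation:
    """Compute the LCA mapping of ``gene_tree`` into the species tree.

    ``leaf_map`` sends gene leaf names to species labels or species-tree
    nodes (internal species nodes are allowed, which is what polytomy
    resolution needs for pre-resolved child subtrees).
    """
    index = (
        species_index
        if isinstance(species_index, SpeciesIndex)
        else SpeciesIndex(species_index)
    )
    mapping: dict[TreeNode, TreeNode] = {}
    for node in gene_tree.iter_postorder():
        if node.is_leaf():
            if node.name not in leaf_map:
                raise ValueError(f"gene leaf {node.name!r} has no species mapping")
            mapping[node] = _resolve_leaf_image(leaf_map[node.name], index)
        else:
            image = mapping[node.children[0]]
            for child in node.children[1:]:
                image = index.lca(image, mapping[child])
            mapping[node] = image
    return Reconciliation(gene_tree, index, mapping)


def annotate_events(rec: Reconciliation) -> Reconciliation:
    """Label each internal gene node duplication or speciation (in place).

    A node is a duplication iff it maps to the same species node as at
    least one of its children.  Leaves keep ``"leaf"`` (or a pre-set
    ``"loss-stub"`` flag).
    """
    for node in rec.gene_tree.iter_postorder():
        if node.is_leaf():
            rec.events[node] = node.event if node.event == "loss-stub" else "leaf"
            continue
        image = rec.mapping[node]
        if any(rec.mapping[c] is image for c in node.children):
            rec.events[node] = "duplication"
        else:
            rec.events[node] = "speciation"
        node.event = rec.events[node]
    return rec


def _edge_path(rec: Reconciliation, child: TreeNode) -> list[TreeNode]:
    """Species nodes from image(parent) down to image(child), exclusive of
    the top: ``[c1, c2, ..., image(child)]`` (empty when images coincide)."""
    top = rec.mapping[child.parent]
    chain = []
    node = rec.mapping[child]
    while node is not top:
        chain.append(node)
        node = node.parent
    chain.reverse()
    return chain


def count_losses(rec: Reconciliation) -> Reconciliation:
    """Count losses per species branch (keyed by the species node below
    the branch), following the edge-subdivision construction.

    For a gene edge (u, v) descending from species a = image(u) to
    b = image(v) through the chain a -> c1 -> ... -> b: if u is a
    speciation, the lineage is already committed to the c1 side, so the
    siblings of c2..b are lost; if u is a duplication, the siblings of
    c1..b are lost.  Explicit loss stubs in the gene tree each add one
    loss on their own species branch.
    """
    if not rec.events:
        annotate_events(rec)
    losses: dict[TreeNode, int] = {}

    def add(species: TreeNode, k: int = 1) -> None:
        losses[species] = losses.get(species, 0) + k

    for node in rec.gene_tree.iter_preorder():
        if rec.events.get(node) == "loss-stub":
            add(rec.mapping[node])
        if node.parent is None:
            continue
        chain = _edge_path(rec, node)
        skip_first = rec.events[node.parent] == "speciation"
        for i, c in enumerate(chain):
            if i == 0 and skip_first:
                continue
            add(rec.index.sibling(c))
    rec.losses = losses
    return rec


def gene_content(rec: Reconciliation) -> dict[TreeNode, int]:
    """Number of gene lineages entering each species node.

    Counts, on the subdivided-and-completed gene tree, the nodes mapped to
    a species node whose parent maps elsewhere; this includes pass-through
    lineages and the entry points of lineages that are subsequently lost.
    """
    if not rec.events:
        annotate_events(rec)
    content: dict[TreeNode, int] = {}

    def add(species: TreeNode, k: int = 1) -> None:
        content[species] = content.get(species, 0) + k

    add(rec.mapping[rec.gene_tree])
    for node in rec.gene_tree.iter_preorder():
        if node.parent is None:
            continue
        chain = _edge_path(rec, node)
        skip_first = rec.events[node.parent] == "speciation"
        for i, c in enumerate(chain):
            add(c)  # the lineage itself enters c
            if i == 0 and skip_first:
                continue
            add(rec.index.sibling(c))  # the lost sibling lineage entered too
    return content


def reconcile(
    gene_tree: TreeNode,
    species_index: SpeciesIndex | TreeNode,
    leaf_map: Mapping[str, object],
) -> Reconciliation:
    """Full reconciliation: mapping, events and per-branch losses."""
    rec = lca_map(gene_tree, species_index, leaf_map)
    annotate_events(rec)
    count_losses(rec)
    return rec


def branch_tally(
    recs: Iterable[Reconciliation],
    index: Optional[SpeciesIndex] = None,
) -> dict[TreeNode, tuple[int, int]]:
    """Sum per-species-branch (duplications, losses) over reconciliations.

    All reconciliations must share one species tree.
    """
    recs = list(recs)
    if index is None:
        if not recs:
            return {}
        index = recs[0].index
    tally: dict[TreeNode, tuple[int, int]] = {n: (0, 0) for n in index.nodes}
    for rec in recs:
        if rec.index.root is not index.root:
            raise ValueError("reconciliations tallied against different species trees")
        for node in rec.duplications():
            d, l = tally[rec.mapping[node]]
            tally[rec.mapping[node]] = (d + 1, l)
        for species, k in rec.losses.items():
            d, l = tally[species]
            tally[species] = (d, l + k)
    return tally


def tally_table(tally: Mapping[TreeNode, tuple[int, int]], index: SpeciesIndex) -> str:
    """Render a tally as TSV: branch id, duplications, losses."""
    lines = ["branch\tduplications\tlosses"]
    for node in index.nodes:
        d, l = tally.get(node, (0, 0))
        lines.append(f"{index.branch_id(node)}\t{d}\t{l}")
    return "\n".join(lines) + "\n"
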