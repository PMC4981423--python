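"""Synthetic fixtures: species trees, birth-death gene families with
recorded event placements, additive noisy distance matrices, support
degradation and topology perturbation.

Gene families evolve along the species tree under a per-branch
birth-death process with exponential waiting times.  Lineages extinct in
all species are rejected and redrawn.  The recorded ground truth consists
of the *observable* events: raw birth-death events whose evidence
survives pruning of extinct subtrees, recomputed with an independent
clade-set reconciliation (``observable_events``) so that reconciling the
true tree reproduces the recorded counts exactly.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np

from .treeio import DistanceMatrix, TreeNode, write_distance_matrix, write_newick

__all__ = [
    "GeneFamily",
    "simulate_species_tree",
    "simulate_gene_family",
    "simulate_distances",
    "degrade_supports",
    "perturb_topology",
    "observable_events",
    "write_fixture_bundle",
]


def simulate_species_tree(n_leaves: int, seed: int, prefix: str = "sp") -> TreeNode:
    """Random rooted binary species tree with unit branch lengths."""
    if n_leaves < 2:
        raise ValueError("species tree needs at least 2 leaves")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(f"{prefix}{i + 1}", length=1.0) for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        right = nodes.pop(j)
        left = nodes.pop(i)
        parent = TreeNode(length=1.0)
        parent.add_child(left)
        parent.add_child(right)
        nodes.append(parent)
    root = nodes[0]
    root.length = None
    return root


# ---------------------------------------------------------------------------
# Independent clade-set reconciliation (ground-truth recorder)
# ---------------------------------------------------------------------------

def observable_events(
    gene_tree: TreeNode,
    species_tree: TreeNode,
    leaf_species: dict[str, str],
) -> tuple[dict[TreeNode, int], dict[TreeNode, int]]:
    """Duplications and losses per species node, by brute-force clade-set
    reconciliation with an explicit walk down the species tree.

    Deliberately independent of :mod:`polynj.reconcile`: node images are
    found by scanning species clades, and losses by walking each gene edge
    down the species tree and attaching one loss per bypassed sibling.
    """
    species_nodes = list(species_tree.iter_postorder())
    clade = {s: frozenset(s.leaf_names()) for s in species_nodes}
    by_size = sorted(species_nodes, key=lambda s: len(clade[s]))

    def image_of(labels: frozenset) -> TreeNode:
        for s in by_size:
            if labels <= clade[s]:
                return s
        raise ValueError(f"no species clade contains {sorted(labels)}")

    image: dict[TreeNode, TreeNode] = {}
    labels_of: dict[TreeNode, frozenset] = {}
    for node in gene_tree.iter_postorder():
        if node.is_leaf():
            labels_of[node] = frozenset({leaf_species[node.name]})
        else:
            labels_of[node] = frozenset().union(*(labels_of[c] for c in node.children))
        image[node] = image_of(labels_of[node])

    dups: dict[TreeNode, int] = {}
    losses: dict[TreeNode, int] = {}
    for node in gene_tree.iter_preorder():
        if node.is_leaf():
            continue
        is_dup = any(image[c] is image[node] for c in node.children)
        if is_dup:
            dups[image[node]] = dups.get(image[node], 0) + 1
        for child in node.children:
            target = image[child]
            if is_dup:
                current = image[node]
            else:
                # a speciation commits the lineage to the child side first
                current = _step_towards(image[node], target)
            while current is not target:
                nxt = _step_towards(current, target)
                other = [c for c in current.children if c is not nxt][0]
                losses[other] = losses.get(other, 0) + 1
                current = nxt
    return dups, losses


def _step_towards(ancestor: TreeNode, descendant: TreeNode) -> TreeNode:
    """The child of ``ancestor`` on the path down to ``descendant``."""
    node = descendant
    while node.parent is not ancestor:
        node = node.parent
    return node


# ---------------------------------------------------------------------------
# Birth-death gene families
# ---------------------------------------------------------------------------

@dataclass
class GeneFamily:
    """A simulated family: pruned true tree plus recorded ground truth."""

    tree: TreeNode
    leaf_species: dict[str, str]
    truth_dups: dict[TreeNode, int]
    truth_losses: dict[TreeNode, int]
    raw_dup_count: int
    raw_loss_count: int
    census: dict[str, int] = field(default_factory=dict)

    @property
    def size(self) -> int:
        return len(self.leaf_species)


def simulate_gene_family(
    species_tree: TreeNode,
    rate_dup: float,
    rate_loss: float,
    seed: int,
    stem_length: float = 1.0,
    max_genes: int = 500,
    max_tries: int = 200,
) -> GeneFamily:
    """Evolve one gene family along ``species_tree`` by birth-death.

    Families extinct in every species (or exploding past ``max_genes``)
    are rejected and redrawn with fresh randomness.
    """
    if rate_dup < 0 or rate_loss < 0:
        raise ValueError("rates must be nonnegative")
    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        counters = {"dup": 0, "loss": 0, "alive": 0}
        tree = _evolve_branch(species_tree, stem_length, rng, rate_dup, rate_loss,
                              counters, max_genes)
        if tree is None or counters["alive"] == 0:
            continue
        per_species: dict[str, int] = {}
        leaf_species: dict[str, str] = {}
        for leaf in tree.iter_leaves():
            label = leaf.species.name
            per_species[label] = per_species.get(label, 0) + 1
            leaf.name = f"g{per_species[label]}_{label}"
            leaf_species[leaf.name] = label
        for node in tree.iter_postorder():
            if node.children:
                node.support = 1.0
        dups, losses = observable_events(tree, species_tree, leaf_species)
        return GeneFamily(
            tree=tree,
            leaf_species=leaf_species,
            truth_dups=dups,
            truth_losses=losses,
            raw_dup_count=counters["dup"],
            raw_loss_count=counters["loss"],
            census=per_species,
        )
    raise RuntimeError(f"no surviving family after {max_tries} draws")


def _evolve_branch(species, t_remaining, rng, rd, rl, counters, max_genes):
    """One lineage entering the branch above ``species`` with
    ``t_remaining`` time to go; returns the pruned subtree or None."""
    total = rd + rl
    waited = 0.0
    while True:
        if counters["alive"] > max_genes:
            return None
        t = rng.exponential(1.0 / total) if total > 0 else np.inf
        if waited + t >= t_remaining:
            break
        waited += t
        if rng.random() < (rd / total if total else 0.0):
            counters["dup"] += 1
            left = _evolve_branch(species, t_remaining - waited, rng, rd, rl,
                                  counters, max_genes)
            right = _evolve_branch(species, t_remaining - waited, rng, rd, rl,
                                   counters, max_genes)
            return _merge(left, right, waited)
        counters["loss"] += 1
        return None
    if species.is_leaf():
        leaf = TreeNode(length=t_remaining)
        leaf.species = species
        counters["alive"] += 1
        return leaf
    left = _evolve_branch(species.children[0],
                          species.children[0].length or 1.0,
                          rng, rd, rl, counters, max_genes)
    right = _evolve_branch(species.children[1],
                           species.children[1].length or 1.0,
                           rng, rd, rl, counters, max_genes)
    node = _merge(left, right, t_remaining)
    if node is not None and node.children:
        node.species = species
    return node


def _merge(left, right, elapsed):
    if left is not None and right is not None:
        node = TreeNode(length=elapsed)
        node.add_child(left)
        node.add_child(right)
        return node
    survivor = left if left is not None else right
    if survivor is not None:
        survivor.length = (survivor.length or 0.0) + elapsed
    return survivor


# ---------------------------------------------------------------------------
# Distances, supports, perturbation
# ---------------------------------------------------------------------------

def simulate_distances(
    gene_tree: TreeNode,
    noise_sd: float = 0.0,
    seed: int = 0,
    model: str = "lengths",
) -> DistanceMatrix:
    """Additive leaf-to-leaf path distances, optionally perturbed by
    truncated Gaussian noise (kept symmetric and nonnegative)."""
    if model not in ("lengths", "unit"):
        raise ValueError("model must be 'lengths' or 'unit'")
    leaves = list(gene_tree.iter_leaves())
    labels = [l.name for l in leaves]
    depth: dict[TreeNode, float] = {}
    for node in gene_tree.iter_preorder():
        step = 1.0 if model == "unit" else (node.length or 0.0)
        depth[node] = step if node.parent is None else depth[node.parent] + step

    def ancestors(node):
        out = []
        while node is not None:
            out.append(node)
            node = node.parent
        return out

    anc = {l: ancestors(l) for l in leaves}
    anc_sets = {l: set(a) for l, a in anc.items()}
    n = len(leaves)
    matrix = np.zeros((n, n))
    rng = np.random.default_rng(seed)
    for i, j in itertools.combinations(range(n), 2):
        a, b = leaves[i], leaves[j]
        lca = next(x for x in anc[a] if x in anc_sets[b])
        d = depth[a] + depth[b] - 2 * depth[lca]
        if noise_sd > 0:
            d = max(d + rng.normal(0.0, noise_sd), 0.0)
        matrix[i, j] = matrix[j, i] = d
    return DistanceMatrix(labels, matrix)


def _internal_edges(tree: TreeNode) -> list[TreeNode]:
    return [n for n in tree.iter_postorder()
            if n.children and n.parent is not None]


def degrade_supports(
    gene_tree: TreeNode,
    n_weak: int,
    seed: int,
    low: float = 0.5,
    high: float = 0.99,
) -> tuple[TreeNode, list[TreeNode]]:
    """Copy the tree with ``n_weak`` random internal branches weakly
    supported (< default threshold) and the rest strongly supported.

    Returns the degraded copy and the weakened nodes.
    """
    tree = gene_tree.copy()
    internal = _internal_edges(tree)
    if n_weak > len(internal):
        raise ValueError(f"n_weak={n_weak} exceeds {len(internal)} internal branches")
    rng = np.random.default_rng(seed)
    weak_idx = set(rng.choice(len(internal), size=n_weak, replace=False).tolist()) if n_weak else set()
    weak = []
    for i, node in enumerate(internal):
        if i in weak_idx:
            node.support = low
            weak.append(node)
        else:
            node.support = high
    return tree, weak


def perturb_topology(
    gene_tree: TreeNode,
    n_moves: int,
    seed: int,
) -> tuple[TreeNode, list[TreeNode]]:
    """Apply ``n_moves`` random nearest-neighbor interchanges.

    Each move swaps a random child of a random internal node with that
    node's sibling, changing exactly that branch's bipartition.  Returns
    the perturbed copy and the list of moved (internal) nodes.
    """
    tree = gene_tree.copy()
    rng = np.random.default_rng(seed)
    moved = []
    for _ in range(n_moves):
        candidates = [n for n in _internal_edges(tree) if len(n.parent.children) == 2]
        if not candidates:
            break
        node = candidates[rng.integers(len(candidates))]
        parent = node.parent
        sibling = parent.children[0] if parent.children[1] is node else parent.children[1]
        ci = int(rng.integers(len(node.children)))
        child = node.children[ci]
        si = parent.children.index(sibling)
        parent.children[si] = child
        child.parent = parent
        node.children[ci] = sibling
        sibling.parent = node
        moved.append(node)
    return tree, moved


def write_fixture_bundle(
    directory,
    species_tree: TreeNode,
    families: list[GeneFamily],
    distances: Optional[list[DistanceMatrix]] = None,
) -> None:
    """Write species.nw, geneN.nw[, geneN.dist], geneN.truth.tsv and a
    manifest.tsv under ``directory`` (plain text only)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    (directory / "species.nw").write_text(write_newick(species_tree) + "\n")
    manifest = ["family\tn_genes\tdups\tlosses"]
    for i, fam in enumerate(families, 1):
        (directory / f"gene{i}.nw").write_text(write_newick(fam.tree) + "\n")
        if distances is not None:
            (directory / f"gene{i}.dist").write_text(write_distance_matrix(distances[i - 1]))
        rows = ["species\tduplications\tlosses"]
        keys = set(fam.truth_dups) | set(fam.truth_losses)
        for s in species_tree.iter_postorder():
            if s in keys:
                rows.append(
                    f"{s.name or id(s)}\t{fam.truth_dups.get(s, 0)}\t{fam.truth_losses.get(s, 0)}"
                )
        (directory / f"gene{i}.truth.tsv").write_text("\n".join(rows) + "\n")
        manifest.append(
            f"gene{i}\t{fam.size}\t{sum(fam.truth_dups.values())}\t{sum(fam.truth_losses.values())}"
        )
    (directory / "manifest.tsv").write_text("\n".join(manifest) + "\n")
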