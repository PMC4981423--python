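"""Independent reference implementations used only by the test suite.

These deliberately avoid the package's own algorithms: node images are
found by scanning species clade sets quadratically, losses by explicitly
constructing the subdivided-and-completed gene tree, and optimal count
profiles by exhaustive enumeration.
"""

from __future__ import annotations

import itertools
from collections import Counter

from polynj.treeio import TreeNode


def species_clades(species_tree: TreeNode) -> dict:
    return {s: frozenset(s.leaf_names()) for s in species_tree.iter_postorder()}


def leafset_images(gene_tree: TreeNode, species_tree: TreeNode, leaf_species: dict) -> dict:
    """Brute-force LCA mapping: the smallest species clade containing each
    gene node's descendant species labels."""
    clades = species_clades(species_tree)
    by_size = sorted(clades, key=lambda s: len(clades[s]))
    images = {}
    below = {}
    for node in gene_tree.iter_postorder():
        if node.is_leaf():
            if node.event == "loss-stub":
                below[node] = frozenset(node.species.leaf_names())
            else:
                below[node] = frozenset({leaf_species[node.name]})
        else:
            below[node] = frozenset().union(*(below[c] for c in node.children))
        images[node] = next(s for s in by_size if below[node] <= clades[s])
    return images


def build_completed_tree(gene_tree: TreeNode, species_tree: TreeNode, leaf_species: dict):
    """Explicitly construct the subdivided, loss-completed gene tree.

    Every edge of the result connects nodes mapped either to the same
    species node or to the two ends of a species-tree edge.  Returns the
    completed tree, its node->species map, and the Counter of loss leaves
    per species node.
    """
    images = leafset_images(gene_tree, species_tree, leaf_species)
    losses: Counter = Counter()
    mapping = {}

    def path_down(a, b):
        out = []
        node = b
        while node is not a:
            out.append(node)
            node = node.parent
        out.reverse()
        return out  # [child of a, ..., b]

    def rebuild(gnode) -> TreeNode:
        clone = TreeNode(gnode.name)
        mapping[clone] = images[gnode]
        if gnode.is_leaf():
            return clone
        is_dup = any(images[c] is images[gnode] for c in gnode.children)
        for child in gnode.children:
            sub = rebuild(child)
            chain = path_down(images[gnode], images[child])
            if not is_dup and chain:
                chain = chain[1:]  # speciation commits the first step
            # walk down, attaching one loss leaf per bypassed sibling
            top = sub
            for c in reversed(chain):
                sib = [x for x in c.parent.children if x is not c][0]
                joint = TreeNode()
                mapping[joint] = c.parent
                loss_leaf = TreeNode(f"*loss*{len(mapping)}")
                mapping[loss_leaf] = sib
                losses[sib] += 1
                joint.add_child(top)
                joint.add_child(loss_leaf)
                top = joint
            clone.add_child(top)
        return clone

    completed = rebuild(gene_tree)
    return completed, mapping, losses


def subdivision_losses(gene_tree, species_tree, leaf_species) -> Counter:
    return build_completed_tree(gene_tree, species_tree, leaf_species)[2]


def leafset_duplications(gene_tree, species_tree, leaf_species) -> Counter:
    images = leafset_images(gene_tree, species_tree, leaf_species)
    dups: Counter = Counter()
    for node in gene_tree.iter_postorder():
        if node.children and any(images[c] is images[node] for c in node.children):
            dups[images[node]] += 1
    return dups


def wagner_optimal_profiles(species_root: TreeNode, mult: dict, dup: float, loss: float, K: int):
    """Exhaustive minimization of weighted gains+losses over all count
    profiles (lineages entering each species node, root fixed at 1).

    Enumerates, per internal node, the common entering count of its two
    children; the copy number at a node is forced to entering(children) +
    local multiplicity (leaves: multiplicity).  Returns (min cost, set of
    optimal profiles as tuples over postorder nodes).
    """
    nodes = list(species_root.iter_postorder())
    internal = [s for s in nodes if s.children]
    totals = {}
    for s in nodes:
        totals[s] = mult.get(s, 0) + sum(totals[c] for c in s.children)

    def delta(k, v):
        return dup * (v - k) if v >= k else loss * (k - v)

    best = float("inf")
    winners = set()
    for combo in itertools.product(range(K + 1), repeat=len(internal)):
        enter = {species_root: 1}
        down = dict(zip(internal, combo))
        feasible = True
        for s in internal:
            for c in s.children:
                enter[c] = down[s]
        cost = 0.0
        for s in nodes:
            k = enter[s]
            if k == 0 and totals[s] > 0:
                feasible = False
                break
            if s.children:
                v = down[s] + mult.get(s, 0)
            else:
                v = mult.get(s, 0)
            if v < mult.get(s, 0) or (k == 0 and v > 0):
                feasible = False
                break
            cost += delta(k, v)
        if not feasible:
            continue
        profile = tuple(enter[s] for s in nodes)
        if cost < best - 1e-9:
            best = cost
            winners = {profile}
        elif cost <= best + 1e-9:
            winners.add(profile)
    return best, winners
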