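"""End-to-end gene-tree correction and the command-line interface.

Pipeline: contract weakly supported branches -> (optionally) enumerate
rootings -> per-polytomy cost table and count vectors -> NJ-guided
resolution -> assembled corrected trees ranked by reconciliation cost.

All polytomies of one candidate share a single evolving metric space, so
later polytomies see the NJ-reduced distance rows of earlier resolutions.
Supported clades that were never part of a polytomy enter the space with
the arithmetic mean of their member rows.
"""

from __future__ import annotations

import sys
from dataclasses import dataclass, field
from typing import Optional

import click

from . import njresolve, polytomysolver, prepare, reconcile, treeio
from .njresolve import MetricSpace, Resolution
from .polytomysolver import build_table, backtrack_count_vectors, optimal_cost
from .prepare import contract_low_support, enumerate_rootings, extract_polytomies
from .reconcile import CostScheme, Reconciliation, SpeciesIndex, lca_map
from .treeio import DistanceMatrix, TreeNode

__all__ = ["Correction", "correct_tree", "rank_outputs", "strip_loss_stubs", "main"]


@dataclass
class Correction:
    """One corrected tree candidate with its reconciliation evidence."""

    tree: TreeNode
    cost: float
    reconciliation: Reconciliation
    rooting: int
    resolutions: list[Resolution] = field(default_factory=list)
    working_tree: Optional[TreeNode] = None  # with loss stubs retained
    order: int = 0


def strip_loss_stubs(tree: TreeNode) -> Optional[TreeNode]:
    """Copy ``tree`` without loss-stub leaves, suppressing unary nodes."""

    def rec(node: TreeNode) -> Optional[TreeNode]:
        if node.is_leaf():
            if node.event == "loss-stub":
                return None
            clone = TreeNode(node.name, node.support, node.length)
            clone.species = node.species
            return clone
        kids = [k for k in (rec(c) for c in node.children) if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            child = kids[0]
            if node.length is not None or child.length is not None:
                child.length = (node.length or 0.0) + (child.length or 0.0)
            if child.support is None:
                child.support = node.support
            return child
        clone = TreeNode(node.name, node.support, node.length)
        clone.species = node.species
        for k in kids:
            clone.add_child(k)
        return clone

    return rec(tree)


def _leaf_images(tree: TreeNode, leaf_map: dict[str, str], index: SpeciesIndex):
    images: dict[str, object] = {}
    for leaf in tree.iter_leaves():
        if leaf.event == "loss-stub":
            images[leaf.name] = leaf.species
        else:
            images[leaf.name] = leaf_map[leaf.name]
    return images


def _seed_metric_space(tree: TreeNode, dmatrix: Optional[DistanceMatrix]):
    """One point per gene leaf, distances from the input matrix."""
    ms = MetricSpace()
    point_of: dict[TreeNode, int] = {}
    if dmatrix is None:
        return ms, point_of
    leaves = list(tree.iter_leaves())
    missing = [l.name for l in leaves if l.name not in dmatrix._index]
    if missing:
        raise ValueError(f"distance matrix lacks gene leaves: {missing}")
    idx_label: dict[int, str] = {}
    for leaf in leaves:
        row = {i: dmatrix.get(leaf.name, lab) for i, lab in idx_label.items()}
        point = ms.add_point(leaf, None, row)
        idx_label[point.idx] = leaf.name
        point_of[leaf] = point.idx
    return ms, point_of


def _child_point(
    child: TreeNode,
    image: TreeNode,
    ms: MetricSpace,
    point_of: dict[TreeNode, int],
) -> int:
    """The metric-space point standing for a polytomy child."""
    if child in point_of:
        idx = point_of[child]
        ms.points[idx].species = image
        return idx
    members = [point_of[n] for n in child.iter_preorder() if n in point_of]
    if not members:
        raise ValueError(
            "polytomy child has no distance information; supply a distance matrix"
        )
    point = ms.collapse(members, child, image)
    for n in [n for n, i in point_of.items() if i not in ms.points]:
        del point_of[n]
    point_of[child] = point.idx
    return point.idx


def _resolve_candidate(
    tree: TreeNode,
    ms: MetricSpace,
    point_of: dict[TreeNode, int],
    leaf_map: dict[str, str],
    index: SpeciesIndex,
    costs: CostScheme,
    slimit: Optional[int],
    plimit: Optional[int],
    stats: list[Resolution],
    outputs: list[tuple[TreeNode, list[Resolution]]],
    max_outputs: int,
) -> None:
    """Depth-first resolution of every polytomy, branching over optimal
    count vectors (truncated by slimit/plimit)."""
    if len(outputs) >= max_outputs:
        return
    polytomies = extract_polytomies(tree)
    if not polytomies:
        outputs.append((tree, list(stats)))
        return
    poly = polytomies[0]  # bottom-up order: no polytomy below this one
    rec = lca_map(tree, index, _leaf_images(tree, leaf_map, index))
    images = [rec.mapping[c] for c in poly.children]
    species_root = images[0]
    for img in images[1:]:
        species_root = index.lca(species_root, img)
    pools: dict[TreeNode, list[int]] = {}
    mult: dict[TreeNode, int] = {}
    for child, image in zip(list(poly.children), images):
        idx = _child_point(child, image, ms, point_of)
        pools.setdefault(image, []).append(idx)
        mult[image] = mult.get(image, 0) + 1
    table = build_table(species_root, mult, costs)
    vectors = backtrack_count_vectors(table, limit=slimit)
    if plimit is not None:
        vectors = vectors[:plimit]
    for i, vector in enumerate(vectors):
        if i < len(vectors) - 1:
            # branch on a private copy of the evolving state
            btree, node_map = tree.copy_with_map()
            bms = ms.copy(node_map)
            bpoint_of = {node_map[n]: idx for n, idx in point_of.items()}
            bpools = {s: list(ids) for s, ids in pools.items()}
            bpoly_node = node_map[poly.node]
        else:
            btree, bms, bpoint_of, bpools, bpoly_node = tree, ms, point_of, pools, poly.node
        resolution = njresolve.resolve_polytomy(species_root, vector, bms, bpools)
        new_root = resolution.tree
        new_root.support = bpoly_node.support
        new_root.length = bpoly_node.length
        parent = bpoly_node.parent
        if parent is None:
            btree = new_root
        else:
            pos = parent.children.index(bpoly_node)
            parent.children[pos] = new_root
            new_root.parent = parent
        for n in [n for n, idx in bpoint_of.items() if idx not in bms.points]:
            del bpoint_of[n]
        bpoint_of[new_root] = resolution.root.idx
        _resolve_candidate(
            btree, bms, bpoint_of, leaf_map, index, costs,
            slimit, plimit, stats + [resolution], outputs, max_outputs,
        )


def rank_outputs(corrections: list[Correction]) -> list[Correction]:
    """Stable sort by cost; equal costs keep generation order."""
    return sorted(corrections, key=lambda c: (c.cost, c.order))


def correct_tree(
    gene_tree: TreeNode,
    species_tree: TreeNode,
    dmatrix: Optional[DistanceMatrix],
    leaf_map: dict[str, str],
    threshold: float = 0.95,
    costs: CostScheme = CostScheme(),
    root_mode: str = "none",
    slimit: Optional[int] = 1,
    plimit: Optional[int] = 1,
    firstbest: bool = False,
    keep_losses: bool = False,
    missing_support: float = 1.0,
    max_outputs: int = 64,
) -> list[Correction]:
    """Correct ``gene_tree``: contract, root, resolve, rank.

    Returns corrected rooted binary trees sorted by weighted
    duplication+loss cost (then by deterministic generation order).  With
    ``root_mode="best"`` only minimal-cost rootings survive;
    ``"all"`` keeps one block of outputs per rooting; ``"none"`` keeps the
    input root.  ``firstbest`` truncates to the single best output.
    """
    if root_mode not in ("none", "best", "all"):
        raise ValueError(f"root_mode must be none/best/all, got {root_mode!r}")
    if not gene_tree.leaf_names():
        raise ValueError("empty gene tree")
    index = SpeciesIndex(species_tree)
    for leaf in gene_tree.iter_leaves():
        if leaf.name not in leaf_map:
            raise ValueError(f"gene leaf {leaf.name!r} missing from the species map")
        if leaf_map[leaf.name] not in index.by_label:
            raise ValueError(
                f"gene leaf {leaf.name!r} maps to unknown species {leaf_map[leaf.name]!r}"
            )
    contracted = contract_low_support(gene_tree, threshold, missing_support)
    n_leaves = sum(1 for _ in contracted.iter_leaves())
    if root_mode == "none" or n_leaves < 3:
        candidates = [contracted]
    else:
        candidates = enumerate_rootings(contracted)

    corrections: list[Correction] = []
    order = 0
    for rooting, candidate in enumerate(candidates):
        ms, point_of = _seed_metric_space(candidate, dmatrix)
        outputs: list[tuple[TreeNode, list[Resolution]]] = []
        _resolve_candidate(
            candidate, ms, point_of, leaf_map, index, costs,
            slimit, plimit, [], outputs, max_outputs,
        )
        for working, stats in outputs:
            stripped = strip_loss_stubs(working)
            rec = reconcile.reconcile(stripped, index, leaf_map)
            corrections.append(
                Correction(
                    tree=stripped,
                    cost=rec.cost(costs),
                    reconciliation=rec,
                    rooting=rooting,
                    resolutions=stats,
                    working_tree=working if keep_losses else None,
                    order=order,
                )
            )
            order += 1
    ranked = rank_outputs(corrections)
    if root_mode == "best" and ranked:
        best_cost = ranked[0].cost
        best_rootings = {c.rooting for c in ranked if c.cost <= best_cost + 1e-9}
        keep_rooting = min(best_rootings)
        ranked = [c for c in ranked if c.rooting == keep_rooting]
    if firstbest and ranked:
        ranked = ranked[:1]
    return ranked


# ---------------------------------------------------------------------------
# CLI
# ---------------------------------------------------------------------------

@click.command(name="polynj")
@click.option("-s", "--species", "species_file", required=True,
              type=click.Path(exists=True), help="Species tree (rooted binary Newick).")
@click.option("-g", "--gene", "gene_file", required=True,
              type=click.Path(exists=True), help="Gene tree with branch supports (Newick).")
@click.option("-d", "--dist", "dist_file", type=click.Path(exists=True),
              help="Square PHYLIP distance matrix over the gene leaves.")
@click.option("-o", "--output", "output_file", type=click.Path(),
              help="Output Newick file (one corrected tree per line).")
@click.option("-t", "--seuil", "threshold", type=float, default=0.95, show_default=True,
              help="Support threshold: branches with support < threshold are contracted.")
@click.option("-r", "--root", "root_mode", type=click.Choice(["best", "all", "none"]),
              default="none", show_default=True,
              help="Root search: try every edge and keep the best, keep all, or keep the input root.")
@click.option("-c", "--criterion", type=click.Choice(["nj"]), default="nj",
              show_default=True, help="Pair-selection criterion (reserved for future criteria).")
@click.option("--slimit", type=int, default=1, show_default=True,
              help="Maximum count vectors per polytomy (0 = unlimited).")
@click.option("--plimit", type=int, default=1, show_default=True,
              help="Maximum resolutions retained per polytomy (0 = unlimited).")
@click.option("--firstbest", is_flag=True, help="Output only the first optimal tree.")
@click.option("--cost", "cost_pair", type=float, nargs=2, default=(1.0, 1.0),
              show_default=True, metavar="DUP LOSS",
              help="Duplication and loss costs.")
@click.option("-n", "no_op", is_flag=True,
              help="Accepted for command-line compatibility; no effect (semantics "
                   "of the original flag are undocumented).")
@click.option("--seed", type=int, default=0, show_default=True,
              help="Random seed (the pipeline itself is deterministic).")
@click.option("--keep-losses", is_flag=True, help="Keep loss stubs in the output trees.")
@click.option("--map", "map_file", type=click.Path(exists=True),
              help="Two-column gene-to-species table (overrides the naming rule).")
@click.option("--pattern", type=click.Choice(["suffix", "strip-digits"]), default="suffix",
              show_default=True, help="Leaf-name rule binding genes to species.")
@click.option("--report", "report_file", type=click.Path(),
              help="Write a TSV cost report (default: OUTPUT.report.tsv).")
def main(species_file, gene_file, dist_file, output_file, threshold, root_mode,
         criterion, slimit, plimit, firstbest, cost_pair, no_op, seed,
         keep_losses, map_file, pattern, report_file):
    """Correct a gene tree against a species tree.

    Contracts weakly supported branches, resolves the resulting polytomies
    with minimal weighted duplication+loss cost, and chooses among optimal
    resolutions with a Neighbor-Joining criterion on the distance matrix.
    """
    try:
        with open(species_file) as fh:
            species_tree = treeio.parse_newick(fh.read(), kind="species")
        with open(gene_file) as fh:
            gene_tree = treeio.parse_newick(fh.read(), kind="gene")
        dmatrix = None
        if dist_file:
            with open(dist_file) as fh:
                dmatrix = treeio.read_distance_matrix(fh.read())
        table = None
        if map_file:
            with open(map_file) as fh:
                table = treeio.read_mapping_table(fh.read())
        leaf_map = treeio.bind_species(gene_tree, species_tree, rule=pattern, table=table)
        costs = CostScheme(dup=cost_pair[0], loss=cost_pair[1])
        results = correct_tree(
            gene_tree, species_tree, dmatrix, leaf_map,
            threshold=threshold, costs=costs, root_mode=root_mode,
            slimit=None if slimit == 0 else slimit,
            plimit=None if plimit == 0 else plimit,
            firstbest=firstbest, keep_losses=keep_losses,
        )
    except (ValueError, treeio.TreeError, njresolve.ResolutionError,
            polytomysolver.SolverError) as exc:
        raise click.ClickException(str(exc)) from exc

    newick_lines = []
    for corr in results:
        out_tree = corr.working_tree if (keep_losses and corr.working_tree) else corr.tree
        newick_lines.append(treeio.write_newick(out_tree))
    text = "\n".join(newick_lines) + "\n"
    if output_file:
        with open(output_file, "w") as fh:
            fh.write(text)
    else:
        click.echo(text, nl=False)

    report_lines = ["rank\trooting\tcost\tduplications\tlosses"]
    for rank, corr in enumerate(results, 1):
        rec = corr.reconciliation
        report_lines.append(
            f"{rank}\t{corr.rooting}\t{corr.cost:.6g}\t{rec.dup_count()}\t{rec.loss_count()}"
        )
    report_text = "\n".join(report_lines) + "\n"
    if report_file is None and output_file:
        report_file = output_file + ".report.tsv"
    if report_file:
        with open(report_file, "w") as fh:
            fh.write(report_text)

    click.echo(
        f"corrected {len(results)} tree(s); best cost "
        f"{results[0].cost:.6g}" if results else "no output trees",
        err=True,
    )


if __name__ == "__main__":  # pragma: no cover
    main(sys.argv[1:])
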