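"""Trees, distance matrices and gene-to-species binding.

The central data structure is :class:`TreeNode`, a minimal mutable rooted
tree used for both gene trees and species trees.  Newick parsing is
delegated to dendropy; numeric internal-node labels are interpreted as
branch supports on gene trees (values in ``(1, 100]`` are read as
percentages and divided by 100, covering both aLRT and bootstrap
conventions).  Distance matrices use the square PHYLIP dialect with
relaxed, whitespace-delimited labels.
"""

from __future__ import annotations

import math
import re
from typing import Callable, Iterable, Iterator, Optional

import dendropy
import numpy as np

INF = math.inf

__all__ = [
    "INF",
    "TreeNode",
    "TreeError",
    "DistanceMatrix",
    "parse_newick",
    "write_newick",
    "read_distance_matrix",
    "write_distance_matrix",
    "bind_species",
    "read_mapping_table",
]


class TreeError(ValueError):
    """Raised for malformed trees or violated tree contracts."""


class TreeNode:
    """A node of a rooted (gene or species) tree.

    Attributes
    ----------
    name : str or None
        Leaf label, or an internal node name.
    support : float or None
        Branch support of the edge above this node, in [0, 1].
    length : float or None
        Branch length of the edge above this node.
    species : TreeNode or None
        For gene-tree nodes: the species-tree node this node maps to
        (filled in by reconciliation).
    event : str or None
        Event annotation: ``"speciation"``, ``"duplication"`` or
        ``"loss-stub"``.
    """

    __slots__ = ("name", "parent", "children", "support", "length", "species", "event")

    def __init__(self, name=None, support=None, length=None):
        self.name = name
        self.parent: Optional[TreeNode] = None
        self.children: list[TreeNode] = []
        self.support: Optional[float] = support
        self.length: Optional[float] = length
        self.species: Optional[TreeNode] = None
        self.event: Optional[str] = None

    # -- structure ---------------------------------------------------------

    def add_child(self, node: "TreeNode") -> "TreeNode":
        node.parent = self
        self.children.append(node)
        return node

    def remove_child(self, node: "TreeNode") -> None:
        self.children.remove(node)
        node.parent = None

    def is_leaf(self) -> bool:
        return not self.children

    def is_root(self) -> bool:
        return self.parent is None

    def is_binary(self) -> bool:
        return all(len(n.children) == 2 for n in self.iter_postorder() if n.children)

    # -- traversal ---------------------------------------------------------

    def iter_postorder(self) -> Iterator["TreeNode"]:
        stack, out = [self], []
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return reversed(out)

    def iter_preorder(self) -> Iterator["TreeNode"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def iter_leaves(self) -> Iterator["TreeNode"]:
        for node in self.iter_preorder():
            if node.is_leaf():
                yield node

    def leaf_names(self) -> list[str]:
        return [l.name for l in self.iter_leaves()]

    def leaf_set(self) -> frozenset:
        return frozenset(self.leaf_names())

    # -- copying -----------------------------------------------------------

    def copy(self, _map: Optional[dict] = None) -> "TreeNode":
        """Deep copy of the subtree; ``_map`` (if given) collects old->new."""
        clone = TreeNode(self.name, self.support, self.length)
        clone.species = self.species
        clone.event = self.event
        if _map is not None:
            _map[self] = clone
        for child in self.children:
            clone.add_child(child.copy(_map))
        return clone

    def copy_with_map(self) -> tuple["TreeNode", dict]:
        mapping: dict[TreeNode, TreeNode] = {}
        return self.copy(mapping), mapping

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"<TreeNode {self.name or '*'} nchildren={len(self.children)}>"

    def __str__(self) -> str:
        return write_newick(self)


# ---------------------------------------------------------------------------
# Newick I/O
# ---------------------------------------------------------------------------

def _interpret_support(label: Optional[str]) -> tuple[Optional[float], Optional[str]]:
    """Split an internal-node label into (support, name).

    A label parsing as a number in [0, 1] is a support; in (1, 100] it is a
    percentage support divided by 100; anything else is kept as a name.
    """
    if label is None or label == "":
        return None, None
    try:
        value = float(label)
    except ValueError:
        return None, label
    if 0.0 <= value <= 1.0:
        return value, None
    if 1.0 < value <= 100.0:
        return value / 100.0, None
    return None, label


def parse_newick(text: str, kind: str = "gene") -> TreeNode:
    """Parse a Newick string into a :class:`TreeNode`.

    Parameters
    ----------
    text : str
        Newick source.
    kind : {"gene", "species"}
        For gene trees, numeric internal labels become branch supports.
        Species trees must be rooted and binary; their internal labels are
        kept as node names.
    """
    if kind not in ("gene", "species"):
        raise ValueError(f"kind must be 'gene' or 'species', got {kind!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:  # dendropy raises schema-specific error types
        raise TreeError(f"newick parse error: {exc}") from exc

    def convert(dnode) -> TreeNode:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label
        node = TreeNode()
        node.length = dnode.edge.length
        if dnode.child_nodes():
            if kind == "gene":
                node.support, node.name = _interpret_support(label)
            else:
                node.name = label or None
            for dchild in dnode.child_nodes():
                node.add_child(convert(dchild))
        else:
            node.name = label
        return node

    root = convert(dtree.seed_node)

    leaves = list(root.iter_leaves())
    names = [l.name for l in leaves]
    if any(n is None or n == "" for n in names):
        raise TreeError("every leaf must carry a non-empty label")
    seen = set()
    for n in names:
        if n in seen:
            raise TreeError(f"duplicate leaf label: {n!r}")
        seen.add(n)

    if kind == "species":
        for node in root.iter_postorder():
            if node.children and len(node.children) != 2:
                raise TreeError(
                    "species tree must be rooted and binary; node with "
                    f"{len(node.children)} children found"
                )
    return root


_SAFE_LABEL = re.compile(r"^[\w.+\-|/]+$")


def _quote(label: str) -> str:
    if _SAFE_LABEL.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _format_num(x: float) -> str:
    return format(x, ".12g")


def write_newick(tree: TreeNode, with_supports: bool = True) -> str:
    """Serialize a tree back to Newick (supports as internal labels)."""

    def fmt(node: TreeNode) -> str:
        if node.is_leaf():
            s = _quote(node.name)
        else:
            s = "(" + ",".join(fmt(c) for c in node.children) + ")"
            if node.name is not None:
                s += _quote(node.name)
            elif with_supports and node.support is not None:
                s += _format_num(node.support)
        if node.length is not None:
            s += ":" + _format_num(node.length)
        return s

    return fmt(tree) + ";"


# ---------------------------------------------------------------------------
# Distance matrices
# ---------------------------------------------------------------------------

class DistanceMatrix:
    """A symmetric nonnegative matrix over an ordered list of labels.

    Entries may be ``inf`` (used downstream for artificial loss nodes).
    """

    def __init__(self, labels: Iterable[str], matrix):
        self.labels = list(labels)
        self.matrix = np.asarray(matrix, dtype=float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.matrix.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise ValueError("duplicate labels in distance matrix")
        finite = self.matrix[np.isfinite(self.matrix)]
        if (finite < 0).any():
            raise ValueError("negative entries in distance matrix")
        if not np.allclose(np.diag(self.matrix), 0.0):
            raise ValueError("nonzero diagonal in distance matrix")
        if not np.array_equal(self.matrix, self.matrix.T):
            raise ValueError("distance matrix not symmetric")
        self._index = {lab: i for i, lab in enumerate(self.labels)}

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self._index[label]

    def get(self, a: str, b: str) -> float:
        return float(self.matrix[self._index[a], self._index[b]])

    def row(self, label: str) -> dict[str, float]:
        i = self._index[label]
        return {lab: float(self.matrix[i, j]) for j, lab in enumerate(self.labels)}


def read_distance_matrix(text: str, tol: float = 1e-6) -> DistanceMatrix:
    """Read a square PHYLIP distance matrix (relaxed labels).

    Asymmetries up to ``tol`` are averaged away; larger ones are errors.
    """
    tokens = text.split()
    if not tokens:
        raise ValueError("empty distance matrix input")
    try:
        n = int(tokens[0])
    except ValueError as exc:
        raise ValueError(f"first token must be the taxon count, got {tokens[0]!r}") from exc
    expected = 1 + n * (n + 1)
    if len(tokens) != expected:
        raise ValueError(
            f"token count mismatch: expected {expected} tokens for {n} taxa, "
            f"got {len(tokens)}"
        )
    labels = []
    matrix = np.zeros((n, n))
    pos = 1
    for i in range(n):
        labels.append(tokens[pos])
        pos += 1
        for j in range(n):
            try:
                matrix[i, j] = float(tokens[pos])
            except ValueError as exc:
                raise ValueError(f"bad matrix entry {tokens[pos]!r}") from exc
            pos += 1
    asym = np.abs(matrix - matrix.T)
    if asym.max() > tol:
        i, j = np.unravel_index(np.argmax(asym), asym.shape)
        raise ValueError(
            f"matrix asymmetry beyond tolerance between {labels[i]!r} and "
            f"{labels[j]!r}: {matrix[i, j]} vs {matrix[j, i]}"
        )
    matrix = (matrix + matrix.T) / 2.0
    np.fill_diagonal(matrix, 0.0)
    return DistanceMatrix(labels, matrix)


def write_distance_matrix(dm: DistanceMatrix) -> str:
    lines = [f" {len(dm)}"]
    for i, lab in enumerate(dm.labels):
        row = " ".join(_format_num(x) for x in dm.matrix[i])
        lines.append(f"{lab} {row}")
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# Gene -> species binding
# ---------------------------------------------------------------------------

_TRAILING_DIGITS = re.compile(r"\d+$")


def _rule_suffix(name: str) -> str:
    """Species = suffix after the last underscore (``g1_human`` -> ``human``)."""
    if "_" not in name:
        return name
    return name.rsplit("_", 1)[1]


def _rule_strip_digits(name: str) -> str:
    """Species = leaf id with trailing digits removed (``b1`` -> ``b``)."""
    return _TRAILING_DIGITS.sub("", name)


_RULES: dict[str, Callable[[str], str]] = {
    "suffix": _rule_suffix,
    "strip-digits": _rule_strip_digits,
}


def read_mapping_table(text: str) -> dict[str, str]:
    """Parse a two-column (gene TAB species) mapping table."""
    table = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 2:
            raise ValueError(f"mapping table line {lineno}: expected 2 columns")
        table[parts[0]] = parts[1]
    return table


def bind_species(
    gene_tree: TreeNode,
    species_tree: TreeNode,
    rule: str | Callable[[str], str] = "suffix",
    table: Optional[dict[str, str]] = None,
) -> dict[str, str]:
    """Bind every gene-tree leaf to a species-tree leaf label.

    ``rule`` is a naming convention (``"suffix"``/``"strip-digits"`` or a
    callable); an explicit ``table`` entry always wins over the rule.
    """
    if callable(rule):
        func = rule
    else:
        try:
            func = _RULES[rule]
        except KeyError:
            raise ValueError(f"unknown binding rule {rule!r}") from None
    species_leaves = set(species_tree.leaf_names())
    mapping: dict[str, str] = {}
    for leaf in gene_tree.iter_leaves():
        if table is not None and leaf.name in table:
            image = table[leaf.name]
        else:
            image = func(leaf.name)
        if image not in species_leaves:
            raise ValueError(
                f"gene {leaf.name!r} maps to {image!r}, which is not a species-tree leaf"
            )
        mapping[leaf.name] = image
    return mapping
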