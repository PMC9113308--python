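"""Rooted phylogenetic trees with planted root edges and duplication-points.

Trees are binary and *planted*: an extra root edge hangs above the root
vertex, which matters both for the gene duplication-loss process (the
birth-death process starts on that edge) and for the coalescent (the final
coalescences happen above the root).  Edge lengths are in coalescent units;
leaves sit at time 0 and time increases rootward.

A *duplication-point* marks the start of a novel locus: it sits on the edge
above a node at an absolute height, and all gene lineages descending from
that node must coalesce to a single lineage strictly below it.  We store at
most one duplication-point per edge (the lowest one: it implies any higher
ones on the same edge).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from enum import IntEnum
from typing import Iterator

import dendropy

__all__ = [
    "Node",
    "PhyloTree",
    "LocusTree",
    "GeneTree",
    "DuplicationPoint",
    "QuartetType",
    "NewickError",
    "StructureError",
    "parse_newick",
    "write_newick",
    "restrict",
    "quartet_topology",
    "species_from_label",
]


class NewickError(ValueError):
    """Malformed Newick input."""


class StructureError(ValueError):
    """Tree violates a structural requirement (e.g. non-binary node)."""


class Node:
    """A tree node.  ``length`` is the length of the edge *above* the node.

    For the root, ``length`` is the planted root-edge length.  ``dup_time``
    is the absolute height of the lowest duplication-point on the edge above
    this node, or None.
    """

    __slots__ = ("label", "length", "children", "dup_time")

    def __init__(self, label=None, length=0.0, children=None, dup_time=None):
        self.label = label
        self.length = length
        self.children: list[Node] = children if children is not None else []
        self.dup_time = dup_time

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Node({self.label!r}, len={self.length}, dup={self.dup_time})"


@dataclass(frozen=True)
class DuplicationPoint:
    """Duplication-point on the edge above ``node_label``/node, at absolute
    height ``time`` (leaves at 0)."""

    node: Node
    time: float


class PhyloTree:
    """Planted rooted binary tree with edge lengths in coalescent units."""

    def __init__(self, root: Node, root_open: bool = False):
        self.root = root
        #: if True the planted edge is open-ended above (unbounded stem)
        self.root_open = root_open

    # -- basic traversals -------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            nd = stack.pop()
            yield nd
            stack.extend(reversed(nd.children))

    def postorder(self) -> Iterator[Node]:
        out = []
        stack = [self.root]
        while stack:
            nd = stack.pop()
            out.append(nd)
            stack.extend(nd.children)
        return iter(reversed(out))

    def leaves(self) -> list[Node]:
        return [nd for nd in self.preorder() if nd.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [nd.label for nd in self.leaves()]

    @property
    def root_edge_length(self) -> float:
        return self.root.length

    def heights(self) -> dict[Node, float]:
        """Node heights with leaves at 0, increasing rootward.

        Raises StructureError when the tree is not ultrametric (leaves not
        aligned in time), which all trees in this package are.
        """
        h: dict[Node, float] = {}
        for nd in self.postorder():
            if nd.is_leaf:
                h[nd] = 0.0
            else:
                cand = [h[c] + c.length for c in nd.children]
                if max(cand) - min(cand) > 1e-6 * max(1.0, max(cand)):
                    raise StructureError(
                        f"tree is not ultrametric at node {nd!r}: {cand}"
                    )
                h[nd] = sum(cand) / len(cand)
        return h

    def dup_points(self) -> list[DuplicationPoint]:
        return [
            DuplicationPoint(nd, nd.dup_time)
            for nd in self.preorder()
            if nd.dup_time is not None
        ]

    def copy(self) -> "PhyloTree":
        def rec(nd: Node) -> Node:
            return Node(nd.label, nd.length, [rec(c) for c in nd.children], nd.dup_time)

        return PhyloTree(rec(self.root), self.root_open)

    def validate(self) -> None:
        """Check binarity, positive internal lengths and unique leaf labels."""
        seen = set()
        for nd in self.preorder():
            if nd.is_leaf:
                if nd.label is None or nd.label in seen:
                    raise StructureError(f"duplicate or missing leaf label {nd.label!r}")
                seen.add(nd.label)
            elif len(nd.children) != 2:
                raise StructureError(
                    f"non-binary node with {len(nd.children)} children"
                )
            if nd is not self.root and nd.length <= 0:
                raise StructureError("non-positive edge length")
        if self.root.length < 0:
            raise StructureError("negative root edge length")

    def __str__(self):
        return write_newick(self)


@dataclass
class LocusTree:
    """A duplication/loss history restricted to surviving loci.

    ``species_of`` maps each leaf label to its species.  Duplication-points
    live on the underlying tree's nodes (``Node.dup_time``).
    """

    tree: PhyloTree
    species_of: dict[str, str]

    def leaf_labels(self):
        return self.tree.leaf_labels()


@dataclass
class GeneTree:
    """A gene-family tree; leaves map to species (many-to-one) and to the
    extant locus-tree leaf they were sampled from."""

    tree: PhyloTree
    species_of: dict[str, str]
    locus_of: dict[str, str] = field(default_factory=dict)


class QuartetType(IntEnum):
    """The three unrooted topologies on an ordered leaf tuple (a, b, c, d)."""

    AB_CD = 0
    AC_BD = 1
    AD_BC = 2

    def pretty(self, four=("a", "b", "c", "d")) -> str:
        a, b, c, d = four
        return {
            QuartetType.AB_CD: f"{a}{b}|{c}{d}",
            QuartetType.AC_BD: f"{a}{c}|{b}{d}",
            QuartetType.AD_BC: f"{a}{d}|{b}{c}",
        }[self]


def species_from_label(label: str, sep: str = "_") -> str:
    """Extract the species name from a gene/locus leaf label.

    Labels follow the ``species_copyIndex`` convention (e.g. ``A_2`` is the
    second sampled copy in species A); a label without the separator is its
    own species.
    """
    head, _, tail = label.rpartition(sep)
    return head if head else label


# ---------------------------------------------------------------------------
# Newick / NHX I/O (parsing through dendropy)
# ---------------------------------------------------------------------------

_DUP_KEY = "DUPTIME"


def parse_newick(text: str, dialect: str = "plain", rooted: bool = True) -> PhyloTree:
    """Parse a Newick string into a PhyloTree.

    dialect 'plain' ignores comments; 'nhx-dup' reads duplication-points
    from ``[&&NHX:DUPTIME=<height>]`` edge annotations (absolute heights,
    leaves at 0).  With ``rooted=False`` a trifurcating outermost node is
    accepted and re-rooted arbitrarily on its first child edge, which leaves
    the unrooted topology unchanged.
    """
    if dialect not in ("plain", "nhx-dup"):
        raise ValueError(f"unknown dialect {dialect!r}")
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
            rooting="force-rooted",
            extract_comment_metadata=(dialect == "nhx-dup"),
        )
    except Exception as exc:  # dendropy raises several error types
        raise NewickError(f"malformed Newick: {exc}") from exc

    def convert(dnode) -> Node:
        nd = Node(
            label=dnode.taxon.label if dnode.taxon else None,
            length=float(dnode.edge.length) if dnode.edge.length is not None else 0.0,
            children=[convert(c) for c in dnode.child_nodes()],
        )
        if dialect == "nhx-dup":
            val = dnode.annotations.get_value(_DUP_KEY, None)
            if val is not None:
                nd.dup_time = float(val)
        return nd

    root = convert(dtree.seed_node)
    if len(root.children) == 3:
        if rooted:
            raise StructureError("non-binary root; pass rooted=False for unrooted input")
        # re-root on the first child edge: ((c1)root') stays binary
        c1 = root.children[0]
        rest = Node(label=None, length=c1.length, children=root.children[1:])
        root = Node(label=None, length=0.0, children=[c1, rest])
    tree = PhyloTree(root)
    tree.validate()
    return tree


def _fmt(x: float) -> str:
    return format(float(x), ".10g")


def write_newick(tree: PhyloTree, dialect: str = "plain") -> str:
    """Canonical Newick writer: children ordered by smallest descendant
    label, 10 significant digits, optional NHX duplication annotations.

    ``parse_newick(write_newick(t), ...)`` reproduces ``t`` exactly up to
    the printed precision, and re-writing is bit-stable.
    """
    out = io.StringIO()

    def min_label(nd: Node) -> str:
        if nd.is_leaf:
            return nd.label
        return min(min_label(c) for c in nd.children)

    def rec(nd: Node, top: bool) -> None:
        if nd.is_leaf:
            out.write(nd.label)
        else:
            out.write("(")
            for i, c in enumerate(sorted(nd.children, key=min_label)):
                if i:
                    out.write(",")
                rec(c, False)
            out.write(")")
        out.write(":" + _fmt(nd.length))
        if dialect == "nhx-dup" and nd.dup_time is not None:
            out.write(f"[&&NHX:{_DUP_KEY}={_fmt(nd.dup_time)}]")

    rec(tree.root, True)
    out.write(";")
    return out.getvalue()


# ---------------------------------------------------------------------------
# Restriction and quartet extraction
# ---------------------------------------------------------------------------


def _restrict_node(nd: Node, keep: frozenset) -> Node | None:
    if nd.is_leaf:
        if nd.label not in keep:
            return None
        return Node(nd.label, nd.length, [], nd.dup_time)
    kept = [r for c in nd.children if (r := _restrict_node(c, keep)) is not None]
    if not kept:
        return None
    if len(kept) == 1:
        # suppress the degree-2 node: merge the two edge segments; of the
        # duplication-points landing on the merged edge only the lowest
        # matters (it forces coalescence below the higher ones too)
        child = kept[0]
        child.length += nd.length
        if nd.dup_time is not None:
            child.dup_time = (
                nd.dup_time if child.dup_time is None else min(child.dup_time, nd.dup_time)
            )
        return child
    return Node(nd.label, nd.length, kept, nd.dup_time)


def restrict(tree: PhyloTree | LocusTree, leaves) -> PhyloTree | LocusTree:
    """Restrict to a leaf subset, preserving leaf-to-root path lengths.

    Suppressed degree-2 nodes have their edge lengths summed; duplication-
    points migrate to the merged edge keeping only the lowest per edge.
    Accepts and returns a LocusTree transparently.
    """
    if isinstance(tree, LocusTree):
        sub = restrict(tree.tree, leaves)
        return LocusTree(sub, {l: tree.species_of[l] for l in sub.leaf_labels()})
    keep = frozenset(leaves)
    have = set(tree.leaf_labels())
    missing = keep - have
    if missing:
        raise KeyError(f"unknown leaf labels: {sorted(missing)}")
    if len(keep) < 2:
        raise ValueError("restriction needs at least 2 leaves")
    root = _restrict_node(tree.root, keep)
    new = PhyloTree(root, tree.root_open)
    return new


def quartet_topology(tree: PhyloTree | LocusTree | GeneTree, four) -> QuartetType:
    """Unrooted quartet displayed by the tree on four leaf labels.

    The displayed quartet pairs the cherry of the 4-leaf restriction
    against the remaining two leaves.
    """
    if isinstance(tree, (LocusTree, GeneTree)):
        tree = tree.tree
    a, b, c, d = four
    if len({a, b, c, d}) != 4:
        raise ValueError("quartet requires four distinct leaves")
    sub = tree if len(tree.root.children) and _n_leaves(tree.root) == 4 else None
    if sub is not None and set(sub.leaf_labels()) != {a, b, c, d}:
        sub = None
    if sub is None:
        sub = restrict(tree, (a, b, c, d))
    pair = _cherry_pair(sub.root)
    if a in pair:
        partner = next(iter(pair - {a}))
    else:
        partner = next(iter({b, c, d} - pair))
    if partner == b:
        return QuartetType.AB_CD
    if partner == c:
        return QuartetType.AC_BD
    return QuartetType.AD_BC


def _n_leaves(nd: Node) -> int:
    if nd.is_leaf:
        return 1
    return sum(_n_leaves(c) for c in nd.children)


def _cherry_pair(root: Node) -> set:
    """Leaf pair forming a cherry in a 4-leaf rooted binary tree."""
    stack = [root]
    while stack:
        nd = stack.pop()
        if not nd.is_leaf:
            if all(c.is_leaf for c in nd.children):
                return {c.label for c in nd.children}
            stack.extend(nd.children)
    raise StructureError("no cherry found; tree is not a binary 4-leaf tree")
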