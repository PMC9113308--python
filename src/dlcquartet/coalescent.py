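"""Exact coalescent probability kernels and closed-form quartet probabilities.

The central quantity is ``g(i, j, x)``: under the Kingman coalescent (rate 1
per lineage pair, time in coalescent units) the probability that *i*
lineages entering an edge have merged to exactly *j* lineages after time
*x*.  On top of it we build

* the bounded pair-coalescence law (coalescence conditioned to happen below
  a duplication-point),
* a lineage-count dynamic program giving the probability that all samples
  of a locus tree have fully coalesced by a given bound time, and
* the closed-form distribution of the three unrooted quartet topologies of
  a gene tree evolving inside a fixed 4-leaf locus tree, for every possible
  placement of duplication-points.

Quartet orientation convention: probabilities are always reported relative
to the quartet *displayed by the locus tree* (``p_match`` for the displayed
topology, ``p_alt`` for each of the two others; the two alternatives have
equal probability by symmetry).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache

from .trees import LocusTree, Node, PhyloTree, QuartetType, StructureError

__all__ = [
    "g",
    "p_pair_bounded",
    "p_all_coalesce_before",
    "CaseParams",
    "QuartetDistribution",
    "quartet_probs",
    "classify_locus_case",
    "locus_tree_from_case",
    "DUP_NONE",
    "DUP_ON_X",
    "DUP_ON_Y",
    "DUP_ON_ROOT_EDGE",
    "DUP_AT_ROOT_VERTEX",
]

_SUM_TOL = 1e-12


@lru_cache(maxsize=None)
def _g_coeffs(i: int, j: int) -> tuple[float, ...]:
    """Exact (rational) series coefficients of g_{i,j}; index k runs j..i."""
    coeffs = []
    for k in range(j, i + 1):
        c = Fraction((2 * k - 1) * (-1) ** (k - j),
                     math.factorial(j) * math.factorial(k - j) * (j + k - 1))
        for m in range(k):
            c *= Fraction((j + m) * (i - m), i + m)
        coeffs.append(float(c))
    return tuple(coeffs)


def g(i: int, j: int, x: float) -> float:
    """Probability that i lineages coalesce to exactly j within time x.

    Computed by Tavaré's spectral expansion of the lineage-count death
    chain; exact coefficients keep it stable for the small i (<= ~20) used
    here.
    """
    if not (1 <= j <= i):
        raise ValueError(f"need 1 <= j <= i, got i={i}, j={j}")
    if x < 0:
        raise ValueError("negative time")
    if x == 0:
        return 1.0 if i == j else 0.0
    coeffs = _g_coeffs(i, j)
    terms = [c * math.exp(-k * (k - 1) / 2.0 * x)
             for c, k in zip(coeffs, range(j, i + 1))]
    val = math.fsum(terms)
    return min(1.0, max(0.0, val))


def p_pair_bounded(x: float, p_prior: float) -> float:
    """P[pair coalesces within x | it coalesces before the bound].

    ``p_prior`` is the unconditioned probability that the pair coalesces
    before the duplication bound; with the bound at infinity (p_prior = 1)
    this reduces to the unbounded law 1 - e^-x.
    """
    if x < 0:
        raise ValueError("negative time")
    if not (0 < p_prior <= 1):
        raise ValueError("conditioning on an impossible (p_prior <= 0) event")
    raw = -math.expm1(-x)
    if raw > p_prior + 1e-9:
        raise ValueError("x exceeds the time to the bound (1-e^-x > p_prior)")
    return min(1.0, raw / p_prior)


def _lineage_dist_at_root(tree: PhyloTree) -> tuple[dict[int, float], float]:
    """Distribution of the number of surviving lineages at the root vertex,
    ignoring duplication constraints, plus the root height."""
    heights = tree.heights()

    def up(nd: Node) -> dict[int, float]:
        # distribution of lineage counts at the *top* of nd's edge
        if nd.is_leaf:
            at_node = {1: 1.0}
        else:
            at_node: dict[int, float] = {}
            dists = [up(c) for c in nd.children]
            acc = dists[0]
            for d in dists[1:]:
                nxt: dict[int, float] = {}
                for i1, p1 in acc.items():
                    for i2, p2 in d.items():
                        nxt[i1 + i2] = nxt.get(i1 + i2, 0.0) + p1 * p2
                acc = nxt
            at_node = acc
        if nd is tree.root:
            return at_node
        out: dict[int, float] = {}
        for i, p in at_node.items():
            for j in range(1, i + 1):
                gp = g(i, j, nd.length)
                if gp > 0:
                    out[j] = out.get(j, 0.0) + p * gp
        return out

    return up(tree.root), heights[tree.root]


def p_all_coalesce_before(tree: PhyloTree | LocusTree, bound_time: float) -> float:
    """Probability that all sampled lineages (one per leaf) coalesce to a
    single lineage before absolute time ``bound_time``, under the unbounded
    coalescent run along the tree.

    This is the lineage-count dynamic program: convolve counts with
    g(i, j, .) along each edge, sum counts at internal nodes, and finish
    with g(n, 1, bound - root height) on the stem.
    """
    if isinstance(tree, LocusTree):
        tree = tree.tree
    dist, h_root = _lineage_dist_at_root(tree)
    if bound_time < h_root - 1e-9:
        raise ValueError("bound lies below the tree root")
    t = max(0.0, bound_time - h_root)
    return math.fsum(p * g(i, 1, t) for i, p in dist.items())


# ---------------------------------------------------------------------------
# Closed-form quartet probabilities
# ---------------------------------------------------------------------------

DUP_NONE = "none"
DUP_ON_X = "dup_on_X"
DUP_ON_Y = "dup_on_Y"
DUP_ON_ROOT_EDGE = "dup_on_root_edge"
DUP_AT_ROOT_VERTEX = "dup_at_root_vertex"

BALANCED = "balanced"
CATERPILLAR = "caterpillar"


@dataclass
class CaseParams:
    """Geometry of a 4-leaf locus tree for the closed forms.

    ``x`` and ``y`` are the lengths of the internal edges X and Y.  For the
    balanced shape X and Y are the two cherry edges; for the caterpillar,
    X is the edge above the cherry and Y the edge above the three-leaf
    clade.  ``t`` is the time from the point where the bounded lineages
    enter the edge carrying the duplication-point up to that point: for
    root-edge duplications that is the quartet root vertex, for a
    caterpillar Y-edge duplication it is the bottom of Y.  ``z`` is the
    absolute height of the relevant duplication-point (informational).
    """

    shape: str
    x: float
    y: float = 0.0
    t: float | None = None
    z: float | None = None
    dup_case: str = DUP_NONE
    #: displayed quartet as a pair of label pairs, filled by classification
    display: tuple[tuple[str, str], tuple[str, str]] | None = None


@dataclass(frozen=True)
class QuartetDistribution:
    """Probabilities of (displayed, alternative 1, alternative 2) quartets
    in the gene tree; the two alternatives are exactly equal by symmetry."""

    p_match: float
    p_alt: float

    @property
    def p_alt1(self) -> float:
        return self.p_alt

    @property
    def p_alt2(self) -> float:
        return self.p_alt

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.p_match, self.p_alt, self.p_alt)


def _check_prob(p: float, what: str) -> float:
    if p < -_SUM_TOL or p > 1 + _SUM_TOL:
        raise ArithmeticError(f"{what} = {p} outside [0, 1]")
    return min(1.0, max(0.0, p))


def _denom_balanced_root(x: float, y: float, t: float) -> float:
    """P[all four coalesced within t of the quartet root] for a balanced
    quartet with cherry edges x and y (lineage-count DP)."""
    return math.fsum(
        g(2, j, x) * g(2, k, y) * g(j + k, 1, t)
        for j in (1, 2)
        for k in (1, 2)
    )


def _denom_caterpillar_y(x: float, t: float) -> float:
    """P[a, b, c coalesced within t of entering edge Y] (cherry edge x)."""
    return math.fsum(g(2, j, x) * g(j + 1, 1, t) for j in (1, 2))


def _denom_caterpillar_root(x: float, y: float, t: float) -> float:
    """P[all four coalesced within t of the quartet root] for a caterpillar
    with edges x (above the cherry) and y (above the 3-clade)."""
    total = 0.0
    for j in (1, 2):           # lineages leaving edge X
        px = g(2, j, x)
        for k in range(1, j + 2):   # lineages leaving edge Y (entered j+1)
            total += px * g(j + 1, k, y) * g(k + 1, 1, t)
    return total


def quartet_probs(params: CaseParams) -> QuartetDistribution:
    """Exact gene-tree quartet distribution for a classified 4-leaf locus
    tree (probabilities relative to the locus tree's displayed quartet)."""
    s, case = params.shape, params.dup_case
    x, y, t = params.x, params.y, params.t
    if s not in (BALANCED, CATERPILLAR):
        raise ValueError(f"unknown shape {s!r}")

    if case == DUP_AT_ROOT_VERTEX:
        if s == BALANCED:
            # the dup-point sits right below the root on a cherry edge,
            # forcing that cherry pair to coalesce there: certainty
            return QuartetDistribution(1.0, 0.0)
        # caterpillar: the dup-point tops edge Y, i.e. a Y-edge duplication
        # with the bound a full edge length above the entry point
        case, t = DUP_ON_Y, y

    if case == DUP_ON_X or (case == DUP_ON_Y and s == BALANCED):
        # a duplication-point on an internal edge below which only the
        # displayed cherry pair lives forces that pair to coalesce on the
        # edge: the gene tree displays the locus quartet with certainty
        return QuartetDistribution(1.0, 0.0)

    if case == DUP_NONE:
        s_len = x + y if s == BALANCED else x
        p_alt = _check_prob(math.exp(-s_len) / 3.0, "p_alt")
        return QuartetDistribution(_check_prob(1 - 2 * p_alt, "p_match"), p_alt)

    if t is None:
        raise ValueError(f"case {case!r} needs parameter t")
    if t < 0:
        raise ValueError("negative t")

    if s == BALANCED and case == DUP_ON_ROOT_EDGE:
        denom = _denom_balanced_root(x, y, t)
        if denom <= 0:
            raise ValueError("conditioning event has probability 0 (t too small)")
        p_alt = math.exp(-(x + y)) * g(4, 1, t) / (3.0 * denom)
    elif s == CATERPILLAR and case == DUP_ON_Y:
        denom = _denom_caterpillar_y(x, t)
        if denom <= 0:
            raise ValueError("conditioning event has probability 0 (t too small)")
        p_alt = math.exp(-x) * g(3, 1, t) / (3.0 * denom)
    elif s == CATERPILLAR and case == DUP_ON_ROOT_EDGE:
        denom = _denom_caterpillar_root(x, y, t)
        if denom <= 0:
            raise ValueError("conditioning event has probability 0 (t too small)")
        num = (
            g(3, 2, y) * g(3, 1, t)
            + g(3, 1, y) * g(2, 1, t)
            + g(3, 3, y) * g(4, 1, t)
        )
        p_alt = math.exp(-x) * num / (3.0 * denom)
    else:
        raise ValueError(f"unsupported combination shape={s!r}, dup_case={case!r}")

    p_alt = _check_prob(p_alt, "p_alt")
    p_match = _check_prob(1.0 - 2.0 * p_alt, "p_match")
    return QuartetDistribution(p_match, p_alt)


# ---------------------------------------------------------------------------
# Classification of concrete 4-leaf locus trees
# ---------------------------------------------------------------------------

_H_TOL = 1e-9


def classify_locus_case(L: LocusTree) -> CaseParams:
    """Map a 4-leaf locus tree (4 distinct species) onto the closed-form
    case that governs its gene-tree quartet distribution.

    Duplication-points on external (pendant) edges constrain a single
    lineage and are ignored.  A duplication-point on an internal edge
    dominates a root-edge one (it already forces the displayed quartet);
    for the caterpillar, an X-edge duplication dominates a Y-edge one.
    """
    tree = L.tree
    leaves = tree.leaves()
    if len(leaves) != 4:
        raise ValueError("classification requires exactly 4 leaves")
    species = [L.species_of[l.label] for l in leaves]
    if len(set(species)) != 4:
        raise ValueError("leaves must come from 4 distinct species")
    h = tree.heights()
    root = tree.root
    c1, c2 = root.children
    n1 = sum(1 for _ in _leaf_iter(c1))
    h_root = h[root]

    if n1 == 2 and sum(1 for _ in _leaf_iter(c2)) == 2:
        shape = BALANCED
        cherry_a, cherry_b = c1, c2
        # orient X on the duplication-carrying cherry edge when there is one
        if cherry_a.dup_time is None and cherry_b.dup_time is not None:
            cherry_a, cherry_b = cherry_b, cherry_a
        x = cherry_a.length
        y = cherry_b.length
        display = (
            tuple(sorted(l.label for l in _leaf_iter(cherry_a))),
            tuple(sorted(l.label for l in _leaf_iter(cherry_b))),
        )
        if cherry_a.dup_time is not None:
            at_root = abs(cherry_a.dup_time - h_root) <= _H_TOL * max(1.0, h_root)
            case = DUP_AT_ROOT_VERTEX if at_root else DUP_ON_X
            return CaseParams(shape, x, y, None, cherry_a.dup_time, case, display)
        if root.dup_time is not None:
            z = root.dup_time
            return CaseParams(shape, x, y, z - h_root, z, DUP_ON_ROOT_EDGE, display)
        return CaseParams(shape, x, y, None, None, DUP_NONE, display)

    # caterpillar: one root child is a leaf (d), the other has 3 leaves
    if n1 == 1:
        d_side, inner = c1, c2
    elif n1 == 3:
        d_side, inner = c2, c1
    else:
        raise StructureError("unexpected 4-leaf tree shape")
    if not d_side.is_leaf:
        raise StructureError("unexpected 4-leaf tree shape")
    # inner = ((p, q), r): cherry node + leaf r
    kid1, kid2 = inner.children
    cherry = kid1 if not kid1.is_leaf else kid2
    if cherry.is_leaf:
        raise StructureError("unexpected 4-leaf tree shape")
    shape = CATERPILLAR
    x = cherry.length
    y = inner.length
    h_mid = h[inner]            # bottom of edge Y
    display = (
        tuple(sorted(l.label for l in _leaf_iter(cherry))),
        tuple(sorted({l.label for l in leaves}
                     - {l.label for l in _leaf_iter(cherry)})),
    )
    if cherry.dup_time is not None:
        return CaseParams(shape, x, y, None, cherry.dup_time, DUP_ON_X, display)
    if inner.dup_time is not None:
        z = inner.dup_time
        return CaseParams(shape, x, y, z - h_mid, z, DUP_ON_Y, display)
    if root.dup_time is not None:
        z = root.dup_time
        return CaseParams(shape, x, y, z - h_root, z, DUP_ON_ROOT_EDGE, display)
    return CaseParams(shape, x, y, None, None, DUP_NONE, display)


def _leaf_iter(nd: Node):
    stack = [nd]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            yield n
        else:
            stack.extend(n.children)


def locus_tree_from_case(
    params: CaseParams, labels=("a", "b", "c", "d"), pendant: float = 1.0
) -> LocusTree:
    """Build a concrete 4-leaf locus tree realizing a closed-form case.

    Labels are placed so that the displayed quartet pairs the first two
    labels against the last two.  The inverse of classify_locus_case (up
    to the arbitrary X/Y orientation of the balanced shape).
    """
    a, b, c, d = labels
    x, y, t = params.x, params.y, params.t
    if params.shape == BALANCED:
        h_root = pendant + max(x, y)
        h1, h2 = h_root - x, h_root - y
        cab = Node(None, x, [Node(a, h1), Node(b, h1)])
        ccd = Node(None, y, [Node(c, h2), Node(d, h2)])
        root = Node(None, 0.0, [cab, ccd])
        if params.dup_case == DUP_ON_X:
            cab.dup_time = params.z if params.z is not None else h1 + x / 2.0
        elif params.dup_case == DUP_ON_Y:
            ccd.dup_time = params.z if params.z is not None else h2 + y / 2.0
        elif params.dup_case == DUP_AT_ROOT_VERTEX:
            cab.dup_time = h_root
        elif params.dup_case == DUP_ON_ROOT_EDGE:
            root.dup_time = h_root + t
            root.length = t + 1.0
    elif params.shape == CATERPILLAR:
        if params.dup_case == DUP_ON_Y and (y == 0.0 or y < t):
            y = t  # Y must reach the duplication-point; its length is immaterial
        h1 = pendant
        h2 = h1 + x
        h3 = h2 + y
        cab = Node(None, x, [Node(a, h1), Node(b, h1)])
        inner = Node(None, y, [cab, Node(c, h2)])
        root = Node(None, 0.0, [inner, Node(d, h3)])
        if params.dup_case == DUP_ON_X:
            cab.dup_time = params.z if params.z is not None else h1 + x / 2.0
        elif params.dup_case == DUP_ON_Y:
            inner.dup_time = h2 + t
        elif params.dup_case == DUP_ON_ROOT_EDGE:
            root.dup_time = h3 + t
            root.length = t + 1.0
        elif params.dup_case == DUP_AT_ROOT_VERTEX:
            inner.dup_time = h3
    else:
        raise ValueError(f"unknown shape {params.shape!r}")
    tree = PhyloTree(root, root_open=(root.dup_time is None))
    tree.validate()
    return LocusTree(tree, {lab: lab.upper() for lab in labels})
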