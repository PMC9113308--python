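"""The duplication-loss-coalescence (DLCoal) generative process.

Stage one runs a birth-death gene duplication/loss process top-down inside
the species tree, producing a *locus tree* whose nodes are speciations or
duplications; each duplication leaves a duplication-point on its daughter
(novel-locus) edge.  Stage two runs the *bounded* multispecies coalescent
bottom-up along the locus tree: one gene lineage per extant locus, pairwise
coalescence at rate 1 per pair within each edge, and all lineages below a
duplication-point forced to coalesce to a single lineage below it.

The bound is enforced by exact conditional sampling of the lineage-count
chain: a forward filter propagates the distribution of lineage counts up
the locus tree with the count forced to one at every duplication-point,
and a backward pass samples counts and then coalescence times segment by
segment from the exact conditional law (coalescing pairs are uniform by
exchangeability, independently of the counts).  No rejection is involved,
so arbitrarily tight bounds cost the same as loose ones.  A
per-daughter-locus rejection sampler is kept as an independent
cross-validation route (``method='rejection'``); both draw from the same
conditional distribution.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

from .trees import GeneTree, LocusTree, Node, PhyloTree, species_from_label

__all__ = [
    "GDLParams",
    "GdlEvent",
    "LocusHistory",
    "ScenarioLabel",
    "BoundRejectionError",
    "BmscSampler",
    "simulate_locus_tree",
    "simulate_gene_tree_bmsc",
    "validate_bounds",
    "classify_scenario",
    "make_rng",
]

RETRY_CAP = 10 ** 6


class BoundRejectionError(RuntimeError):
    """Conditional resampling of a bounded daughter locus failed to accept
    within the retry cap; the requested bound is pathologically tight."""


def make_rng(seed, *keys) -> random.Random:
    """Deterministic substream: one master seed plus context keys.

    String seeding of ``random.Random`` hashes with SHA-512, so substreams
    are stable across runs and platforms.
    """
    return random.Random(":".join(str(k) for k in (seed, *keys)))


@dataclass
class GDLParams:
    """Duplication/loss birth-death rates (events per coalescent unit) and
    the finite length of the species-tree root edge where the process
    starts."""

    lam: float
    mu: float
    root_edge_length: float = 1.0
    seed: int | None = None

    def __post_init__(self):
        if self.lam < 0 or self.mu < 0:
            raise ValueError("rates must be non-negative")
        if self.root_edge_length < 0:
            raise ValueError("root edge length must be non-negative")


@dataclass(frozen=True)
class GdlEvent:
    """One unpruned duplication or loss event."""

    kind: str           # 'dup' | 'loss'
    height: float       # absolute height (leaves at 0)
    species_edge: str   # label of the species node below the edge ('' = root edge)


@dataclass
class LocusHistory:
    """Result of the duplication/loss stage.

    ``locus_tree`` is None when every lineage went extinct.  ``l`` is the
    number of locus lineages crossing the root speciation (the root
    lineages), and ``root_lineage_of`` maps each extant locus leaf to the
    1-based index of the root lineage it descends from.
    """

    locus_tree: LocusTree | None
    l: int
    root_lineage_of: dict[str, int]
    full_history: list[GdlEvent] = field(default_factory=list)

    @property
    def extinct(self) -> bool:
        return self.locus_tree is None


@dataclass(frozen=True)
class ScenarioLabel:
    """Partition of the four sampled genes by the root lineage each
    descends from, e.g. (ab,cd) when i_a = i_b != i_c = i_d."""

    indices: dict  # gene name -> root lineage index
    l: int

    @property
    def partition(self) -> frozenset:
        groups: dict[int, list[str]] = {}
        for name in sorted(self.indices):
            groups.setdefault(self.indices[name], []).append(name)
        return frozenset(frozenset(v) for v in groups.values())

    @property
    def kind(self) -> str:
        groups = sorted(
            ("".join(sorted(grp)) for grp in self.partition),
            key=lambda s: (sorted(s)[0]),
        )
        groups.sort(key=lambda s: (s[0]))
        return "(" + ",".join(sorted(groups, key=lambda s: (s[0]))) + ")"


# ---------------------------------------------------------------------------
# Stage 1: birth-death duplication/loss on the species tree
# ---------------------------------------------------------------------------


def simulate_locus_tree(
    species_tree: PhyloTree, params: GDLParams, rng: random.Random | None = None
) -> LocusHistory:
    """Run the duplication/loss birth-death process inside the species tree.

    The process starts with one locus lineage at the top of the (finite)
    species root edge; a duplication splits a lineage into a mother (same
    locus) and a daughter (novel locus, marked by a duplication-point at
    the duplication height); a loss terminates it; at each speciation every
    surviving lineage is copied into both child branches.  Extinct lineages
    are pruned and degree-2 nodes suppressed with their edge lengths
    summed, so the returned locus tree is again planted, binary and
    ultrametric.
    """
    if rng is None:
        rng = random.Random(params.seed)
    lam, mu = params.lam, params.mu
    total = lam + mu
    heights = species_tree.heights()
    sroot = species_tree.root
    start_h = heights[sroot] + params.root_edge_length
    events: list[GdlEvent] = []
    counter = {"rl": 0, "leaf": {}}

    def run_edge(snode: Node, entry_h: float, root_idx: int | None) -> Node | None:
        """One locus lineage descending the species edge above ``snode``
        from ``entry_h``; returns the surviving locus subtree (with
        per-node absolute heights stashed in ``length``) or None."""
        bottom = heights[snode]
        h = entry_h
        sp_label = snode.label if snode.is_leaf else (snode.label or _clade_tag(snode))
        while True:
            if total > 0:
                w = rng.expovariate(total)
            else:
                w = float("inf")
            if h - w <= bottom:
                break
            h -= w
            if rng.random() * total < lam:
                events.append(GdlEvent("dup", h, sp_label))
                mother = run_edge(snode, h, root_idx)
                daughter = run_edge(snode, h, root_idx)
                if rng.random() < 0.5:
                    mother, daughter = daughter, mother
                if daughter is not None:
                    # the duplication-point marks the start of the novel
                    # locus at the duplication height; if the daughter's
                    # surviving top already carries a lower one, the lower
                    # (more restrictive) bound is kept
                    daughter.dup_time = (
                        h if daughter.dup_time is None else min(daughter.dup_time, h)
                    )
                if mother is None:
                    return daughter
                if daughter is None:
                    return mother
                nd = Node(None, h, [mother, daughter])
                return nd
            events.append(GdlEvent("loss", h, sp_label))
            return None
        # reached the bottom of the species edge
        if snode is sroot:
            counter["rl"] += 1
            root_idx = counter["rl"]
        if snode.is_leaf:
            sp = snode.label
            idx = counter["leaf"].get(sp, 0) + 1
            counter["leaf"][sp] = idx
            leaf = Node(f"{sp}_{idx}", 0.0)
            _leaf_rl[leaf.label] = root_idx
            return leaf
        kids = [run_edge(c, bottom, root_idx) for c in snode.children]
        kids = [k for k in kids if k is not None]
        if not kids:
            return None
        if len(kids) == 1:
            return kids[0]
        return Node(None, bottom, kids)

    _leaf_rl: dict[str, int] = {}
    top = run_edge(sroot, start_h, None)
    if top is None:
        return LocusHistory(None, counter["rl"], {}, events)
    # convert stashed absolute heights into edge lengths
    _heights_to_lengths(top, start_h)
    tree = PhyloTree(top, root_open=True)
    if not top.is_leaf:
        tree.validate()
    species_of = {lab: species_from_label(lab) for lab in tree.leaf_labels()}
    return LocusHistory(LocusTree(tree, species_of), counter["rl"], dict(_leaf_rl), events)


def _clade_tag(nd: Node) -> str:
    lab = nd.label
    if lab:
        return lab
    while not nd.is_leaf:
        nd = nd.children[0]
    return f"anc({nd.label})"


def _heights_to_lengths(top: Node, start_h: float) -> None:
    """In-place: nodes built by run_edge carry absolute heights in
    ``length``; rewrite them as edge lengths (planted edge for the top)."""

    def rec(nd: Node, parent_h: float) -> None:
        h = 0.0 if nd.is_leaf else nd.length
        for c in nd.children:
            rec(c, h)
        nd.length = parent_h - h

    rec(top, start_h)


# ---------------------------------------------------------------------------
# Stage 2: bounded multispecies coalescent on the locus tree
# ---------------------------------------------------------------------------


def simulate_gene_tree_bmsc(
    L: LocusHistory | LocusTree,
    rng: random.Random | int | None = None,
    method: str = "auto",
) -> GeneTree:
    """Sample a gene tree from the bounded multispecies coalescent on a
    locus tree.

    One gene lineage starts at every extant locus leaf; within each locus
    edge any pair of co-existing lineages coalesces at rate 1; lineages
    below a duplication-point must have fully coalesced when its height is
    reached.  Above the locus root the remaining lineages coalesce on an
    unbounded stem.

    ``method`` selects the bound-enforcement strategy: 'exact' samples the
    conditioned lineage-count chain directly (forward filter / backward
    sampler), 'rejection' resamples each constrained daughter locus until
    its bound holds, and 'auto' (default) uses the exact sampler whenever a
    bound is present.  Both methods target the same distribution.
    """
    locus = L.locus_tree if isinstance(L, LocusHistory) else L
    if locus is None or not locus.tree.leaf_labels():
        raise ValueError("cannot run the coalescent on an empty locus tree")
    if not isinstance(rng, random.Random):
        rng = random.Random(rng)
    ltree = locus.tree
    if method not in ("auto", "exact", "rejection"):
        raise ValueError(f"unknown method {method!r}")
    if method == "auto":
        bounded = any(nd.dup_time is not None for nd in ltree.preorder())
        method = "exact" if bounded else "rejection"
    if method == "exact":
        gnode = BmscSampler(ltree).sample(rng)
        gtree = PhyloTree(gnode, root_open=True)
        return GeneTree(
            gtree, dict(locus.species_of), {lab: lab for lab in gtree.leaf_labels()}
        )
    heights = ltree.heights()

    # a gene lineage is (gene_node, height_of_node)
    def coalesce(lineages, h_from, h_to):
        k = len(lineages)
        h = h_from
        while k >= 2:
            rate = k * (k - 1) / 2.0
            h = h + rng.expovariate(rate)
            if h > h_to:
                break
            i = rng.randrange(k)
            j = rng.randrange(k - 1)
            if j >= i:
                j += 1
            (ni, hi), (nj, hj) = lineages[i], lineages[j]
            ni.length = h - hi
            nj.length = h - hj
            merged = (Node(None, 0.0, [ni, nj]), h)
            lineages = [l for m, l in enumerate(lineages) if m not in (i, j)]
            lineages.append(merged)
            k -= 1
        return lineages

    def sim_up(v: Node, h_top: float):
        """Lineages surviving at ``h_top``, the top of v's edge, with the
        edge's duplication bound (if any) satisfied."""
        h_v = heights[v]
        z = v.dup_time
        if z is None:
            return coalesce(gather(v, h_v), h_v, h_top)
        for _ in range(RETRY_CAP):
            lineages = coalesce(gather(v, h_v), h_v, z)
            if len(lineages) == 1:
                return coalesce(lineages, z, h_top)
        raise BoundRejectionError(
            f"daughter locus below height {z} failed to coalesce in "
            f"{RETRY_CAP} resampling attempts"
        )

    def gather(v: Node, h_v: float):
        if v.is_leaf:
            return [(Node(v.label, 0.0), 0.0)]
        out = []
        for c in v.children:
            out.extend(sim_up(c, h_v))
        return out

    root = ltree.root
    final = sim_up(root, float("inf"))
    assert len(final) == 1
    gnode, _ = final[0]
    gnode.length = 0.0
    gtree = PhyloTree(gnode, root_open=True)
    return GeneTree(
        gtree,
        dict(locus.species_of),
        {lab: lab for lab in gtree.leaf_labels()},
    )


# ---------------------------------------------------------------------------
# Exact conditional sampler for the bounded coalescent
# ---------------------------------------------------------------------------


def _transition(dist: dict[int, float], length: float) -> dict[int, float]:
    """Push a lineage-count distribution through an edge of given length."""
    from .coalescent import g

    out: dict[int, float] = {}
    for i, p in dist.items():
        for j in range(1, i + 1):
            gp = g(i, j, length)
            if gp > 0:
                out[j] = out.get(j, 0.0) + p * gp
    return out


def _weighted_choice(rng: random.Random, items: list, weights: list[float]):
    total = math.fsum(weights)
    if total <= 0:
        raise BoundRejectionError("duplication bound has probability 0")
    u = rng.random() * total
    acc = 0.0
    for it, w in zip(items, weights):
        acc += w
        if u <= acc:
            return it
    return items[-1]


def _sample_death_times(i: int, j: int, length: float, rng: random.Random):
    """Relative jump times of the Kingman lineage-count chain conditioned
    to pass from i to j lineages in exactly ``length`` time units.

    Sequentially samples each next-coalescence time by inverting its exact
    conditional CDF: with k lineages and residual time T, the next jump
    has density  C(k,2) e^{-C(k,2) tau} g(k-1, j, T - tau) / g(k, j, T),
    whose CDF is a closed-form exponential sum (spectral expansion of g).
    """
    from .coalescent import _g_coeffs, g

    times: list[float] = []
    s = 0.0
    k = i
    while k > j:
        T = length - s
        rk = k * (k - 1) / 2.0
        # CDF(tau) = rk * sum_m a_m * expm1(b_m * tau) with the exact
        # spectral coefficients of g(k-1, j, .)
        terms = [
            (c * math.exp(-lam * T) / (lam - rk), lam - rk)
            for c, lam in zip(
                _g_coeffs(k - 1, j),
                (m * (m - 1) / 2.0 for m in range(j, k)),
            )
        ]
        target = rng.random() * g(k, j, T) / rk
        lo, hi = 0.0, T
        tol = 1e-11 * max(T, 1.0)
        expm1 = math.expm1
        while hi - lo > tol:
            mid = 0.5 * (lo + hi)
            acc = 0.0
            for a, b in terms:
                acc += a * expm1(b * mid)
            if acc < target:
                lo = mid
            else:
                hi = mid
        s += 0.5 * (lo + hi)
        times.append(s)
        k -= 1
    return times


class BmscSampler:
    """Reusable exact sampler of the bounded coalescent on one locus tree.

    The forward filter (lineage-count distributions with counts forced to
    one at every duplication-point) is computed once at construction; each
    ``sample`` call then draws counts and coalescence times from the exact
    conditional law by backward sampling.  Construct once and reuse when
    simulating many gene trees on the same locus tree.
    """

    def __init__(self, ltree: PhyloTree):
        from .coalescent import g

        self.ltree = ltree
        self.heights = ltree.heights()
        self.entry: dict[Node, dict[int, float]] = {}
        self.top: dict[Node, dict[int, float]] = {}
        root = ltree.root
        for nd in ltree.postorder():
            if nd.is_leaf:
                e = {1: 1.0}
            else:
                dists = [self.top[c] for c in nd.children]
                e = dists[0]
                for d in dists[1:]:
                    nxt: dict[int, float] = {}
                    for i1, p1 in e.items():
                        for i2, p2 in d.items():
                            nxt[i1 + i2] = nxt.get(i1 + i2, 0.0) + p1 * p2
                    e = nxt
            self.entry[nd] = e
            if nd is root:
                continue
            z = nd.dup_time
            if z is not None:
                seg = z - self.heights[nd]
                if seg < -1e-9:
                    raise BoundRejectionError("duplication-point below its edge")
                mass = math.fsum(p * g(i, 1, max(seg, 0.0)) for i, p in e.items())
                if mass <= 0.0:
                    raise BoundRejectionError(
                        f"bound at height {z} cannot be met (probability 0)"
                    )
                self.top[nd] = {1: mass}
            else:
                self.top[nd] = _transition(e, nd.length)

    def sample(self, rng: random.Random) -> Node:
        """Draw one gene tree; returns its root node."""
        from .coalescent import g

        ltree, heights = self.ltree, self.heights
        entry, top = self.entry, self.top
        root = ltree.root
        entry_count: dict[Node, int] = {}
        merge_heights: dict[Node, list[float]] = {}

        def sample_edge(nd: Node, j_exit: int) -> None:
            h_v = heights[nd]
            e = entry[nd]
            if nd.dup_time is not None:
                seg_len = max(nd.dup_time - h_v, 0.0)
                j_seg = 1
            else:
                seg_len = nd.length
                j_seg = j_exit
            items = [i for i in sorted(e) if i >= j_seg]
            if len(items) == 1:
                i = items[0]
            else:
                weights = [e[i] * g(i, j_seg, seg_len) for i in items]
                i = _weighted_choice(rng, items, weights)
            entry_count[nd] = i
            merge_heights[nd] = [
                h_v + t for t in _sample_death_times(i, j_seg, seg_len, rng)
            ]
            descend(nd, i)

        def descend(nd: Node, i: int) -> None:
            if nd.is_leaf:
                return
            c1, c2 = nd.children
            d1, d2 = top[c1], top[c2]
            pairs = [(i1, i - i1) for i1 in sorted(d1) if (i - i1) in d2]
            if len(pairs) == 1:
                i1, i2 = pairs[0]
            else:
                weights = [d1[a] * d2[b] for a, b in pairs]
                i1, i2 = _weighted_choice(rng, pairs, weights)
            sample_edge(c1, i1)
            sample_edge(c2, i2)

        # root stem: unbounded above unless the planted edge carries a bound
        e = entry[root]
        h_root = heights[root]
        items = sorted(e)
        if root.dup_time is not None:
            seg_len = max(root.dup_time - h_root, 0.0)
            weights = [e[i] * g(i, 1, seg_len) for i in items]
            i0 = items[0] if len(items) == 1 else _weighted_choice(rng, items, weights)
            stem_rel = _sample_death_times(i0, 1, seg_len, rng)
        else:
            weights = [e[i] for i in items]
            i0 = items[0] if len(items) == 1 else _weighted_choice(rng, items, weights)
            stem_rel = []
            s = 0.0
            for k in range(i0, 1, -1):
                s += rng.expovariate(k * (k - 1) / 2.0)
                stem_rel.append(s)
        entry_count[root] = i0
        merge_heights[root] = [h_root + t for t in stem_rel]
        descend(root, i0)

        # assembly: merge uniformly chosen pairs at the sampled heights
        def build(nd: Node) -> list[tuple[Node, float]]:
            if nd.is_leaf:
                lineages = [(Node(nd.label, 0.0), 0.0)]
            else:
                lineages = []
                for c in nd.children:
                    lineages.extend(build(c))
            assert len(lineages) == entry_count[nd], "count bookkeeping broken"
            for h_m in merge_heights[nd]:
                k = len(lineages)
                a = rng.randrange(k)
                b = rng.randrange(k - 1)
                if b >= a:
                    b += 1
                (na, ha), (nb, hb) = lineages[a], lineages[b]
                na.length = h_m - ha
                nb.length = h_m - hb
                merged = (Node(None, 0.0, [na, nb]), h_m)
                lineages = [l for m, l in enumerate(lineages) if m not in (a, b)]
                lineages.append(merged)
            return lineages

        final = build(root)
        assert len(final) == 1
        gnode, _ = final[0]
        gnode.length = 0.0
        return gnode


def validate_bounds(G: GeneTree, L: LocusHistory | LocusTree):
    """Check every duplication-point bound on a gene tree.

    Returns (ok, violations); each violation is (constrained leaf set,
    bound height, observed MRCA height).
    """
    locus = L.locus_tree if isinstance(L, LocusHistory) else L
    gh = G.tree.heights()
    locus_leaf_of_gene = {g: loc for g, loc in G.locus_of.items()}
    gene_of_locus: dict[str, list[str]] = {}
    for g, loc in locus_leaf_of_gene.items():
        gene_of_locus.setdefault(loc, []).append(g)
    if set(gene_of_locus) != set(locus.tree.leaf_labels()):
        raise ValueError("gene tree leaves do not match the locus tree's leaf set")
    violations = []
    for dp in locus.tree.dup_points():
        constrained_loci = [l.label for l in _subtree_leaves(dp.node)]
        genes = [g for loc in constrained_loci for g in gene_of_locus[loc]]
        mrca_h = _mrca_height(G.tree, genes, gh)
        if not mrca_h < dp.time:
            violations.append((frozenset(genes), dp.time, mrca_h))
    return (not violations, violations)


def _subtree_leaves(nd: Node):
    stack = [nd]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            yield n
        else:
            stack.extend(n.children)


def _mrca_height(tree: PhyloTree, labels, heights) -> float:
    want = set(labels)
    if len(want) == 1:
        return 0.0
    best = None

    def rec(nd: Node) -> set:
        if nd.is_leaf:
            return {nd.label} & want
        acc = set()
        for c in nd.children:
            acc |= rec(c)
        nonlocal best
        if best is None and acc == want:
            best = heights[nd]
        return acc

    rec(tree.root)
    if best is None:
        raise ValueError(f"labels {sorted(want)} not all present")
    return best


def classify_scenario(H: LocusHistory, genes: dict[str, str]) -> ScenarioLabel:
    """Partition sampled genes by the root lineage they descend from.

    ``genes`` maps short gene names (e.g. 'a'..'d') to extant locus leaf
    labels of ``H``.
    """
    idx = {}
    for name, leaf in genes.items():
        if leaf not in H.root_lineage_of:
            raise KeyError(f"locus leaf {leaf!r} not present in this history")
        idx[name] = H.root_lineage_of[leaf]
    return ScenarioLabel(idx, H.l)
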