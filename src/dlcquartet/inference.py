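"""Quartet extraction from multi-copy gene trees and exact quartet-score
species-tree estimation.

Two extraction rules for gene families with several copies per species:

* *one*: sample a single copy per species uniformly at random (once per
  gene tree) and record the single quartet those copies display;
* *multi*: enumerate every combination of one copy per species and count
  the quartets of all combinations.

The estimator maximizes the total number of input quartets displayed by a
candidate unrooted species topology; at the small taxon counts handled
here the search is exhaustive, so the returned tree is the exact optimum
of the quartet-score criterion.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from itertools import combinations, product

import numpy as np

from .trees import GeneTree, Node, PhyloTree, QuartetType, quartet_topology, write_newick

__all__ = [
    "QuartetTally",
    "astral_one_sample",
    "astral_multi_tally",
    "dominant_quartet",
    "infer_species_tree_exact",
    "InferenceResult",
    "enumerate_unrooted_topologies",
    "copies_by_species",
]

MAX_EXACT_TAXA = 8


@dataclass
class QuartetTally:
    """Counts of the three quartet topologies on an ordered species
    4-tuple.  ``counts[QuartetType.AB_CD]`` counts gene quartets pairing
    species4[0] with species4[1]."""

    species4: tuple[str, str, str, str]
    counts: np.ndarray = field(default_factory=lambda: np.zeros(3, dtype=np.int64))
    provenance: str = "multi"
    n_trees_used: int = 0

    def add(self, qt: QuartetType, n: int = 1) -> None:
        self.counts[int(qt)] += n

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def copies_by_species(G: GeneTree) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for leaf in sorted(G.tree.leaf_labels()):
        out.setdefault(G.species_of[leaf], []).append(leaf)
    return out


def astral_one_sample(
    G: GeneTree,
    species4: tuple[str, str, str, str],
    rng: random.Random | int | None = None,
    chosen: dict[str, str] | None = None,
) -> QuartetType | None:
    """Quartet displayed by one uniformly sampled copy per species.

    Returns None when any of the four species has no copy in the tree
    (the gene tree casts no vote on this 4-tuple).  Pass ``chosen`` (a
    species -> leaf map, e.g. from a single per-tree draw) to reuse one
    sample across several 4-tuples of the same tree.
    """
    if len(set(species4)) != 4:
        raise ValueError("species must be distinct")
    pools = copies_by_species(G)
    if any(sp not in pools for sp in species4):
        return None
    if chosen is None:
        if not isinstance(rng, random.Random):
            rng = random.Random(rng)
        chosen = {sp: rng.choice(pools[sp]) for sp in species4}
    picks = tuple(chosen[sp] for sp in species4)
    return quartet_topology(G.tree, picks)


def astral_multi_tally(G: GeneTree, species4: tuple[str, str, str, str]) -> QuartetTally:
    """Count the quartets displayed by every combination of one gene copy
    per species; the counts sum to the product of the four copy numbers."""
    if len(set(species4)) != 4:
        raise ValueError("species must be distinct")
    pools = copies_by_species(G)
    tally = QuartetTally(tuple(species4), provenance="multi")
    if any(sp not in pools for sp in species4):
        return tally
    tally.n_trees_used = 1
    for picks in product(*(pools[sp] for sp in species4)):
        tally.add(quartet_topology(G.tree, picks))
    return tally


def dominant_quartet(tally: QuartetTally) -> QuartetType:
    """Topology with the largest count; ties broken by the fixed order
    ab|cd < ac|bd < ad|bc."""
    if tally.total == 0:
        raise ValueError("empty tally has no dominant quartet")
    return QuartetType(int(np.argmax(tally.counts)))


# ---------------------------------------------------------------------------
# Exhaustive quartet-score search
# ---------------------------------------------------------------------------


@dataclass
class InferenceResult:
    tree: PhyloTree
    score: int
    n_optima: int          # number of score-tied topologies (1 = unique)


def _rooted_topologies(labels: tuple[str, ...]):
    """All rooted binary topologies on a label tuple, as nested pairs."""
    if len(labels) == 1:
        yield labels[0]
        return
    first, rest = labels[0], labels[1:]
    n = len(rest)
    for r in range(0, n):
        for extra in combinations(rest, r):
            left_set = (first, *extra)
            right_set = tuple(x for x in rest if x not in extra)
            if not right_set:
                continue
            for lt in _rooted_topologies(left_set):
                for rt in _rooted_topologies(right_set):
                    yield (lt, rt)


def enumerate_unrooted_topologies(taxa):
    """All unrooted binary topologies on a taxon set, each returned as a
    rooted nested-pair structure whose unrooted shape is the topology
    (the last taxon hangs off the root, fixing the rooting)."""
    taxa = tuple(sorted(taxa))
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa")
    for sub in _rooted_topologies(taxa[:-1]):
        yield (sub, taxa[-1])


def _displayed_pairing(topo, four: frozenset):
    """Partner structure of a 4-leaf restriction of a nested-pair topology:
    returns the frozenset pair forming the cherry side."""

    def leafset(t):
        if isinstance(t, str):
            return frozenset((t,)) & four
        return leafset(t[0]) | leafset(t[1])

    node = topo
    while True:
        ls, rs = leafset(node[0]), leafset(node[1])
        nl, nr = len(ls), len(rs)
        if nl == 4:
            node = node[0]
        elif nr == 4:
            node = node[1]
        elif nl == 2:
            return ls
        elif nr == 2:
            return rs
        elif nl == 3:
            node = node[0]
        else:
            node = node[1]


def _quartet_of_pairing(species4, cherry: frozenset) -> QuartetType:
    a, b, c, d = species4
    partner = next(iter(cherry - {a})) if a in cherry else next(iter({b, c, d} - cherry))
    if partner == b:
        return QuartetType.AB_CD
    if partner == c:
        return QuartetType.AC_BD
    return QuartetType.AD_BC


def _topo_to_tree(topo) -> PhyloTree:
    def rec(t) -> Node:
        if isinstance(t, str):
            return Node(t, 1.0)
        return Node(None, 1.0, [rec(t[0]), rec(t[1])])

    root = rec(topo)
    root.length = 0.0
    return PhyloTree(root)


def infer_species_tree_exact(
    tallies: dict[frozenset, QuartetTally], taxa=None
) -> InferenceResult:
    """Exhaustively score every unrooted topology by the total number of
    input quartets it displays and return the argmax.

    ``tallies`` maps each 4-taxon frozenset to its QuartetTally.  Ties are
    broken by the lexicographic order of the canonical Newick strings and
    reported via ``n_optima``.
    """
    if taxa is None:
        taxa = sorted({t for key in tallies for t in key})
    taxa = tuple(sorted(taxa))
    if len(taxa) > MAX_EXACT_TAXA:
        raise ValueError(
            f"exhaustive search refused for n={len(taxa)} > {MAX_EXACT_TAXA} taxa"
        )
    quartet_keys = [frozenset(c) for c in combinations(taxa, 4)]
    best = None
    for topo in enumerate_unrooted_topologies(taxa):
        score = 0
        for key in quartet_keys:
            tally = tallies.get(key)
            if tally is None or tally.total == 0:
                continue
            cherry = _displayed_pairing(topo, key)
            qt = _quartet_of_pairing(tally.species4, cherry)
            score += int(tally.counts[int(qt)])
        nwk = write_newick(_topo_to_tree(topo))
        if best is None or score > best[0]:
            best = (score, nwk, topo, 1)
        elif score == best[0]:
            n = best[3] + 1
            if nwk < best[1]:
                best = (score, nwk, topo, n)
            else:
                best = (best[0], best[1], best[2], n)
    score, _, topo, ties = best
    return InferenceResult(_topo_to_tree(topo), score, ties)
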