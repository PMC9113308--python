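"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately re-derive quantities through different
algorithms than the package (set-based MRCA logic instead of restriction,
naive event-driven coalescent simulation instead of the lineage-count
samplers) so that agreement is evidence, not tautology.
"""

from __future__ import annotations

import math
import random

import pytest

from dlcquartet.trees import Node, PhyloTree


def random_ultrametric_tree(rng: random.Random, labels, max_depth: float = 2.0) -> PhyloTree:
    """Random coalescent-style ultrametric tree over the given labels."""
    lineages = [(Node(lab, 0.0), 0.0) for lab in labels]
    h = 0.0
    while len(lineages) > 1:
        # heights on a fixed decimal grid keep the tree exactly ultrametric
        # and its canonical Newick round-trippable at 10 significant digits
        h = round(h + rng.uniform(0.05, max_depth / len(labels)), 6)
        i, j = rng.sample(range(len(lineages)), 2)
        (ni, hi), (nj, hj) = lineages[i], lineages[j]
        ni.length = h - hi
        nj.length = h - hj
        merged = (Node(None, 0.0, [ni, nj]), h)
        lineages = [l for k, l in enumerate(lineages) if k not in (i, j)]
        lineages.append(merged)
    root, _ = lineages[0]
    root.length = round(rng.uniform(0.0, 1.0), 6)
    return PhyloTree(root)


def oracle_quartet_pair(tree: PhyloTree, four) -> frozenset:
    """Cherry pair of the displayed quartet via pairwise-MRCA heights
    (independent of the package's restriction-based extraction)."""
    heights = tree.heights()
    leafsets: dict[Node, set] = {}
    for nd in tree.postorder():
        leafsets[nd] = (
            {nd.label} if nd.is_leaf else set().union(*(leafsets[c] for c in nd.children))
        )
    four = list(four)

    def mrca_h(x, y):
        return min(
            heights[nd] for nd, ls in leafsets.items() if x in ls and y in ls
        )

    pairs = [(x, y) for i, x in enumerate(four) for y in four[i + 1:]]
    best = min(pairs, key=lambda p: mrca_h(*p))
    return frozenset(best)


def naive_all_coalesced_before(
    tree: PhyloTree, bound: float, n_reps: int, seed: int
) -> tuple[float, float]:
    """Brute-force Monte-Carlo estimate of P[all lineages coalesce to one
    by the bound], by direct event simulation (frequency, standard error)."""
    rng = random.Random(seed)
    heights = tree.heights()

    def counts_at_top(nd: Node) -> int:
        if nd.is_leaf:
            k = 1
        else:
            k = sum(counts_at_top(c) for c in nd.children)
        h = heights[nd]
        stop = h + nd.length if nd is not tree.root else bound
        while k > 1:
            h += rng.expovariate(k * (k - 1) / 2.0)
            if h > stop:
                break
            k -= 1
        return k

    hits = sum(counts_at_top(tree.root) == 1 for _ in range(n_reps))
    p = hits / n_reps
    return p, math.sqrt(p * (1 - p) / n_reps)


@pytest.fixture
def rng():
    return random.Random(20210528)
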