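"""Monte-Carlo verification harness.

The closed-form quartet probabilities and the simulator are two independent
routes to the same distributions, so each validates the other: this module
estimates quartet frequencies by repeated bounded-coalescent simulation and
compares them with the closed forms (z-scores), stratifies full DLCoal
simulations by root-lineage scenario to check the scenario-level
inequalities, and runs convergence experiments for the quartet-based
species-tree estimators.

All outputs are plain pandas DataFrames and are bit-reproducible for a
fixed configuration and master seed.
"""

from __future__ import annotations

import math
import random
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import coalescent as cm
from .inference import QuartetTally, astral_multi_tally, astral_one_sample, dominant_quartet
from .simulate import (
    BmscSampler,
    GDLParams,
    LocusHistory,
    classify_scenario,
    make_rng,
    simulate_gene_tree_bmsc,
    simulate_locus_tree,
)
from .trees import LocusTree, Node, PhyloTree, QuartetType, quartet_topology

__all__ = [
    "McEstimate",
    "ExperimentConfig",
    "mc_quartet_probability",
    "default_case_grid",
    "check_closed_forms",
    "scenario_stratified_check",
    "convergence_experiment",
    "quartet_species_tree",
    "sample_family",
]


@dataclass(frozen=True)
class McEstimate:
    """A Monte-Carlo frequency with its binomial standard error."""

    value: float
    se: float
    n_reps: int

    def z_against(self, truth: float) -> float:
        se = max(self.se, 1e-12)
        return (self.value - truth) / se


@dataclass
class ExperimentConfig:
    """Configuration of a verification run."""

    species_shape: str = "balanced"          # 'balanced' | 'caterpillar'
    internal_length: float = 1.0             # species-tree internal edges
    pendant_length: float = 1.0
    root_edge_length: float = 1.0
    lam_mu_grid: tuple = ((0.1, 0.1), (0.3, 0.3), (0.5, 0.5))
    n_families: int = 10_000
    gene_counts: tuple = (10, 100, 1000)
    n_replicates: int = 10
    seed: int = 20210528

    def __post_init__(self):
        if not self.lam_mu_grid or not self.gene_counts:
            raise ValueError("grids must be non-empty")


def quartet_species_tree(
    shape: str = "balanced",
    internal: float = 1.0,
    pendant: float = 1.0,
    labels=("A", "B", "C", "D"),
) -> PhyloTree:
    """A 4-taxon ultrametric species tree displaying labels[0:2]|labels[2:4]."""
    a, b, c, d = labels
    if shape == "balanced":
        h1 = pendant
        hr = h1 + internal
        t = PhyloTree(
            Node(None, 0.0, [
                Node(None, internal, [Node(a, h1), Node(b, h1)]),
                Node(None, internal, [Node(c, h1), Node(d, h1)]),
            ])
        )
    elif shape == "caterpillar":
        h1 = pendant
        h2 = h1 + internal
        h3 = h2 + internal
        t = PhyloTree(
            Node(None, 0.0, [
                Node(None, internal, [
                    Node(None, internal, [Node(a, h1), Node(b, h1)]),
                    Node(c, h2),
                ]),
                Node(d, h3),
            ])
        )
    else:
        raise ValueError(f"unknown shape {shape!r}")
    t.validate()
    return t


def mc_quartet_probability(
    L: LocusTree, n_reps: int, seed, labels=None
) -> dict[QuartetType, McEstimate]:
    """Empirical gene-tree quartet frequencies on a 4-leaf locus tree.

    ``labels`` fixes the (a, b, c, d) orientation; default is the sorted
    leaf labels.  Frequencies sum to one exactly.
    """
    leaf_labels = sorted(L.tree.leaf_labels())
    if len(leaf_labels) != 4:
        raise ValueError("Monte-Carlo quartet estimation needs a 4-leaf locus tree")
    if n_reps < 100:
        raise ValueError("n_reps < 100 gives meaningless standard errors")
    four = tuple(labels) if labels is not None else tuple(leaf_labels)
    rng = make_rng(seed, "mc_quartet")
    counts = [0, 0, 0]
    sampler = BmscSampler(L.tree)   # forward filter shared across replicates
    for _ in range(n_reps):
        gnode = sampler.sample(rng)
        counts[int(quartet_topology(PhyloTree(gnode), four))] += 1
    out = {}
    for qt in QuartetType:
        p = counts[int(qt)] / n_reps
        out[qt] = McEstimate(p, math.sqrt(p * (1 - p) / n_reps), n_reps)
    return out


def default_case_grid() -> list[tuple[str, cm.CaseParams]]:
    """One representative parameter cell per closed-form case.

    The cells mix a weak-ILS edge (x = 0.5) with moderate edges (1.0) and
    put duplication bounds at t in {0.5, 1.0}: deep enough that the
    conditional laws differ visibly from the unbounded ones, loose enough
    that rejection sampling stays cheap.
    """
    B, C = cm.BALANCED, cm.CATERPILLAR
    return [
        ("balanced/none", cm.CaseParams(B, 0.5, 1.0, dup_case=cm.DUP_NONE)),
        ("balanced/dup_on_X", cm.CaseParams(B, 1.0, 1.0, dup_case=cm.DUP_ON_X)),
        ("balanced/dup_at_root_vertex",
         cm.CaseParams(B, 1.0, 0.5, dup_case=cm.DUP_AT_ROOT_VERTEX)),
        ("balanced/dup_on_root_edge",
         cm.CaseParams(B, 0.5, 0.5, t=1.0, dup_case=cm.DUP_ON_ROOT_EDGE)),
        ("balanced/dup_on_root_edge_tight",
         cm.CaseParams(B, 1.0, 1.0, t=0.5, dup_case=cm.DUP_ON_ROOT_EDGE)),
        ("caterpillar/none", cm.CaseParams(C, 0.5, 1.0, dup_case=cm.DUP_NONE)),
        ("caterpillar/dup_on_X", cm.CaseParams(C, 1.0, 1.0, dup_case=cm.DUP_ON_X)),
        ("caterpillar/dup_on_Y",
         cm.CaseParams(C, 0.5, 1.0, t=1.0, dup_case=cm.DUP_ON_Y)),
        ("caterpillar/dup_on_Y_tight",
         cm.CaseParams(C, 1.0, 1.0, t=0.5, dup_case=cm.DUP_ON_Y)),
        ("caterpillar/dup_on_root_edge",
         cm.CaseParams(C, 0.5, 1.0, t=1.0, dup_case=cm.DUP_ON_ROOT_EDGE)),
    ]


def check_closed_forms(
    cases=None, n_reps: int = 100_000, seed: int = 20210528
) -> pd.DataFrame:
    """Closed form vs Monte-Carlo for every quartet-probability case.

    Returns one row per case with the analytic and empirical matching
    probabilities and the z-score of their difference.
    """
    if cases is None:
        cases = default_case_grid()
    rows = []
    for name, params in cases:
        dist = cm.quartet_probs(params)
        L = cm.locus_tree_from_case(params)
        est = mc_quartet_probability(L, n_reps, make_rng(seed, "cf", name).random())
        mc_match = est[QuartetType.AB_CD]
        alt1, alt2 = est[QuartetType.AC_BD], est[QuartetType.AD_BC]
        rows.append({
            "case": name,
            "x": params.x, "y": params.y, "t": params.t,
            "p_match_closed": dist.p_match,
            "p_match_mc": mc_match.value,
            "se": mc_match.se,
            "z_match": mc_match.z_against(dist.p_match),
            "p_alt_closed": dist.p_alt,
            "p_alt1_mc": alt1.value,
            "p_alt2_mc": alt2.value,
            "z_alt1": alt1.z_against(dist.p_alt),
            "z_alt2": alt2.z_against(dist.p_alt),
            "n_reps": n_reps,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Full DLCoal sampling of one gene family
# ---------------------------------------------------------------------------


@dataclass
class FamilySample:
    """One simulated gene family with four sampled genes."""

    history: LocusHistory
    gene_tree: object
    genes: dict[str, str]          # 'a'..'d' -> gene/locus leaf label
    scenario: object
    quartet: QuartetType


_GENE_NAMES = ("a", "b", "c", "d")


def sample_family(
    species_tree: PhyloTree,
    params: GDLParams,
    rng: random.Random,
    species=("A", "B", "C", "D"),
):
    """Simulate one DLCoal family and sample one gene per species uniformly.

    Returns None when some species has no surviving gene copy (the family
    is discarded, matching the conditioning on all four genes existing).
    """
    hist = simulate_locus_tree(species_tree, params, rng)
    if hist.extinct:
        return None
    by_species: dict[str, list[str]] = {}
    for lab in hist.locus_tree.tree.leaf_labels():
        by_species.setdefault(hist.locus_tree.species_of[lab], []).append(lab)
    if any(sp not in by_species for sp in species):
        return None
    G = simulate_gene_tree_bmsc(hist, rng)
    genes = {
        name: rng.choice(sorted(by_species[sp]))
        for name, sp in zip(_GENE_NAMES, species)
    }
    scenario = classify_scenario(hist, genes)
    quartet = quartet_topology(G.tree, tuple(genes[n] for n in _GENE_NAMES))
    return FamilySample(hist, G, genes, scenario, quartet)


def scenario_stratified_check(config: ExperimentConfig) -> dict[str, pd.DataFrame]:
    """Simulate families, stratify quartet outcomes by root-lineage
    scenario, and tabulate the scenario-level frequencies.

    Returns
    -------
    dict with
      'by_scenario': quartet frequencies per scenario kind and (lam, mu),
      'pairings':    frequencies of i_a=i_b, i_a=i_c and 1/l comparisons,
      'summary':     per-rate aggregate quartet frequencies and discards.
    """
    S = quartet_species_tree(config.species_shape, config.internal_length,
                             config.pendant_length)
    rows, pair_rows, summary = [], [], []
    for lam, mu in config.lam_mu_grid:
        params = GDLParams(lam, mu, config.root_edge_length)
        rng = make_rng(config.seed, "scenario", config.species_shape, lam, mu)
        strata: dict[str, np.ndarray] = {}
        strata_l: dict[int, dict[str, int]] = {}
        counts = np.zeros(3, dtype=np.int64)
        n_discarded = 0
        for _ in range(config.n_families):
            fam = sample_family(S, params, rng)
            if fam is None:
                n_discarded += 1
                continue
            counts[int(fam.quartet)] += 1
            kind = fam.scenario.kind
            strata.setdefault(kind, np.zeros(3, dtype=np.int64))[int(fam.quartet)] += 1
            idx = fam.scenario.indices
            rec = strata_l.setdefault(fam.scenario.l, {"n": 0, "ab": 0, "ac": 0})
            rec["n"] += 1
            rec["ab"] += idx["a"] == idx["b"]
            rec["ac"] += idx["a"] == idx["c"]
        n_used = int(counts.sum())
        for kind, cts in sorted(strata.items()):
            tot = int(cts.sum())
            rows.append({
                "lam": lam, "mu": mu, "scenario": kind, "n": tot,
                "f_ab_cd": cts[0] / tot, "f_ac_bd": cts[1] / tot,
                "f_ad_bc": cts[2] / tot,
                # thin strata are kept but flagged: their frequencies carry
                # no statistical weight
                "conclusive": tot >= 100,
            })
        for l, rec in sorted(strata_l.items()):
            n = rec["n"]
            pair_rows.append({
                "lam": lam, "mu": mu, "l": l, "n": n,
                "f_ia_eq_ib": rec["ab"] / n,
                "f_ia_eq_ic": rec["ac"] / n,
                "expected_cross": 1.0 / l,
                "se_cross": math.sqrt((1 / l) * (1 - 1 / l) / n) if n else float("nan"),
                "conclusive": n >= 100,
            })
        summary.append({
            "lam": lam, "mu": mu, "n_families": config.n_families,
            "n_used": n_used, "n_discarded": n_discarded,
            "discard_rate": n_discarded / config.n_families,
            "f_match": counts[0] / n_used,
            "f_alt1": counts[1] / n_used,
            "f_alt2": counts[2] / n_used,
            "se": math.sqrt(0.25 / n_used),
        })
    return {
        "by_scenario": pd.DataFrame(rows),
        "pairings": pd.DataFrame(pair_rows),
        "summary": pd.DataFrame(summary),
    }


def convergence_experiment(config: ExperimentConfig, mode: str = "one") -> pd.DataFrame:
    """Fraction of replicate datasets whose dominant quartet matches the
    species quartet, as the number of gene families grows.

    mode 'one' votes with a single sampled copy per species per family;
    mode 'multi' accumulates all copy combinations.  Also reports the mean
    per-family tally of each topology.
    """
    if mode not in ("one", "multi"):
        raise ValueError("mode must be 'one' or 'multi'")
    S = quartet_species_tree(config.species_shape, config.internal_length,
                             config.pendant_length)
    species = ("A", "B", "C", "D")
    lam, mu = config.lam_mu_grid[0]
    params = GDLParams(lam, mu, config.root_edge_length)
    rows = []
    for m in config.gene_counts:
        correct = 0
        grand = np.zeros(3, dtype=float)
        for rep in range(config.n_replicates):
            rng = make_rng(config.seed, "conv", mode, m, rep)
            tally = QuartetTally(species, provenance=mode)
            for _ in range(m):
                hist = simulate_locus_tree(S, params, rng)
                if hist.extinct:
                    continue
                sp_present = set(hist.locus_tree.species_of.values())
                if not set(species) <= sp_present:
                    continue
                G = simulate_gene_tree_bmsc(hist, rng)
                if mode == "one":
                    qt = astral_one_sample(G, species, rng)
                    if qt is not None:
                        tally.add(qt)
                else:
                    sub = astral_multi_tally(G, species)
                    tally.counts += sub.counts
                tally.n_trees_used += 1
            if tally.total and dominant_quartet(tally) == QuartetType.AB_CD:
                correct += 1
            grand += tally.counts / max(tally.n_trees_used, 1)
        rows.append({
            "mode": mode, "m": m, "lam": lam, "mu": mu,
            "n_replicates": config.n_replicates,
            "fraction_correct": correct / config.n_replicates,
            "mean_tally_match": grand[0] / config.n_replicates,
            "mean_tally_alt1": grand[1] / config.n_replicates,
            "mean_tally_alt2": grand[2] / config.n_replicates,
        })
    return pd.DataFrame(rows)
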