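"""DLCoal generative process: locus-tree birth-death and bounded coalescent."""

import math
import random
from collections import Counter

import pytest

from dlcquartet.coalescent import (
    CaseParams,
    locus_tree_from_case,
    quartet_probs,
)
from dlcquartet.experiments import quartet_species_tree
from dlcquartet.simulate import (
    BmscSampler,
    BoundRejectionError,
    GDLParams,
    LocusHistory,
    classify_scenario,
    make_rng,
    simulate_gene_tree_bmsc,
    simulate_locus_tree,
    validate_bounds,
)
from dlcquartet.trees import (
    GeneTree,
    LocusTree,
    Node,
    PhyloTree,
    parse_newick,
    quartet_topology,
    write_newick,
)


class TestLocusTreeSimulation:
    def test_no_events_reproduces_species_tree(self):
        S = quartet_species_tree("caterpillar", internal=0.7, pendant=0.4)
        hist = simulate_locus_tree(S, GDLParams(0.0, 0.0, 1.0), random.Random(1))
        assert hist.l == 1
        got = hist.locus_tree.tree
        # same topology and metric, leaves renamed species -> species_1
        expected = write_newick(S).replace(":0;", ":1;")
        for sp in "ABCD":
            expected = expected.replace(f"{sp}:", f"{sp}_1:")
        assert write_newick(got) == expected
        assert got.dup_points() == []
        assert set(hist.root_lineage_of.values()) == {1}

    def test_pure_birth_mean_copy_number(self):
        # one species, one edge of length T, no losses: E[copies] = e^(lam*T)
        S = PhyloTree(Node("A", 0.0))
        lam, T = 0.5, 1.5
        rng = random.Random(42)
        n_reps = 4000
        counts = []
        for _ in range(n_reps):
            hist = simulate_locus_tree(S, GDLParams(lam, 0.0, T), rng)
            counts.append(len(hist.locus_tree.tree.leaf_labels()))
        mean = sum(counts) / n_reps
        expected = math.exp(lam * T)
        se = (sum((c - mean) ** 2 for c in counts) / n_reps) ** 0.5 / n_reps**0.5
        assert abs(mean - expected) < 4 * se

    def test_duplication_points_sit_at_duplication_nodes(self):
        S = quartet_species_tree("balanced")
        rng = random.Random(9)
        seen_dup = 0
        for _ in range(300):
            hist = simulate_locus_tree(S, GDLParams(0.4, 0.2, 1.0), rng)
            if hist.extinct:
                continue
            t = hist.locus_tree.tree
            h = t.heights()
            for nd in t.preorder():
                if nd.dup_time is None:
                    continue
                seen_dup += 1
                top = h[nd] + nd.length if nd is not t.root else float("inf")
                assert h[nd] <= nd.dup_time <= top + 1e-9
        assert seen_dup > 50  # the rate grid must actually exercise duplications

    def test_losses_prune_species(self):
        S = quartet_species_tree("balanced")
        rng = random.Random(5)
        lost_some = False
        for _ in range(200):
            hist = simulate_locus_tree(S, GDLParams(0.0, 0.8, 1.0), rng)
            if hist.extinct:
                lost_some = True
                continue
            species = set(hist.locus_tree.species_of.values())
            lost_some = lost_some or species != {"A", "B", "C", "D"}
        assert lost_some

    def test_root_lineage_indices_cover_surviving_leaves(self):
        S = quartet_species_tree("balanced")
        rng = random.Random(12)
        for _ in range(100):
            hist = simulate_locus_tree(S, GDLParams(0.5, 0.3, 2.0), rng)
            if hist.extinct:
                continue
            labels = set(hist.locus_tree.tree.leaf_labels())
            assert set(hist.root_lineage_of) == labels
            assert all(1 <= i <= hist.l for i in hist.root_lineage_of.values())

    def test_seeded_determinism(self):
        S = quartet_species_tree("caterpillar")
        a = simulate_locus_tree(S, GDLParams(0.3, 0.3, 1.0), make_rng(7, "locus", 0))
        b = simulate_locus_tree(S, GDLParams(0.3, 0.3, 1.0), make_rng(7, "locus", 0))
        assert write_newick(a.locus_tree.tree, "nhx-dup") == write_newick(
            b.locus_tree.tree, "nhx-dup"
        )
        assert a.root_lineage_of == b.root_lineage_of


class TestBoundedCoalescent:
    def test_single_leaf_locus(self):
        L = LocusTree(PhyloTree(Node("A_1", 1.0)), {"A_1": "A"})
        G = simulate_gene_tree_bmsc(L, 3)
        assert G.tree.leaf_labels() == ["A_1"]

    def test_unbounded_matches_closed_form(self):
        p = CaseParams("balanced", 0.6, 0.9)
        L = locus_tree_from_case(p)
        cf = quartet_probs(p)
        rng = random.Random(31)
        n = 20000
        hits = 0
        for _ in range(n):
            G = simulate_gene_tree_bmsc(L, rng)
            hits += quartet_topology(G.tree, ("a", "b", "c", "d")) == 0
        f = hits / n
        se = math.sqrt(cf.p_match * (1 - cf.p_match) / n)
        assert abs(f - cf.p_match) < 4 * se

    def test_internal_duplication_forces_match_every_time(self):
        p = CaseParams("caterpillar", 1.0, 1.0, dup_case="dup_on_X")
        L = locus_tree_from_case(p)
        rng = random.Random(8)
        for _ in range(500):
            G = simulate_gene_tree_bmsc(L, rng)
            assert quartet_topology(G.tree, ("a", "b", "c", "d")) == 0

    def test_exact_and_rejection_methods_agree(self):
        p = CaseParams("balanced", 0.5, 0.5, t=1.0, dup_case="dup_on_root_edge")
        L = locus_tree_from_case(p)
        n = 6000
        counts = {}
        for method, seed in (("exact", 100), ("rejection", 200)):
            rng = random.Random(seed)
            c = Counter(
                quartet_topology(
                    simulate_gene_tree_bmsc(L, rng, method=method).tree,
                    ("a", "b", "c", "d"),
                )
                for _ in range(n)
            )
            counts[method] = c
        for qt in (0, 1, 2):
            fa = counts["exact"][qt] / n
            fb = counts["rejection"][qt] / n
            se = math.sqrt(2 * 0.25 / n)
            assert abs(fa - fb) < 4 * se

    def test_gene_tree_is_ultrametric_and_complete(self):
        S = quartet_species_tree("balanced")
        rng = random.Random(77)
        for _ in range(50):
            hist = simulate_locus_tree(S, GDLParams(0.4, 0.4, 1.5), rng)
            if hist.extinct:
                continue
            G = simulate_gene_tree_bmsc(hist, rng)
            G.tree.heights()  # raises if leaves are not aligned
            assert sorted(G.tree.leaf_labels()) == sorted(
                hist.locus_tree.tree.leaf_labels()
            )

    def test_generator_output_always_satisfies_bounds(self):
        S = quartet_species_tree("balanced")
        for lam, mu in ((0.1, 0.1), (0.3, 0.3), (0.5, 0.2)):
            rng = make_rng(13, "bounds", lam, mu)
            checked = 0
            for _ in range(400):
                hist = simulate_locus_tree(S, GDLParams(lam, mu, 1.0), rng)
                if hist.extinct:
                    continue
                G = simulate_gene_tree_bmsc(hist, rng)
                ok, violations = validate_bounds(G, hist)
                assert ok, violations
                checked += 1
            assert checked > 200

    def test_seeded_determinism(self):
        p = CaseParams("caterpillar", 0.5, 1.0, t=0.8, dup_case="dup_on_Y")
        L = locus_tree_from_case(p)
        a = simulate_gene_tree_bmsc(L, make_rng(3, "g"))
        b = simulate_gene_tree_bmsc(L, make_rng(3, "g"))
        assert write_newick(a.tree) == write_newick(b.tree)

    def test_impossible_bound_raises(self):
        # dup-point below the cherry that must coalesce under it
        s = "((a:1,b:1):1[&&NHX:DUPTIME=0.5],(c:1,d:1):1):1;"
        t = parse_newick(s, dialect="nhx-dup")
        L = LocusTree(t, {l: l.upper() for l in t.leaf_labels()})
        with pytest.raises(BoundRejectionError):
            simulate_gene_tree_bmsc(L, 1, method="exact")

    def test_sampler_reuse_matches_one_shot(self):
        p = CaseParams("balanced", 1.0, 1.0, t=0.5, dup_case="dup_on_root_edge")
        L = locus_tree_from_case(p)
        sampler = BmscSampler(L.tree)
        a = sampler.sample(random.Random(5))
        b = simulate_gene_tree_bmsc(L, random.Random(5), method="exact")
        assert write_newick(PhyloTree(a)) == write_newick(b.tree)


class TestValidateBounds:
    def _toy_locus(self):
        s = "((a:1,b:1):1[&&NHX:DUPTIME=1.5],(c:1,d:1):1):1;"
        t = parse_newick(s, dialect="nhx-dup")
        return LocusTree(t, {l: l.upper() for l in t.leaf_labels()})

    def test_hand_built_violation_detected(self):
        L = self._toy_locus()
        # a and b only meet at height 3 > 1.5: violates the bound
        g = parse_newick("((a:2,c:2):1,(b:2,d:2):1):0;")
        G = GeneTree(g, {l: l.upper() for l in g.leaf_labels()},
                     {l: l for l in g.leaf_labels()})
        ok, violations = validate_bounds(G, L)
        assert not ok
        assert len(violations) == 1
        assert violations[0][0] == frozenset({"a", "b"})

    def test_no_duplication_points_vacuously_true(self):
        s = "((a:1,b:1):1,(c:1,d:1):1):1;"
        t = parse_newick(s)
        L = LocusTree(t, {l: l.upper() for l in t.leaf_labels()})
        G = simulate_gene_tree_bmsc(L, 4)
        ok, violations = validate_bounds(G, L)
        assert ok and not violations

    def test_leaf_mismatch_rejected(self):
        L = self._toy_locus()
        g = parse_newick("((a:1,b:1):1,(c:1,x:1):1):0;")
        G = GeneTree(g, {l: l.upper() for l in g.leaf_labels()},
                     {l: l for l in g.leaf_labels()})
        with pytest.raises(ValueError):
            validate_bounds(G, L)


class TestScenarioClassification:
    def _hist(self, indices, l):
        leaves = {f"{sp}_1": idx for sp, idx in indices.items()}
        return LocusHistory(None, l, leaves)

    def test_all_same_lineage(self):
        h = self._hist({"A": 1, "B": 1, "C": 1, "D": 1}, 1)
        s = classify_scenario(h, {"a": "A_1", "b": "B_1", "c": "C_1", "d": "D_1"})
        assert s.kind == "(abcd)"

    def test_paired_lineages(self):
        h = self._hist({"A": 1, "B": 1, "C": 2, "D": 2}, 2)
        s = classify_scenario(h, {"a": "A_1", "b": "B_1", "c": "C_1", "d": "D_1"})
        assert s.kind == "(ab,cd)"
        assert s.partition == frozenset(
            {frozenset({"a", "b"}), frozenset({"c", "d"})}
        )

    def test_all_distinct(self):
        h = self._hist({"A": 1, "B": 2, "C": 3, "D": 4}, 4)
        s = classify_scenario(h, {"a": "A_1", "b": "B_1", "c": "C_1", "d": "D_1"})
        assert s.kind == "(a,b,c,d)"

    def test_missing_gene_errors(self):
        h = self._hist({"A": 1, "B": 1, "C": 1, "D": 1}, 1)
        with pytest.raises(KeyError):
            classify_scenario(h, {"a": "E_1", "b": "B_1", "c": "C_1", "d": "D_1"})
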