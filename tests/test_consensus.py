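"""Consensus trees, SPR distance, anticonsensus and CI/RI fit."""

import numpy as np
import pytest

from mrpforge import (BinaryMatrix, anticonsensus, character_fit,
                      fitch_score, frequency_difference_consensus,
                      semistrict_consensus, spr_distance, spr_distance_exact,
                      strict_consensus)
from mrpforge.errors import TaxonMismatchError
from mrpforge.trees import Topology, rf_distance

from conftest import brute_force_steps, random_binary_tree

T = Topology.from_newick


class TestStrictConsensus:
    def test_only_shared_clade_survives(self):
        out = strict_consensus([T("((A,B),(C,D));"), T("(((A,B),C),D);")])
        assert out.clades() == {frozenset("AB")}

    def test_single_tree_is_its_own_consensus(self):
        t = T("((A,B),(C,D));")
        assert strict_consensus([t]) == t

    def test_incompatible_trees_collapse_to_star(self):
        out = strict_consensus([T("((A,B),(C,D));"), T("((A,C),(B,D));")])
        assert out.n_informative_nodes() == 0

    def test_leaf_set_mismatch_rejected(self):
        with pytest.raises(TaxonMismatchError):
            strict_consensus([T("((A,B),C);"), T("((A,B),D);")])


class TestSemistrictConsensus:
    def test_uncontradicted_clade_included(self):
        out = semistrict_consensus([T("((A,B),(C,D));"), T("((A,B),C,D);")])
        assert out == T("((A,B),(C,D));")

    def test_stars_stay_star(self):
        out = semistrict_consensus([T("(A,B,C,D);"), T("(A,B,C,D);")])
        assert out.n_informative_nodes() == 0

    def test_contains_strict_on_random_sets(self, rng):
        taxa = [f"L{i}" for i in range(8)]
        for _ in range(10):
            trees = [random_binary_tree(taxa, rng) for _ in range(4)]
            strict = strict_consensus(trees).clades()
            semi = semistrict_consensus(trees).clades()
            assert strict <= semi


class TestFrequencyDifferenceConsensus:
    def test_majority_beats_rival(self):
        trees = [T("((A,B),(C,D));")] * 10 + [T("((A,C),(B,D));")] * 4
        out = frequency_difference_consensus(trees)
        assert frozenset("AB") in out.clades()

    def test_tied_rivals_both_excluded(self):
        trees = [T("((A,B),(C,D));")] * 7 + [T("((A,C),(B,D));")] * 7
        out = frequency_difference_consensus(trees)
        assert out.n_informative_nodes() == 0

    def test_identical_trees_reduce_to_strict(self):
        trees = [T("(((A,B),C),D);")] * 5
        assert frequency_difference_consensus(trees) \
            == strict_consensus(trees)


class TestSprDistance:
    def test_identical_trees(self):
        r = spr_distance(T("((A,B),(C,D));"), T("(D,C,B,A);"))
        # unrooted, the star differs; use truly identical shapes instead
        r = spr_distance(T("((A,B),(C,D));"), T("(((A,B),C),D);"))
        assert r.d_spr == 0 and r.similarity_pct == 100.0

    def test_one_spr_apart(self):
        t1 = T("(((A,B),C),(D,E));")
        t2 = T("(((A,C),B),(D,E));")   # move B: one SPR
        r = spr_distance(t1, t2)
        assert r.d_spr == 1

    def test_symmetry_and_similarity_monotonicity(self, rng):
        taxa = [f"L{i}" for i in range(6)]
        pairs = [(random_binary_tree(taxa, rng), random_binary_tree(taxa, rng))
                 for _ in range(5)]
        for a, b in pairs:
            ra, rb = spr_distance(a, b), spr_distance(b, a)
            assert ra.d_spr == rb.d_spr
            assert ra.similarity_pct == 100 * (1 - ra.d_spr / 3)

    def test_heuristic_bound_dominates_exact(self, rng):
        from mrpforge.consensus_compare import _greedy_agreement_bound
        taxa = [f"L{i}" for i in range(6)]
        for _ in range(30):
            a = random_binary_tree(taxa, rng).unroot()
            b = random_binary_tree(taxa, rng).unroot()
            exact = spr_distance_exact(a, b)
            bound = _greedy_agreement_bound(a, b)
            assert bound >= exact
            if exact <= 1:
                assert spr_distance(a, b).d_spr == exact

    def test_large_trees_flagged_approximate(self, rng):
        taxa = [f"L{i}" for i in range(12)]
        a, b = (random_binary_tree(taxa, rng) for _ in range(2))
        if a.unroot() == b.unroot():
            pytest.skip("random pair coincided")
        r = spr_distance(a, b)
        assert r.approximate and r.d_spr >= 1


class TestRfDistance:
    def test_metric_properties_spot_check(self, rng):
        taxa = [f"L{i}" for i in range(7)]
        a, b, c = (random_binary_tree(taxa, rng).unroot() for _ in range(3))
        assert rf_distance(a, a) == 0
        assert rf_distance(a, b) == rf_distance(b, a)
        assert rf_distance(a, c) <= rf_distance(a, b) + rf_distance(b, c)

    def test_agrees_with_dendropy(self, rng):
        import dendropy
        from dendropy.calculate import treecompare
        taxa = [f"L{i}" for i in range(9)]
        ns = dendropy.TaxonNamespace()
        for _ in range(10):
            a = random_binary_tree(taxa, rng).unroot()
            b = random_binary_tree(taxa, rng).unroot()
            da = dendropy.Tree.get(data=a.to_newick(), schema="newick",
                                   taxon_namespace=ns)
            db = dendropy.Tree.get(data=b.to_newick(), schema="newick",
                                   taxon_namespace=ns)
            assert rf_distance(a, b) == treecompare.symmetric_difference(da, db)


class TestAnticonsensus:
    def test_identical_trees_empty(self):
        t = T("((A,B),(C,D));")
        assert anticonsensus(t, t) == ((), ())

    def test_conflicting_cherries_reported_both_ways(self):
        a, b = anticonsensus(T("((A,B),(C,D));"), T("((A,C),(B,D));"))
        assert set(a) == {frozenset("AB"), frozenset("CD")}
        assert set(b) == {frozenset("AC"), frozenset("BD")}

    def test_star_contradicts_nothing(self):
        a, b = anticonsensus(T("((A,B),(C,D));"), T("(A,B,C,D);"))
        assert a == () and b == ()


class TestCharacterFit:
    TREE6 = T("(((A,B),(C,D)),(E,F));")

    def test_exact_clade_character(self):
        m = BinaryMatrix.from_symbols("ABCDEF", list("110000"))
        recs, ci, ri = character_fit(self.TREE6, m)
        assert recs[0].s == 1 and recs[0].ci == 1.0 and recs[0].ri == 1.0

    def test_ci_min_is_one_over_n(self):
        m = BinaryMatrix.from_symbols("ABCDEF", list("111110"))
        recs, _, _ = character_fit(self.TREE6, m)
        assert recs[0].n_scored == 5 and recs[0].ci_min == pytest.approx(0.2)

    def test_homoplastic_character(self):
        # A, C, E scored 1: three separate origins on the reference tree
        m = BinaryMatrix.from_symbols("ABCDEF", list("101010"))
        recs, _, _ = character_fit(self.TREE6, m)
        states = dict(zip("ABCDEF", [1, 0, 1, 0, 1, 0]))
        expected = brute_force_steps(self.TREE6, states)
        assert recs[0].s == expected
        assert recs[0].ci == pytest.approx(1 / expected)
        assert recs[0].ri == pytest.approx((3 - expected) / (3 - 1))

    def test_constant_character_excluded_from_ensemble(self):
        m = BinaryMatrix.from_symbols("ABCDEF", ["11", "11", "10", "10",
                                                 "10", "10"])
        recs, ci, _ = character_fit(self.TREE6, m)
        assert not recs[0].defined   # the all-1 column
        assert ci == 1.0             # only the clade-like column counts

    def test_ci_never_below_ci_min_random(self, rng):
        taxa = [f"L{i}" for i in range(10)]
        tree = random_binary_tree(taxa, rng)
        for _ in range(200):
            col = rng.integers(0, 2, size=10)
            if col.sum() in (0, 10):
                continue
            m = BinaryMatrix.from_symbols(taxa, [str(x) for x in col])
            recs, _, _ = character_fit(tree, m)
            r = recs[0]
            if r.defined:
                assert r.ci >= r.ci_min - 1e-12

    def test_ensembles_combine_sums(self, rng):
        taxa = list("ABCDEF")
        m = BinaryMatrix.from_symbols(taxa, ["11", "10", "01", "01",
                                             "10", "00"])
        recs, ci, ri = character_fit(self.TREE6, m)
        sm = sum(r.m for r in recs if r.defined)
        ss = sum(r.s for r in recs if r.defined)
        sg = sum(r.g for r in recs if r.defined)
        assert ci == pytest.approx(sm / ss)
        assert ri == pytest.approx((sg - ss) / (sg - sm))
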