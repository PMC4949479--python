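"""Fitch scoring against brute-force and dendropy oracles; MP searches."""

import numpy as np
import pytest

from mrpforge import (BinaryMatrix, OUTGROUP, SearchConfig, char_step_bounds,
                      code_tree, exhaustive_search, fitch_score,
                      heuristic_search, write_matrix)
from mrpforge.errors import SearchError, TaxonMismatchError
from mrpforge.matrix_rep import apply_rooting_all
from mrpforge.trees import Topology

from conftest import (all_unrooted_topologies, brute_force_steps,
                      random_binary_tree)


def _random_matrix(taxa, n_chars, rng, missing=0.0):
    symbols = np.array(["0", "1", "?"])
    probs = [(1 - missing) / 2, (1 - missing) / 2, missing]
    rows = ["".join(rng.choice(symbols, p=probs)) for _ in range(n_chars)]
    grid = ["".join(rng.choice(symbols, p=probs) for _ in range(n_chars))
            for _ in taxa]
    del rows
    return BinaryMatrix.from_symbols(taxa, grid)


class TestFitchScore:
    def test_single_origin_character(self):
        m = BinaryMatrix.from_symbols("ABCD", ["1", "1", "0", "0"])
        assert fitch_score(Topology.from_newick("((A,B),(C,D));"), m) == 1

    def test_two_origins_forced(self):
        m = BinaryMatrix.from_symbols("ABCD", ["1", "1", "0", "0"])
        assert fitch_score(Topology.from_newick("((A,C),(B,D));"), m) == 2

    def test_all_missing_scores_zero(self):
        m = BinaryMatrix.from_symbols("ABCD", ["?", "?", "?", "?"])
        assert fitch_score(Topology.from_newick("((A,B),(C,D));"), m) == 0

    def test_taxon_mismatch_reports_difference(self):
        m = BinaryMatrix.from_symbols("ABCE", ["1", "1", "0", "0"])
        with pytest.raises(TaxonMismatchError):
            fitch_score(Topology.from_newick("((A,B),(C,D));"), m)

    def test_matches_brute_force_on_random_trees(self, rng):
        taxa = [f"L{i}" for i in range(7)]
        for _ in range(15):
            t = random_binary_tree(taxa, rng)
            m = _random_matrix(taxa, 4, rng, missing=0.2)
            total = 0
            for j in range(m.n_chars):
                states = {tx: (None if m.states[i, j] < 0
                               else int(m.states[i, j]))
                          for i, tx in enumerate(taxa)}
                total += brute_force_steps(t, states)
            assert fitch_score(t, m) == total

    def test_matches_brute_force_with_polytomies(self, rng):
        t = Topology.from_newick("((A,B,C),(D,E),F);")
        m = _random_matrix(sorted(t.leaves), 6, rng, missing=0.15)
        total = sum(
            brute_force_steps(t, {tx: (None if m.states[i, j] < 0
                                       else int(m.states[i, j]))
                                  for i, tx in enumerate(m.taxa)})
            for j in range(m.n_chars))
        assert fitch_score(t, m) == total

    def test_matches_dendropy_fitch(self, rng):
        import dendropy
        from dendropy.model import parsimony as dp

        taxa = [f"T{i}" for i in range(8)]
        for _ in range(5):
            tree = random_binary_tree(taxa, rng)
            m = _random_matrix(taxa, 10, rng, missing=0.1)
            ns = dendropy.TaxonNamespace()
            data = dendropy.StandardCharacterMatrix.get(
                data=write_matrix(m, "nexus"), schema="nexus",
                taxon_namespace=ns)
            dtree = dendropy.Tree.get(data=tree.to_newick(), schema="newick",
                                      taxon_namespace=ns)
            tsm = data.taxon_state_sets_map(gaps_as_missing=True)
            score = dp.fitch_down_pass(dtree.postorder_node_iter(),
                                       taxon_state_sets_map=tsm)
            assert fitch_score(tree, m) == score

    def test_invariant_under_rerooting(self, rng):
        taxa = [f"L{i}" for i in range(8)]
        t = random_binary_tree(taxa, rng)
        m = _random_matrix(taxa, 12, rng, missing=0.2)
        base = fitch_score(t, m)
        u = t.unroot()
        assert fitch_score(u, m) == base
        for leaf in list(taxa)[:3]:
            r = u.root_at_leaf(leaf, remove=False)
            assert fitch_score(r, m) == base

    def test_weight_zero_character_never_changes_score(self, rng):
        taxa = [f"L{i}" for i in range(6)]
        t = random_binary_tree(taxa, rng)
        m = _random_matrix(taxa, 8, rng)
        w = m.weights.copy()
        w[3] = 0
        diff = fitch_score(t, m.with_weights(w))
        _, steps = fitch_score(t, m, per_character=True)
        assert diff == fitch_score(t, m) - int(steps[3])

    def test_weight_scaling_scales_score(self, rng):
        taxa = [f"L{i}" for i in range(6)]
        t = random_binary_tree(taxa, rng)
        m = _random_matrix(taxa, 8, rng)
        assert fitch_score(t, m.with_weights(m.weights * 7)) \
            == 7 * fitch_score(t, m)


class TestStepBounds:
    @pytest.mark.parametrize("column,expected", [
        ([1, 1, 0, 0, 0], (1, 2)),
        ([1, 0], (1, 1)),
        ([1, 1, -1, -1], (0, 0)),      # constant among observed
        ([0, 0, 0], (0, 0)),
        ([1, 1, 1, 0, 0, 0, 0], (1, 3)),
    ])
    def test_bounds(self, column, expected):
        assert char_step_bounds(np.array(column)) == expected


class TestExhaustiveSearch:
    def test_mrp_identity_four_taxa(self):
        t = Topology.from_newick("((A,B),(C,D));")
        m = apply_rooting_all(code_tree(t, sorted(t.leaves)))
        res = exhaustive_search(m)
        assert res.exhausted and res.best_score == 2
        mp = [x.root_at_leaf(OUTGROUP) for x in res.mp_trees]
        assert mp == [t]

    def test_optimum_matches_independent_enumeration(self, rng):
        taxa = [f"X{i}" for i in range(5)]
        m = _random_matrix(taxa, 8, rng)
        res = exhaustive_search(m)
        scores = {fitch_score(t, m) for t in all_unrooted_topologies(taxa)}
        assert res.best_score == min(scores)
        assert len(res.mp_trees) == sum(
            1 for t in all_unrooted_topologies(taxa)
            if fitch_score(t, m) == res.best_score)

    def test_refuses_large_taxon_sets(self, rng):
        taxa = [f"X{i}" for i in range(11)]
        with pytest.raises(SearchError):
            exhaustive_search(_random_matrix(taxa, 3, rng))


class TestHeuristicSearch:
    def test_mrp_identity_twenty_taxa(self, rng):
        taxa = [f"P{i:02d}" for i in range(20)]
        t = random_binary_tree(taxa, rng)
        m = apply_rooting_all(code_tree(t, taxa))
        res = heuristic_search(m, SearchConfig(n_addition_replicates=5,
                                               swap="spr", seed=11))
        assert res.best_score == m.n_chars
        assert [x.root_at_leaf(OUTGROUP) for x in res.mp_trees] == [t]

    def test_compatible_sources_give_perfect_supertree(self, rng):
        # two clade-compatible source trees on overlapping taxa
        full = Topology.from_newick("(((A,B),(C,D)),((E,F),G));")
        s1 = full.restrict("ABCDE")
        s2 = full.restrict("CDEFG")
        from mrpforge.matrix_rep import build_merged_matrix
        from mrpforge.treeio import SourceRecord
        sources = [
            SourceRecord("s1", "tree", "genomic_tree", True, tree=s1),
            SourceRecord("s2", "tree", "mtdna_tree", True, tree=s2)]
        m = apply_rooting_all(build_merged_matrix(sources))
        res = heuristic_search(m, SearchConfig(n_addition_replicates=5,
                                               swap="spr", seed=3))
        assert res.best_score == m.n_chars  # every source clade displayed
        sup = res.mp_trees[0].root_at_leaf(OUTGROUP)
        for src in (s1, s2):
            restricted = sup.restrict(src.leaves)
            assert src.clades() <= restricted.clades(include_root=True)

    def test_never_beats_exhaustive_and_usually_matches(self, rng):
        taxa = [f"X{i}" for i in range(8)]
        hits = 0
        for seed in range(20):
            m = _random_matrix(taxa, 15, np.random.default_rng(seed + 100))
            ex = exhaustive_search(m)
            h = heuristic_search(m, SearchConfig(n_addition_replicates=5,
                                                 swap="tbr", seed=seed))
            assert h.best_score >= ex.best_score
            hits += h.best_score == ex.best_score
        assert hits >= 19

    def test_deterministic_given_seed(self, rng):
        taxa = [f"X{i}" for i in range(9)]
        m = _random_matrix(taxa, 12, rng)
        cfg = SearchConfig(n_addition_replicates=4, swap="spr", seed=17)
        a = heuristic_search(m, cfg)
        b = heuristic_search(m, cfg)
        assert a.best_score == b.best_score and a.mp_trees == b.mp_trees

    def test_mp_set_complete_on_ambiguous_matrix(self, rng):
        # a matrix with one character cannot separate ties: plateau search
        # must recover every optimum found by exhaustive enumeration
        taxa = [f"X{i}" for i in range(6)]
        m = _random_matrix(taxa, 3, np.random.default_rng(5))
        ex = exhaustive_search(m)
        h = heuristic_search(m, SearchConfig(n_addition_replicates=8,
                                             swap="spr", seed=0,
                                             max_trees_retained=2000))
        assert h.best_score == ex.best_score
        assert set(h.mp_trees) == set(ex.mp_trees)

    def test_ratchet_runs_and_stays_optimal(self, rng):
        taxa = [f"X{i}" for i in range(7)]
        m = _random_matrix(taxa, 10, rng)
        ex = exhaustive_search(m)
        h = heuristic_search(m, SearchConfig(n_addition_replicates=2,
                                             swap="spr", seed=1,
                                             ratchet_iterations=2))
        assert h.best_score >= ex.best_score
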