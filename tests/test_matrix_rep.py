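"""Baum–Ragan tree coding, admixture coding, merging, rooting, weighting."""

import numpy as np
import pytest

from mrpforge import (AdmixtureCodingConfig, OUTGROUP, QMatrix, SourceRecord,
                      apply_rooting, apply_weights, code_admixture, code_tree,
                      exhaustive_search, implied_admixture_tree, merge)
from mrpforge.errors import ValidationError
from mrpforge.matrix import INAPPLICABLE, STATE0, STATE1, UNKNOWN
from mrpforge.trees import Topology

from conftest import random_binary_tree


def _char_as_dict(matrix, j):
    return dict(zip(matrix.taxa, matrix.states[:, j]))


class TestCodeTree:
    def test_single_clade_with_absent_taxon(self):
        t = Topology.from_newick("((A,B),C);")
        m = code_tree(t, ["A", "B", "C", "D"])
        assert m.n_chars == 1
        assert _char_as_dict(m, 0) == {"A": STATE1, "B": STATE1,
                                       "C": STATE0, "D": INAPPLICABLE}

    def test_nested_clades(self):
        t = Topology.from_newick("(((A,B),C),D);")
        m = code_tree(t, ["A", "B", "C", "D"])
        ones = {frozenset(t for t in m.taxa
                          if m.states[m.taxon_index(t), j] == STATE1)
                for j in range(m.n_chars)}
        assert ones == {frozenset("AB"), frozenset("ABC")}

    def test_unrooted_star_codes_nothing(self):
        t = Topology.from_newick("(A,B,C);", rooted=False)
        assert code_tree(t, "ABC").n_chars == 0

    def test_tiny_tree_warns_not_errors(self):
        t = Topology.from_newick("(A,B);")
        with pytest.warns(UserWarning):
            m = code_tree(t, "AB")
        assert m.n_chars == 0

    def test_rooted_binary_yields_n_minus_2_characters(self, rng):
        for n in (4, 7, 12, 20):
            t = random_binary_tree([f"L{i}" for i in range(n)], rng)
            assert code_tree(t, sorted(t.leaves)).n_chars == n - 2

    def test_unrooted_binary_yields_n_minus_3_characters(self, rng):
        t = random_binary_tree([f"L{i}" for i in range(10)], rng).unroot()
        assert code_tree(t, sorted(t.leaves)).n_chars == 7


class TestCodeAdmixture:
    ROWS = np.array([[0.95, 0.05], [0.90, 0.10], [0.12, 0.88], [0.50, 0.50]])

    def test_crisp_ten_percent_rule(self):
        q = QMatrix(("t1", "t2", "t3", "t4"), self.ROWS)
        m = code_admixture(q, AdmixtureCodingConfig(), q.taxa)
        assert m.symbol_column(0) == "1111"
        assert m.symbol_column(1) == "0111"

    def test_borderline_band_codes_unknown(self):
        q = QMatrix(("t1", "t2", "t3", "t4"), self.ROWS)
        cfg = AdmixtureCodingConfig(0.10, (0.05, 0.15))
        m = code_admixture(q, cfg, q.taxa)
        assert m.states[0, 1] == UNKNOWN      # 0.05 in band
        assert m.states[2, 0] == UNKNOWN      # 0.12 in band
        assert m.states[3, 0] == STATE1

    def test_constant_cluster_flagged_uninformative(self):
        q = QMatrix(("a", "b", "c"),
                    np.array([[0.95, 0.05], [0.96, 0.04], [0.97, 0.03]]))
        m = code_admixture(q, AdmixtureCodingConfig(), q.taxa)
        assert m.symbol_column(1) == "000"
        assert not m.informative_mask()[1]

    def test_absent_universe_taxa_inapplicable(self):
        q = QMatrix(("a", "b", "c"),
                    np.array([[0.9, 0.1], [0.2, 0.8], [0.15, 0.85]]))
        m = code_admixture(q, AdmixtureCodingConfig(), ["a", "b", "c", "d"])
        assert m.states[3, 0] == INAPPLICABLE


class TestImpliedAdmixtureTree:
    def test_perfect_split_recovered(self):
        q = QMatrix(("A", "B", "C", "D"),
                    np.array([[0.98, 0.02], [0.97, 0.03],
                              [0.03, 0.97], [0.02, 0.98]]))
        t = implied_admixture_tree(q, AdmixtureCodingConfig())
        assert frozenset("AB") in t.clades() or frozenset("CD") in t.clades()

    def test_uninformative_plot_gives_star(self):
        q = QMatrix(("A", "B", "C"),
                    np.array([[0.9, 0.1], [0.2, 0.8], [0.3, 0.7]]))
        t = implied_admixture_tree(q, AdmixtureCodingConfig())
        assert t.n_informative_nodes() <= 1

    def test_nested_plots_combine_to_displayed_tree(self):
        # K=2 and K=3 cuts of ((A,B),(C,(D,E))), coded and searched together
        true = Topology.from_newick("((A,B),(C,(D,E)));")
        taxa = sorted(true.leaves)

        def crisp(parts):
            rows = []
            for t in taxa:
                own = next(i for i, p in enumerate(parts) if t in p)
                row = np.full(len(parts), 0.01 / (len(parts) - 1))
                row[own] = 0.99
                rows.append(row)
            return QMatrix(tuple(taxa), np.array(rows))

        q2 = crisp([set("AB"), set("CDE")])
        q3 = crisp([set("AB"), set("C"), set("DE")])
        cfg = AdmixtureCodingConfig()
        merged = merge([code_admixture(q2, cfg, taxa, source_id="k2"),
                        code_admixture(q3, cfg, taxa, source_id="k3")])
        from mrpforge.matrix_rep import apply_rooting_all
        res = exhaustive_search(apply_rooting_all(
            merged.select_chars(merged.informative_mask())))
        mp = [t.root_at_leaf(OUTGROUP) for t in res.mp_trees]
        assert all({frozenset("AB"), frozenset("DE")} <= t.clades()
                   for t in mp)


class TestMerge:
    def test_union_of_taxa_with_missing_fill(self):
        m1 = code_tree(Topology.from_newick("((A,B),C);"), "ABC",
                       source_id="s1")
        m2 = code_tree(Topology.from_newick("((B,C),D);"), "BCD",
                       source_id="s2")
        merged = merge([m1, m2])
        assert merged.taxa == ("A", "B", "C", "D")
        j = merged.provenance.index(m2.provenance[0])
        assert merged.states[0, j] == INAPPLICABLE  # A absent from s2

    def test_order_invariance(self):
        m1 = code_tree(Topology.from_newick("((A,B),C);"), "ABC",
                       source_id="s1")
        m2 = code_tree(Topology.from_newick("((B,C),D);"), "BCD",
                       source_id="s2")
        assert merge([m1, m2]) == merge([m2, m1])

    def test_self_merge_doubles_columns(self):
        m = code_tree(Topology.from_newick("(((A,B),C),D);"), "ABCD")
        mm = merge([m, m])
        assert mm.n_chars == 2 * m.n_chars

    def test_merge_never_changes_states(self):
        m1 = code_tree(Topology.from_newick("((A,B),C);"), "ABC",
                       source_id="s1")
        merged = merge([m1])
        assert merged.symbol_rows() == m1.sorted_columns().symbol_rows()

    def test_empty_input_rejected(self):
        with pytest.raises(ValidationError):
            merge([])


def _sources_fixture():
    lang = SourceRecord("lang1", "tree", "language_tree", rooted=True,
                        tree=Topology.from_newick("((A,B),C);"))
    mtdna = SourceRecord("mt1", "tree", "mtdna_tree", rooted=True,
                         tree=Topology.from_newick("((A,C),D);"))
    genomic = SourceRecord("gen1", "tree", "genomic_tree", rooted=True,
                           has_hominin_outgroup=True,
                           tree=Topology.from_newick("((B,C),D);"))
    unrooted = SourceRecord("hla1", "tree", "hla_tree", rooted=False,
                            tree=Topology.from_newick("((A,B),C,D);",
                                                      rooted=False))
    q = QMatrix(("A", "B", "C", "D"),
                np.array([[0.9, 0.1], [0.8, 0.2], [0.1, 0.9], [0.2, 0.8]]))
    admix = SourceRecord("adm1", "admixture", "admixture_genomic",
                         rooted=False, qmatrix=q)
    return [lang, mtdna, genomic, unrooted, admix]


class TestRooting:
    @pytest.fixture
    def coded(self):
        sources = _sources_fixture()
        from mrpforge.matrix_rep import build_merged_matrix
        return sources, build_merged_matrix(sources)

    def _all0_states(self, matrix):
        row = matrix.taxon_index(OUTGROUP)
        by_source = {}
        for j, (sid, _) in enumerate(matrix.provenance):
            by_source.setdefault(sid, set()).add(int(matrix.states[row, j]))
        return by_source

    def test_scheme_a_roots_trees_and_plots(self, coded):
        sources, base = coded
        states = self._all0_states(apply_rooting(base, sources, "A"))
        assert states["lang1"] == {STATE0}
        assert states["adm1"] == {STATE0}
        assert states["hla1"] == {UNKNOWN}   # unrooted source stays unrooted

    def test_scheme_b_roots_only_rooted_trees(self, coded):
        sources, base = coded
        states = self._all0_states(apply_rooting(base, sources, "B"))
        assert states["lang1"] == {STATE0}
        assert states["adm1"] == {UNKNOWN}

    def test_scheme_c_roots_only_genetic_trees(self, coded):
        sources, base = coded
        states = self._all0_states(apply_rooting(base, sources, "C"))
        assert states["lang1"] == {UNKNOWN}
        assert states["mt1"] == {STATE0}

    def test_scheme_d_requires_hominin_outgroup(self, coded):
        sources, base = coded
        states = self._all0_states(apply_rooting(base, sources, "D"))
        assert states["gen1"] == {STATE0}
        assert states["mt1"] == {UNKNOWN}

    def test_unknown_scheme_rejected(self, coded):
        sources, base = coded
        with pytest.raises(ValidationError):
            apply_rooting(base, sources, "E")


class TestWeights:
    @pytest.fixture
    def base(self):
        sources = _sources_fixture()
        from mrpforge.matrix_rep import build_merged_matrix
        return build_merged_matrix(sources)

    def _weights_by_partition(self, m):
        out = {}
        for j, p in enumerate(m.partitions):
            out.setdefault(p, set()).add(int(m.weights[j]))
        return out

    def test_scheme_1_all_equal(self, base):
        assert set(apply_weights(base, 1).weights) == {1}

    def test_scheme_2_trees_over_plots(self, base):
        w = self._weights_by_partition(apply_weights(base, 2))
        assert w["language_tree"] == {1000}
        assert w["admixture_genomic"] == {1}

    def test_scheme_3_genetic_over_language_and_plots(self, base):
        w = self._weights_by_partition(apply_weights(base, 3))
        assert w["mtdna_tree"] == {1000}
        assert w["language_tree"] == {1}

    def test_scheme_4_genomic_over_everything(self, base):
        w = self._weights_by_partition(apply_weights(base, 4))
        assert w["genomic_tree"] == {1000}
        assert w["hla_tree"] == {1}

    def test_deactivation_zeroes_low_class(self, base):
        w = self._weights_by_partition(apply_weights(base, 3,
                                                     deactivate=True))
        assert w["language_tree"] == {0}
        assert w["admixture_genomic"] == {0}
        assert w["mtdna_tree"] == {1000}

    def test_weights_preserve_states_and_count(self, base):
        m = apply_weights(base, 4)
        assert m.n_chars == base.n_chars
        assert m.symbol_rows() == base.symbol_rows()
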