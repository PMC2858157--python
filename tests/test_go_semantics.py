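"""Information content, semantic similarity, cluster validity, enrichment."""

import itertools
import math

import numpy as np
import pytest

from trnmotif.clustering import ClusterSet
from trnmotif.data_io import AnnotationSet, Ontology
from trnmotif.go_semantics import (GeneSimilarity, enrichment,
                                   gene_similarity, information_content,
                                   partition_validity,
                                   select_from_clustersets, term_similarity)

# hand-derived annotation frequencies for the toy DAG fixture
P = {"R": 1.0, "A": 0.7, "B": 0.5, "C": 0.3, "D": 0.3, "E": 0.2}
IC = {t: -math.log(p) for t, p in P.items()}


class TestInformationContent:
    def test_matches_hand_counts(self, toy_dag):
        ont, ann = toy_dag
        ic = information_content(ann, ont)
        for t, p in P.items():
            assert ic.p[t] == pytest.approx(p)
            assert ic.ic[t] == pytest.approx(IC[t])
        assert ic.ic["R"] == 0.0

    def test_quarter_frequency_term_ic_is_ln4(self):
        ns = "molecular_function"
        terms = {t: {"name": t, "namespace": ns} for t in ("root", "t")}
        ont = Ontology(terms, {"root": frozenset(), "t": frozenset({"root"})})
        direct = {f"g{i}": ({"t"} if i < 25 else {"root"}) for i in range(100)}
        ic = information_content(AnnotationSet.from_direct(direct, ont), ont)
        assert ic.ic["t"] == pytest.approx(math.log(4))

    def test_child_frequency_never_exceeds_parent(self, toy_dag):
        ont, ann = toy_dag
        ic = information_content(ann, ont)
        # brute-force count from propagated sets
        for t in ont.terms:
            n_t = sum(t in ts for ts in ann.propagated.values())
            assert ic.p[t] == pytest.approx(n_t / 10)
            for parent in ont.parents[t]:
                assert ic.p[t] <= ic.p[parent]

    def test_empty_annotations_error(self, toy_dag):
        ont, _ = toy_dag
        with pytest.raises(ValueError):
            information_content(AnnotationSet({}, {}), ont)


class TestTermSimilarity:
    @pytest.fixture()
    def ic(self, toy_dag):
        ont, ann = toy_dag
        return ont, information_content(ann, ont)

    def test_self_relevance_is_one_minus_p(self, ic):
        ont, table = ic
        assert term_similarity("E", "E", table, ont, "rel") == \
            pytest.approx(1 - P["E"])

    def test_root_only_common_ancestor_scores_zero(self, ic):
        ont, table = ic
        # C (under A only) vs B: common ancestor is the root R
        assert term_similarity("C", "B", table, ont, "rel") == pytest.approx(
            2 * IC["R"] / (IC["C"] + IC["B"]) * (1 - 1.0))
        assert term_similarity("C", "B", table, ont, "rel") == 0.0

    @pytest.mark.parametrize("t1,t2,anc", [("E", "D", "A"), ("C", "D", "A"),
                                           ("E", "C", "C")])
    def test_hand_computed_relevance_values(self, ic, t1, t2, anc):
        ont, table = ic
        common = {a for a in "RABCDE"
                  if a in _anc(ont, t1) and a in _anc(ont, t2)}
        expected = max(2 * IC[a] / (IC[t1] + IC[t2]) * (1 - P[a])
                       for a in common)
        # the expected best ancestor was identified by hand
        assert expected == pytest.approx(
            2 * IC[anc] / (IC[t1] + IC[t2]) * (1 - P[anc]))
        assert term_similarity(t1, t2, table, ont, "rel") == \
            pytest.approx(expected, abs=1e-9)

    def test_resnik_and_lin_closed_forms(self, ic):
        ont, table = ic
        assert term_similarity("E", "D", table, ont, "resnik") == \
            pytest.approx(IC["A"])
        assert term_similarity("E", "D", table, ont, "lin") == \
            pytest.approx(2 * IC["A"] / (IC["E"] + IC["D"]))

    def test_rel_bounded_by_lin_and_symmetric(self, ic):
        ont, table = ic
        for t1, t2 in itertools.combinations("ABCDE", 2):
            rel = term_similarity(t1, t2, table, ont, "rel")
            lin = term_similarity(t1, t2, table, ont, "lin")
            assert rel <= lin + 1e-12
            assert rel == term_similarity(t2, t1, table, ont, "rel")

    def test_both_roots_score_zero(self, ic):
        ont, table = ic
        assert term_similarity("R", "R", table, ont, "rel") == 0.0
        assert term_similarity("R", "R", table, ont, "lin") == 0.0


def _anc(ont, t):
    return ont.ancestors(t)


class TestGeneSimilarity:
    def test_single_shared_term_equals_self_relevance(self, toy_dag):
        ont, _ = toy_dag
        ann = AnnotationSet.from_direct(
            {"x": {"E"}, "y": {"E"}, **{f"g{i}": {"D"} for i in range(8)}}, ont)
        ic = information_content(ann, ont)
        s = gene_similarity("x", "y", ann, ic, ont)
        assert s == pytest.approx(1 - ic.p["E"])

    def test_disjoint_subtrees_meeting_at_root_score_zero(self, toy_dag):
        ont, ann = toy_dag
        ic = information_content(ann, ont)
        assert gene_similarity("g3", "g7", ann, ic, ont) == 0.0  # C vs B

    def test_best_match_average_matches_hand_calculation(self, toy_dag):
        ont, ann = toy_dag
        ic = information_content(ann, ont)
        sim = GeneSimilarity(ann, ic, ont)
        ann2 = AnnotationSet.from_direct(
            {**{g: set(ts) for g, ts in ann.direct.items()},
             "u": {"E", "D"}, "v": {"C"}}, ont)
        sim2 = GeneSimilarity(ann2, ic, ont)
        rel_ec = sim.term_sim("E", "C")
        rel_dc = sim.term_sim("D", "C")
        expected = (rel_ec + rel_dc + max(rel_ec, rel_dc)) / 3
        assert sim2.gene_sim("u", "v") == pytest.approx(expected, abs=1e-9)

    def test_no_shared_namespace_is_undefined(self, toy_dag):
        ont, _ = toy_dag
        terms = dict(ont.terms)
        terms["M"] = {"name": "M", "namespace": "molecular_function"}
        parents = dict(ont.parents)
        parents["M"] = frozenset()
        ont2 = Ontology(terms, parents)
        ann = AnnotationSet.from_direct(
            {"x": {"E"}, "y": {"M"}, **{f"g{i}": {"D", "M"} for i in range(8)}},
            ont2)
        ic = information_content(ann, ont2)
        assert GeneSimilarity(ann, ic, ont2).gene_sim("x", "y") is None

    def test_invariant_to_annotation_listing_order(self, toy_dag):
        ont, _ = toy_dag
        a1 = AnnotationSet.from_direct({"x": {"E", "D", "B"}, "y": {"C", "A"}},
                                       ont)
        a2 = AnnotationSet.from_direct({"x": {"B", "E", "D"}, "y": {"A", "C"}},
                                       ont)
        ic = information_content(a1, ont)
        assert gene_similarity("x", "y", a1, ic, ont) == \
            gene_similarity("x", "y", a2, ic, ont)


class TestPartitionValidity:
    def _sim_stub(self, values):
        class Stub:
            def gene_sim(self, g1, g2):
                return values.get(frozenset((g1, g2)))
        return Stub()

    def _cs(self, groups):
        labels = {g: ci for ci, gs in enumerate(groups) for g in gs}
        profiles = {ci: np.zeros(2) for ci in range(len(groups))}
        return ClusterSet(labels, profiles)

    def test_pooled_mean_of_three_pairs(self):
        sim = self._sim_stub({frozenset(("a", "b")): 0.9,
                              frozenset(("a", "c")): 0.6,
                              frozenset(("b", "c")): 0.3})
        vs = partition_validity(self._cs([["a", "b", "c"]]), sim=sim)
        assert vs.score == pytest.approx(0.6)
        assert vs.n_pairs == 3

    def test_singletons_only_is_error(self):
        with pytest.raises(ValueError, match="no scoreable"):
            partition_validity(self._cs([["a"], ["b"]]), sim=self._sim_stub({}))

    def test_skipped_pairs_counted_not_scored(self):
        sim = self._sim_stub({frozenset(("a", "b")): 0.8})
        vs = partition_validity(self._cs([["a", "b", "c"]]), sim=sim)
        assert vs.score == pytest.approx(0.8)
        assert vs.n_skipped == 2

    def test_invariant_to_cluster_relabeling(self, toy_dag):
        ont, ann = toy_dag
        ic = information_content(ann, ont)
        sim = GeneSimilarity(ann, ic, ont)
        groups = [["g1", "g2", "g3"], ["g4", "g5", "g6"], ["g7", "g9"]]
        v1 = partition_validity(self._cs(groups), sim=sim)
        v2 = partition_validity(self._cs(list(reversed(groups))), sim=sim)
        assert v1.score == pytest.approx(v2.score)

    def test_planted_partition_beats_label_shuffles(self, toy_dag):
        ont, ann = toy_dag
        ic = information_content(ann, ont)
        sim = GeneSimilarity(ann, ic, ont)
        planted = [["g1", "g2", "g3"], ["g4", "g5", "g6"], ["g7", "g9", "g8"]]
        base = partition_validity(self._cs(planted), sim=sim).score
        genes = [g for grp in planted for g in grp]
        rng = np.random.default_rng(0)
        for _ in range(10):
            perm = rng.permutation(genes)
            shuffled = [list(perm[:3]), list(perm[3:6]), list(perm[6:])]
            assert partition_validity(self._cs(shuffled), sim=sim).score <= base


class TestSelectOptimal:
    def _item(self, c, groups):
        labels = {g: ci for ci, gs in enumerate(groups) for g in gs}
        return c, ClusterSet(labels, {ci: np.zeros(2)
                                      for ci in range(len(groups))})

    def test_argmax_and_tie_to_smallest_c(self):
        scores = {frozenset(("a", "b")): 0.9, frozenset(("c", "d")): 0.5,
                  frozenset(("a", "c")): 0.1, frozenset(("b", "d")): 0.1,
                  frozenset(("a", "d")): 0.1, frozenset(("b", "c")): 0.1}

        class Stub:
            def gene_sim(self, g1, g2):
                return scores[frozenset((g1, g2))]

        # c=2 separates the coherent pairs; c=3 and c=5 reproduce identical
        # scores -> the smaller c must win on the tie
        items = [
            self._item(2, [["a", "c"], ["b", "d"]]),        # mean 0.1
            self._item(3, [["a", "b"], ["c", "d"], []]),    # mean 0.7
            self._item(5, [["a", "b"], ["c", "d"]]),        # mean 0.7 (tie)
        ]
        best_cs, best_vs, table = select_from_clustersets(
            [(c, cs) for c, cs in items], Stub())
        assert best_vs.c == 3
        assert [v.c for v in table] == [2, 3, 5]
        assert table[1].score == pytest.approx(table[2].score)


class TestEnrichment:
    def test_exact_hypergeometric_tail(self, toy_dag):
        ont, _ = toy_dag
        # universe of 100 genes; exactly 10 carry E and form the cluster
        direct = {f"h{i}": ({"E"} if i < 10 else {"B"}) for i in range(100)}
        ann = AnnotationSet.from_direct(direct, ont)
        cluster = {f"h{i}" for i in range(10)}
        universe = set(direct)
        recs = enrichment(cluster, universe, ann, ont, n_resample=100, seed=0)
        byterm = {r["term"]: r for r in recs}
        assert byterm["E"]["p"] == pytest.approx(1 / math.comb(100, 10))
        assert byterm["E"]["k"] == 10 and byterm["E"]["K"] == 10

    def test_background_frequency_term_not_enriched(self, toy_dag):
        ont, _ = toy_dag
        direct = {f"h{i}": ({"E"} if i % 10 == 0 else {"B"})
                  for i in range(100)}
        ann = AnnotationSet.from_direct(direct, ont)
        cluster = {f"h{i}" for i in range(10)}  # contains exactly one E gene
        recs = enrichment(cluster, set(direct), ann, ont, n_resample=100,
                          seed=0)
        byterm = {r["term"]: r for r in recs}
        assert byterm["E"]["p"] >= 0.5

    def test_adjusted_p_monotone_in_p_and_bounded(self, toy_dag):
        ont, _ = toy_dag
        rng = np.random.default_rng(4)
        terms = list("EDCBA")
        direct = {f"h{i}": {terms[rng.integers(5)]} for i in range(60)}
        ann = AnnotationSet.from_direct(direct, ont)
        cluster = {f"h{i}" for i in range(12)}
        recs = enrichment(cluster, set(direct), ann, ont, n_resample=200,
                          seed=1)
        ps = [r["p"] for r in recs]
        adj = [r["p_adj"] for r in recs]
        assert ps == sorted(ps)
        assert adj == sorted(adj)
        assert all(0 <= a <= 1 for a in adj)
        assert all(0 < p <= 1 for p in ps)

    def test_cluster_outside_universe_is_error(self, toy_dag):
        ont, ann = toy_dag
        with pytest.raises(ValueError):
            enrichment({"zz"}, {"g1"}, ann, ont, n_resample=100)
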