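"""Statistical core: co-citation counts, CI, permutation significance,
one-to-all ranking and star-paper partitioning."""

import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cocite.cocitation import (
    ci_from_count,
    cocitation_count,
    gene_gene_analysis,
    gene_term_analysis,
    one_to_all,
    permutation_test,
    split_star_papers,
    term_term_analysis,
)
from cocite.corpus import AbstractRecord, AbstractStore, CitationIndex, GeneSet, TermSet

pmid_set = st.sets(st.integers(min_value=0, max_value=49), max_size=8)
set_list = st.lists(pmid_set, min_size=1, max_size=6)


def _pairwise_union(a_sets, b_sets):
    out = set()
    for a in a_sets:
        for b in b_sets:
            out |= a & b
    return out


class TestCocitationCount:
    def test_worked_example(self):
        n, cocited = cocitation_count([{1, 2}, {2, 3}], [{2}, {3, 4}])
        assert (n, cocited) == (2, {2, 3})

    def test_disjoint_universes(self):
        n, cocited = cocitation_count([{1}], [{2}])
        assert (n, cocited) == (0, frozenset())

    def test_self_overlap(self):
        assert cocitation_count([{1}], [{1}])[0] == 1

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            cocitation_count([], [{1}])

    @settings(max_examples=200, derandomize=True)
    @given(a=set_list, b=set_list)
    def test_union_identity_against_pairwise_oracle(self, a, b):
        n, cocited = cocitation_count(a, b)
        expected = _pairwise_union(a, b)
        assert cocited == expected and n == len(expected)

    @settings(max_examples=100, derandomize=True)
    @given(a=set_list, b=set_list)
    def test_symmetry(self, a, b):
        assert cocitation_count(a, b)[0] == cocitation_count(b, a)[0]

    @settings(max_examples=100, derandomize=True)
    @given(a=set_list, b=set_list, extra=st.integers(min_value=0, max_value=49))
    def test_monotone_in_added_abstract(self, a, b, extra):
        n0 = cocitation_count(a, b)[0]
        a2 = [set(a[0]) | {extra}] + a[1:]
        assert cocitation_count(a2, b)[0] >= n0


class TestCiFromCount:
    @pytest.mark.parametrize("n,expected", [(0, 0.0), (1, 1.0), (7, 3.0)])
    def test_closed_form(self, n, expected):
        assert ci_from_count(n) == pytest.approx(expected)

    def test_strictly_increasing(self):
        vals = [ci_from_count(n) for n in range(0, 10_001)]
        assert all(b > a for a, b in zip(vals, vals[1:]))

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ci_from_count(-1)

    def test_alternative_base(self):
        assert ci_from_count(7, base=math.e) == pytest.approx(math.log(8))


class TestOneToAll:
    def test_ranking_by_ci_descending(self):
        cit = {"a": set(range(7)), "b": {0}, "c": set()}
        entries = one_to_all(cit, set(range(10)))
        assert [(e.gene_id, e.n, e.ci) for e in entries] == [
            ("a", 7, 3.0),
            ("b", 1, 1.0),
            ("c", 0, 0.0),
        ]
        assert [e.rank for e in entries] == [1, 2, 3]

    def test_gene_with_no_citations_ranked_last(self):
        entries = one_to_all({"z": set(), "a": {1}}, {1})
        assert entries[-1].gene_id == "z"

    def test_input_order_invariance_and_tie_break(self):
        cit1 = {"b": {1}, "a": {2}}
        cit2 = {"a": {2}, "b": {1}}
        e1 = one_to_all(cit1, {1, 2})
        e2 = one_to_all(cit2, {1, 2})
        assert [e.gene_id for e in e1] == [e.gene_id for e in e2] == ["a", "b"]


class TestSplitStarPapers:
    def test_star_at_threshold(self):
        cit = {str(i): {100} for i in range(12)}
        regular, stars = split_star_papers({100}, cit, threshold=10)
        assert stars == {100} and regular == set()

    def test_threshold_one_all_stars(self):
        cit = {"a": {1}, "b": {2}}
        regular, stars = split_star_papers({1, 2}, cit, threshold=1)
        assert stars == {1, 2} and regular == set()

    def test_threshold_above_set_size_no_stars(self):
        cit = {"a": {1}, "b": {1}}
        regular, stars = split_star_papers({1}, cit, threshold=3)
        assert stars == set() and regular == {1}

    def test_partition_exhaustive_disjoint(self):
        cit = {"a": {1, 2}, "b": {1}, "c": {1}}
        regular, stars = split_star_papers({1, 2}, cit, threshold=3)
        assert regular | stars == {1, 2} and not regular & stars


def _uniform_index(n_genes=20, pmids=frozenset({1, 2, 3})):
    index = CitationIndex()
    for i in range(n_genes):
        index.add(9606, str(i), pmids)
    return index


class TestPermutationTest:
    def test_degenerate_identical_citations_p_one(self):
        index = _uniform_index()
        query = GeneSet(9606, ("0", "1"))
        res = permutation_test(query, [{1, 2}], index, n_perm=50, seed=3)
        assert res.p_value == 1.0

    def test_zero_observed_ci_p_one(self):
        index = CitationIndex()
        for i in range(20):
            index.add(9606, str(i), [100 + i])
        res = permutation_test(GeneSet(9606, ("0",)), [{999}], index, n_perm=50, seed=3)
        assert res.n == 0 and res.ci == 0.0 and res.p_value == 1.0
        assert res.adjusted_ci <= 0.0 + 1e-12

    def test_universe_too_small_names_size(self):
        index = _uniform_index(n_genes=3)
        with pytest.raises(ValueError, match="3"):
            permutation_test(GeneSet(9606, tuple("0123")), [{1}], index, n_perm=10, seed=0)

    def test_result_invariants(self, planted_corpus):
        query = GeneSet(9606, tuple(str(i) for i in range(1, 11)))
        target = [planted_corpus.index.citations(9606, str(i)) for i in range(11, 21)]
        res = permutation_test(
            query, target, planted_corpus.index, homologs=planted_corpus.homologs,
            n_perm=100, seed=9,
        )
        assert res.ci == pytest.approx(math.log2(res.n + 1))
        assert len(res.cocited_pmids) == res.n
        assert res.star_pmids <= res.cocited_pmids
        assert 0.0 <= res.p_value <= 1.0
        assert res.adjusted_ci == pytest.approx(res.ci - res.random_ci_mean)

    def test_seed_reproducibility_bit_identical(self, planted_corpus):
        query = GeneSet(9606, tuple(str(i) for i in range(30, 40)))
        target = [planted_corpus.index.citations(9606, str(i)) for i in range(11, 21)]
        kwargs = dict(
            index=planted_corpus.index, homologs=planted_corpus.homologs,
            n_perm=200, seed=77,
        )
        r1 = permutation_test(query, target, **kwargs)
        r2 = permutation_test(query, target, **kwargs)
        assert r1 == r2

    def test_planted_module_detected(self, planted_corpus):
        a = GeneSet(9606, tuple(str(i) for i in range(1, 11)))
        b = GeneSet(9606, tuple(str(i) for i in range(11, 21)))
        res = gene_gene_analysis(
            a, b, planted_corpus.index, homologs=planted_corpus.homologs,
            n_perm=1000, seed=13,
        ).result
        assert res.p_value <= 0.005


class TestGeneGeneAnalysis:
    def test_self_comparison_equals_union_size(self, planted_corpus):
        a = GeneSet(9606, tuple(str(i) for i in range(50, 60)))
        res = gene_gene_analysis(
            a, a, planted_corpus.index, n_perm=10, seed=0
        ).result
        union = set().union(
            *(planted_corpus.index.citations(9606, g) for g in a.genes)
        )
        assert res.n == len(union)

    def test_singleton_query_reduces_to_single_gene_ci(self, planted_corpus):
        a = GeneSet(9606, ("5",))
        b = GeneSet(9606, tuple(str(i) for i in range(11, 21)))
        res = gene_gene_analysis(a, b, planted_corpus.index, n_perm=10, seed=0).result
        b_union = set().union(*(planted_corpus.index.citations(9606, g) for g in b.genes))
        expected_n = len(planted_corpus.index.citations(9606, "5") & b_union)
        assert res.n == expected_n

    def test_one_to_all_subset_of_set_level(self, planted_corpus):
        a = GeneSet(9606, tuple(str(i) for i in range(1, 11)))
        b = GeneSet(9606, tuple(str(i) for i in range(11, 21)))
        out = gene_gene_analysis(
            a, b, planted_corpus.index, homologs=planted_corpus.homologs,
            n_perm=10, seed=0,
        )
        for entry in out.one_to_all:
            assert entry.cocited_pmids <= out.result.cocited_pmids

    def test_log_base_leaves_p_and_ranking_unchanged(self, planted_corpus):
        a = GeneSet(9606, tuple(str(i) for i in range(1, 11)))
        b = GeneSet(9606, tuple(str(i) for i in range(11, 21)))
        kwargs = dict(index=planted_corpus.index, homologs=planted_corpus.homologs,
                      n_perm=200, seed=21)
        r2 = gene_gene_analysis(a, b, base=2.0, **kwargs)
        re_ = gene_gene_analysis(a, b, base=math.e, **kwargs)
        assert r2.result.p_value == re_.result.p_value
        assert [e.gene_id for e in r2.one_to_all] == [e.gene_id for e in re_.one_to_all]
        assert r2.result.n == re_.result.n


class TestGeneTermAnalysis:
    def test_term_matching_gene_citations(self, planted_corpus):
        phrase = planted_corpus.truth["modules"][0]["phrase"]
        a = GeneSet(9606, tuple(str(i) for i in range(1, 11)))
        res = gene_term_analysis(
            a, TermSet((phrase,)), planted_corpus.index, planted_corpus.store,
            homologs=planted_corpus.homologs, n_perm=500, seed=4,
        )
        assert res.n > 0
        assert res.p_value <= 0.01

    def test_absent_term_warns_not_errors(self, planted_corpus):
        a = GeneSet(9606, ("1",))
        with pytest.warns(UserWarning, match="no term"):
            res = gene_term_analysis(
                a, TermSet(("zzqy nonexistent",)), planted_corpus.index,
                planted_corpus.store, n_perm=20, seed=0,
            )
        assert res.n == 0 and res.p_value == 1.0

    def test_synonymous_terms_idempotent(self, planted_corpus):
        phrase = planted_corpus.truth["modules"][0]["phrase"]
        a = GeneSet(9606, tuple(str(i) for i in range(1, 6)))
        kwargs = dict(index=planted_corpus.index, store=planted_corpus.store,
                      n_perm=100, seed=8)
        single = gene_term_analysis(a, TermSet((phrase,)), **kwargs)
        double = gene_term_analysis(a, TermSet((phrase, phrase.upper())), **kwargs)
        # case-insensitive dedup collapses them; union idempotence regardless
        assert single.n == double.n and single.p_value == double.p_value


class TestTermTermAnalysis:
    def _store(self):
        recs = [
            AbstractRecord(i, "t", body, frozenset())
            for i, body in enumerate(
                [
                    "alpha beta shared text",
                    "alpha beta again here",
                    "alpha beta third time",
                    "only alpha beta absent gamma delta",
                    "gamma delta no first term",
                ]
            )
        ]
        return AbstractStore(recs)

    def test_no_p_value_reported(self):
        res = term_term_analysis(TermSet(("alpha",)), TermSet(("beta",)), self._store())
        assert res.p_value is None and res.adjusted_ci is None

    def test_shared_three_abstracts_ci_two(self):
        res = term_term_analysis(
            TermSet(("alpha beta",)), TermSet(("shared", "again", "third")), self._store()
        )
        assert res.n == 3 and res.ci == pytest.approx(2.0)

    def test_identical_term_sets(self):
        ts = TermSet(("alpha beta",))
        res = term_term_analysis(ts, ts, self._store())
        assert res.n == 4  # all abstracts containing the phrase

    def test_disjoint_matches(self):
        res = term_term_analysis(
            TermSet(("third time",)), TermSet(("no first",)), self._store()
        )
        assert res.n == 0 and res.ci == 0.0
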