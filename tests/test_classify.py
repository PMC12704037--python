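"""Category assignment, SuperMatch flags, keyword verification."""

import datetime as dt

import pytest

from litscreen.classify import (
    categorize,
    categorize_candidate,
    summarize_categories,
    supermatch,
    verify_keywords,
)
from litscreen.model import (
    Backend,
    CandidateInput,
    Category,
    IdType,
    PublicationRecord,
    Query,
    ResolvedCandidate,
    RetrievalResult,
    Scope,
    SearchSpec,
    SuperMatch,
    Term,
    TermClass,
)


def _cand(valid=True, proteins=("Decorin",)):
    terms = [Term("DCN", TermClass.GENE_NAME)]
    terms += [Term(p, TermClass.PROTEIN_NAME) for p in proteins]
    return ResolvedCandidate(
        input=CandidateInput("DCN", IdType.GENE_NAME, 9606),
        terms=tuple(terms) if valid else (),
        is_valid=valid,
    )


def _result(records, spec=None, total=None):
    spec = spec or SearchSpec(keywords=("cancer",), backend=Backend.OFFLINE)
    q = Query(candidate_ref="DCN", expression="(x)", terms=(), spec=spec)
    total = len(records) if total is None else total
    return RetrievalResult(
        query=q, records=tuple(records), total_hits=total,
        truncated=total > len(records),
    )


def _rec(pid, title, abstract="", types=("Journal Article",)):
    return PublicationRecord(pid, title, abstract, tuple(types), dt.date(2020, 1, 1))


class TestCategorize:
    def test_any_review_gives_category_1(self):
        recs = [_rec("a1", "t"), _rec("a2", "t", types=("Journal Article", "Review")),
                _rec("a3", "t")]
        assert categorize(_cand(), _result(recs)) is Category.REVIEW

    def test_publications_without_review_give_category_2(self):
        recs = [_rec(f"a{i}", "t") for i in range(5)]
        assert categorize(_cand(), _result(recs)) is Category.PUBLICATION

    def test_valid_with_no_records_gives_category_3(self):
        assert categorize(_cand(), _result([])) is Category.NO_PUBLICATION

    def test_invalid_with_no_records_gives_category_4(self):
        assert categorize(_cand(valid=False), _result([])) is Category.INVALID

    def test_adding_a_review_promotes_2_to_1_only(self):
        recs = [_rec("a1", "t"), _rec("a2", "t")]
        before = categorize(_cand(), _result(recs))
        after = categorize(_cand(), _result(recs + [_rec("a3", "t", types=("Review",))]))
        assert (before, after) == (Category.PUBLICATION, Category.REVIEW)

    def test_removing_all_records_demotes_valid_candidate_to_3(self):
        recs = [_rec("a1", "t", types=("Review",))]
        assert categorize(_cand(), _result(recs)) is Category.REVIEW
        assert categorize(_cand(), _result([])) is Category.NO_PUBLICATION


class TestSuperMatch:
    def test_protein_name_in_title_matches(self):
        rec = _rec("a1", "Decorin suppresses tumor growth")
        assert supermatch(rec, _cand()) is SuperMatch.MATCH

    def test_gene_name_alone_does_not_match(self):
        rec = _rec("a1", "DCN expression analysis")
        assert supermatch(rec, _cand()) is SuperMatch.NO_MATCH

    def test_protein_name_in_abstract_counts_even_for_title_scope(self):
        rec = _rec("a1", "Unrelated title", abstract="We studied Decorin here")
        assert supermatch(rec, _cand()) is SuperMatch.MATCH

    def test_gene_synonym_never_triggers_match(self):
        cand = ResolvedCandidate(
            input=CandidateInput("DCN", IdType.GENE_NAME, 9606),
            terms=(Term("DCN", TermClass.GENE_NAME), Term("SLRR1B", TermClass.SYNONYM)),
            is_valid=True,
        )
        rec = _rec("a1", "SLRR1B and DCN in cancer")
        assert supermatch(rec, cand) is SuperMatch.NO_MATCH

    def test_zero_protein_names_can_never_match(self):
        cand = ResolvedCandidate(
            input=CandidateInput("DCN", IdType.GENE_NAME, 9606),
            terms=(Term("DCN", TermClass.GENE_NAME),),
            is_valid=True,
        )
        rec = _rec("a1", "DCN Decorin everything everywhere")
        # the bundle has no protein-name class terms, so nothing can match
        assert supermatch(rec, cand) is SuperMatch.NO_MATCH

    def test_flags_independent_of_query_scope(self, dcn_corpus):
        from litscreen.pipeline import triage_offline

        table = dcn_corpus.synonym_table()
        flags = {}
        for scope in (Scope.TITLE_ONLY, Scope.TITLE_AND_ABSTRACT):
            spec = SearchSpec(keywords=dcn_corpus.keywords, scope=scope,
                              backend=Backend.OFFLINE)
            cc = triage_offline(dcn_corpus.candidate_inputs(), table, spec,
                                dcn_corpus.documents)[0]
            flags[scope] = dict(zip((r.pub_id for r in cc.result.records),
                                    cc.supermatch_flags))
        shared = set(flags[Scope.TITLE_ONLY]) & set(flags[Scope.TITLE_AND_ABSTRACT])
        assert shared
        for pid in shared:
            assert flags[Scope.TITLE_ONLY][pid] == flags[Scope.TITLE_AND_ABSTRACT][pid]


class TestVerifyKeywords:
    def test_exact_offline_results_all_verify(self, dcn_corpus):
        from litscreen.pipeline import triage_offline

        spec = SearchSpec(keywords=dcn_corpus.keywords, scope=dcn_corpus.scope,
                          backend=Backend.OFFLINE)
        cc = triage_offline(dcn_corpus.candidate_inputs(),
                            dcn_corpus.synonym_table(), spec,
                            dcn_corpus.documents)[0]
        report = verify_keywords(cc.result, spec)
        assert report.false_positive_count == 0
        assert all(c.all_keywords_present for c in report.checks)

    def test_keyword_only_in_abstract_fails_title_scope(self):
        spec = SearchSpec(keywords=("cancer",), scope=Scope.TITLE_ONLY,
                          backend=Backend.OFFLINE)
        rec = _rec("a1", "Decorin title", abstract="cancer only here")
        report = verify_keywords(_result([rec], spec), spec)
        assert not report.checks[0].all_keywords_present
        assert report.false_positive_count == 1

    def test_semantic_pubtator_miss_is_informational_not_failure(self):
        spec = SearchSpec(keywords=("cancer",), scope=Scope.TITLE_AND_ABSTRACT,
                          backend=Backend.PUBTATOR)
        rec = PublicationRecord("a1", "Decorin in carcinoma", "",
                                ("Journal Article",), dt.date(2024, 1, 1),
                                Backend.PUBTATOR)
        report = verify_keywords(_result([rec], spec), spec)
        assert report.false_positive_count == 0
        assert report.semantic_only_count == 1


class TestSummarize:
    def _categorized(self, cat, n_records=0):
        recs = [_rec(f"r{cat}{i}", "t") for i in range(n_records)]
        cand = _cand(valid=cat is not Category.INVALID)
        if cat is Category.REVIEW and recs:
            recs[0] = _rec("rv", "t", types=("Review",))
        return categorize_candidate(cand, _result(recs))

    def test_empty_input_gives_all_zero_counts(self):
        counts, total = summarize_categories([])
        assert counts == {c: 0 for c in Category} and total == 0

    def test_constructed_distribution_is_recovered(self):
        cands = (
            [self._categorized(Category.REVIEW, 2)] * 2
            + [self._categorized(Category.PUBLICATION, 3)] * 3
            + [self._categorized(Category.NO_PUBLICATION)] * 4
            + [self._categorized(Category.INVALID)] * 1
        )
        counts, total_pubs = summarize_categories(cands)
        assert counts == {Category.REVIEW: 2, Category.PUBLICATION: 3,
                          Category.NO_PUBLICATION: 4, Category.INVALID: 1}
        assert sum(counts.values()) == len(cands)
        assert total_pubs == 2 * 2 + 3 * 3

    def test_order_invariance(self):
        cands = [self._categorized(Category.REVIEW, 1),
                 self._categorized(Category.NO_PUBLICATION)]
        assert summarize_categories(cands) == summarize_categories(cands[::-1])
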