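"""Offline search semantics, paging arithmetic, and review detection."""

import datetime as dt
import json
import urllib.parse

import pytest

from litscreen.errors import QuerySyntaxError, TransportError
from litscreen.model import (
    Backend,
    CandidateInput,
    IdType,
    PublicationRecord,
    ResolvedCandidate,
    Scope,
    SearchSpec,
    SortOrder,
    Term,
    TermClass,
)
from litscreen.query import build_pubmed_query, build_pubtator_query
from litscreen.retrieve import (
    PubMedClient,
    is_review,
    search_offline,
    search_pubmed,
    search_pubtator,
)


def _query(terms, spec):
    cand = ResolvedCandidate(
        input=CandidateInput("X1", IdType.GENE_NAME, 9606),
        terms=tuple(Term(t, TermClass.GENE_NAME) for t in terms),
        is_valid=True,
    )
    return build_pubmed_query(cand, spec)


class TestSearchOffline:
    def test_title_only_selects_docs_with_term_and_keyword_in_title(
        self, tiny_corpus, title_spec
    ):
        q = _query(["Decorin"], title_spec)
        res = search_offline(q, tiny_corpus)
        assert {r.pub_id for r in res.records} == {"p1", "p2"}
        assert not res.truncated

    def test_absent_keyword_gives_empty_result(self, tiny_corpus):
        spec = SearchSpec(keywords=("neverinthecorpus",), scope=Scope.TITLE_ONLY,
                          backend=Backend.OFFLINE)
        res = search_offline(_query(["Decorin"], spec), tiny_corpus)
        assert res.records == () and res.total_hits == 0 and not res.truncated

    def test_widening_scope_gives_superset(self, tiny_corpus, title_spec, wide_spec):
        narrow = search_offline(_query(["Decorin"], title_spec), tiny_corpus)
        wide = search_offline(_query(["Decorin"], wide_spec), tiny_corpus)
        narrow_ids = {r.pub_id for r in narrow.records}
        wide_ids = {r.pub_id for r in wide.records}
        assert narrow_ids <= wide_ids
        assert "p5" in wide_ids  # term+keyword only in the abstract

    def test_date_ceiling_excludes_later_documents(self, tiny_corpus):
        spec = SearchSpec(keywords=("cancer",), scope=Scope.TITLE_ONLY,
                          max_date=dt.date(2018, 12, 31), backend=Backend.OFFLINE)
        res = search_offline(_query(["Decorin"], spec), tiny_corpus)
        assert {r.pub_id for r in res.records} == {"p1"}

    def test_token_boundary_no_substring_matches(self, title_spec):
        docs = [PublicationRecord("q1", "Decorinase levels in cancer", "")]
        res = search_offline(_query(["Decorin"], title_spec), docs)
        assert res.records == ()

    def test_cap_and_truncated_flag(self, tiny_corpus):
        spec = SearchSpec(keywords=("cancer",), scope=Scope.TITLE_ONLY,
                          max_publications=1, backend=Backend.OFFLINE)
        res = search_offline(_query(["Decorin"], spec), tiny_corpus)
        assert len(res.records) == 1 and res.total_hits == 2 and res.truncated

    def test_date_sort_descending_with_pub_id_ties(self, title_spec):
        d = dt.date(2020, 1, 1)
        docs = [
            PublicationRecord(pid, "Decorin in cancer", "", (), d)
            for pid in ("b2", "a1", "c3")
        ]
        spec = SearchSpec(keywords=("cancer",), scope=Scope.TITLE_ONLY,
                          sort=SortOrder.DATE, backend=Backend.OFFLINE)
        res = search_offline(_query(["Decorin"], spec), docs)
        assert [r.pub_id for r in res.records] == ["c3", "b2", "a1"]

    def test_relevance_sort_puts_multi_term_hits_first(self):
        docs = [
            PublicationRecord("one", "Decorin in cancer", "", (), dt.date(2024, 1, 1)),
            PublicationRecord("two", "Decorin and DCN in cancer", "", (), dt.date(2000, 1, 1)),
        ]
        spec = SearchSpec(keywords=("cancer",), scope=Scope.TITLE_ONLY,
                          sort=SortOrder.RELEVANCE, backend=Backend.OFFLINE)
        res = search_offline(_query(["Decorin", "DCN"], spec), docs)
        assert [r.pub_id for r in res.records] == ["two", "one"]

    def test_identical_inputs_identical_ordered_output(self, tiny_corpus, wide_spec):
        q = _query(["Decorin", "DCN"], wide_spec)
        a = search_offline(q, tiny_corpus)
        b = search_offline(q, tiny_corpus)
        assert a == b


class TestIsReview:
    @pytest.mark.parametrize(
        "types,expected",
        [
            (("Journal Article", "Review"), True),
            (("Journal Article",), False),
            (("Systematic Review",), True),
            (("Meta-Analysis",), False),
        ],
    )
    def test_review_class_membership(self, types, expected):
        rec = PublicationRecord("x1", "t", publication_types=types)
        assert is_review(rec) is expected

    def test_review_type_set_is_configurable(self):
        rec = PublicationRecord("x1", "t", publication_types=("Meta-Analysis",))
        assert is_review(rec, review_types=frozenset({"Meta-Analysis"}))


def _efetch_xml(pmids):
    arts = "".join(
        f"""<PubmedArticle><MedlineCitation><PMID>{p}</PMID>
        <Article><ArticleTitle>Title {p}</ArticleTitle>
        <Abstract><AbstractText>Abstract {p}</AbstractText></Abstract>
        <Journal><JournalIssue><PubDate><Year>2020</Year><Month>Jan</Month>
        </PubDate></JournalIssue></Journal>
        <PublicationTypeList><PublicationType>Journal Article</PublicationType>
        </PublicationTypeList></Article>
        </MedlineCitation></PubmedArticle>"""
        for p in pmids
    )
    return f"<PubmedArticleSet>{arts}</PubmedArticleSet>".encode()


class _PagedTransport:
    """esearch: 1100 ids served in pages; efetch: minimal XML records."""

    def __init__(self, total=1100):
        self.ids = [str(10_000 + i) for i in range(total)]
        self.esearch_pages = []

    def __call__(self, url):
        parsed = urllib.parse.urlparse(url)
        params = dict(urllib.parse.parse_qsl(parsed.query))
        if "esearch" in parsed.path:
            start, retmax = int(params["retstart"]), int(params["retmax"])
            page = self.ids[start : start + retmax]
            self.esearch_pages.append(len(page))
            return json.dumps(
                {"esearchresult": {"count": str(len(self.ids)), "idlist": page}}
            ).encode()
        if "efetch" in parsed.path:
            return _efetch_xml(params["id"].split(","))
        raise AssertionError(f"unexpected URL {url}")


class TestSearchPubmed:
    def _query(self, max_pubs=1000):
        spec = SearchSpec(keywords=("cancer",), backend=Backend.PUBMED,
                          max_publications=max_pubs)
        return _query(["Decorin"], spec)

    def test_paging_honors_cap_400_400_300(self):
        transport = _PagedTransport(total=1100)
        client = PubMedClient(transport=transport, page_size=400, rate_limited=False)
        res = search_pubmed(self._query(max_pubs=1000), client)
        assert transport.esearch_pages == [400, 400, 200]
        assert len(res.records) == 1000
        assert res.total_hits == 1100
        assert res.truncated
        assert len({r.pub_id for r in res.records}) == 1000

    def test_zero_hits_is_empty_not_truncated(self):
        def transport(url):
            if "esearch" in url:
                return b'{"esearchresult": {"count": "0", "idlist": []}}'
            raise AssertionError("efetch should not be called")

        client = PubMedClient(transport=transport, rate_limited=False)
        res = search_pubmed(self._query(), client)
        assert res.records == () and not res.truncated

    def test_backend_query_error_is_not_a_transport_error(self):
        def transport(url):
            return b'{"esearchresult": {"ERROR": "bad term"}}'

        client = PubMedClient(transport=transport, rate_limited=False)
        with pytest.raises(QuerySyntaxError):
            search_pubmed(self._query(), client)

    def test_transport_failure_raises_after_retries(self):
        def transport(url):
            raise OSError("down")

        client = PubMedClient(transport=transport, rate_limited=False,
                              max_retries=2, retry_wait=0.0)
        with pytest.raises(TransportError):
            client.esearch_page("x", 0, 10, SortOrder.RELEVANCE)

    def test_efetch_parses_fields(self):
        transport = _PagedTransport(total=3)
        client = PubMedClient(transport=transport, rate_limited=False)
        res = search_pubmed(self._query(), client)
        rec = res.records[0]
        assert rec.title == "Title 10000"
        assert rec.abstract == "Abstract 10000"
        assert rec.publication_types == ("Journal Article",)
        assert rec.pub_date == dt.date(2020, 1, 1)
        assert rec.source is Backend.PUBMED


def _pubtator_query():
    cand = ResolvedCandidate(
        input=CandidateInput("X1", IdType.GENE_NAME, 9606),
        terms=(Term("Decorin", TermClass.PROTEIN_NAME),),
        is_valid=True,
    )
    return build_pubtator_query(
        cand, SearchSpec(keywords=("cancer",), backend=Backend.PUBTATOR)
    )


class TestSearchPubtator:
    def test_first_page_of_ten_with_total_and_link(self):
        payload = {
            "count": 37,
            "results": [
                {"pmid": 100 + i, "title": f"Title {i}", "date": "2021-05-01T00:00:00Z"}
                for i in range(10)
            ],
        }
        res = search_pubtator(_pubtator_query(),
                              transport=lambda url: json.dumps(payload).encode(),
                              rate_limited=False)
        assert len(res.records) == 10
        assert res.total_hits == 37
        assert res.truncated
        assert res.results_link and "pubtator3" in res.results_link
        assert res.records[0].pub_date == dt.date(2021, 5, 1)

    def test_empty_response_keeps_link(self):
        res = search_pubtator(_pubtator_query(),
                              transport=lambda url: b'{"count": 0, "results": []}',
                              rate_limited=False)
        assert res.records == () and not res.truncated
        assert res.results_link

    def test_exact_match_mock_gives_subset_of_pubmed(self, tiny_corpus):
        """When both backends perform exact matching over the same corpus,
        the PubTator page (first 10) is a subset of the PubMed result."""
        spec_pm = SearchSpec(keywords=("cancer",), scope=Scope.TITLE_ONLY,
                             backend=Backend.PUBMED)
        pm_ids = {
            r.pub_id for r in search_offline(_query(["Decorin"], spec_pm), tiny_corpus).records
        }

        def transport(url):
            # exact-matching mock backend: serve the offline engine's answer
            hits = sorted(pm_ids)[:10]
            return json.dumps({
                "count": len(pm_ids),
                "results": [{"pmid": h, "title": "t"} for h in hits],
            }).encode()

        res = search_pubtator(_pubtator_query(), transport=transport, rate_limited=False)
        assert {r.pub_id for r in res.records} <= pm_ids
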