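"""Query execution against a backend.

Three backends share one result contract (:class:`RetrievalResult`):

* ``search_pubmed`` — NCBI E-utilities (esearch id paging + efetch XML),
  capped at ``spec.max_publications`` (default 1000: several hundred
  candidates must still fit under the spreadsheet row limit);
* ``search_pubtator`` — the PubTator 3.0 search API, which returns only
  its first page (10 records) but a link to the full result set is kept;
* ``search_offline`` — exact boolean matching over a fixture corpus;
  this is the backend every test runs against.

Live clients take an injectable ``transport`` callable so the whole
paging/parsing path is testable with canned responses and no network.
"""

from __future__ import annotations

import datetime as _dt
import json
import time
import urllib.error
import urllib.parse
import urllib.request
import xml.etree.ElementTree as ET
from typing import Callable, Iterable, Optional, Sequence

from .errors import QuerySyntaxError, TransportError
from .model import (
    Backend,
    PublicationRecord,
    Query,
    RetrievalResult,
    Scope,
    SortOrder,
)
from .textmatch import contains_term, count_term_hits

# ---------------------------------------------------------------------------
# Review detection

#: Publication types that make an article count as a review.  The
#: categorization rule promotes a candidate to Category 1 on the first
#: review among its hits.  Meta-analyses are deliberately excluded —
#: they aggregate primary studies rather than reviewing a molecule —
#: but the set is a parameter for users who disagree.
DEFAULT_REVIEW_TYPES = frozenset({"Review", "Systematic Review"})


def is_review(
    rec: PublicationRecord,
    review_types: frozenset[str] = DEFAULT_REVIEW_TYPES,
) -> bool:
    """True iff the record carries a review-class publication type."""
    return any(pt in review_types for pt in rec.publication_types)


# ---------------------------------------------------------------------------
# Offline backend


def _fields_in_scope(rec: PublicationRecord, scope: Scope) -> str:
    if scope is Scope.TITLE_ONLY:
        return rec.title
    return f"{rec.title}\n{rec.abstract}"


def record_matches(rec: PublicationRecord, q: Query) -> bool:
    """The selection rule: at least one synonym-bundle term AND every
    keyword must occur within the searched scope; the date ceiling, when
    set, excludes later publications."""
    spec = q.spec
    if spec.max_date is not None:
        if rec.pub_date is None or rec.pub_date > spec.max_date:
            return False
    text = _fields_in_scope(rec, spec.scope)
    if not any(contains_term(text, t.text) for t in q.terms):
        return False
    return all(contains_term(text, k) for k in spec.keywords)


def _sort_records(
    records: list[PublicationRecord], q: Query
) -> list[PublicationRecord]:
    date_key = lambda r: r.pub_date or _dt.date.min
    if q.spec.sort is SortOrder.DATE:
        return sorted(records, key=lambda r: (date_key(r), r.pub_id), reverse=True)
    # relevance: distinct term hits in scope, then recency, then pub_id
    term_texts = tuple(t.text for t in q.terms)

    def relevance(r: PublicationRecord) -> tuple:
        hits = count_term_hits(_fields_in_scope(r, q.spec.scope), term_texts)
        return (-hits, date_key(r).toordinal() * -1, r.pub_id)

    return sorted(records, key=relevance)


def search_offline(
    q: Query,
    corpus: Sequence[PublicationRecord],
    cap: Optional[int] = None,
) -> RetrievalResult:
    """Execute a query over an in-memory corpus.

    ``cap`` overrides ``q.spec.max_publications`` (pass ``None`` to use
    the spec's cap).  Matching is case-insensitive whole-token /
    contiguous-phrase matching (see :mod:`litscreen.textmatch`), i.e.
    the exact-match behaviour of a quoted live query, so a fixture run
    is a faithful stand-in for the live path minus service-side
    semantic expansion.
    """
    limit = q.spec.max_publications if cap is None else cap
    matching = [rec for rec in corpus if record_matches(rec, q)]
    ordered = _sort_records(matching, q)
    kept = tuple(ordered[:limit])
    return RetrievalResult(
        query=q,
        records=kept,
        total_hits=len(matching),
        truncated=len(matching) > len(kept),
    )


# ---------------------------------------------------------------------------
# Shared live-client plumbing

Transport = Callable[[str], bytes]


def _urllib_transport(url: str) -> bytes:  # pragma: no cover - live only
    with urllib.request.urlopen(url, timeout=60) as resp:
        return resp.read()


class _RateLimiter:
    """Minimum-interval limiter: NCBI allows 3 requests/s without an API
    key and 10/s with one."""

    def __init__(self, per_second: float):
        self._interval = 1.0 / per_second
        self._last = 0.0

    def wait(self) -> None:
        now = time.monotonic()
        delta = now - self._last
        if delta < self._interval:
            time.sleep(self._interval - delta)
        self._last = time.monotonic()


def _fetch_with_retries(
    transport: Transport,
    url: str,
    limiter: Optional[_RateLimiter],
    max_retries: int = 5,
    base_wait: float = 0.5,
    query: str | None = None,
) -> bytes:
    last: Exception | None = None
    for attempt in range(max_retries):
        if limiter is not None:
            limiter.wait()
        try:
            return transport(url)
        except urllib.error.HTTPError as exc:  # pragma: no cover - live only
            if exc.code in (429, 500, 502, 503, 504):
                last = exc
                time.sleep(base_wait * 2**attempt)
                continue
            raise TransportError(f"HTTP {exc.code} for {url}", query=query) from exc
        except (urllib.error.URLError, OSError) as exc:
            last = exc
            time.sleep(base_wait * 2**attempt)
    raise TransportError(f"request failed after {max_retries} retries: {last}", query=query)


# ---------------------------------------------------------------------------
# PubMed (E-utilities)

EUTILS_BASE = "https://eutils.ncbi.nlm.nih.gov/entrez/eutils"


class PubMedClient:
    """Thin esearch/efetch client with id paging.

    ``email`` identifies the caller to NCBI; an ``api_key`` raises the
    rate limit from 3 to 10 requests per second.
    """

    def __init__(
        self,
        email: str = "",
        api_key: str = "",
        transport: Transport = _urllib_transport,
        page_size: int = 400,
        fetch_batch: int = 200,
        rate_limited: bool = True,
        max_retries: int = 5,
        retry_wait: float = 0.5,
    ):
        self.email = email
        self.api_key = api_key
        self._transport = transport
        self._page_size = page_size
        self._fetch_batch = fetch_batch
        self._max_retries = max_retries
        self._retry_wait = retry_wait
        self._limiter = (
            _RateLimiter(10.0 if api_key else 3.0) if rate_limited else None
        )

    def _common_params(self) -> dict[str, str]:
        params = {"db": "pubmed", "tool": "litscreen"}
        if self.email:
            params["email"] = self.email
        if self.api_key:
            params["api_key"] = self.api_key
        return params

    def esearch_page(
        self, term: str, retstart: int, retmax: int, sort: SortOrder
    ) -> tuple[int, list[str]]:
        params = self._common_params() | {
            "term": term,
            "retstart": str(retstart),
            "retmax": str(retmax),
            "retmode": "json",
            "sort": "pub_date" if sort is SortOrder.DATE else "relevance",
        }
        url = f"{EUTILS_BASE}/esearch.fcgi?" + urllib.parse.urlencode(params)
        raw = _fetch_with_retries(self._transport, url, self._limiter, query=term,
                                  max_retries=self._max_retries, base_wait=self._retry_wait)
        payload = json.loads(raw)
        result = payload.get("esearchresult", {})
        if "ERROR" in result or "error" in payload:
            raise QuerySyntaxError(str(result.get("ERROR") or payload.get("error")))
        return int(result.get("count", 0)), list(result.get("idlist", []))

    def esearch_all(self, term: str, cap: int, sort: SortOrder) -> tuple[int, list[str]]:
        """Page through esearch until ``cap`` ids are collected or the
        result set is exhausted."""
        ids: list[str] = []
        total = 0
        retstart = 0
        while len(ids) < cap:
            retmax = min(self._page_size, cap - len(ids))
            total, page = self.esearch_page(term, retstart, retmax, sort)
            if not page:
                break
            ids.extend(page)
            retstart += len(page)
            if retstart >= total:
                break
        return total, ids[:cap]

    def efetch(self, pmids: Sequence[str]) -> list[PublicationRecord]:
        records: list[PublicationRecord] = []
        for start in range(0, len(pmids), self._fetch_batch):
            batch = pmids[start : start + self._fetch_batch]
            params = self._common_params() | {
                "id": ",".join(batch),
                "retmode": "xml",
            }
            url = f"{EUTILS_BASE}/efetch.fcgi?" + urllib.parse.urlencode(params)
            raw = _fetch_with_retries(self._transport, url, self._limiter,
                                      max_retries=self._max_retries, base_wait=self._retry_wait)
            records.extend(parse_efetch_xml(raw))
        return records


_MONTHS = {m: i for i, m in enumerate(
    ["Jan", "Feb", "Mar", "Apr", "May", "Jun",
     "Jul", "Aug", "Sep", "Oct", "Nov", "Dec"], start=1)}


def _parse_pubdate(node: Optional[ET.Element]) -> Optional[_dt.date]:
    if node is None:
        return None
    year = node.findtext("Year")
    if not year:
        medline = node.findtext("MedlineDate") or ""
        year = medline.split(" ")[0] if medline[:4].isdigit() else None
        if not year:
            return None
    month_txt = node.findtext("Month") or "Jan"
    month = _MONTHS.get(month_txt[:3], None)
    if month is None:
        month = int(month_txt) if month_txt.isdigit() else 1
    day = int(node.findtext("Day") or 1)
    try:
        return _dt.date(int(year), month, day)
    except ValueError:
        return _dt.date(int(year), 1, 1)


def parse_efetch_xml(raw: bytes) -> list[PublicationRecord]:
    """Parse an efetch ``PubmedArticleSet`` into publication records."""
    root = ET.fromstring(raw)
    records: list[PublicationRecord] = []
    for art in root.iterfind(".//PubmedArticle"):
        cite = art.find("MedlineCitation")
        if cite is None:
            continue
        pmid = cite.findtext("PMID") or ""
        article = cite.find("Article")
        if article is None or not pmid:
            continue
        title_node = article.find("ArticleTitle")
        title = "".join(title_node.itertext()).strip() if title_node is not None else ""
        abstract = " ".join(
            "".join(t.itertext()).strip()
            for t in article.iterfind("Abstract/AbstractText")
        ).strip()
        pub_types = tuple(
            (pt.text or "").strip()
            for pt in article.iterfind("PublicationTypeList/PublicationType")
            if pt.text
        )
        pub_date = _parse_pubdate(article.find("Journal/JournalIssue/PubDate"))
        if not title:
            title = "[no title]"
        records.append(
            PublicationRecord(
                pub_id=pmid,
                title=title,
                abstract=abstract,
                publication_types=pub_types,
                pub_date=pub_date,
                source=Backend.PUBMED,
            )
        )
    return records


def search_pubmed(q: Query, client: PubMedClient) -> RetrievalResult:
    """Run a PubMed-dialect query live: esearch ids (paged, capped at
    ``spec.max_publications``), then efetch the article metadata."""
    cap = q.spec.max_publications
    total, ids = client.esearch_all(q.expression, cap, q.spec.sort)
    records = tuple(client.efetch(ids)) if ids else ()
    link = "https://pubmed.ncbi.nlm.nih.gov/?" + urllib.parse.urlencode(
        {"term": q.expression}
    )
    return RetrievalResult(
        query=q,
        records=records,
        total_hits=total,
        results_link=link,
        truncated=total > len(records),
    )


# ---------------------------------------------------------------------------
# PubTator 3.0

PUBTATOR_BASE = "https://www.ncbi.nlm.nih.gov/research/pubtator3-api"
PUBTATOR_PAGE_SIZE = 10


def _pubtator_date(value: object) -> Optional[_dt.date]:
    if not isinstance(value, str) or len(value) < 10:
        return None
    try:
        return _dt.date.fromisoformat(value[:10])
    except ValueError:
        return None


def search_pubtator(
    q: Query,
    transport: Transport = _urllib_transport,
    rate_limited: bool = True,
    max_retries: int = 5,
    retry_wait: float = 0.5,
) -> RetrievalResult:
    """Run a PubTator-dialect query live.

    The search API returns only its first page (10 records); the full
    result set stays behind ``results_link``, which is always recorded.
    The service performs semantic keyword expansion server-side, so live
    hit sets may be supersets of exact matching.
    """
    limiter = _RateLimiter(3.0) if rate_limited else None
    url = f"{PUBTATOR_BASE}/search/?" + urllib.parse.urlencode({"text": q.expression})
    link = "https://www.ncbi.nlm.nih.gov/research/pubtator3/?" + urllib.parse.urlencode(
        {"view": "docsum", "query": q.expression}
    )
    raw = _fetch_with_retries(transport, url, limiter, query=q.expression,
                              max_retries=max_retries, base_wait=retry_wait)
    payload = json.loads(raw)
    total = int(payload.get("count", 0))
    records = []
    for item in payload.get("results", [])[:PUBTATOR_PAGE_SIZE]:
        pub_id = str(item.get("pmid") or item.get("_id") or "")
        title = (item.get("title") or "").strip()
        if not pub_id or not title:
            continue
        records.append(
            PublicationRecord(
                pub_id=pub_id,
                title=title,
                abstract=(item.get("abstract") or "").strip(),
                publication_types=tuple(item.get("publication_types", ())),
                pub_date=_pubtator_date(item.get("date")),
                source=Backend.PUBTATOR,
            )
        )
    records_t = tuple(records)
    return RetrievalResult(
        query=q,
        records=records_t,
        total_hits=max(total, len(records_t)),
        results_link=link,
        truncated=max(total, len(records_t)) > len(records_t),
    )
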