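"""End-to-end triage: resolve → build query → retrieve → classify.

One function per backend family; both return the same
``CategorizedCandidate`` list ready for :func:`litscreen.report.write_report`.
"""

from __future__ import annotations

from typing import Optional, Sequence

from .classify import categorize_candidate
from .errors import VacuousQueryError
from .model import (
    Backend,
    CandidateInput,
    CategorizedCandidate,
    PublicationRecord,
    Query,
    ResolvedCandidate,
    RetrievalResult,
    SearchSpec,
)
from .query import build_pubmed_query, build_pubtator_query
from .resolve import SynonymSource, resolve_candidate
from .retrieve import PubMedClient, search_offline, search_pubmed, search_pubtator


def _empty_result(cand: ResolvedCandidate, spec: SearchSpec) -> RetrievalResult:
    placeholder = Query(
        candidate_ref=cand.input.raw_id, expression="", terms=(), spec=spec
    )
    return RetrievalResult(query=placeholder, records=(), total_hits=0)


def triage_offline(
    inputs: Sequence[CandidateInput],
    source: SynonymSource,
    spec: SearchSpec,
    corpus: Sequence[PublicationRecord],
) -> list[CategorizedCandidate]:
    """Run the whole pipeline against an offline corpus.

    Invalid identifiers (and valid ones whose bundle yields no
    searchable term) get an empty result and fall through the category
    rule — there is one output per input, always.
    """
    out: list[CategorizedCandidate] = []
    for inp in inputs:
        cand = resolve_candidate(inp, source)
        if not cand.is_valid:
            out.append(categorize_candidate(cand, _empty_result(cand, spec)))
            continue
        try:
            q = build_pubmed_query(cand, spec)
        except VacuousQueryError:
            out.append(categorize_candidate(cand, _empty_result(cand, spec)))
            continue
        result = search_offline(q, corpus)
        out.append(categorize_candidate(cand, result))
    return out


def triage_live(
    inputs: Sequence[CandidateInput],
    source: SynonymSource,
    spec: SearchSpec,
    pubmed_client: Optional[PubMedClient] = None,
) -> list[CategorizedCandidate]:
    """Run the pipeline against PubMed or PubTator (per ``spec.backend``)."""
    client = pubmed_client or PubMedClient()
    out: list[CategorizedCandidate] = []
    for inp in inputs:
        cand = resolve_candidate(inp, source)
        if not cand.is_valid:
            out.append(categorize_candidate(cand, _empty_result(cand, spec)))
            continue
        try:
            if spec.backend is Backend.PUBTATOR:
                q = build_pubtator_query(cand, spec)
                result = search_pubtator(q)
            else:
                q = build_pubmed_query(cand, spec)
                result = search_pubmed(q, client)
        except VacuousQueryError:
            out.append(categorize_candidate(cand, _empty_result(cand, spec)))
            continue
        out.append(categorize_candidate(cand, result))
    return out
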