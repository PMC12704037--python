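"""Evidence categorization and the SuperMatch flag.

The category rule is a four-way partition over candidates: at least one
retrieved publication and at least one of them a review → Category 1;
publications but no review → Category 2; no publications but a valid
identifier → Category 3; everything else (chiefly unresolvable
identifiers) → Category 4.

SuperMatch is a per-publication specificity signal: a record earns
``Match`` when a *protein name* — not merely the gene symbol — occurs in
its title or abstract, regardless of the scope the query searched.
Gene symbols like "SCAN" or "DI" collide with ordinary words, so a
candidate with many hits but few SuperMatches is probably riding an
ambiguous symbol; the tool flags this, it never auto-filters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from .model import (
    Backend,
    CategorizedCandidate,
    Category,
    PublicationRecord,
    ResolvedCandidate,
    RetrievalResult,
    Scope,
    SearchSpec,
    SuperMatch,
    TermClass,
)
from .retrieve import DEFAULT_REVIEW_TYPES, _fields_in_scope, is_review
from .textmatch import contains_term


def categorize(
    cand: ResolvedCandidate,
    result: RetrievalResult,
    review_types: frozenset[str] = DEFAULT_REVIEW_TYPES,
) -> Category:
    """Assign the evidence category; total over all inputs.

    Computed from the fetched (possibly capped) record list: a review
    beyond the cap is invisible, which the relevance-first default sort
    mitigates; ``result.truncated`` tells the user when this applies.
    """
    if result.records:
        if any(is_review(r, review_types) for r in result.records):
            return Category.REVIEW
        return Category.PUBLICATION
    if cand.is_valid:
        return Category.NO_PUBLICATION
    return Category.INVALID


def supermatch(rec: PublicationRecord, cand: ResolvedCandidate) -> SuperMatch:
    """``Match`` iff any protein-name term occurs in the title OR the
    abstract — even when the query searched titles only."""
    haystack = f"{rec.title}\n{rec.abstract}"
    for name in cand.protein_names:
        if contains_term(haystack, name):
            return SuperMatch.MATCH
    return SuperMatch.NO_MATCH


def categorize_candidate(
    cand: ResolvedCandidate,
    result: RetrievalResult,
    review_types: frozenset[str] = DEFAULT_REVIEW_TYPES,
) -> CategorizedCandidate:
    """Bundle category + per-record SuperMatch flags for one candidate."""
    return CategorizedCandidate(
        candidate=cand,
        result=result,
        category=categorize(cand, result, review_types),
        supermatch_flags=tuple(supermatch(r, cand) for r in result.records),
    )


@dataclass(frozen=True)
class KeywordCheck:
    """Outcome of re-verifying one record against the search keywords."""

    pub_id: str
    all_keywords_present: bool
    semantic_only: bool  # failed exact matching but came from a semantic backend


@dataclass(frozen=True)
class KeywordReport:
    checks: tuple[KeywordCheck, ...]

    @property
    def false_positive_count(self) -> int:
        return sum(
            1 for c in self.checks if not c.all_keywords_present and not c.semantic_only
        )

    @property
    def semantic_only_count(self) -> int:
        return sum(1 for c in self.checks if c.semantic_only)


def verify_keywords(result: RetrievalResult, spec: SearchSpec) -> KeywordReport:
    """Re-check that every retrieved record contains all keywords within
    the searched scope.

    For exact-matching backends a failure is a false positive.  Records
    from PubTator are exempt from hard failure: the service expands
    keywords to same-meaning words (cancer → tumour/tumor/carcinoma),
    so an exact-match miss there is reported informationally as
    ``semantic_only``.
    """
    checks = []
    for rec in result.records:
        text = _fields_in_scope(rec, spec.scope)
        ok = all(contains_term(text, k) for k in spec.keywords)
        checks.append(
            KeywordCheck(
                pub_id=rec.pub_id,
                all_keywords_present=ok,
                semantic_only=(not ok and rec.source is Backend.PUBTATOR),
            )
        )
    return KeywordReport(tuple(checks))


def summarize_categories(
    cands: Iterable[CategorizedCandidate],
) -> tuple[dict[Category, int], int]:
    """Per-category candidate counts plus the total publication count
    (the numbers behind the summary pie charts)."""
    counts = {c: 0 for c in Category}
    total_pubs = 0
    for cc in cands:
        counts[cc.category] += 1
        total_pubs += len(cc.result.records)
    return counts, total_pubs
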