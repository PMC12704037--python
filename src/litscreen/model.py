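"""Domain types for marker-candidate literature triage.

The pipeline turns a list of gene/protein identifiers into evidence
categories by (1) resolving each identifier to a bundle of searchable
terms, (2) compiling a boolean bibliographic query, (3) retrieving
publications from a backend, and (4) classifying the candidate by the
retrieved evidence.  These dataclasses are the contracts between those
stages.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, field, replace
from typing import Optional


class IdType(str, enum.Enum):
    """How a raw candidate identifier is to be interpreted."""

    ACCESSION = "accession"
    GENE_NAME = "gene_name"


class TermClass(str, enum.Enum):
    """Provenance of a searchable term; ordering encodes priority.

    When the same string appears under several classes it is kept once
    under the highest-priority class (gene_name > synonym > protein_name).
    The protein_name class is what the SuperMatch flag keys on.
    """

    GENE_NAME = "gene_name"
    SYNONYM = "synonym"
    PROTEIN_NAME = "protein_name"


_CLASS_PRIORITY = {
    TermClass.GENE_NAME: 0,
    TermClass.SYNONYM: 1,
    TermClass.PROTEIN_NAME: 2,
}


class Scope(str, enum.Enum):
    """Which article fields terms and keywords are matched against."""

    TITLE_ONLY = "title_only"
    TITLE_AND_ABSTRACT = "title_and_abstract"


class Backend(str, enum.Enum):
    PUBMED = "pubmed"
    PUBTATOR = "pubtator"
    OFFLINE = "offline"


class SortOrder(str, enum.Enum):
    DATE = "date"
    RELEVANCE = "relevance"


class Category(enum.IntEnum):
    """Evidence tier of a candidate.

    1: at least one retrieved publication is a review — the candidate is
       well characterized with respect to the scientific question.
    2: publications exist, none of them reviews.
    3: no publications, but the identifier is valid — potential novelty.
    4: the identifier did not resolve (or otherwise): nothing is known,
       or the name could not be mapped.
    """

    REVIEW = 1
    PUBLICATION = 2
    NO_PUBLICATION = 3
    INVALID = 4


class SuperMatch(str, enum.Enum):
    """Per-publication specificity flag.

    ``MATCH`` when a protein name (not merely the gene symbol) occurs in
    the title or abstract; protein names are usually more specific than
    gene symbols, so many hits with few SuperMatches is the signature of
    an ambiguous gene name.
    """

    MATCH = "Match"
    NO_MATCH = "noMatch"


@dataclass(frozen=True)
class CandidateInput:
    """One raw input identifier plus how to interpret it.

    Parameters
    ----------
    raw_id:
        UniProt accession or gene name, non-blank.
    id_type:
        Explicit interpretation; never inferred from the string shape.
    taxon_id:
        NCBI taxonomy identifier of the organism (positive integer).
    """

    raw_id: str
    id_type: IdType
    taxon_id: int

    def __post_init__(self) -> None:
        trimmed = self.raw_id.strip()
        if not trimmed:
            raise ValueError("raw_id must be non-empty after trimming")
        object.__setattr__(self, "raw_id", trimmed)
        if not isinstance(self.id_type, IdType):
            object.__setattr__(self, "id_type", IdType(self.id_type))
        if self.taxon_id <= 0:
            raise ValueError(f"taxon_id must be positive, got {self.taxon_id}")


@dataclass(frozen=True)
class Term:
    """A searchable string with its provenance class.

    ``text`` keeps the display casing; comparisons are case-insensitive.
    """

    text: str
    term_class: TermClass

    def __post_init__(self) -> None:
        if not self.text:
            raise ValueError("term text must be non-empty")

    @property
    def priority(self) -> int:
        return _CLASS_PRIORITY[self.term_class]


@dataclass(frozen=True)
class ResolvedCandidate:
    """A candidate expanded to its full synonym bundle.

    ``terms`` is the de-duplicated union of gene names, gene synonyms and
    protein names; each term carries its provenance class because the
    SuperMatch rule treats protein names specially.  ``is_valid`` is true
    iff the identifier resolved to a record for the requested taxon.
    """

    input: CandidateInput
    primary_accession: Optional[str] = None
    terms: tuple[Term, ...] = ()
    is_valid: bool = False

    def __post_init__(self) -> None:
        if self.is_valid and not self.terms:
            raise ValueError("a valid candidate must carry at least one term")
        seen: set[str] = set()
        for t in self.terms:
            key = t.text.casefold()
            if key in seen:
                raise ValueError(f"duplicate term (case-insensitive): {t.text!r}")
            seen.add(key)

    def terms_of(self, term_class: TermClass) -> tuple[str, ...]:
        return tuple(t.text for t in self.terms if t.term_class == term_class)

    @property
    def gene_names(self) -> tuple[str, ...]:
        return self.terms_of(TermClass.GENE_NAME)

    @property
    def gene_synonyms(self) -> tuple[str, ...]:
        return self.terms_of(TermClass.SYNONYM)

    @property
    def protein_names(self) -> tuple[str, ...]:
        return self.terms_of(TermClass.PROTEIN_NAME)

    def with_terms(self, terms: tuple[Term, ...]) -> "ResolvedCandidate":
        return replace(self, terms=terms)


DEFAULT_MAX_PUBLICATIONS = 1000


@dataclass(frozen=True)
class SearchSpec:
    """User-level search options shared by every backend.

    ``max_publications`` caps retrieval (default 1000, chosen so several
    hundred candidates still fit in one spreadsheet); for the PubTator
    backend the cap is advisory because the service fixes its page size.
    ``max_date`` enables replaying a search as of a past date.
    """

    keywords: tuple[str, ...]
    scope: Scope = Scope.TITLE_AND_ABSTRACT
    max_date: Optional[_dt.date] = None
    max_publications: int = DEFAULT_MAX_PUBLICATIONS
    sort: SortOrder = SortOrder.RELEVANCE
    backend: Backend = Backend.OFFLINE

    def __post_init__(self) -> None:
        kws = tuple(k.strip() for k in self.keywords)
        if not kws or any(not k for k in kws):
            raise ValueError("keywords must be a non-empty list of non-blank strings")
        object.__setattr__(self, "keywords", kws)
        if self.max_publications < 1:
            raise ValueError("max_publications must be >= 1")
        for name, typ in (("scope", Scope), ("sort", SortOrder), ("backend", Backend)):
            val = getattr(self, name)
            if not isinstance(val, typ):
                object.__setattr__(self, name, typ(val))


@dataclass(frozen=True)
class Query:
    """A compiled boolean query in one backend's dialect.

    ``expression`` is the dialect string actually sent to the backend;
    ``terms``/``keywords`` keep the structured form so the offline engine
    and invariant checks need not re-parse the string.
    """

    candidate_ref: str
    expression: str
    terms: tuple[Term, ...]
    spec: SearchSpec
    #: emitted terms short enough to collide with common words; carried
    #: through to the report so users can eyeball them
    ambiguous_terms: tuple[str, ...] = ()

    @property
    def term_count(self) -> int:
        return len(self.terms)

    @property
    def keywords(self) -> tuple[str, ...]:
        return self.spec.keywords


@dataclass(frozen=True)
class PublicationRecord:
    """One retrieved article."""

    pub_id: str
    title: str
    abstract: str = ""
    publication_types: tuple[str, ...] = ()
    pub_date: Optional[_dt.date] = None
    source: Backend = Backend.OFFLINE

    def __post_init__(self) -> None:
        if not self.pub_id:
            raise ValueError("pub_id must be non-empty")
        if not self.title:
            raise ValueError("title must be non-empty")
        if not isinstance(self.source, Backend):
            object.__setattr__(self, "source", Backend(self.source))


@dataclass(frozen=True)
class RetrievalResult:
    """Ordered result set for one query, with truncation bookkeeping."""

    query: Query
    records: tuple[PublicationRecord, ...]
    total_hits: int
    results_link: Optional[str] = None
    truncated: bool = False

    def __post_init__(self) -> None:
        if self.total_hits < 0:
            raise ValueError("total_hits must be non-negative")
        if len(self.records) > self.total_hits:
            raise ValueError("records cannot exceed total_hits")
        ids = [r.pub_id for r in self.records]
        if len(ids) != len(set(ids)):
            raise ValueError("pub_ids must be unique within a result set")
        expected_trunc = self.total_hits > len(self.records)
        if self.truncated != expected_trunc:
            raise ValueError("truncated flag inconsistent with counts")


@dataclass(frozen=True)
class CategorizedCandidate:
    """Final verdict for one candidate: category plus per-record flags."""

    candidate: ResolvedCandidate
    result: RetrievalResult
    category: Category
    supermatch_flags: tuple[SuperMatch, ...]

    def __post_init__(self) -> None:
        if len(self.supermatch_flags) != len(self.result.records):
            raise ValueError("one SuperMatch flag per retrieved record required")

    @property
    def supermatch_count(self) -> int:
        return sum(1 for f in self.supermatch_flags if f is SuperMatch.MATCH)


@dataclass(frozen=True)
class RejectedId:
    """An input identifier that could not be mapped, with the reason."""

    raw_id: str
    reason: str


__all__ = [
    "Backend",
    "CandidateInput",
    "CategorizedCandidate",
    "Category",
    "DEFAULT_MAX_PUBLICATIONS",
    "IdType",
    "PublicationRecord",
    "Query",
    "RejectedId",
    "ResolvedCandidate",
    "RetrievalResult",
    "Scope",
    "SearchSpec",
    "SortOrder",
    "SuperMatch",
    "Term",
    "TermClass",
]
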