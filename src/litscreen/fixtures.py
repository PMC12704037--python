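"""Synthetic corpora with planted ground truth, and the brute-force
search oracle.

The generator emulates what the live services provide — a UniProt-like
synonym table and a publication corpus — with every candidate's category
and matching publication set planted by construction.  Document text is
assembled from a closed nonsense vocabulary plus deliberately injected
terms and keywords, so token-boundary matching is unambiguous and truth
is recomputable.  Ambiguous-name probes (a gene named like an ordinary
corpus word, the "SCAN"/"DI" situation) are planted to exhibit the noise
signature: many hits, zero SuperMatches.

:func:`oracle_search` is the independent oracle: a nested-loop scan with
its own character-level matching code, sharing nothing with
:mod:`litscreen.textmatch` or the offline engine it is used to check.
"""

from __future__ import annotations

import datetime as _dt
import functools as _functools
import json
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .errors import CorpusSpecError
from .model import (
    Backend,
    CandidateInput,
    Category,
    IdType,
    PublicationRecord,
    Scope,
)
from .resolve import OfflineSynonymTable, SynonymRecord

# Closed filler vocabulary: nonsense tokens that never collide with any
# term or keyword (no real gene symbols, no English words used as
# keywords in tests).
_VOCAB = (
    "blorv", "crantu", "drellis", "fornax", "glimber", "hastrel",
    "jintor", "kelvax", "lumbra", "morvel", "nextil", "ovrand",
    "prellin", "quastor", "rembal", "sorvex", "trandel", "umbrix",
    "vastrel", "wrelkin", "yintor", "zorbal", "axtrem", "belfor",
)

# Words an ambiguous gene symbol may be named after; they appear in
# ordinary (non-keyword) filler text too, which is exactly the hazard.
_AMBIGUOUS_WORDS = ("scan", "dial", "bright", "mode")


@dataclass(frozen=True)
class TruthEntry:
    """Planted expectation for one candidate under the corpus's own
    query configuration (its keywords, scope and no date ceiling)."""

    raw_id: str
    id_type: IdType
    category: Category
    pub_ids: tuple[str, ...]
    ambiguous_probe: bool = False


@dataclass(frozen=True)
class CorpusSpec:
    """Recipe for one synthetic corpus.

    ``quotas`` fixes how many candidates land in each category;
    ``n_ambiguous`` of the Category-2 quota are ambiguous-name probes.
    ``keywords`` are the query keywords every planted matching document
    contains (decoys omit at least one).  All randomness flows from
    ``seed``.
    """

    n_documents: int = 500
    quotas: dict[Category, int] = field(
        default_factory=lambda: {
            Category.REVIEW: 5,
            Category.PUBLICATION: 7,
            Category.NO_PUBLICATION: 5,
            Category.INVALID: 3,
        }
    )
    keywords: tuple[str, ...] = ("cancer",)
    scope: Scope = Scope.TITLE_AND_ABSTRACT
    n_ambiguous: int = 2
    review_fraction: float = 0.1
    date_range: tuple[_dt.date, _dt.date] = (_dt.date(1990, 1, 1), _dt.date(2024, 12, 31))
    taxon_id: int = 9606
    seed: int = 0

    @property
    def n_candidates(self) -> int:
        return sum(self.quotas.values())

    def validate(self) -> None:
        if any(v < 0 for v in self.quotas.values()):
            raise CorpusSpecError("quotas must be non-negative")
        if not self.keywords:
            raise CorpusSpecError("at least one keyword is required")
        if self.quotas.get(Category.REVIEW, 0) > 0 and self.review_fraction <= 0:
            raise CorpusSpecError(
                "Category-1 quota requires review_fraction > 0 (no review-typed "
                "documents can exist otherwise)"
            )
        if self.n_ambiguous > self.quotas.get(Category.PUBLICATION, 0):
            raise CorpusSpecError(
                "ambiguous probes are drawn from the Category-2 quota"
            )
        if self.n_ambiguous > len(_AMBIGUOUS_WORDS):
            raise CorpusSpecError(
                f"at most {len(_AMBIGUOUS_WORDS)} ambiguous probes are available"
            )
        if self.date_range[0] > self.date_range[1]:
            raise CorpusSpecError("empty date range")


@dataclass
class FixtureCorpus:
    """Documents + synonym table + planted truth."""

    documents: list[PublicationRecord]
    synonym_records: list[SynonymRecord]
    truth: dict[str, TruthEntry]
    keywords: tuple[str, ...] = ("cancer",)
    scope: Scope = Scope.TITLE_AND_ABSTRACT
    taxon_id: int = 9606

    def synonym_table(self) -> OfflineSynonymTable:
        return OfflineSynonymTable(self.synonym_records)

    def candidate_inputs(self) -> list[CandidateInput]:
        return [
            CandidateInput(t.raw_id, t.id_type, self.taxon_id)
            for t in self.truth.values()
        ]

    # -- bundle IO ---------------------------------------------------------
    def save(self, directory: str | Path) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "documents.jsonl", "w", encoding="utf-8") as fh:
            for rec in self.documents:
                fh.write(json.dumps({
                    "pub_id": rec.pub_id,
                    "title": rec.title,
                    "abstract": rec.abstract,
                    "publication_types": list(rec.publication_types),
                    "pub_date": rec.pub_date.isoformat() if rec.pub_date else None,
                }) + "\n")
        self.synonym_table().to_tsv(d / "synonyms.tsv")
        with open(d / "truth.tsv", "w", encoding="utf-8") as fh:
            fh.write("raw_id\tid_type\tcategory\tambiguous_probe\tpub_ids\n")
            for t in self.truth.values():
                fh.write(
                    f"{t.raw_id}\t{t.id_type.value}\t{int(t.category)}\t"
                    f"{int(t.ambiguous_probe)}\t{';'.join(t.pub_ids)}\n"
                )
        (d / "manifest.json").write_text(json.dumps({
            "documents": "documents.jsonl",
            "synonym_table": "synonyms.tsv",
            "truth": "truth.tsv",
            "keywords": list(self.keywords),
            "scope": self.scope.value,
            "taxon_id": self.taxon_id,
        }, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "FixtureCorpus":
        d = Path(directory)
        manifest = json.loads((d / "manifest.json").read_text())
        documents = []
        with open(d / manifest["documents"], encoding="utf-8") as fh:
            for line in fh:
                obj = json.loads(line)
                documents.append(PublicationRecord(
                    pub_id=obj["pub_id"],
                    title=obj["title"],
                    abstract=obj.get("abstract", ""),
                    publication_types=tuple(obj.get("publication_types", ())),
                    pub_date=_dt.date.fromisoformat(obj["pub_date"]) if obj.get("pub_date") else None,
                    source=Backend.OFFLINE,
                ))
        table = OfflineSynonymTable.from_tsv(d / manifest["synonym_table"])
        truth: dict[str, TruthEntry] = {}
        with open(d / manifest["truth"], encoding="utf-8") as fh:
            next(fh)
            for line in fh:
                raw_id, id_type, cat, amb, pubs = line.rstrip("\n").split("\t")
                truth[raw_id] = TruthEntry(
                    raw_id=raw_id,
                    id_type=IdType(id_type),
                    category=Category(int(cat)),
                    pub_ids=tuple(p for p in pubs.split(";") if p),
                    ambiguous_probe=bool(int(amb)),
                )
        return cls(
            documents=documents,
            synonym_records=table.records,
            truth=truth,
            keywords=tuple(manifest["keywords"]),
            scope=Scope(manifest["scope"]),
            taxon_id=manifest["taxon_id"],
        )


# ---------------------------------------------------------------------------
# Generation


def _sentence(rng: random.Random, vocab: Sequence[str], n: int) -> str:
    return " ".join(rng.choice(vocab) for _ in range(n))


def _rand_date(rng: random.Random, lo: _dt.date, hi: _dt.date) -> _dt.date:
    return lo + _dt.timedelta(days=rng.randrange((hi - lo).days + 1))


def generate_corpus(spec: CorpusSpec) -> FixtureCorpus:
    """Build a corpus whose oracle categories equal the quota plan.

    Terms of non-ambiguous candidates are unique synthetic tokens that
    never occur in filler text, so a candidate's matching set is exactly
    its planted documents.  Ambiguous probes reuse a filler word as the
    gene symbol; their planted documents contain the word plus all
    keywords but never a protein name, so every hit is SuperMatch-free.
    Deterministic under ``spec.seed``.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    lo, hi = spec.date_range

    safe_vocab = tuple(w for w in _VOCAB if w not in spec.keywords)

    # --- candidates -------------------------------------------------------
    plan: list[Category] = []
    for cat in Category:
        plan.extend([cat] * spec.quotas.get(cat, 0))
    rng.shuffle(plan)

    synonym_records: list[SynonymRecord] = []
    truth: dict[str, TruthEntry] = {}
    documents: list[PublicationRecord] = []
    doc_no = 0

    def next_id() -> str:
        nonlocal doc_no
        doc_no += 1
        return f"d{doc_no:05d}"

    def make_doc(
        title_extra: list[str],
        abstract_extra: list[str],
        review: bool,
        vocab: Sequence[str] = safe_vocab,
    ) -> PublicationRecord:
        title_words = _sentence(rng, vocab, rng.randint(4, 8))
        abstract_words = _sentence(rng, vocab, rng.randint(10, 20))
        title = " ".join(title_extra + [title_words]) if title_extra else title_words
        abstract = (
            " ".join([abstract_words] + abstract_extra) if abstract_extra else abstract_words
        )
        return PublicationRecord(
            pub_id=next_id(),
            title=title,
            abstract=abstract,
            publication_types=("Journal Article", "Review") if review else ("Journal Article",),
            pub_date=_rand_date(rng, lo, hi),
            source=Backend.OFFLINE,
        )

    def plant(term: str, review: bool) -> PublicationRecord:
        """A document matching: term + all keywords, placed within the
        corpus scope (title under title_only, else split over both)."""
        injected = [term, *spec.keywords]
        rng.shuffle(injected)
        if spec.scope is Scope.TITLE_ONLY:
            return make_doc(injected, [], review)
        cut = rng.randint(0, len(injected))
        return make_doc(injected[:cut], injected[cut:], review)

    ambiguous_left = spec.n_ambiguous
    amb_words = list(_AMBIGUOUS_WORDS)
    for i, cat in enumerate(plan):
        is_probe = cat is Category.PUBLICATION and ambiguous_left > 0
        if is_probe:
            ambiguous_left -= 1
            gene = amb_words.pop(0).upper()
            synonyms: tuple[str, ...] = ()
            proteins: tuple[str, ...] = (f"Improbable-protein-{i} gamma",)
        else:
            gene = f"GN{i:03d}X"
            synonyms = tuple(f"GS{i:03d}{c}" for c in "AB"[: rng.randint(1, 2)])
            proteins = (f"Fixprotein-{i} alpha", f"FP-{i}-beta")
        raw_id = gene
        if cat is Category.INVALID:
            # deliberately absent from the synonym table
            truth[raw_id] = TruthEntry(raw_id, IdType.GENE_NAME, cat, ())
            continue
        synonym_records.append(SynonymRecord(
            accession=f"PX{i:04d}",
            taxon_id=spec.taxon_id,
            gene_name=gene,
            gene_synonyms=synonyms,
            protein_names=proteins,
        ))
        if cat is Category.NO_PUBLICATION:
            # decoys exercise AND semantics: term without full keyword set
            if rng.random() < 0.7:
                documents.append(make_doc([gene], list(spec.keywords[1:]), review=False))
            truth[raw_id] = TruthEntry(raw_id, IdType.GENE_NAME, cat, ())
            continue
        n_docs = rng.randint(5, 9) if is_probe else rng.randint(1, 4)
        planted: list[PublicationRecord] = []
        for j in range(n_docs):
            review = (cat is Category.REVIEW) and (
                j == 0 or rng.random() < spec.review_fraction
            )
            if is_probe:
                planted.append(plant(gene.lower(), review))
            else:
                term = rng.choice([gene, *synonyms, *proteins])
                planted.append(plant(term, review))
        documents.extend(planted)
        truth[raw_id] = TruthEntry(
            raw_id, IdType.GENE_NAME, cat,
            tuple(sorted(p.pub_id for p in planted)),
            ambiguous_probe=is_probe,
        )

    # --- filler -----------------------------------------------------------
    # keyword-only decoys (no term ⇒ no match) and pure-filler documents;
    # filler may be review-typed at the corpus review fraction
    while len(documents) < spec.n_documents:
        review = rng.random() < spec.review_fraction
        if rng.random() < 0.2:
            documents.append(make_doc(list(spec.keywords), [], review))
        else:
            documents.append(make_doc([], [], review, vocab=_VOCAB))
    if len(documents) > spec.n_documents:
        raise CorpusSpecError(
            f"planted documents ({len(documents)}) exceed n_documents ({spec.n_documents})"
        )
    rng.shuffle(documents)
    return FixtureCorpus(
        documents=documents,
        synonym_records=synonym_records,
        truth=truth,
        keywords=spec.keywords,
        scope=spec.scope,
        taxon_id=spec.taxon_id,
    )


# ---------------------------------------------------------------------------
# The worked-example-shaped regression fixture


def dcn_like_corpus() -> FixtureCorpus:
    """Deterministic corpus mirroring, at fixture scale, the classic
    decorin situation: a gene-name-only query finds 2 documents, the
    full synonym bundle finds 54 (the 2 included), and all 52 additional
    documents are reached through the protein name "Decorin" alone —
    each of them a SuperMatch.
    """
    rng = random.Random(20190913)
    lo, hi = _dt.date(1995, 1, 1), _dt.date(2019, 9, 13)
    docs: list[PublicationRecord] = []

    def filler(n: int) -> str:
        return _sentence(rng, _VOCAB, n)

    # 2 documents carrying the gene symbol itself (+ keyword), no protein name
    for i in range(1, 3):
        docs.append(PublicationRecord(
            pub_id=f"dcn{i:04d}",
            title=f"DCN expression in cancer {filler(4)}",
            abstract=filler(12),
            publication_types=("Journal Article",),
            pub_date=_rand_date(rng, lo, hi),
            source=Backend.OFFLINE,
        ))
    # 52 documents reachable only via the protein name
    for i in range(3, 55):
        review = i <= 7  # a few reviews so the candidate lands in Category 1
        docs.append(PublicationRecord(
            pub_id=f"dcn{i:04d}",
            title=f"Decorin and cancer {filler(4)}",
            abstract=filler(12),
            publication_types=("Journal Article", "Review") if review else ("Journal Article",),
            pub_date=_rand_date(rng, lo, hi),
            source=Backend.OFFLINE,
        ))
    # decoys: protein name without the keyword; keyword without any term
    for i in range(55, 65):
        docs.append(PublicationRecord(
            pub_id=f"dcn{i:04d}",
            title=(f"Decorin in {filler(4)}" if i % 2 else f"cancer of the {filler(4)}"),
            abstract=filler(10),
            publication_types=("Journal Article",),
            pub_date=_rand_date(rng, lo, hi),
            source=Backend.OFFLINE,
        ))
    record = SynonymRecord(
        accession="PX9001",  # synthetic accession; fixture-scale stand-in
        taxon_id=9606,
        gene_name="DCN",
        gene_synonyms=("SLRR1B",),
        protein_names=("Decorin", "Bone-proteoglycan-II", "PG-S2", "PG40"),
    )
    truth = {
        "DCN": TruthEntry(
            raw_id="DCN",
            id_type=IdType.GENE_NAME,
            category=Category.REVIEW,
            pub_ids=tuple(f"dcn{i:04d}" for i in range(1, 55)),
        )
    }
    return FixtureCorpus(
        documents=docs,
        synonym_records=[record],
        truth=truth,
        keywords=("Cancer",),
        scope=Scope.TITLE_ONLY,
        taxon_id=9606,
    )


# ---------------------------------------------------------------------------
# The brute-force oracle (independent implementation)

_ORACLE_ALNUM = set("abcdefghijklmnopqrstuvwxyz0123456789")
_ORACLE_HYPHENS = "‐‑‒–−"


@_functools.lru_cache(maxsize=65536)
def _oracle_normalize(text: str) -> str:
    # independent re-statement of the matching semantics: lowercase,
    # unify hyphen variants, collapse whitespace (memoized — pure)
    chars = []
    for ch in text:
        if ch in _ORACLE_HYPHENS:
            chars.append("-")
        elif ch.isspace():
            chars.append(" ")
        else:
            chars.append(ch)
    collapsed = " ".join("".join(chars).split())
    return collapsed.casefold()


def _oracle_occurs(needle: str, haystack: str) -> bool:
    n, h = _oracle_normalize(needle), _oracle_normalize(haystack)
    if not n:
        return False
    start = 0
    while True:
        idx = h.find(n, start)
        if idx < 0:
            return False
        before_ok = idx == 0 or h[idx - 1] not in _ORACLE_ALNUM
        after = idx + len(n)
        after_ok = after >= len(h) or h[after] not in _ORACLE_ALNUM
        if before_ok and after_ok:
            return True
        start = idx + 1


def oracle_search(
    documents: Iterable[PublicationRecord],
    terms: Sequence[str],
    keywords: Sequence[str],
    scope: Scope,
    max_date: Optional[_dt.date] = None,
) -> set[str]:
    """Nested-loop reference search: a document is selected iff at least
    one term occurs AND every keyword occurs within the scope fields
    (and it is not dated past ``max_date``).  Returns the full uncapped
    id set.  Shares no matching code with the engine it validates.
    """
    if not keywords:
        raise ValueError("keywords must be non-empty")
    hits: set[str] = set()
    for doc in documents:
        if max_date is not None:
            if doc.pub_date is None or doc.pub_date > max_date:
                continue
        if scope is Scope.TITLE_ONLY:
            text = doc.title
        else:
            text = doc.title + "\n" + doc.abstract
        any_term = False
        for t in terms:
            if _oracle_occurs(t, text):
                any_term = True
                break
        if not any_term:
            continue
        all_kw = True
        for k in keywords:
            if not _oracle_occurs(k, text):
                all_kw = False
                break
        if all_kw:
            hits.add(doc.pub_id)
    return hits


def oracle_supermatch_ids(
    documents: Iterable[PublicationRecord], protein_names: Sequence[str]
) -> set[str]:
    """Documents whose title or abstract contains any protein name —
    the reference for the SuperMatch flag."""
    return {
        doc.pub_id
        for doc in documents
        if any(_oracle_occurs(p, doc.title + "\n" + doc.abstract) for p in protein_names)
    }
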