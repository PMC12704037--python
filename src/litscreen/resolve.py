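"""Identifier resolution: expand an accession or gene name into a bundle
of searchable terms (gene name, gene synonyms, protein names) for one
organism.

Two interchangeable synonym sources implement the same protocol: a live
UniProtKB REST client and an offline tab-separated synonym table.  Live
resolution is restricted to primary accessions (the REST search endpoint
only resolves primary accession numbers); secondary or deprecated
accessions should be converted first with
:func:`map_accessions_to_gene_names`.
"""

from __future__ import annotations

import json
import time
import urllib.error
import urllib.parse
import urllib.request
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Optional, Protocol

import pandas as pd

from .errors import TransportError
from .model import CandidateInput, IdType, RejectedId, ResolvedCandidate, Term, TermClass
from .textmatch import normalize_text

# ---------------------------------------------------------------------------
# Synonym-source protocol


@dataclass(frozen=True)
class SynonymRecord:
    """One synonym-source entry (the shape of a UniProt record slice)."""

    accession: str
    taxon_id: int
    gene_name: str
    gene_synonyms: tuple[str, ...]
    protein_names: tuple[str, ...]


class SynonymSource(Protocol):
    """Anything that can look up synonym records by identifier."""

    def lookup(self, raw_id: str, id_type: IdType, taxon_id: int) -> Optional[SynonymRecord]:
        """Return the matching record, or None if the identifier does not
        resolve for the given taxon.  Raises TransportError on failure."""
        ...


# ---------------------------------------------------------------------------
# Offline synonym table

OFFLINE_TABLE_COLUMNS = [
    "accession",
    "taxon_id",
    "gene_name",
    "gene_synonyms",
    "protein_names",
]


def _split_semicolons(cell: object) -> tuple[str, ...]:
    if cell is None or (isinstance(cell, float) and pd.isna(cell)):
        return ()
    return tuple(p.strip() for p in str(cell).split(";") if p.strip())


class OfflineSynonymTable:
    """Synonym source backed by a TSV table.

    Expected header: ``accession  taxon_id  gene_name  gene_synonyms
    protein_names`` with the last two semicolon-separated.  Lookups are
    exact (case-insensitive on gene names, case-preserving on
    accessions) and restricted to the requested taxon.
    """

    def __init__(self, records: Iterable[SynonymRecord]):
        self._records = list(records)
        self._by_accession: dict[tuple[str, int], SynonymRecord] = {}
        self._by_gene: dict[tuple[str, int], SynonymRecord] = {}
        for rec in self._records:
            self._by_accession[(rec.accession.upper(), rec.taxon_id)] = rec
            self._by_gene.setdefault((rec.gene_name.casefold(), rec.taxon_id), rec)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OfflineSynonymTable":
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
        missing = set(OFFLINE_TABLE_COLUMNS) - set(df.columns)
        if missing:
            raise ValueError(f"synonym table missing columns: {sorted(missing)}")
        records = [
            SynonymRecord(
                accession=row["accession"],
                taxon_id=int(row["taxon_id"]),
                gene_name=row["gene_name"],
                gene_synonyms=_split_semicolons(row["gene_synonyms"]),
                protein_names=_split_semicolons(row["protein_names"]),
            )
            for _, row in df.iterrows()
        ]
        return cls(records)

    def to_tsv(self, path: str | Path) -> None:
        df = pd.DataFrame(
            {
                "accession": [r.accession for r in self._records],
                "taxon_id": [r.taxon_id for r in self._records],
                "gene_name": [r.gene_name for r in self._records],
                "gene_synonyms": [";".join(r.gene_synonyms) for r in self._records],
                "protein_names": [";".join(r.protein_names) for r in self._records],
            }
        )
        df.to_csv(path, sep="\t", index=False)

    @property
    def records(self) -> list[SynonymRecord]:
        return list(self._records)

    def lookup(self, raw_id: str, id_type: IdType, taxon_id: int) -> Optional[SynonymRecord]:
        if id_type is IdType.ACCESSION:
            return self._by_accession.get((raw_id.upper(), taxon_id))
        return self._by_gene.get((raw_id.casefold(), taxon_id))


# ---------------------------------------------------------------------------
# Live UniProt client

UNIPROT_SEARCH_URL = "https://rest.uniprot.org/uniprotkb/search"

Transport = Callable[[str], bytes]


def _default_transport(url: str) -> bytes:
    req = urllib.request.Request(url, headers={"Accept": "application/json"})
    with urllib.request.urlopen(req, timeout=30) as resp:  # pragma: no cover - live
        return resp.read()


class UniProtClient:
    """UniProtKB REST synonym source.

    Queries filter on exact gene name (or primary accession) AND
    organism id, preferring reviewed (Swiss-Prot) entries; among several
    reviewed hits the entry with the most annotations wins and the
    discards are logged on the instance (``discarded``).  Responses are
    cached on disk keyed by (identifier, taxon, snapshot date) so reruns
    are deterministic and polite to the API.
    """

    def __init__(
        self,
        transport: Transport = _default_transport,
        cache_dir: str | Path | None = None,
        snapshot_date: str = "latest",
        max_retries: int = 5,
        retry_wait: float = 1.0,
    ):
        self._transport = transport
        self._cache_dir = Path(cache_dir) if cache_dir else None
        self._snapshot = snapshot_date
        self._max_retries = max_retries
        self._retry_wait = retry_wait
        self.discarded: list[str] = []

    # -- caching -----------------------------------------------------------
    def _cache_path(self, key: str) -> Optional[Path]:
        if self._cache_dir is None:
            return None
        safe = urllib.parse.quote(key, safe="")
        return self._cache_dir / f"{safe}.{self._snapshot}.json"

    def _fetch(self, url: str, cache_key: str) -> dict:
        path = self._cache_path(cache_key)
        if path is not None and path.exists():
            return json.loads(path.read_text())
        last: Exception | None = None
        for attempt in range(self._max_retries):
            try:
                raw = self._transport(url)
                break
            except (urllib.error.URLError, OSError) as exc:
                last = exc
                time.sleep(self._retry_wait * 2**attempt)
        else:
            raise TransportError(f"UniProt request failed after retries: {last}")
        payload = json.loads(raw)
        if path is not None:
            path.parent.mkdir(parents=True, exist_ok=True)
            path.write_text(json.dumps(payload))
        return payload

    # -- record extraction -------------------------------------------------
    @staticmethod
    def _protein_names(entry: dict) -> tuple[str, ...]:
        # recommended full name + short names + alternative names;
        # EC numbers and "Cleaved into" subchains are too noisy for
        # title matching and are skipped.
        desc = entry.get("proteinDescription", {})
        names: list[str] = []

        def harvest(block: dict) -> None:
            full = block.get("fullName", {}).get("value")
            if full:
                names.append(full)
            for short in block.get("shortNames", []):
                if short.get("value"):
                    names.append(short["value"])

        if "recommendedName" in desc:
            harvest(desc["recommendedName"])
        for alt in desc.get("alternativeNames", []):
            harvest(alt)
        return tuple(names)

    @staticmethod
    def _gene_fields(entry: dict) -> tuple[str, tuple[str, ...]]:
        genes = entry.get("genes", [])
        if not genes:
            return "", ()
        primary = genes[0].get("geneName", {}).get("value", "")
        synonyms = tuple(
            s["value"] for g in genes for s in g.get("synonyms", []) if s.get("value")
        )
        return primary, synonyms

    def lookup(self, raw_id: str, id_type: IdType, taxon_id: int) -> Optional[SynonymRecord]:
        if id_type is IdType.ACCESSION:
            query = f"accession:{raw_id} AND organism_id:{taxon_id}"
        else:
            query = f"gene_exact:{raw_id} AND organism_id:{taxon_id}"
        url = (
            f"{UNIPROT_SEARCH_URL}?format=json&size=25&query="
            + urllib.parse.quote(query)
        )
        payload = self._fetch(url, cache_key=f"{raw_id}|{taxon_id}|{id_type.value}")
        results = payload.get("results", [])
        if not results:
            return None
        reviewed = [
            e for e in results
            if e.get("entryType", "").startswith("UniProtKB reviewed")
        ]
        pool = reviewed or results
        # most-annotated reviewed entry wins; annotationScore breaks ties
        pool.sort(
            key=lambda e: (e.get("annotationScore", 0), e.get("primaryAccession", "")),
            reverse=True,
        )
        chosen, rest = pool[0], pool[1:]
        for e in rest:
            self.discarded.append(
                f"{raw_id} (taxon {taxon_id}): discarded {e.get('primaryAccession')}"
            )
        gene, synonyms = self._gene_fields(chosen)
        return SynonymRecord(
            accession=chosen.get("primaryAccession", ""),
            taxon_id=taxon_id,
            gene_name=gene,
            gene_synonyms=synonyms,
            protein_names=self._protein_names(chosen),
        )


# ---------------------------------------------------------------------------
# Resolution operations


def dedupe_terms(terms: Iterable[Term]) -> tuple[Term, ...]:
    """Trim, collapse internal whitespace, and de-duplicate terms
    case-insensitively across classes.

    When the same string appears under several classes the
    highest-priority class wins (gene_name > synonym > protein_name);
    the first-seen display casing is preserved.
    """
    best: dict[str, Term] = {}
    order: list[str] = []
    for term in terms:
        cleaned = " ".join(term.text.split())
        if not cleaned:
            continue
        key = normalize_text(cleaned)
        if not key:
            continue
        incoming = Term(cleaned, term.term_class)
        if key not in best:
            best[key] = incoming
            order.append(key)
        elif incoming.priority < best[key].priority:
            best[key] = Term(best[key].text, incoming.term_class)
    return tuple(best[k] for k in order)


def normalize_terms(cand: ResolvedCandidate) -> ResolvedCandidate:
    """De-duplicated copy of a candidate (see :func:`dedupe_terms`).
    Never increases the term count and never removes the last term of a
    valid candidate."""
    return cand.with_terms(dedupe_terms(cand.terms))


def _bundle_terms(rec: SynonymRecord) -> tuple[Term, ...]:
    terms: list[Term] = []
    if rec.gene_name:
        terms.append(Term(rec.gene_name, TermClass.GENE_NAME))
    terms.extend(Term(s, TermClass.SYNONYM) for s in rec.gene_synonyms)
    terms.extend(Term(p, TermClass.PROTEIN_NAME) for p in rec.protein_names)
    return tuple(terms)


def resolve_candidate(inp: CandidateInput, backend: SynonymSource) -> ResolvedCandidate:
    """Resolve one identifier against a synonym source.

    Returns an invalid candidate (``is_valid=False``, empty terms) when
    no record matches the identifier and taxon; transport failures
    propagate as :class:`TransportError` so callers can distinguish
    "not found" from "could not ask".
    """
    rec = backend.lookup(inp.raw_id, inp.id_type, inp.taxon_id)
    if rec is None:
        return ResolvedCandidate(input=inp, is_valid=False)
    return ResolvedCandidate(
        input=inp,
        primary_accession=rec.accession or None,
        terms=dedupe_terms(_bundle_terms(rec)),
        is_valid=True,
    )


def map_accessions_to_gene_names(
    ids: list[str], backend: SynonymSource, taxon_id: int
) -> tuple[list[CandidateInput], list[RejectedId]]:
    """Map accession numbers to gene-name inputs.

    Recommended for candidate lists published before the current UniProt
    release cycle, where accessions may have been merged or demoted.
    Each mappable accession yields exactly one gene-name input;
    unmappable or deprecated accessions land in the rejection list with
    a reason, preserving input order.
    """
    if not ids:
        raise ValueError("ids must be non-empty")
    mapped: list[CandidateInput] = []
    rejected: list[RejectedId] = []
    for raw in ids:
        rec = backend.lookup(raw.strip(), IdType.ACCESSION, taxon_id)
        if rec is None:
            rejected.append(RejectedId(raw, "accession not found for taxon (deprecated or secondary?)"))
        elif not rec.gene_name:
            rejected.append(RejectedId(raw, "record has no gene name"))
        else:
            mapped.append(CandidateInput(rec.gene_name, IdType.GENE_NAME, taxon_id))
    return mapped, rejected
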