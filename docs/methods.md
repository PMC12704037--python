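# Methods

## Pipeline

`litscreen` triages a list of gene/protein identifiers in four stages.

**Resolution.** Each identifier (UniProt accession or gene name, plus an
NCBI taxonomy id) is expanded into a term bundle with three provenance
classes: primary gene name, gene synonyms, and protein names
(recommended full name, short names, alternative names; EC numbers and
"Cleaved into" subchain names are excluded as too noisy for title
matching). Sources are interchangeable: a live UniProtKB REST client or
an offline tab-separated synonym table. Live gene-name lookups filter on
exact gene name AND organism id and prefer reviewed (Swiss-Prot)
entries; among several reviewed hits the highest annotation score wins
and the discards are logged, never silently dropped. Only primary
accessions resolve directly; older lists should first go through
`map_accessions_to_gene_names`, which returns a gene-name input per
mappable accession and a reasoned rejection list for the rest. Terms
are whitespace-normalized and de-duplicated case-insensitively; when a
string appears under several classes the highest-priority class is kept
(gene name > synonym > protein name) — the partition matters because
SuperMatch keys on the protein-name class only.

**Query building.** The bundle forms one OR-group; every keyword is
AND-ed; an optional date ceiling becomes a publication-date range from
1800-01-01 (nothing older is indexed) to the ceiling, inclusive. The
same logical structure is rendered in two dialects: E-utilities syntax
with `[Title]`/`[Title/Abstract]` field tags, and the PubTator search
string (no field tags; the service scopes itself). Design choices made
here, with reasons:

- The scope (title-only vs title+abstract) applies to *both* terms and
  keywords, for symmetry — one scope, one meaning.
- Multi-word and punctuation-bearing terms are explicitly phrase-quoted
  (embedded quotes doubled, CSV-style, so parsing recovers the term
  exactly). Explicit quoting may retrieve marginally fewer hits than
  relying on a service's automatic phrase handling, but it makes the
  emitted query unambiguous and round-trippable.
- Terms of length 1 are never emitted (they cannot be meaningfully
  field-searched); length-2 terms are emitted but carried in the report
  as `ambiguous_terms`, since short symbols collide with common words.
- A valid candidate whose bundle is empty after these rules raises a
  hard error rather than emitting a vacuous query.

The module ships its own parser for both dialects; emit→parse being the
identity on every term is enforced by property tests.

**Retrieval.** Three backends return the same result contract (ordered
records, total hit count, truncation flag, optional full-results link).
PubMed: esearch id paging (400 ids/page) then efetch XML, capped at
`max_publications` (default 1000 — the cap keeps several hundred
candidates under the spreadsheet row limit). PubTator 3.0: the service
returns only its first page of 10 records; the link to the full result
set is always recorded. Rate limiting is 3 requests/s without an NCBI
API key, 10/s with one; transient failures (timeouts, 429/5xx) retry
with exponential backoff up to 5 times and then raise a transport error
that is distinct from a backend-reported query-syntax error (the former
implicates the network, the latter the query builder). The offline
backend applies exact boolean matching over an in-memory corpus.

Matching semantics (offline engine, keyword verification, SuperMatch):
case-insensitive; Unicode hyphen variants are unified to `-` and
whitespace runs collapsed; a term matches iff its normalized form occurs
with no alphanumeric character adjacent on either side — single tokens
match at token boundaries, multi-word terms as contiguous phrases. This
mirrors the quoted-phrase behaviour of the live dialects.

Sort orders: `date` is descending publication date; `relevance` is
delegated to live backends and defined offline as distinct-term-hit
count, then recency, then identifier. All ties break on the publication
identifier, so identical inputs give byte-identical outputs.

**Classification.** Category 1: ≥1 record and ≥1 review. Category 2:
≥1 record, no review. Category 3: no records but a valid identifier.
Category 4: otherwise. Review detection is membership of a publication
type in {Review, Systematic Review}; Meta-Analysis is excluded (it
aggregates primary studies rather than reviewing a molecule) but the
set is a parameter. The category is computed from the fetched, possibly
capped record list: a review beyond the cap is invisible — a documented
limitation mitigated by the relevance-first default sort and surfaced
through the `truncated` flag. SuperMatch is computed per record: `Match`
iff any protein-name term occurs in title or abstract, regardless of the
query scope. Gene synonyms never trigger it — protein names are usually
more specific than gene symbols, which is the point of the flag. The
candidate-level SuperMatch count is reported so users can spot the
ambiguous-symbol signature (many hits, few SuperMatches); the tool
flags, it never auto-filters. `verify_keywords` re-checks every record
against the keywords in scope; records from PubTator are exempt from
hard failure because the service expands keywords semantically (cancer
→ tumour/tumor/carcinoma), and such records are reported as
semantic-only matches.

**Reporting.** One row per (candidate, publication); zero-hit candidates
emit one row with empty publication fields, so row count is
Σ max(1, hits). Candidates are ordered by category then input order.
TSV is the canonical, byte-stable format (ISO-8601 dates, empty strings
for missing values); XLSX renders the same rows and splits into
numbered sheets before the 1,048,576-row sheet limit, never truncating
silently. Summary pie charts follow a fixed colour convention
(Category 1 orange, 2 yellow, 3 blue, 4 grey); the plotting function
reports wedge fractions read back from the drawn wedges so tests can
check self-consistency.

## Synthetic corpora and the oracle

The generator emulates the two inputs the live services provide — a
synonym table and a publication corpus — with planted ground truth.
Document text is assembled from a closed nonsense vocabulary plus
deliberately injected terms and keywords; non-ambiguous candidates get
unique synthetic tokens that cannot occur in filler text, so each
candidate's matching set is exactly its planted documents. Per-category
quotas fix the planted outcome: Category-1 candidates get 1–4 matching
documents with at least one review; Category-2 get matching non-review
documents; Category-3 candidates exist in the synonym table but have at
most decoy documents (term present, at least one keyword missing —
exercising AND semantics); Category-4 probes are absent from the table
entirely. Ambiguous-name probes take a common word as gene symbol and
receive 5–9 keyword-bearing documents that never contain a protein
name. Default study conditions: 500 documents, 20 candidates per corpus
(quotas 5/7/5/3 across categories, 2 ambiguous probes), one keyword,
title+abstract scope, 10 % review fraction, dates 1990–2024 — sized so
that one corpus generates and triages in well under a second while all
four categories and the probe signature are exercised. A fixed-seed
corpus mirrors the decorin worked example at fixture scale (2 gene-name
hits contained in 54 full-bundle hits; all 52 extra hits protein-name
only). Its synonym row uses a synthetic accession.

The oracle (`oracle_search`) is a deliberately naive nested-loop scan
with its own character-level normalization and boundary checks; it
shares no code with the engine. Engine-vs-oracle equality over random
corpora, planted-category recovery, boolean monotonicity (terms grow ⇒
results grow; keywords grow ⇒ results shrink; scope widens ⇒ results
grow) and SuperMatch soundness are the package's acceptance properties,
recomputed by `scripts/acceptance.py`.

What the synthetic corpora do **not** emulate: natural language (no
morphology, no plural/inflection effects on matching), PubTator's
semantic keyword expansion, MeSH indexing, and real-world identifier
churn (merged/demoted accessions beyond simple absence). Passing tests
therefore demonstrate the correctness of the selection, categorization
and serialization logic — not retrieval recall on live databases, which
depends on database state at query time.

## Numerical/behavioural edge cases

- Degenerate inputs: empty keyword lists, blank identifiers,
  non-positive taxon ids and empty accession batches are rejected at
  construction time.
- Records without a date are excluded by any date ceiling (an undated
  record cannot be shown to precede it) and sort as oldest.
- Normalization is memoized (pure string functions) for throughput;
  memoization does not change semantics.
- The XLSX row-count verifier streams the sheet XML directly from the
  archive instead of loading cells.

## Known limitations

- Category reflects the capped record list (see above).
- Live PubTator hit counts are semantic and service-dependent; offline
  equivalence checks model only exact matching.
- No fuzzy identifier matching, no orthology expansion, no isoform
  handling, no MeSH expansion, no full-text retrieval.
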