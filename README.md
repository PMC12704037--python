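# litscreen

Batch literature triage for omics marker candidates.

Proteomics and transcriptomics experiments routinely end with a list of
dozens to hundreds of significantly regulated genes or proteins, and the
question "which of these are already well studied in my context, and
which are genuinely new?" Answering it by hand means one PubMed session
per candidate, with every gene symbol, synonym and protein name tried
separately. `litscreen` automates that loop: it expands each identifier
into its full synonym bundle, runs one keyword-constrained boolean
search per candidate, and sorts the list into four evidence tiers.

## The method

For each candidate *P* with searchable terms
*T(P) = gene name ∪ gene synonyms ∪ protein names* and user keywords
*K = {k₁, …, kₘ}*, the query is

```
( t₁ OR t₂ OR … OR tₙ ) AND k₁ AND … AND kₘ
```

scoped to the title or to title+abstract, optionally bounded by a
publication-date ceiling, and capped at 1000 records (so several hundred
candidates still fit in one spreadsheet). A publication is selected only
if it contains **all** keywords and **at least one** term. The candidate
is then categorized:

| Category | Meaning |
|----------|---------|
| 1 | at least one retrieved publication is a review — well characterized |
| 2 | publications exist, none of them reviews |
| 3 | no publications, but the identifier is valid — potential novelty |
| 4 | the identifier did not resolve — unknown or unmappable |

Protein names matter twice. First, they go into the OR-group: gene
symbols alone miss most of the literature (a decorin search by gene
symbol `DCN`/`SLRR1B` finds a fraction of what the protein name
"Decorin" finds). Second, they power the **SuperMatch** flag: a
retrieved publication is marked `Match` when a protein name — not merely
the gene symbol — occurs in its title or abstract. Gene symbols like
`SCAN` or `DI` collide with ordinary words; a candidate with many hits
but zero SuperMatches is probably riding an ambiguous symbol.

Backends: live PubMed (NCBI E-utilities), live PubTator 3.0 (semantic
search; first 10 records plus a link to the full result set), and an
exact-matching offline engine over fixture corpora that makes the whole
pipeline testable without a network connection.

## Worked example (offline, no network)

```python
import litscreen as ls

corpus = ls.dcn_like_corpus()          # shipped regression fixture
spec = ls.SearchSpec(keywords=corpus.keywords, scope=corpus.scope,
                     backend=ls.Backend.OFFLINE)
[cc] = ls.triage_offline(corpus.candidate_inputs(),
                         corpus.synonym_table(), spec, corpus.documents)
print("category", int(cc.category),
      "hits", cc.result.total_hits,
      "supermatches", cc.supermatch_count)
```

prints

```
category 1 hits 54 supermatches 52
```

The candidate `DCN` resolves to the bundle {DCN, SLRR1B, Decorin,
Bone-proteoglycan-II, PG-S2, PG40}. Searching the fixture corpus with
the gene terms alone finds 2 documents; the full bundle finds 54, and
the 52 additional documents are reached through the protein name
"Decorin" only — each of them flagged `Match`. Because some of the hits
are reviews, the candidate lands in Category 1.

From a shell, the same pipeline runs as:

```bash
litscreen fixtures generate --out bundle/ --n-documents 500 --seed 0
litscreen run --ids ids.txt --taxid 9606 --keywords cancer \
    --backend offline --fixtures bundle/ --out report.tsv --format tsv
```

Live searches use `--backend pubmed` (add `--email`, optionally
`--api-key`) or `--backend pubtator`; `litscreen replay --max-date
YYYY-MM-DD` re-runs a search as of a past date.

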