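# litmine

A full-text literature mining and biocuration engine for the scientific
literature, built for curators at model-organism databases and for anyone
who needs targeted, concept-aware search over a corpus of research
articles.

`litmine` converts JATS/NXML (PubMed-Central style) or plain-text articles
into **standoff-annotated documents**: the article's full text (title,
abstract, body paragraphs, figure/table captions) is assembled into one
immutable string — the *subject of analysis* (SofA) — and every analysis
result (tokens, sentences, sections, dictionary matches, manual curation)
is attached as a typed `[begin, end)` span that never modifies the text.
On top of this model the package provides:

- **Categories** — OBO ontologies (GO, SO, ChEBI, anatomy ontologies, …)
  and custom word lists compiled into a shallow category forest (maximum
  browsable depth 4).  Terms deeper than the cut are not lost: their names
  and synonyms are folded into the lexicon of their depth-4 ancestor, so
  every ontology term stays searchable.
- **Dictionary annotation** — a token-sequence lexicon trie marks every
  occurrence of every category's surface forms (term names + synonyms) in
  every sentence.  Matching is token-aware ("Gene" never fires inside
  "Generation"), reports *all* matches at a position (both "kinase" and
  "kinase activity"), tolerates hyphen/space orthography ("DNA binding" ↔
  "DNA-binding"), and applies a per-form case policy (gene symbols like
  `ZYG-1` match exactly; ordinary words match case-insensitively).
- **Search** — an inverted index over word tokens and category
  annotations answers boolean queries (`AND`, `OR`, `NOT`, quoted
  phrases, parentheses) combined with category clauses, at **sentence or
  document scope**, with author/journal/year/accession/section filters,
  keyword exclusion, and sub-corpus restriction.  Hits are ranked by
  tf·idf, normalized so the best document scores 1.0, and can be
  re-sorted chronologically.
- **Curation** — configurable curation forms (line edits, text areas,
  pull-downs, check boxes on a grid) with validators and autocomplete
  sources, pre-populated from bibliography or from the category terms
  found in highlighted evidence spans; filled records carry
  (possibly non-contiguous) evidence spans and export as JSON or as an
  RFC 3986 parameterized URI with an external system's identity token
  passed through verbatim.
- **Synthetic fixtures** — deterministic generators for toy OBO
  ontologies and NXML corpora with planted term occurrences at known
  offsets, so the whole pipeline is testable offline with exact ground
  truth.

## Scoring model

Each positive query clause *c* (term, phrase, or category) contributes

    raw(unit) = Σ_c (1 + ln tf_c) · ln(1 + N / (1 + df_c))

where `tf_c` is the clause's occurrence count in the scored unit, `df_c`
its document frequency (phrases use the df of their rarest member token;
categories count documents with at least one matching annotation), and
`N` the corpus size.  Displayed document scores are normalized by the
best-scoring returned document, so the top hit always reads 1.000.

## Worked example

Generate a small synthetic corpus, run the pipeline, and search it:

```bash
tpc fixtures make --seed 4 --docs 12 --terms 30 --out fx
tpc ingest   --in fx/nxml --store store
tpc annotate --store store --forest fx/forest.json
tpc index    --store store --out ix
tpc search   --index ix --forest fx/forest.json --query tyor --scope sentence
```

which prints

```
1 document(s), 1 matching sentence(s)
Accession    Title                                        Journal                  Year  Type               Score
700002       Population genetics of gfeajm                Archives of Medicinal    2002  research-article   1.000
```

`tyor` is a term planted by the fixture generator into exactly one
article; the search finds exactly that article, and its normalized score
is 1.000 because the top document defines the scale.  A category search
expands a node to all of its descendants:

```bash
tpc search --index ix --forest fx/forest.json \
    --category FX:0000001:children --scope sentence
```

```
11 document(s), 23 matching sentence(s)
Accession    Title                                        Journal                  Year  Type               Score
700003       Structural biology of ahbj                   Annals of Field Studie   2000  research-article   1.000
700004       Clinical medicine approaches to ehiebi       Journal of Model Biolo   2020  research-article   1.000
700002       Population genetics of gfeajm                Archives of Medicinal    2002  research-article   0.804
...
```

23 sentences across 11 of the 12 articles contain at least one surface
form from the root category or its descendants — exactly the sentences
the generator planted.  Combining keywords and categories conjoins them
(`--query tyor --category FX:0000001:children` returns only the one
sentence satisfying both).  The same operations are available as a
library (`litmine.search.search`, `litmine.query.Query`, …), which is the
interface the test suite exercises.

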