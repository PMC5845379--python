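# Methods

This note documents the models, conventions and numerical choices behind
`litmine`, in the spirit of the methods documentation of mature
scientific packages: what the engine computes, under which assumptions,
and what its tests do and do not demonstrate.

## Document model

A document is an immutable full-text string (the *subject of analysis*,
SofA) plus standoff annotations — typed spans `[begin, end)` in Unicode
code points, 0-based and half-open.  Nothing ever rewrites the SofA;
every pipeline stage appends annotations.  Layers form a closed set:
`token`, `sentence`, `paragraph`, `section`, `image` (structural),
`lexical` (dictionary matches), `manual` (curation records) and
`computational` (reserved for attached third-party annotators; none is
shipped).  Token/sentence/paragraph layers must be pairwise
non-overlapping; lexical annotations may overlap freely across
categories.  Validation is total: an invalid annotation raises a
diagnostic naming the offender, it is never silently dropped.

Persistence is one JSON file per document under a manifest that records
each document's pipeline stage (1 converted, 2 lexically annotated) and
sub-corpus labels.  JSON output is key-sorted, making stores and indexes
byte-reproducible; the save/load round trip preserves the SofA
byte-for-byte and the annotation multiset exactly (serialization orders
annotations by `(begin, end, layer)`).

## Conversion

The SofA is assembled from title, abstract, body paragraphs and
figure/table captions, in document order, joined by single blank lines.
Captions are included deliberately so that searches can be restricted to
sentences that reference a table or figure.  Section titles become
`section` annotation labels, not SofA text.  The NXML reader accepts the
JATS `front/article-meta` subset (article-title, journal-title, pub-date
year, contrib authors, subjects, abstract, article-ids) and flattens
inline markup; missing optional fields become empty rather than errors.
Accession preference is pmid > pmc > doi > filename stem.  Plain-text
ingestion (blank-line paragraphs plus a JSON metadata sidecar) covers
user-supplied corpora; PDF extraction is out of scope.

**Tokens** are maximal runs of letters/digits in which `- . / _ '` are
token-internal iff flanked by letters/digits on both sides, so `zyg-1`,
`3.5` and `p53/mdm2` are single tokens while trailing or doubled
connectors split.  **Sentences** break after `.`, `!` or `?` followed by
whitespace and an uppercase letter or digit, except after entries of a
configurable abbreviation list (`Fig.`, `Figs.`, `et al.`, `e.g.`,
`i.e.`, `vs.`, `ca.`, `cf.`, `approx.`, `no.`/`No.` by default) and after
single-capital genus abbreviations (`C. elegans`, `E. coli`).  Runs of
terminators (`...`, `?!`) count as one boundary.  Every token lies in
exactly one sentence and one paragraph; conversion is a pure function of
the input bytes.

## Categories

OBO `[Term]` stanzas are parsed for `id`, `name`, `synonym` (all scopes
harvested: EXACT, RELATED, BROAD, NARROW), `is_a` and `is_obsolete`;
other tags are ignored, obsolete terms dropped, and stanzas missing id or
name skipped with a warning.  The category forest is built breadth-first
from the chosen roots with siblings ordered by term id, which pins the
attachment of multi-parent terms (first reach wins) and makes compilation
deterministic.  Terms within depth 4 of a root become browsable nodes;
deeper terms fold their names and synonyms into the lexicon of their
depth-4 ancestor, so expansion over the browsable forest and expansion
over the full ontology coincide — the reason folding was chosen over
discarding.  Word lists (one canonical term per line, tab-separated
synonyms) are rendered as OBO stanzas and compiled through the same
builder with the depth cut at the root, yielding one root-level category
whose lexicon holds every listed term and synonym; generated ids follow
the `tpc:0000001` pattern.  The category's display name labels the node
but is not itself a lexicon entry.

**Case policy.**  A surface form matches case-sensitively iff it contains
a digit or an uppercase letter after its first character.  `ZYG-1`,
`DnaK` must match exactly; `kinase` also matches `Kinase` at sentence
start.  The policy is fixed per form at compile time.

## Dictionary annotation

Surface forms are held in a trie keyed by lowercased *token segments* —
tokens split at internal hyphens.  Scanning each sentence's segment
sequence from every token-initial position yields **all** matches
starting there (not only the longest), provided the separator between
consecutive matched segments is whitespace or a single hyphen and the
match begins at a token begin and ends at a token end.  This combination
lets the two-token form `DNA binding` match the one-token spelling
`DNA-binding` (and vice versa) while keeping matches aligned to whole
tokens.  One lexical annotation is emitted per distinct (span, category)
pair, carrying `category_id`, `matched_form` and the source `term_id`;
matches never cross sentence boundaries.  The annotator is a pure
function; re-annotating after clearing the lexical layer reproduces the
same set.  Hyphen tolerance can be disabled
(`annotate(..., allow_hyphen_separator=False)`).

Sub-corpus rules are (label, regex) pairs applied to title, journal and
subject fields; a document may receive any number of labels.  The
shipped examples follow the `[Gg]enet` pattern style.

## Index and search

The inverted index stores, per normalized (lowercased) token, postings of
(document, sentence ordinal, token position, span) — positions support
phrase adjacency — and per category, postings of annotation spans; plus
bibliographic fields, sentence spans and section membership per document.
Document frequency is the number of distinct documents in a posting list.

Query evaluation is set-algebraic over postings: leaves produce unit sets
(sentences or documents), `AND`/`OR` intersect/union, `NOT` complements
against the filtered universe.  A phrase is true of a unit iff its tokens
occur at consecutive positions within one sentence of the unit.  Category
clauses (optionally expanded to forest descendants) are conjoined with
each other and with the keyword expression.  Excluded keywords remove
units at the query's scope.  Filters: author/journal are case-insensitive
substring matches, accession exact, year a value or inclusive range,
sub-corpus a label equality (an unknown label yields an empty result with
a warning), and section restricts evaluation to sentences inside sections
of that label (case-insensitive) at both scopes, besides excluding
documents lacking the section.

**Scoring** is pinned to `raw = Σ_c (1 + ln tf_c) · ln(1 + N/(1+df_c))`
over positive clauses (leaves under an even number of negations, plus all
category clauses); clauses with `tf = 0` in a unit contribute 0, and
negated clauses contribute 0 by construction.  Phrase df uses the rarest
member token (an index-compactness approximation affecting ranking only,
not membership).  The displayed document score is the raw score of the
whole document bag normalized by the best returned document, so the top
hit is 1.0 and all scores lie in (0, 1].  Sentence hits carry raw
sentence-level scores (sentence tf, document-level df).  Two degenerate
conventions: if every returned document has raw score 0 (satisfaction
purely through negation), all are reported as 1.0 — an all-way tie; and
chronological sort places unknown years last, breaking ties by score then
document id.

One useful non-theorem: documents owning sentence-scope hits are a subset
of the document-scope result *only for negation-free queries*.  A
sentence can satisfy `NOT x` while its document contains `x` elsewhere.
The randomized oracle-equivalence tests cover negation in full; the
nesting property is asserted only where it holds.

## Curation

Form schemas place typed fields (line edit, text area, pulldown,
checkbox) on a grid; duplicate ids or positions, pulldowns without value
lists, and malformed validator/autocomplete/prepopulate rules are
reported as diagnostics, not exceptions.  Prepopulation draws from static
text, bibliography fields, or the lexical annotations lying fully inside
the curator's highlighted spans (`surface_form [term_id]`, deduplicated,
in document order).  Validators check value-list membership, regular
expressions, or category membership (a bracketed id anywhere in the
category's expanded term set, or a bare name in its expanded lexicon).
External autocomplete/validation sources are represented as
`external:<url>` and resolved through a pluggable fetch interface; no
network transport is shipped.

Records carry merged, non-overlapping, possibly non-contiguous evidence
spans.  Export refuses records with outstanding diagnostics; otherwise it
produces a canonical payload (form name, accession, evidence slices taken
verbatim from the SofA, field values, curator, timestamp, and the
external system's identity token unchanged) either as JSON plus target
URL or as a percent-encoded GET URI whose structured parameters are
JSON-encoded, making decoding exact.  The parameter naming of the URI is
this package's own convention.

## Synthetic fixtures

The generators emulate the *structure* of a PMC-style corpus, not its
language: front matter exercising the sub-corpus regexes, abstracts,
sectioned body paragraphs, figure/table captions, and planted category
terms.  Ground truth is exact by construction: background words use only
letters a–m, ontology term words only n–z (plus uppercase/digit
gene-symbol variants such as `NQR-3` to exercise case sensitivity), and
every surface form is built from globally unique words, so no form can
occur by accident, nest inside another, or collide with the abbreviation
handling ("Fig. 3" and "C. elegans" are inserted deliberately to test the
splitter's exceptions).  Default conditions: 20 articles, a 50-term
ontology up to depth 5 (one level past the browsable cut so folding is
exercised), 2–4 body paragraphs of 2–5 sentences of 4–10 words, up to 6
planted occurrences per article.  Everything derives from a single seed;
two runs are byte-identical.

Because the vocabulary is synthetic and collision-free, passing tests
demonstrate the engine's *mechanics* (offsets, matching policies, set
semantics, scoring arithmetic, determinism) — they do not measure recall
on real biomedical prose, where lexical variation, shared substrings
between term names, and messy markup dominate.

## Problem sizes and tolerances

The test suite and acceptance script use: 200 random document/lexicon
pairs (≤ 30 sentences, ≤ 50 forms) for annotator/oracle equivalence; a
100-document seeded corpus with 50 randomized queries for search/oracle
equivalence; 20 random 50-term ontologies for compilation properties;
200 random ASTs for query round-trips; 20 random records for export
round-trips.  These sizes keep the full suite under half a minute on one
core while exercising every code path; scores are compared to an
independent implementation at 1e-12, and all membership comparisons are
exact.

## Known limitations

No PDF ingestion, OCR, or reference-list structuring; no fuzzy or
stemmed matching; no machine-learning annotators (the `computational`
layer is a mount point); category clauses are conjunctive only;
single-writer file store; the sentence splitter's abbreviation list is
minimal and English-centric.
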