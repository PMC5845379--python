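"""Independent brute-force oracles used to cross-check the engine.

These deliberately avoid the package's trie and inverted index: the
annotation oracle tests every (start, end) token window against the full
lexicon list, and the search oracle evaluates the query truth-functionally
against each document/sentence directly.
"""

from __future__ import annotations

from litmine.ingest import tokenize
from litmine.query import And, Not, Or, Phrase, Term


def _segments_of(text: str) -> list[str]:
    segs = []
    for b, e in tokenize(text):
        segs.extend(p for p in text[b:e].split("-") if p)
    return segs


def _window_matches(sofa: str, window: list[tuple[int, int]], form: str,
                    case_sensitive: bool) -> bool:
    """Does the token window match the surface form under the case policy?"""
    # flatten window tokens into hyphen-split segments with offsets
    segs: list[tuple[int, int, str]] = []
    for tb, te in window:
        text = sofa[tb:te]
        off = tb
        for part in [p for p in text.split("-") if p]:
            start = sofa.index(part, off, te)
            segs.append((start, start + len(part), part))
            off = start + len(part)
    form_segs = _segments_of(form)
    if len(segs) != len(form_segs) or not form_segs:
        return False
    for (_, _, got), want in zip(segs, form_segs):
        if case_sensitive:
            if got != want:
                return False
        elif got.lower() != want.lower():
            return False
    for (pb, pe, _), (nb, ne, _) in zip(segs, segs[1:]):
        gap = sofa[pe:nb]
        if not (gap.isspace() or gap == "-"):
            return False
    return True


def brute_force_annotate(doc, lexicon):
    """All (begin, end, category_id) matches of ``lexicon`` in ``doc``.

    ``lexicon`` is an iterable of (category_id, surface_form,
    case_sensitive) triples.  Every contiguous token window within every
    sentence is tested against every form.
    """
    sofa = doc.sofa
    sentences = doc.layer("sentence")
    tokens = [(t.begin, t.end) for t in doc.layer("token")]
    out = set()
    for sent in sentences:
        stoks = [t for t in tokens if t[0] >= sent.begin and t[1] <= sent.end]
        for i in range(len(stoks)):
            for j in range(i, len(stoks)):
                window = stoks[i : j + 1]
                for cid, form, cs in lexicon:
                    if _window_matches(sofa, window, form, cs):
                        out.add((window[0][0], window[-1][1], cid))
    return out


# ---------------------------------------------------------------------------
# Search oracle
# ---------------------------------------------------------------------------


class DocView:
    """Direct, index-free view of a document for truth evaluation."""

    def __init__(self, doc):
        self.doc = doc
        self.bib = doc.bibliography
        self.subcorpora = set(doc.subcorpora)
        sentences = doc.layer("sentence")
        self.sent_spans = [(s.begin, s.end) for s in sentences]
        toks = doc.layer("token")
        self.sent_tokens: list[list[str]] = []
        for b, e in self.sent_spans:
            self.sent_tokens.append(
                [doc.sofa[t.begin : t.end].lower() for t in toks
                 if t.begin >= b and t.end <= e]
            )
        self.sent_cats: list[set[str]] = [set() for _ in self.sent_spans]
        for a in doc.layer("lexical"):
            for k, (b, e) in enumerate(self.sent_spans):
                if b <= a.begin and a.end <= e:
                    self.sent_cats[k].add(a.attributes["category_id"])
        self.sections: dict[str, set[int]] = {}
        for sec in doc.layer("section"):
            label = sec.attributes.get("label", "").lower()
            ords = {
                k
                for k, (b, e) in enumerate(self.sent_spans)
                if b >= sec.begin and e <= sec.end
            }
            if label:
                self.sections.setdefault(label, set()).update(ords)


def _term_in_sentences(view: DocView, token: str, ordinals) -> bool:
    return any(token in view.sent_tokens[s] for s in ordinals)


def _phrase_in_sentence(tokens, phrase) -> bool:
    n = len(phrase)
    return any(tuple(tokens[k : k + n]) == tuple(phrase)
               for k in range(len(tokens) - n + 1))


def _eval_node(node, view: DocView, ordinals) -> bool:
    if isinstance(node, Term):
        return _term_in_sentences(view, node.token, ordinals)
    if isinstance(node, Phrase):
        return any(_phrase_in_sentence(view.sent_tokens[s], node.tokens)
                   for s in ordinals)
    if isinstance(node, Not):
        return not _eval_node(node.child, view, ordinals)
    if isinstance(node, And):
        return all(_eval_node(c, view, ordinals) for c in node.children)
    if isinstance(node, Or):
        return any(_eval_node(c, view, ordinals) for c in node.children)
    raise TypeError(node)


def _passes_filters(view: DocView, f) -> bool:
    if f.author is not None and f.author.lower() not in " ; ".join(view.bib.authors).lower():
        return False
    if f.journal is not None and f.journal.lower() not in view.bib.journal.lower():
        return False
    if f.year is not None:
        y = view.bib.year
        if y is None:
            return False
        if isinstance(f.year, tuple):
            if not (f.year[0] <= y <= f.year[1]):
                return False
        elif y != f.year:
            return False
    if f.accession is not None and view.bib.accession != f.accession:
        return False
    if f.subcorpus is not None and f.subcorpus not in view.subcorpora:
        return False
    if f.section is not None and f.section.lower() not in view.sections:
        return False
    return True


def brute_force_search(docs, query, forest):
    """Result membership: set of doc_ids (document scope) or
    (doc_id, sentence_ordinal) pairs (sentence scope)."""
    views = [DocView(d) for d in docs]
    cat_ids = []
    for cid, children in query.categories:
        cat_ids.append(set(forest.descendants(cid)) if children else {cid})
    exclude_tokens = []
    for raw in query.filters.exclude:
        from litmine.ingest import tokenize as tk

        exclude_tokens.extend(raw[b:e].lower() for b, e in tk(raw))

    out = set()
    for view in views:
        if not _passes_filters(view, query.filters):
            continue
        if query.filters.section is not None:
            allowed = sorted(view.sections.get(query.filters.section.lower(), ()))
        else:
            allowed = range(len(view.sent_spans))
        if query.scope == "sentence":
            for s in allowed:
                if query.keyword_expr is not None and not _eval_node(
                    query.keyword_expr, view, [s]
                ):
                    continue
                if any(not (ids & view.sent_cats[s]) for ids in cat_ids):
                    continue
                if any(t in view.sent_tokens[s] for t in exclude_tokens):
                    continue
                out.add((view.bib.accession, s))
        else:
            ordinals = list(allowed)
            if query.keyword_expr is not None and not _eval_node(
                query.keyword_expr, view, ordinals
            ):
                continue
            doc_cats = set()
            for s in ordinals:
                doc_cats |= view.sent_cats[s]
            if any(not (ids & doc_cats) for ids in cat_ids):
                continue
            if any(_term_in_sentences(view, t, ordinals) for t in exclude_tokens):
                continue
            out.add(view.bib.accession)
    return out


def result_membership(result, scope: str):
    if scope == "sentence":
        return {
            (h.doc_id, sh.sentence_ordinal)
            for h in result.hits
            for sh in h.sentence_hits
        }
    return {h.doc_id for h in result.hits}


# ---------------------------------------------------------------------------
# Random query generation over a concrete corpus
# ---------------------------------------------------------------------------


def make_query_pool(docs, forest):
    """Corpus-derived raw material for randomized queries."""
    vocab = set()
    phrases = []
    authors, journals, years, accessions, labels = [], [], set(), [], set()
    for doc in docs:
        view = DocView(doc)
        for toks in view.sent_tokens:
            vocab.update(toks)
            if len(toks) >= 2:
                phrases.append(tuple(toks[:2]))
        authors.extend(doc.bibliography.authors)
        journals.append(doc.bibliography.journal)
        if doc.bibliography.year:
            years.add(doc.bibliography.year)
        accessions.append(doc.bibliography.accession)
        labels.update(doc.subcorpora)
    return {
        "vocab": sorted(vocab) + ["zzzabsent", "qqqmissing"],
        "phrases": sorted(set(phrases)),
        "authors": sorted(set(authors)),
        "journals": sorted(set(journals)),
        "years": sorted(years),
        "accessions": sorted(accessions),
        "labels": sorted(labels),
        "categories": sorted(forest.nodes),
        "sections": ["title", "abstract", "Introduction", "Methods", "figure"],
    }


def _random_expr(rng, pool, depth=0):
    from litmine.query import And, Not, Or, Phrase, Term

    kinds = ["term", "term", "phrase"]
    if depth < 2:
        kinds += ["and", "or", "not"]
    kind = rng.choice(kinds)
    if kind == "term":
        return Term(rng.choice(pool["vocab"]))
    if kind == "phrase":
        if pool["phrases"] and rng.random() < 0.7:
            return Phrase(rng.choice(pool["phrases"]))
        return Phrase((rng.choice(pool["vocab"]), rng.choice(pool["vocab"])))
    if kind == "not":
        return Not(_random_expr(rng, pool, depth + 1))
    children = tuple(_random_expr(rng, pool, depth + 1) for _ in range(rng.randint(2, 3)))
    return And(children) if kind == "and" else Or(children)


def random_query(rng, pool):
    """A randomized Query covering operators, phrases, categories with and
    without child expansion, both scopes, filters and exclusions."""
    from litmine.query import Filters, Not, Query

    expr = None
    if rng.random() < 0.8:
        expr = _random_expr(rng, pool)
    n_cats = rng.choice((0, 0, 1, 1, 2, 3))
    cats = tuple(
        (rng.choice(pool["categories"]), rng.random() < 0.5) for _ in range(n_cats)
    )
    if expr is None and not cats:
        expr = _random_expr(rng, pool)
    while isinstance(expr, Not) and not cats:
        expr = expr.child

    kw = {}
    if rng.random() < 0.15 and pool["authors"]:
        kw["author"] = rng.choice(pool["authors"])[:4]
    if rng.random() < 0.15 and pool["journals"]:
        kw["journal"] = rng.choice(pool["journals"]).split()[0]
    if rng.random() < 0.15 and pool["years"]:
        if rng.random() < 0.5:
            kw["year"] = rng.choice(pool["years"])
        else:
            lo, hi = sorted((rng.choice(pool["years"]), rng.choice(pool["years"])))
            kw["year"] = (lo, hi)
    if rng.random() < 0.08 and pool["accessions"]:
        kw["accession"] = rng.choice(pool["accessions"])
    if rng.random() < 0.15 and pool["labels"]:
        kw["subcorpus"] = rng.choice(pool["labels"])
    if rng.random() < 0.15:
        kw["section"] = rng.choice(pool["sections"])
    if rng.random() < 0.25:
        kw["exclude"] = tuple(
            rng.choice(pool["vocab"]) for _ in range(rng.randint(1, 2))
        )
    return Query(
        keyword_expr=expr,
        categories=cats,
        scope=rng.choice(("sentence", "document")),
        filters=Filters(**kw),
        sort=rng.choice(("score", "year")),
    )


# ---------------------------------------------------------------------------
# Independent reference implementation of the pinned scoring formula
# ---------------------------------------------------------------------------


def reference_raw_scores(docs, query, forest, result_doc_ids):
    """Raw tf*idf document scores computed directly from the documents,
    bypassing the inverted index: raw = sum over positive clauses of
    (1 + ln tf) * ln(1 + N/(1+df))."""
    import math

    from litmine.query import Phrase, Term, positive_leaves

    views = {d.bibliography.accession: DocView(d) for d in docs}
    N = len(docs)

    def term_tf(view, token):
        return sum(toks.count(token) for toks in view.sent_tokens)

    def phrase_tf(view, tokens):
        n = len(tokens)
        total = 0
        for toks in view.sent_tokens:
            total += sum(
                1 for k in range(len(toks) - n + 1)
                if tuple(toks[k : k + n]) == tuple(tokens)
            )
        return total

    def cat_tf(view, ids):
        total = 0
        for a in view.doc.layer("lexical"):
            if a.attributes["category_id"] in ids:
                total += 1
        return total

    clauses = []
    if query.keyword_expr is not None:
        for leaf in positive_leaves(query.keyword_expr):
            if isinstance(leaf, Term):
                df = sum(1 for v in views.values() if term_tf(v, leaf.token) > 0)
                clauses.append(("t", leaf.token, df))
            else:
                df = min(
                    sum(1 for v in views.values() if term_tf(v, tok) > 0)
                    for tok in leaf.tokens
                )
                clauses.append(("p", leaf.tokens, df))
    for cid, children in query.categories:
        ids = set(forest.descendants(cid)) if children else {cid}
        df = sum(1 for v in views.values() if cat_tf(v, ids) > 0)
        clauses.append(("c", ids, df))

    out = {}
    for doc_id in result_doc_ids:
        view = views[doc_id]
        raw = 0.0
        for kind, payload, df in clauses:
            if kind == "t":
                tf = term_tf(view, payload)
            elif kind == "p":
                tf = phrase_tf(view, payload)
            else:
                tf = cat_tf(view, payload)
            if tf > 0:
                raw += (1.0 + math.log(tf)) * math.log(1.0 + N / (1.0 + df))
        out[doc_id] = raw
    return out


def contains_not(node) -> bool:
    """True iff the expression tree uses negation anywhere."""
    if node is None or isinstance(node, (Term, Phrase)):
        return False
    if isinstance(node, Not):
        return True
    return any(contains_not(c) for c in node.children)
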