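"""Query execution: boolean evaluation over the inverted index, tf*idf
scoring normalized to the top document, and result sorting.

Scoring uses the pinned variant  raw = Σ_c (1 + ln tf_c) · ln(1 + N/(1+df_c))
over the positive clauses c of the query (term and phrase leaves outside
NOT, plus every category clause); tf is the occurrence count in the scored
unit, df the document frequency (phrases use the df of their rarest member
token; categories the number of documents with at least one matching
annotation).  The displayed document score is the raw score of the whole
document bag, normalized by the best-scoring returned document, so the top
hit always reads 1.0.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

from .categories import CategoryForest
from .errors import InvalidInputError, NotFoundError
from .index import InvertedIndex
from .ingest import tokenize
from .query import And, Filters, Node, Not, Or, Phrase, Query, Term, positive_leaves


@dataclass(frozen=True)
class SentenceHit:
    sentence_ordinal: int
    sentence_score: float
    #: (begin, end, clause label) spans for highlighting
    spans: tuple[tuple[int, int, str], ...] = ()


@dataclass(frozen=True)
class DocHit:
    doc_id: str
    title: str
    journal: str
    year: int | None
    article_type: str
    doc_score: float
    raw_score: float
    sentence_hits: tuple[SentenceHit, ...] = ()


@dataclass(frozen=True)
class SearchResult:
    hits: tuple[DocHit, ...] = ()
    total_documents: int = 0
    total_sentences: int = 0
    warnings: tuple[str, ...] = ()


# ---------------------------------------------------------------------------


def _year_matches(year, wanted) -> bool:
    if wanted is None:
        return True
    if year is None:
        return False
    if isinstance(wanted, tuple):
        lo, hi = wanted
        return lo <= year <= hi
    return year == wanted


def _filter_docs(index: InvertedIndex, f: Filters) -> list[str]:
    out = []
    for doc_id, meta in index.docs.items():
        if f.author is not None:
            joined = " ; ".join(meta["authors"]).lower()
            if f.author.lower() not in joined:
                continue
        if f.journal is not None and f.journal.lower() not in meta["journal"].lower():
            continue
        if not _year_matches(meta["year"], f.year):
            continue
        if f.accession is not None and meta["accession"] != f.accession:
            continue
        if f.subcorpus is not None and f.subcorpus not in meta["subcorpora"]:
            continue
        if f.section is not None and f.section.lower() not in meta["sections"]:
            continue
        out.append(doc_id)
    return sorted(out)


class _Evaluator:
    """Posting-list evaluation of one query over the candidate documents."""

    def __init__(
        self,
        index: InvertedIndex,
        query: Query,
        forest: CategoryForest | None,
        candidates: list[str],
    ):
        self.index = index
        self.query = query
        self.forest = forest
        self.candidates = candidates
        sec = query.filters.section.lower() if query.filters.section else None
        #: allowed sentence ordinals per candidate doc
        self.allowed: dict[str, set[int]] = {}
        for d in candidates:
            meta = index.docs[d]
            if sec is None:
                self.allowed[d] = set(range(meta["n_sentences"]))
            else:
                self.allowed[d] = set(meta["sections"].get(sec, ()))
        self.universe: set = (
            {(d, s) for d in candidates for s in self.allowed[d]}
            if query.scope == "sentence"
            else set(candidates)
        )

    # -- leaf occurrence maps -------------------------------------------

    def term_occurrences(self, token: str) -> dict[str, dict[int, list[tuple[int, int]]]]:
        """doc -> sentence ordinal -> [(begin, end)] within allowed sentences."""
        postings = self.index.kw.get(token, {})
        out: dict[str, dict[int, list[tuple[int, int]]]] = {}
        for d in self.candidates:
            entries = postings.get(d)
            if not entries:
                continue
            per: dict[int, list[tuple[int, int]]] = {}
            for s_ord, _pos, b, e in entries:
                if s_ord in self.allowed[d]:
                    per.setdefault(s_ord, []).append((b, e))
            if per:
                out[d] = per
        return out

    def phrase_occurrences(
        self, tokens: tuple[str, ...]
    ) -> dict[str, dict[int, list[tuple[int, int]]]]:
        """Consecutive-position runs of the phrase tokens inside one sentence."""
        member_postings = [self.index.kw.get(t, {}) for t in tokens]
        out: dict[str, dict[int, list[tuple[int, int]]]] = {}
        for d in self.candidates:
            per_member = [m.get(d) for m in member_postings]
            if any(not p for p in per_member):
                continue
            follow = [
                {(s, pos): (b, e) for s, pos, b, e in p} for p in per_member[1:]
            ]
            per: dict[int, list[tuple[int, int]]] = {}
            for s_ord, pos, b, e in per_member[0]:
                if s_ord not in self.allowed[d]:
                    continue
                end_span = (b, e)
                ok = True
                for k, f in enumerate(follow, start=1):
                    nxt = f.get((s_ord, pos + k))
                    if nxt is None:
                        ok = False
                        break
                    end_span = nxt
                if ok:
                    per.setdefault(s_ord, []).append((b, end_span[1]))
            if per:
                out[d] = per
        return out

    def category_occurrences(
        self, category_ids: list[str]
    ) -> dict[str, dict[int, list[tuple[int, int]]]]:
        out: dict[str, dict[int, list[tuple[int, int]]]] = {}
        for cid in category_ids:
            postings = self.index.cat.get(cid, {})
            for d in self.candidates:
                for s_ord, b, e in postings.get(d, ()):
                    if s_ord in self.allowed[d]:
                        out.setdefault(d, {}).setdefault(s_ord, []).append((b, e))
        return out

    def leaf_occurrences(self, leaf) -> dict[str, dict[int, list[tuple[int, int]]]]:
        if isinstance(leaf, Term):
            return self.term_occurrences(leaf.token)
        if isinstance(leaf, Phrase):
            return self.phrase_occurrences(leaf.tokens)
        raise TypeError(leaf)

    def units_of(self, occ: dict[str, dict[int, list]]) -> set:
        if self.query.scope == "sentence":
            return {(d, s) for d, per in occ.items() for s in per}
        return set(occ)

    # -- boolean evaluation ---------------------------------------------

    def eval_expr(self, node: Node) -> set:
        if isinstance(node, (Term, Phrase)):
            return self.units_of(self.leaf_occurrences(node))
        if isinstance(node, Not):
            return self.universe - self.eval_expr(node.child)
        if isinstance(node, And):
            result: set | None = None
            for c in node.children:
                s = self.eval_expr(c)
                result = s if result is None else (result & s)
                if not result:
                    return set()
            return result or set()
        if isinstance(node, Or):
            result: set = set()
            for c in node.children:
                result |= self.eval_expr(c)
            return result
        raise TypeError(node)


def _expand_category(
    forest: CategoryForest | None, cid: str, children: bool
) -> list[str]:
    if forest is not None:
        return forest.descendants(cid) if children else [cid]
    if children:
        raise InvalidInputError(
            "include_children requires the category forest used at annotation time"
        )
    return [cid]


def search(
    index: InvertedIndex,
    query: Query,
    forest: CategoryForest | None = None,
) -> SearchResult:
    """Execute a query and return scored, sorted document hits.

    ``forest`` supplies the category hierarchy for child-term expansion and
    category validation; it may be omitted for keyword-only searches.
    """
    warn_list: list[str] = []
    f = query.filters

    if f.subcorpus is not None:
        known = {lbl for m in index.docs.values() for lbl in m["subcorpora"]}
        if f.subcorpus not in known:
            msg = f"unknown subcorpus label {f.subcorpus!r}"
            warnings.warn(msg)
            return SearchResult(warnings=(msg,))

    for cid, _children in query.categories:
        if forest is not None:
            forest.node(cid)  # raises NotFoundError for unknown ids
        elif cid not in index.cat:
            raise NotFoundError(f"unknown category {cid!r}")

    candidates = _filter_docs(index, f)
    ev = _Evaluator(index, query, forest, candidates)

    # boolean membership
    surviving = (
        ev.eval_expr(query.keyword_expr)
        if query.keyword_expr is not None
        else set(ev.universe)
    )
    cat_occs = []
    for cid, children in query.categories:
        ids = _expand_category(forest, cid, children)
        occ = ev.category_occurrences(ids)
        cat_occs.append(((cid, children), ids, occ))
        surviving &= ev.units_of(occ)

    # keyword exclusion at the query's scope
    for raw in f.exclude:
        for b, e in tokenize(raw):
            tok = raw[b:e].lower()
            surviving -= ev.units_of(ev.term_occurrences(tok))

    if not surviving:
        return SearchResult(warnings=tuple(warn_list))

    if query.scope == "sentence":
        doc_ids = sorted({d for d, _s in surviving})
        sent_by_doc: dict[str, set[int]] = {}
        for d, s in surviving:
            sent_by_doc.setdefault(d, set()).add(s)
    else:
        doc_ids = sorted(surviving)
        sent_by_doc = {}

    # -- scoring ---------------------------------------------------------
    N = index.n_docs
    clauses: list[tuple[str, dict, float]] = []  # (label, occurrences, idf)
    if query.keyword_expr is not None:
        for leaf in positive_leaves(query.keyword_expr):
            occ = ev.leaf_occurrences(leaf)
            if isinstance(leaf, Phrase):
                df = min(index.df_kw(t) for t in leaf.tokens)
            else:
                df = index.df_kw(leaf.token)
            idf = math.log(1.0 + N / (1.0 + df))
            clauses.append((str(leaf), occ, idf))
    for (cid, children), ids, occ in cat_occs:
        df = index.df_cat(ids)
        idf = math.log(1.0 + N / (1.0 + df))
        label = f"category:{cid}" + ("+children" if children else "")
        clauses.append((label, occ, idf))

    def tf_weight(tf: int) -> float:
        return 1.0 + math.log(tf) if tf > 0 else 0.0

    hits = []
    total_sentences = 0
    for d in doc_ids:
        meta = index.docs[d]
        raw = 0.0
        sent_scores: dict[int, float] = {}
        sent_spans: dict[int, list[tuple[int, int, str]]] = {}
        matched_sents: set[int] = set()
        for label, occ, idf in clauses:
            per = occ.get(d, {})
            doc_tf = sum(len(v) for v in per.values())
            raw += tf_weight(doc_tf) * idf
            for s_ord, spans in per.items():
                matched_sents.add(s_ord)
                sent_scores[s_ord] = sent_scores.get(s_ord, 0.0) + tf_weight(
                    len(spans)
                ) * idf
                sent_spans.setdefault(s_ord, []).extend(
                    (b, e, label) for b, e in spans
                )
        if query.scope == "sentence":
            shown = sorted(sent_by_doc[d])
        else:
            shown = sorted(matched_sents)
        sentence_hits = tuple(
            SentenceHit(
                s,
                sent_scores.get(s, 0.0),
                tuple(sorted(sent_spans.get(s, ()))),
            )
            for s in shown
        )
        total_sentences += len(sentence_hits)
        hits.append(
            DocHit(
                doc_id=d,
                title=meta["title"],
                journal=meta["journal"],
                year=meta["year"],
                article_type=meta["article_type"],
                doc_score=0.0,  # normalized below
                raw_score=raw,
                sentence_hits=sentence_hits,
            )
        )

    max_raw = max(h.raw_score for h in hits)
    if max_raw > 0:
        hits = [replace(h, doc_score=h.raw_score / max_raw) for h in hits]
    else:
        # degenerate case: every hit satisfied the query only through
        # negation; all documents tie at the top
        hits = [replace(h, doc_score=1.0) for h in hits]

    result = SearchResult(
        hits=tuple(hits),
        total_documents=len(hits),
        total_sentences=total_sentences,
        warnings=tuple(warn_list),
    )
    return sort_results(result, query.sort)


def sort_results(result: SearchResult, mode: str = "score") -> SearchResult:
    """Order hits by normalized score or by year (most recent first).

    Ties in year mode break by score descending, then doc_id; the sort is a
    permutation of the input hits.
    """
    if mode == "score":
        key = lambda h: (-h.doc_score, h.doc_id)
    elif mode == "year":
        key = lambda h: (-(h.year if h.year is not None else -(10**9)), -h.doc_score, h.doc_id)
    else:
        raise InvalidInputError(f"unknown sort mode {mode!r}")
    return replace(result, hits=tuple(sorted(result.hits, key=key)))
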