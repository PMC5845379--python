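"""Index construction, boolean search vs brute force, scoring, sorting."""

import math
import random

import pytest

from litmine.errors import InvalidInputError, NotFoundError
from litmine.index import InvertedIndex, build_index
from litmine.query import Filters, Not, Phrase, Query, Term, parse_query
from litmine.search import search, sort_results

from oracle_utils import (
    brute_force_search,
    make_query_pool,
    random_query,
    reference_raw_scores,
    result_membership,
)


def simple_corpus():
    """Two tiny documents, one containing 'kinase'."""
    from litmine.ingest import convert
    from litmine.lexical import annotate, build_lexicon_tree
    from litmine.model import Bibliography
    from test_lexical import forest_of

    forest = forest_of({"catA": ["enzyme assay"]})
    tree = build_lexicon_tree(forest)
    d1 = convert(
        "A kinase was measured. The enzyme assay ran overnight. "
        "Another enzyme assay failed.",
        Bibliography(accession="A1", title="First", journal="J1", year=2010),
    )
    d2 = convert(
        "Nothing relevant here. Plain words only.",
        Bibliography(accession="A2", title="Second", journal="J2", year=2017),
    )
    return forest, [annotate(d1, tree), annotate(d2, tree)]


class TestBuildIndex:
    def test_df_and_n(self):
        _forest, docs = simple_corpus()
        idx = build_index(docs)
        assert idx.n_docs == 2
        assert idx.df_kw("kinase") == 1
        assert idx.df_kw("the") == 1

    def test_category_postings_sentence_ordinals(self):
        _forest, docs = simple_corpus()
        idx = build_index(docs)
        ords = {s for s, _b, _e in idx.cat["catA"]["A1"]}
        assert ords == {1, 2}

    def test_duplicate_doc_id_rejected(self):
        _forest, docs = simple_corpus()
        with pytest.raises(InvalidInputError):
            build_index([docs[0], docs[0]])

    def test_stage1_document_rejected(self):
        from litmine.ingest import convert
        from litmine.model import Bibliography

        doc = convert("Stage one only.", Bibliography(accession="S"))
        with pytest.raises(InvalidInputError):
            build_index([doc])

    def test_fixture_posting_counts_match_plants(self, corpus_index, fixture_corpus):
        _files, truth = fixture_corpus
        planted: dict[str, set] = {}
        for t in truth.docs.values():
            for p in t.plants:
                planted.setdefault(p.category_id, set()).add(
                    (t.accession, p.begin, p.end)
                )
        for cid, expected in planted.items():
            got = {
                (d, b, e)
                for d, entries in corpus_index.cat.get(cid, {}).items()
                for _s, b, e in entries
            }
            assert got == expected

    def test_round_trip_serialization(self, corpus_index, tmp_path):
        path = corpus_index.save(tmp_path / "ix")
        loaded = InvertedIndex.load(path)
        assert loaded.to_json() == corpus_index.to_json()


class TestSearchBasics:
    def test_no_hit_query_returns_empty(self):
        _forest, docs = simple_corpus()
        idx = build_index(docs)
        res = search(idx, Query(keyword_expr=Term("x"), scope="document"))
        assert res.total_documents == 0

    def test_unknown_category_rejected(self):
        forest, docs = simple_corpus()
        idx = build_index(docs)
        with pytest.raises(NotFoundError):
            search(idx, Query(categories=(("nope", False),)), forest)

    def test_unknown_subcorpus_warns_and_is_empty(self):
        forest, docs = simple_corpus()
        idx = build_index(docs)
        with pytest.warns(UserWarning, match="subcorpus"):
            res = search(
                idx,
                Query(keyword_expr=Term("kinase"),
                      filters=Filters(subcorpus="Ghost")),
                forest,
            )
        assert res.total_documents == 0 and res.warnings

    def test_sentence_scope_reports_only_satisfying_sentences(self):
        forest, docs = simple_corpus()
        idx = build_index(docs)
        res = search(
            idx,
            Query(keyword_expr=parse_query("enzyme assay"), scope="sentence"),
            forest,
        )
        (hit,) = res.hits
        assert {s.sentence_ordinal for s in hit.sentence_hits} == {1, 2}


class TestOracleEquivalence:
    def test_randomized_queries_match_brute_force(
        self, corpus_index, annotated_docs, fixture_forest
    ):
        """60 randomized queries over the 20-document fixture corpus:
        result membership equals the direct document-scanning evaluator."""
        pool = make_query_pool(annotated_docs, fixture_forest)
        rng = random.Random(2024)
        checked = 0
        for _ in range(60):
            q = random_query(rng, pool)
            got = result_membership(
                search(corpus_index, q, fixture_forest), q.scope
            )
            want = brute_force_search(annotated_docs, q, fixture_forest)
            assert got == want, q
            checked += 1
        assert checked == 60

    def test_scope_nesting(self, corpus_index, annotated_docs, fixture_forest):
        """For negation-free queries, documents owning sentence-scope hits
        are a subset of the document-scope result set (a sentence satisfying
        NOT x does not imply its document does, so NOT is excluded)."""
        from litmine.query import Not as _Not

        def has_not(node):
            if node is None or isinstance(node, (Term, Phrase)):
                return False
            if isinstance(node, _Not):
                return True
            return any(has_not(c) for c in node.children)

        pool = make_query_pool(annotated_docs, fixture_forest)
        rng = random.Random(7)
        import dataclasses

        for _ in range(30):
            q = random_query(rng, pool)
            if has_not(q.keyword_expr):
                continue
            q = dataclasses.replace(q, scope="sentence")
            sent_docs = {
                d for d, _s in result_membership(
                    search(corpus_index, q, fixture_forest), "sentence"
                )
            }
            q_doc = dataclasses.replace(q, scope="document")
            doc_set = result_membership(
                search(corpus_index, q_doc, fixture_forest), "document"
            )
            assert sent_docs <= doc_set

    def test_exclusion_law(self, corpus_index, annotated_docs, fixture_forest):
        """Adding an excluded keyword never adds a unit to the result."""
        pool = make_query_pool(annotated_docs, fixture_forest)
        rng = random.Random(13)
        import dataclasses

        for _ in range(15):
            q = random_query(rng, pool)
            base = result_membership(search(corpus_index, q, fixture_forest), q.scope)
            word = rng.choice(pool["vocab"])
            q2 = dataclasses.replace(
                q,
                filters=dataclasses.replace(
                    q.filters, exclude=q.filters.exclude + (word,)
                ),
            )
            restricted = result_membership(
                search(corpus_index, q2, fixture_forest), q.scope
            )
            assert restricted <= base

    def test_filters_only_shrink(self, corpus_index, annotated_docs, fixture_forest):
        pool = make_query_pool(annotated_docs, fixture_forest)
        rng = random.Random(99)
        import dataclasses

        for _ in range(15):
            q = dataclasses.replace(
                random_query(rng, pool), filters=Filters(), sort="score"
            )
            base = result_membership(search(corpus_index, q, fixture_forest), q.scope)
            year = rng.choice(pool["years"])
            q2 = dataclasses.replace(q, filters=Filters(year=(year, year + 5)))
            assert (
                result_membership(search(corpus_index, q2, fixture_forest), q.scope)
                <= base
            )


class TestCategorySemantics:
    def test_multi_category_conjunction(self, corpus_index, annotated_docs,
                                        fixture_forest):
        """Sentence-scope multi-category search returns only sentences with
        at least one annotation from every selected category."""
        from oracle_utils import DocView

        pool = make_query_pool(annotated_docs, fixture_forest)
        rng = random.Random(5)
        views = {d.doc_id: DocView(d) for d in annotated_docs}
        tried = 0
        for _ in range(40):
            cids = [rng.choice(pool["categories"]) for _ in range(rng.randint(2, 3))]
            q = Query(categories=tuple((c, True) for c in cids), scope="sentence")
            res = search(corpus_index, q, fixture_forest)
            for h in res.hits:
                view = views[h.doc_id]
                for sh in h.sentence_hits:
                    for cid in cids:
                        ids = set(fixture_forest.descendants(cid))
                        assert ids & view.sent_cats[sh.sentence_ordinal]
            tried += 1
        assert tried == 40

    def test_child_expansion_monotone(self, corpus_index, annotated_docs,
                                      fixture_forest):
        """include_children results are a superset of without-children
        results on 20 random category queries."""
        pool = make_query_pool(annotated_docs, fixture_forest)
        rng = random.Random(17)
        for _ in range(20):
            cid = rng.choice(pool["categories"])
            scope = rng.choice(("sentence", "document"))
            without = result_membership(
                search(corpus_index, Query(categories=((cid, False),), scope=scope),
                       fixture_forest),
                scope,
            )
            with_children = result_membership(
                search(corpus_index, Query(categories=((cid, True),), scope=scope),
                       fixture_forest),
                scope,
            )
            assert without <= with_children


class TestScoring:
    def test_ln2_hand_computed_case(self):
        """Single term, tf=1, df=1, N=2: raw = (1+ln 1) * ln(1 + 2/2) = ln 2."""
        _forest, docs = simple_corpus()
        idx = build_index(docs)
        res = search(idx, Query(keyword_expr=Term("kinase"), scope="document"))
        (hit,) = res.hits
        assert abs(hit.raw_score - math.log(2)) < 1e-12
        assert hit.doc_score == 1.0

    def test_top_document_normalized_to_one(self, corpus_index, annotated_docs,
                                            fixture_forest):
        # negation-free queries: a hit matching only via NOT has no
        # positive occurrence mass and scores 0 before normalization
        from oracle_utils import contains_not

        pool = make_query_pool(annotated_docs, fixture_forest)
        rng = random.Random(31)
        seen = 0
        for _ in range(60):
            q = random_query(rng, pool)
            if contains_not(q.keyword_expr):
                continue
            res = search(corpus_index, q, fixture_forest)
            if not res.hits:
                continue
            scores = [h.doc_score for h in res.hits]
            assert max(scores) == 1.0
            assert all(0 < s <= 1.0 for s in scores)
            if q.sort == "score":
                assert scores == sorted(scores, reverse=True)
            seen += 1
        assert seen > 10

    def test_reference_implementation_agreement(self, corpus_index, annotated_docs,
                                                fixture_forest):
        """Raw document scores agree with an independently coded
        implementation of the pinned formula to 1e-12."""
        pool = make_query_pool(annotated_docs, fixture_forest)
        rng = random.Random(47)
        compared = 0
        import dataclasses

        for _ in range(25):
            q = dataclasses.replace(random_query(rng, pool), filters=Filters())
            res = search(corpus_index, q, fixture_forest)
            if not res.hits:
                continue
            expected = reference_raw_scores(
                annotated_docs, q, fixture_forest, [h.doc_id for h in res.hits]
            )
            for h in res.hits:
                assert abs(h.raw_score - expected[h.doc_id]) < 1e-12
                compared += 1
        assert compared > 20


class TestSort:
    def test_year_order(self):
        # chronological sort puts most recent first
        _forest, docs = simple_corpus()
        idx = build_index(docs)
        res = search(
            idx,
            Query(keyword_expr=parse_query("kinase OR plain"), scope="document",
                  sort="year"),
        )
        years = [h.year for h in res.hits]
        assert years == sorted(years, reverse=True)

    def test_sort_is_permutation(self, corpus_index, annotated_docs, fixture_forest):
        pool = make_query_pool(annotated_docs, fixture_forest)
        rng = random.Random(3)
        for _ in range(10):
            q = random_query(rng, pool)
            res = search(corpus_index, q, fixture_forest)
            by_year = sort_results(res, "year")
            by_score = sort_results(res, "score")
            ids = sorted(h.doc_id for h in res.hits)
            assert sorted(h.doc_id for h in by_year.hits) == ids
            assert sorted(h.doc_id for h in by_score.hits) == ids

    def test_year_ties_break_by_score(self):
        from litmine.search import DocHit, SearchResult

        hits = tuple(
            DocHit(d, "", "", 2015, "", s, s)
            for d, s in [("a", 0.2), ("b", 1.0), ("c", 0.5)]
        )
        res = sort_results(SearchResult(hits=hits, total_documents=3), "year")
        assert [h.doc_id for h in res.hits] == ["b", "c", "a"]
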