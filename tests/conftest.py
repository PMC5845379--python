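from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))

from litmine.categories import build_category_forest, parse_obo
from litmine.fixtures import FixtureSpec, generate_corpus, generate_obo
from litmine.ingest import convert, parse_nxml
from litmine.lexical import (
    DEFAULT_SUBCORPUS_RULES,
    annotate,
    apply_subcorpora,
    build_lexicon_tree,
)
from litmine.index import build_index


@pytest.fixture(scope="session")
def fixture_spec():
    return FixtureSpec(seed=11, n_docs=20, n_terms=50)


@pytest.fixture(scope="session")
def fixture_obo(fixture_spec):
    return generate_obo(fixture_spec)


@pytest.fixture(scope="session")
def fixture_forest(fixture_obo):
    obo_text, truth = fixture_obo
    return build_category_forest(parse_obo(obo_text), [truth["root"]], 4)


@pytest.fixture(scope="session")
def fixture_corpus(fixture_spec, fixture_forest):
    """(files, truth) for the session's seeded 20-document corpus."""
    return generate_corpus(fixture_spec, fixture_forest)


@pytest.fixture(scope="session")
def converted_docs(fixture_corpus):
    files, _truth = fixture_corpus
    docs = []
    for name, data in sorted(files.items()):
        docs.append(convert(parse_nxml(data, fallback_accession=Path(name).stem)))
    return docs


@pytest.fixture(scope="session")
def annotated_docs(converted_docs, fixture_forest):
    tree = build_lexicon_tree(fixture_forest)
    return [
        apply_subcorpora(annotate(doc, tree), DEFAULT_SUBCORPUS_RULES)
        for doc in converted_docs
    ]


@pytest.fixture(scope="session")
def corpus_index(annotated_docs):
    return build_index(annotated_docs)
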