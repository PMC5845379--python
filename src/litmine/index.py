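"""Inverted index over word tokens and lexical (category) annotations.

Postings are kept at sentence granularity with token positions, which
supports phrase queries, sentence-scope search and highlighting.  Document
frequencies are derived from the postings (df = number of distinct
documents), and bibliographic fields are stored alongside for filtering.
The index serializes to a single sorted JSON file, so identical corpora
produce byte-identical indexes.
"""

from __future__ import annotations

import bisect
import json
from pathlib import Path
from typing import Iterable

from .errors import InvalidInputError, ParseError
from .model import Document

INDEX_FILE = "index.json"


class InvertedIndex:
    def __init__(self):
        #: token -> doc_id -> list of (sentence_ordinal, token_position, begin, end)
        self.kw: dict[str, dict[str, list[tuple[int, int, int, int]]]] = {}
        #: category_id -> doc_id -> list of (sentence_ordinal, begin, end)
        self.cat: dict[str, dict[str, list[tuple[int, int, int]]]] = {}
        #: doc_id -> bibliographic + structural metadata
        self.docs: dict[str, dict] = {}

    @property
    def n_docs(self) -> int:
        return len(self.docs)

    def df_kw(self, token: str) -> int:
        return len(self.kw.get(token, ()))

    def df_cat(self, category_ids: Iterable[str]) -> int:
        docs: set[str] = set()
        for cid in category_ids:
            docs.update(self.cat.get(cid, ()))
        return len(docs)

    def add_document(self, doc: Document) -> None:
        if doc.doc_id in self.docs:
            raise InvalidInputError(f"duplicate doc_id {doc.doc_id!r}")
        if doc.stage < 2:
            raise InvalidInputError(
                f"document {doc.doc_id} is stage {doc.stage}; index needs stage >= 2"
            )
        sentences = doc.layer("sentence")
        sent_begins = [s.begin for s in sentences]

        def ordinal(begin: int) -> int:
            i = bisect.bisect_right(sent_begins, begin) - 1
            if i >= 0 and begin < sentences[i].end:
                return i
            return -1

        sections: dict[str, set[int]] = {}
        for sec in doc.layer("section"):
            label = sec.attributes.get("label", "").lower()
            if not label:
                continue
            ords = {
                i
                for i, s in enumerate(sentences)
                if s.begin >= sec.begin and s.end <= sec.end
            }
            sections.setdefault(label, set()).update(ords)

        for pos, tok in enumerate(doc.layer("token")):
            s_ord = ordinal(tok.begin)
            if s_ord < 0:
                continue
            norm = doc.sofa[tok.begin : tok.end].lower()
            self.kw.setdefault(norm, {}).setdefault(doc.doc_id, []).append(
                (s_ord, pos, tok.begin, tok.end)
            )

        for ann in doc.layer("lexical"):
            s_ord = ordinal(ann.begin)
            if s_ord < 0:
                continue
            cid = ann.attributes["category_id"]
            self.cat.setdefault(cid, {}).setdefault(doc.doc_id, []).append(
                (s_ord, ann.begin, ann.end)
            )

        bib = doc.bibliography
        self.docs[doc.doc_id] = {
            "accession": bib.accession,
            "title": bib.title,
            "authors": list(bib.authors),
            "journal": bib.journal,
            "year": bib.year,
            "article_type": bib.article_type,
            "subcorpora": sorted(doc.subcorpora),
            "n_sentences": len(sentences),
            "sentence_spans": [[s.begin, s.end] for s in sentences],
            "sections": {k: sorted(v) for k, v in sorted(sections.items())},
        }

    # -- persistence ----------------------------------------------------

    def to_json(self) -> dict:
        return {
            "docs": {k: self.docs[k] for k in sorted(self.docs)},
            "kw": {
                t: {d: sorted(ps) for d, ps in sorted(m.items())}
                for t, m in sorted(self.kw.items())
            },
            "cat": {
                c: {d: sorted(ps) for d, ps in sorted(m.items())}
                for c, m in sorted(self.cat.items())
            },
        }

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        if path.suffix != ".json":
            path.mkdir(parents=True, exist_ok=True)
            path = path / INDEX_FILE
        path.write_text(
            json.dumps(self.to_json(), indent=0, sort_keys=True, ensure_ascii=False),
            "utf-8",
        )
        return path

    @classmethod
    def load(cls, path: str | Path) -> "InvertedIndex":
        path = Path(path)
        if path.is_dir():
            path = path / INDEX_FILE
        try:
            obj = json.loads(path.read_text("utf-8"))
        except (OSError, json.JSONDecodeError) as exc:
            raise ParseError(f"cannot read index {path}: {exc}") from exc
        idx = cls()
        idx.docs = obj["docs"]
        idx.kw = {
            t: {d: [tuple(p) for p in ps] for d, ps in m.items()}
            for t, m in obj["kw"].items()
        }
        idx.cat = {
            c: {d: [tuple(p) for p in ps] for d, ps in m.items()}
            for c, m in obj["cat"].items()
        }
        return idx


def build_index(documents: Iterable[Document]) -> InvertedIndex:
    """Index keywords (normalized tokens) and category annotations of
    stage >= 2 documents."""
    idx = InvertedIndex()
    for doc in documents:
        idx.add_document(doc)
    return idx
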