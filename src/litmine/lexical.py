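"""Dictionary markup: match category lexica against a converted document.

Matching operates on the token layer, not on raw substrings, so a lexicon
form "Gene" never fires inside the word "Generation".  Tokens are broken
at internal hyphens into *segments* for matching purposes, and the
separator between consecutive matched segments must be whitespace or a
single hyphen; this lets the two-word form "DNA binding" match the
hyphenated spelling "DNA-binding" (and vice versa) while every emitted
span still covers whole tokens.  At each starting token *all* matches are
reported, not only the longest, so "kinase" and "kinase activity" both
fire on "kinase activity".
"""

from __future__ import annotations

import dataclasses
import re
import warnings
from dataclasses import dataclass
from typing import Iterable, NamedTuple

from .categories import CategoryForest
from .errors import InvalidInputError
from .ingest import tokenize
from .model import Annotation, Document, add_annotations


class _Payload(NamedTuple):
    category_id: str
    surface_form: str
    case_sensitive: bool
    source_term_id: str
    segments: tuple[str, ...]  # original-case segment texts of the form


class _Node:
    __slots__ = ("children", "payloads")

    def __init__(self):
        self.children: dict[str, _Node] = {}
        self.payloads: list[_Payload] = []


def form_segments(form: str) -> list[str]:
    """Token segments of a surface form: tokens split at internal hyphens."""
    segs: list[str] = []
    for b, e in tokenize(form):
        segs.extend(p for p in form[b:e].split("-") if p)
    return segs


class LexiconTree:
    """Token-segment trie over all surface forms of a category forest.

    Edges are labelled with lowercased segments; terminal nodes hold the
    payloads (category, form, case policy, source term) of every form
    whose segment sequence ends there, so one terminal may serve several
    categories.  Lookup is deterministic and independent of insertion
    order.
    """

    def __init__(self):
        self.root = _Node()
        self.n_forms = 0

    def insert(
        self,
        category_id: str,
        surface_form: str,
        case_sensitive: bool,
        source_term_id: str,
    ) -> bool:
        segs = form_segments(surface_form)
        if not segs:
            warnings.warn(f"surface form {surface_form!r} has no tokens; skipped")
            return False
        node = self.root
        for seg in segs:
            node = node.children.setdefault(seg.lower(), _Node())
        payload = _Payload(
            category_id, surface_form, case_sensitive, source_term_id, tuple(segs)
        )
        if payload not in node.payloads:
            node.payloads.append(payload)
            self.n_forms += 1
        return True

    def lookup(self, segments: list[str]) -> list[_Payload]:
        """Payloads stored at the exact (lowercased) segment path, if any."""
        node = self.root
        for seg in segments:
            node = node.children.get(seg.lower())
            if node is None:
                return []
        return list(node.payloads)


def build_lexicon_tree(forest: CategoryForest) -> LexiconTree:
    if not forest.nodes:
        raise InvalidInputError("cannot build a lexicon tree from an empty forest")
    tree = LexiconTree()
    for cid in sorted(forest.nodes):
        for entry in forest.nodes[cid].own_lexicon:
            tree.insert(cid, entry.surface_form, entry.case_sensitive, entry.source_term_id)
    return tree


class _Seg(NamedTuple):
    begin: int
    end: int
    text: str
    token_start: bool
    token_end: bool


def _sentence_segments(sofa: str, tokens: list[tuple[int, int]]) -> list[_Seg]:
    segs: list[_Seg] = []
    for b, e in tokens:
        text = sofa[b:e]
        parts = [p for p in text.split("-") if p]
        # recover sub-offsets of the hyphen-split parts
        off = b
        for i, part in enumerate(parts):
            start = sofa.index(part, off, e)
            segs.append(
                _Seg(start, start + len(part), part, i == 0, i == len(parts) - 1)
            )
            off = start + len(part)
    return segs


def annotate(
    doc: Document,
    tree: LexiconTree,
    allow_hyphen_separator: bool = True,
) -> Document:
    """Append lexical annotations for every lexicon match and advance to stage 2.

    Matches never cross sentence boundaries; one annotation is emitted per
    distinct (span, category) pair, from the first matched token's begin to
    the last matched token's end.
    """
    sentences = doc.layer("sentence")
    tokens = doc.layer("token")
    if doc.stage < 1 or not tokens:
        raise InvalidInputError(
            f"document {doc.doc_id} lacks the token layer; run conversion first"
        )

    matches: dict[tuple[int, int, str], _Payload] = {}
    ti = 0
    for sent in sentences:
        sent_tokens = []
        while ti < len(tokens) and tokens[ti].begin < sent.end:
            if tokens[ti].begin >= sent.begin:
                sent_tokens.append((tokens[ti].begin, tokens[ti].end))
            ti += 1
        segs = _sentence_segments(doc.sofa, sent_tokens)
        for i, seg in enumerate(segs):
            if not seg.token_start:
                continue
            node = tree.root
            j = i
            while j < len(segs):
                cur = segs[j]
                if j > i:
                    gap = doc.sofa[segs[j - 1].end : cur.begin]
                    # a hyphen gap inside one token is always fine; across
                    # tokens only under the separator-tolerance option
                    hyphen_ok = allow_hyphen_separator or not segs[j - 1].token_end
                    if not (gap.isspace() or (gap == "-" and hyphen_ok)):
                        break
                node = node.children.get(cur.text.lower())
                if node is None:
                    break
                if node.payloads and cur.token_end:
                    window = [s.text for s in segs[i : j + 1]]
                    for payload in node.payloads:
                        if payload.case_sensitive and tuple(window) != payload.segments:
                            continue
                        key = (seg.begin, cur.end, payload.category_id)
                        matches.setdefault(key, payload)
                j += 1

    counter = len(doc.annotations)
    anns = []
    for (b, e, cid), payload in sorted(matches.items()):
        counter += 1
        anns.append(
            Annotation(
                f"lx{counter:06d}",
                "lexical",
                b,
                e,
                {
                    "category_id": cid,
                    "matched_form": payload.surface_form,
                    "term_id": payload.source_term_id,
                },
            )
        )
    doc = add_annotations(doc, anns)
    return dataclasses.replace(doc, stage=max(doc.stage, 2))


def clear_lexical(doc: Document) -> Document:
    """Drop the lexical layer (used before re-annotation)."""
    kept = tuple(a for a in doc.annotations if a.layer != "lexical")
    return dataclasses.replace(doc, annotations=kept, stage=min(doc.stage, 1))


@dataclass(frozen=True)
class SubcorpusRule:
    """A (label, regex) pair assigning a sub-corpus to matching documents."""

    label: str
    pattern: str

    def __post_init__(self):
        object.__setattr__(self, "_rx", re.compile(self.pattern))

    def matches(self, text: str) -> bool:
        return bool(self._rx.search(text))


#: Example rules in the style the corpus builder ships by default.
DEFAULT_SUBCORPUS_RULES = (
    SubcorpusRule("Genetics", "[Gg]enet"),
    SubcorpusRule("Genomics", "[Gg]enom"),
    SubcorpusRule("Medicine", "[Mm]edicin"),
)


def classify_subcorpus(doc: Document, rules: Iterable[SubcorpusRule]) -> set[str]:
    """Labels whose pattern matches the title, journal, or any subject."""
    bib = doc.bibliography
    fields = [bib.title, bib.journal, *bib.subjects]
    return {r.label for r in rules if any(r.matches(f) for f in fields if f)}


def apply_subcorpora(doc: Document, rules: Iterable[SubcorpusRule]) -> Document:
    return dataclasses.replace(
        doc, subcorpora=frozenset(doc.subcorpora | classify_subcorpus(doc, rules))
    )


def load_rules(path) -> list[SubcorpusRule]:
    import json
    from pathlib import Path

    data = json.loads(Path(path).read_text("utf-8"))
    return [SubcorpusRule(r["label"], r["pattern"]) for r in data]
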