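"""Article conversion: NXML / plain text to a stage-1 standoff document.

The converter assembles the SofA as title, abstract, body paragraphs and
figure/table captions in document order, separated by single blank lines,
and attaches paragraph, section, sentence, token and image annotations.
Captions are part of the SofA so that searches restricted to figure/table
sentences can match them.
"""

from __future__ import annotations

import dataclasses
import re
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from .errors import InvalidInputError, ParseError
from .model import Annotation, Bibliography, Document, add_annotations, create_document

# A word token is a maximal run of Unicode letters/digits in which the
# connector characters - . / _ ' are token-internal iff flanked on both
# sides by a letter or digit ("zyg-1", "C", "elegans", "3.5", "p53/mdm2").
_TOKEN_RE = re.compile(r"[^\W_]+(?:[-./_'][^\W_]+)*")

#: Default sentence-splitting abbreviation exceptions.  A candidate boundary
#: immediately after one of these strings is suppressed.  Single-capital
#: genus abbreviations ("C. elegans", "E. coli") are handled by a separate
#: rule, not this list.
DEFAULT_ABBREVIATIONS = (
    "Fig.",
    "Figs.",
    "et al.",
    "e.g.",
    "i.e.",
    "vs.",
    "ca.",
    "cf.",
    "approx.",
    "no.",
    "No.",
)

_GENUS_RE = re.compile(r"(?:^|[\s(\[])[A-Z]\.$")


def tokenize(text: str) -> list[tuple[int, int]]:
    """Word-token spans of ``text``: non-overlapping, sorted, punctuation-free."""
    return [m.span() for m in _TOKEN_RE.finditer(text)]


def _is_abbreviation(prefix: str, abbreviations: tuple[str, ...]) -> bool:
    for abbr in abbreviations:
        if prefix.endswith(abbr):
            before = prefix[: -len(abbr)]
            if not before or not (before[-1].isalnum() or before[-1] in "-._'"):
                return True
    return bool(_GENUS_RE.search(prefix))


def split_sentences(
    text: str,
    tokens: list[tuple[int, int]] | None = None,
    abbreviations: tuple[str, ...] = DEFAULT_ABBREVIATIONS,
) -> list[tuple[int, int]]:
    """Sentence spans partitioning the token-bearing extent of ``text``.

    A boundary occurs after ``.``, ``!`` or ``?`` followed by whitespace and
    an uppercase letter or digit, unless the terminator closes an
    abbreviation from the exception list or a single-capital genus
    abbreviation.  Every token lies in exactly one sentence.
    """
    if tokens is None:
        tokens = tokenize(text)
    if not tokens:
        return []

    boundaries: list[int] = []  # index of the terminator character
    for m in re.finditer(r"[.!?]", text):
        i = m.start()
        j = i + 1
        while j < len(text) and text[j] in ".!?":
            j += 1  # treat runs like "?!" or "..." as one terminator
        k = j
        while k < len(text) and text[k].isspace():
            k += 1
        if k == j or k >= len(text):
            continue  # no whitespace after, or end of text
        if not (text[k].isupper() or text[k].isdigit()):
            continue
        if _is_abbreviation(text[: i + 1], abbreviations):
            continue
        boundaries.append(j - 1)

    spans: list[tuple[int, int]] = []
    bi = 0
    start_idx: int | None = None
    for idx, (b_tok, e_tok) in enumerate(tokens):
        if start_idx is None:
            start_idx = idx
        next_begin = tokens[idx + 1][0] if idx + 1 < len(tokens) else len(text) + 1
        while bi < len(boundaries) and boundaries[bi] < e_tok:
            bi += 1  # boundary with no tokens after the previous close
        if bi < len(boundaries) and boundaries[bi] < next_begin:
            spans.append((tokens[start_idx][0], max(e_tok, boundaries[bi] + 1)))
            start_idx = None
            bi += 1
    if start_idx is not None:
        end = tokens[-1][1]
        while end < len(text) and text[end] in ".!?":
            end += 1
        spans.append((tokens[start_idx][0], end))
    return spans


def _norm_ws(text: str) -> str:
    return re.sub(r"\s+", " ", text).strip()


@dataclass
class NxmlArticle:
    """Parsed JATS/NXML article: front matter plus ordered body blocks."""

    raw: bytes
    accession: str
    title: str = ""
    journal: str = ""
    year: int | None = None
    authors: tuple[str, ...] = ()
    article_type: str = ""
    subjects: tuple[str, ...] = ()
    abstract: str = ""
    #: ordered (section_label, paragraph_text) pairs
    body_blocks: list[tuple[str, str]] = field(default_factory=list)
    #: ordered (fig_id, caption_text, graphic_href)
    figures: list[tuple[str, str, str]] = field(default_factory=list)


def _text_of(elem) -> str:
    return _norm_ws("".join(elem.itertext()))


def _first(tree, *paths) -> str:
    for path in paths:
        hits = tree.findall(path)
        for h in hits:
            txt = _text_of(h)
            if txt:
                return txt
    return ""


def parse_nxml(xml: bytes, fallback_accession: str = "") -> NxmlArticle:
    """Parse a JATS-style NXML article.

    Missing optional fields become empty/unknown.  Inline markup (italics,
    cross-references) is flattened to text.  Accession preference:
    pmid > pmc > doi > ``fallback_accession`` (usually the filename stem).
    A document with neither a title nor any accession is rejected as
    unidentifiable.
    """
    try:
        root = etree.fromstring(xml)
    except etree.XMLSyntaxError as exc:
        raise ParseError(f"malformed XML: {exc}") from exc
    if root.tag != "article":
        art = root.find(".//article")
        if art is None:
            raise ParseError("no <article> element found")
        root = art

    ids = {}
    for el in root.findall(".//front//article-id"):
        ids[el.get("pub-id-type", "")] = _text_of(el)
    accession = (
        ids.get("pmid") or ids.get("pmc") or ids.get("doi") or fallback_accession
    )

    title = _first(root, ".//front//title-group/article-title", ".//front//article-title")
    if not title and not accession:
        raise ParseError("document unidentifiable: no article-title and no accession")
    if not accession:
        accession = re.sub(r"\W+", "_", title.lower())[:64]

    journal = _first(
        root,
        ".//front//journal-meta//journal-title",
        ".//front//journal-title",
    )

    year: int | None = None
    for el in root.findall(".//front//article-meta//pub-date/year"):
        txt = _text_of(el)
        if txt.isdigit() and len(txt) == 4:
            year = int(txt)
            break

    authors = []
    for contrib in root.findall(".//front//contrib-group/contrib"):
        if contrib.get("contrib-type", "author") != "author":
            continue
        surname = _first(contrib, ".//name/surname")
        given = _first(contrib, ".//name/given-names")
        name = " ".join(x for x in (surname, given) if x)
        if not name:
            name = _text_of(contrib)
        if name:
            authors.append(name)

    subjects = [
        _text_of(el)
        for el in root.findall(".//front//article-categories//subject")
        if _text_of(el)
    ]

    abstract = ""
    abs_el = root.find(".//front//article-meta/abstract")
    if abs_el is not None:
        abstract = _text_of(abs_el)

    body_blocks: list[tuple[str, str]] = []
    figures: list[tuple[str, str, str]] = []
    body = root.find("body")

    def harvest_figures(elem):
        for fig in elem.iter("fig", "table-wrap"):
            cap = fig.find("caption")
            cap_text = _text_of(cap) if cap is not None else ""
            graphic = fig.find(".//graphic")
            href = ""
            if graphic is not None:
                for key, val in graphic.attrib.items():
                    if key.endswith("href"):
                        href = val
            if cap_text:
                figures.append((fig.get("id", ""), cap_text, href))

    def walk_body(elem, label: str):
        for child in elem:
            if child.tag == "sec":
                sec_title = child.find("title")
                sec_label = _text_of(sec_title) if sec_title is not None else label
                walk_body(child, sec_label or label)
            elif child.tag == "p":
                txt = _para_text(child)
                if txt:
                    body_blocks.append((label, txt))

    def _para_text(p) -> str:
        # flatten inline markup but exclude embedded fig/table-wrap content
        parts: list[str] = []

        def rec(el):
            if el.tag in ("fig", "table-wrap"):
                if el.tail:
                    parts.append(el.tail)
                return
            if el.text:
                parts.append(el.text)
            for c in el:
                rec(c)
            if el.tail:
                parts.append(el.tail)

        if p.text:
            parts.append(p.text)
        for c in p:
            rec(c)
        return _norm_ws("".join(parts))

    if body is not None:
        walk_body(body, "body")
        harvest_figures(body)

    return NxmlArticle(
        raw=xml,
        accession=accession,
        title=title,
        journal=journal,
        year=year,
        authors=tuple(authors),
        article_type=root.get("article-type", ""),
        subjects=tuple(subjects),
        abstract=abstract,
        body_blocks=body_blocks,
        figures=figures,
    )


_BLOCK_SEP = "\n\n"


def _assemble_blocks(
    article: NxmlArticle,
) -> list[tuple[str, str, dict]]:
    """Ordered (label, text, extra_attrs) blocks forming the SofA."""
    blocks: list[tuple[str, str, dict]] = []
    if article.title:
        blocks.append(("title", article.title, {}))
    if article.abstract:
        blocks.append(("abstract", article.abstract, {}))
    for label, text in article.body_blocks:
        blocks.append((label, text, {}))
    for fig_id, caption, href in article.figures:
        blocks.append(
            ("figure", caption, {"image": {"graphic": href, "fig_id": fig_id}})
        )
    return blocks


def convert(
    source: NxmlArticle | str,
    bibliography: Bibliography | None = None,
    abbreviations: tuple[str, ...] = DEFAULT_ABBREVIATIONS,
) -> Document:
    """Build a stage-1 document from a parsed article or plain text.

    Plain-text sources require an explicit bibliography; paragraphs are
    blank-line separated.  The conversion is a pure function of its inputs:
    identical sources yield identical documents.
    """
    if isinstance(source, NxmlArticle):
        bib = Bibliography(
            accession=source.accession,
            title=source.title,
            authors=source.authors,
            journal=source.journal,
            year=source.year,
            article_type=source.article_type,
            subjects=source.subjects,
            abstract=source.abstract,
        )
        blocks = _assemble_blocks(source)
    else:
        if bibliography is None:
            raise InvalidInputError("plain-text conversion requires a bibliography")
        bib = bibliography
        blocks = [
            ("body", _norm_ws(p), {})
            for p in re.split(r"\n\s*\n", source)
            if _norm_ws(p)
        ]
    if not blocks:
        raise InvalidInputError(f"article {bib.accession}: no text content")

    sofa = _BLOCK_SEP.join(text for _, text, _ in blocks)
    doc = create_document(sofa, bib)

    anns: list[Annotation] = []
    counter = 0

    def nid() -> str:
        nonlocal counter
        counter += 1
        return f"a{counter:06d}"

    offset = 0
    for label, text, extra in blocks:
        b, e = offset, offset + len(text)
        anns.append(Annotation(nid(), "paragraph", b, e))
        anns.append(Annotation(nid(), "section", b, e, {"label": label}))
        if "image" in extra:
            anns.append(Annotation(nid(), "image", b, e, dict(extra["image"])))
        toks = tokenize(text)
        for sb, se in split_sentences(text, toks, abbreviations):
            anns.append(Annotation(nid(), "sentence", b + sb, b + se))
        for tb, te in toks:
            anns.append(Annotation(nid(), "token", b + tb, b + te))
        offset = e + len(_BLOCK_SEP)

    doc = add_annotations(doc, anns)
    return dataclasses.replace(doc, stage=1)


def ingest_path(
    path: str | Path,
    fmt: str = "nxml",
    abbreviations: tuple[str, ...] = DEFAULT_ABBREVIATIONS,
) -> Document:
    """Convert one article file (.nxml/.xml or .txt with JSON sidecar)."""
    path = Path(path)
    if fmt == "nxml":
        article = parse_nxml(path.read_bytes(), fallback_accession=path.stem)
        return convert(article, abbreviations=abbreviations)
    if fmt == "txt":
        import json as _json

        sidecar = path.with_suffix(".json")
        meta = _json.loads(sidecar.read_text("utf-8")) if sidecar.exists() else {}
        bib = Bibliography(
            accession=meta.get("accession", path.stem),
            title=meta.get("title", ""),
            authors=tuple(meta.get("authors", ())),
            journal=meta.get("journal", ""),
            year=meta.get("year"),
        )
        return convert(path.read_text("utf-8"), bib, abbreviations=abbreviations)
    raise InvalidInputError(f"unknown format {fmt!r}")
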