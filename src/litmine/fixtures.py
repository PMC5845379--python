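"""Deterministic synthetic data: toy OBO ontologies and NXML corpora with
planted lexicon occurrences at known offsets.

The generators make ground truth *exact* rather than probabilistic:

* filler (background) words use only the letters a..m, while ontology term
  words use only n..z (plus uppercase/digit variants to exercise the
  case-sensitivity policy), so no planted surface form can collide with
  background text;
* every surface form is built from globally unique words, so no form is a
  sub-sequence of another and the all-matches annotator finds exactly the
  planted occurrences;
* sentence separators avoid the abbreviation pitfalls ("Fig. 3",
  "C. elegans") except where a fixture deliberately plants them inside a
  sentence to exercise the splitter's exception rules.

Everything is a pure function of the spec and its seed.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from lxml import etree

from .categories import CategoryForest
from .errors import InvalidInputError

_FILLER_ALPHABET = "abcdefghijklm"
_TERM_ALPHABET = "nopqrstuvwxyz"
_BAD_FILLER = {"figs", "approx"}  # would collide with abbreviation handling

XLINK = "http://www.w3.org/1999/xlink"


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for the synthetic corpus.

    Defaults describe a small but structurally complete corpus: 20
    articles of a few sections each, a 50-term ontology up to depth 5
    (one level beyond the browsable cut, so folding is exercised), and up
    to 6 planted category occurrences per article.
    """

    seed: int = 0
    n_docs: int = 20
    n_terms: int = 50
    max_ontology_depth: int = 5
    synonyms_per_term: tuple[int, int] = (0, 2)
    paragraphs_per_doc: tuple[int, int] = (2, 4)
    sentences_per_paragraph: tuple[int, int] = (2, 5)
    words_per_sentence: tuple[int, int] = (4, 10)
    plants_per_doc: tuple[int, int] = (0, 6)
    filler_vocab_size: int = 120


class _WordMint:
    """Issues globally unique words from a fixed alphabet."""

    def __init__(self, rng: random.Random, alphabet: str, lo: int, hi: int):
        self.rng = rng
        self.alphabet = alphabet
        self.lo, self.hi = lo, hi
        self.seen: set[str] = set()

    def word(self, transform=None) -> str:
        for _ in range(10000):
            w = "".join(
                self.rng.choice(self.alphabet)
                for _ in range(self.rng.randint(self.lo, self.hi))
            )
            if transform:
                w = transform(w, self.rng)
            if w.lower() not in self.seen and w.lower() not in _BAD_FILLER:
                self.seen.add(w.lower())
                return w
        raise InvalidInputError("word alphabet exhausted")


def _case_variant(w: str, rng: random.Random) -> str:
    """Turn a term word into a gene-symbol-like case-sensitive form."""
    return w[:3].upper() + "-" + str(rng.randint(1, 9))


# ---------------------------------------------------------------------------
# OBO generator
# ---------------------------------------------------------------------------


def generate_obo(spec: FixtureSpec) -> tuple[str, dict]:
    """Rooted is_a tree (with occasional extra DAG edges) as OBO text.

    Returns (obo_text, truth) where truth records, per term id, its name,
    synonyms, is_a parents and tree depth (root = 1).
    """
    if spec.n_terms < 1:
        raise InvalidInputError("n_terms must be >= 1")
    if spec.max_ontology_depth > spec.n_terms:
        raise InvalidInputError("ontology depth cannot exceed the number of terms")
    rng = random.Random(spec.seed * 2654435761 % (2**31) + 1)
    mint = _WordMint(rng, _TERM_ALPHABET, 3, 8)

    def make_name() -> str:
        n_words = rng.choice((1, 1, 2, 2, 3))
        words = []
        for _ in range(n_words):
            if rng.random() < 0.15:
                words.append(mint.word(_case_variant))
            else:
                words.append(mint.word())
        return " ".join(words)

    terms: dict[str, dict] = {}
    ids = [f"FX:{i:07d}" for i in range(1, spec.n_terms + 1)]
    depths = {ids[0]: 1}
    terms[ids[0]] = {"name": make_name(), "synonyms": [], "parents": [], "depth": 1}
    for tid in ids[1:]:
        eligible = [t for t in terms if depths[t] < spec.max_ontology_depth]
        parent = rng.choice(sorted(eligible))
        depth = depths[parent] + 1
        parents = [parent]
        # occasional extra is_a parent to exercise the multi-parent tie-break
        if rng.random() < 0.10:
            extra = [t for t in sorted(terms) if t not in parents]
            if extra:
                parents.append(rng.choice(extra))
        n_syn = rng.randint(*spec.synonyms_per_term)
        terms[tid] = {
            "name": make_name(),
            "synonyms": [make_name() for _ in range(n_syn)],
            "parents": parents,
            "depth": depth,
        }
        depths[tid] = depth

    lines = ["format-version: 1.2", ""]
    scopes = ("EXACT", "RELATED", "BROAD", "NARROW")
    for tid in ids:
        t = terms[tid]
        lines += ["[Term]", f"id: {tid}", f"name: {t['name']}"]
        for i, syn in enumerate(t["synonyms"]):
            lines.append(f'synonym: "{syn}" {scopes[i % len(scopes)]} []')
        for p in t["parents"]:
            lines.append(f"is_a: {p}")
        lines.append("")
    truth = {"root": ids[0], "terms": terms}
    return "\n".join(lines), truth


# ---------------------------------------------------------------------------
# Corpus generator
# ---------------------------------------------------------------------------

_TITLE_TEMPLATES = (
    "Population genetics of {}",
    "Genomic analysis of {} variation",
    "Clinical medicine approaches to {}",
    "Structural biology of {}",
    "Comparative ecology of {} populations",
)

_JOURNALS = (
    "Genome Letters",
    "Journal of Model Biology",
    "Archives of Medicinal Data",
    "Annals of Field Studies",
)

_SUBJECTS = ("Biology", "Genetics", "Data Analysis", "Methods")

_SECTIONS = ("Introduction", "Methods", "Results", "Discussion")

_SPECIALS = ("C. elegans", "Fig. 3")

_BLOCK_SEP = "\n\n"


@dataclass
class Plant:
    category_id: str
    term_id: str
    surface_form: str
    begin: int
    end: int


@dataclass
class DocTruth:
    accession: str
    title: str
    journal: str
    year: int
    authors: list[str]
    subjects: list[str]
    sofa: str
    sentences: list[tuple[int, int]]
    plants: list[Plant]
    labels: list[str]
    n_paragraphs: int

    def to_json(self) -> dict:
        return {
            "accession": self.accession,
            "title": self.title,
            "journal": self.journal,
            "year": self.year,
            "authors": self.authors,
            "subjects": self.subjects,
            "sofa": self.sofa,
            "sentences": [list(s) for s in self.sentences],
            "plants": [vars(p) for p in self.plants],
            "labels": self.labels,
            "n_paragraphs": self.n_paragraphs,
        }


@dataclass
class GroundTruth:
    docs: dict[str, DocTruth] = field(default_factory=dict)

    def to_json(self) -> dict:
        return {"docs": {k: v.to_json() for k, v in sorted(self.docs.items())}}

    def save(self, path) -> None:
        Path(path).write_text(
            json.dumps(self.to_json(), indent=1, ensure_ascii=False), "utf-8"
        )


def _default_rules_regexes() -> list[tuple[str, str]]:
    # the generator recomputes expected labels by direct regex application,
    # independently of the classifier
    return [("Genetics", "[Gg]enet"), ("Genomics", "[Gg]enom"), ("Medicine", "[Mm]edicin")]


def generate_corpus(
    spec: FixtureSpec, forest: CategoryForest
) -> tuple[dict[str, bytes], GroundTruth]:
    """NXML articles with planted lexicon occurrences.

    Returns ({filename: nxml_bytes}, ground_truth).  Ground-truth offsets
    refer to the SofA the converter assembles (title, abstract, body
    paragraphs, captions, blank-line separated).
    """
    import re as _re

    entries = sorted(
        {
            (cid, e.source_term_id, e.surface_form)
            for cid in forest.nodes
            for e in forest.nodes[cid].own_lexicon
        }
    )
    if not entries:
        raise InvalidInputError("forest has no lexicon entries to plant")

    rng = random.Random(spec.seed * 48271 % (2**31) + 7)
    filler_mint = _WordMint(rng, _FILLER_ALPHABET, 4, 8)
    vocab = [filler_mint.word() for _ in range(spec.filler_vocab_size)]

    files: dict[str, bytes] = {}
    truth = GroundTruth()

    for i in range(1, spec.n_docs + 1):
        accession = str(700000 + i)
        title = rng.choice(_TITLE_TEMPLATES).format(rng.choice(vocab))
        journal = rng.choice(_JOURNALS)
        year = rng.randint(1995, 2023)
        authors = [
            f"{rng.choice(vocab).capitalize()} {rng.choice('FGHKLM')}"
            for _ in range(rng.randint(1, 3))
        ]
        subjects = rng.sample(_SUBJECTS, rng.randint(1, 2))

        def sentence() -> list[str]:
            lo, hi = spec.words_per_sentence
            words = [rng.choice(vocab) for _ in range(rng.randint(lo, hi))]
            words[0] = words[0].capitalize()
            return words

        # abstract: filler only
        abstract_sents = [sentence() for _ in range(rng.randint(2, 3))]

        # body paragraphs grouped under section labels
        n_paras = rng.randint(*spec.paragraphs_per_doc)
        para_sents: list[list[list[str]]] = [
            [sentence() for _ in range(rng.randint(*spec.sentences_per_paragraph))]
            for _ in range(n_paras)
        ]
        section_of_para = [
            _SECTIONS[min(p, len(_SECTIONS) - 1)] for p in range(n_paras)
        ]

        # caption block (figures/tables are part of the searchable text)
        caption_sents = None
        if rng.random() < 0.6:
            words = sentence()
            caption_sents = [["Table", "1"] + words]

        # plant lexicon forms into body sentences (never at slot 0, so the
        # sentence-initial capitalisation cannot alter a surface form)
        n_plants = rng.randint(*spec.plants_per_doc)
        planted: list[tuple[int, int, int, tuple[str, str, str]]] = []
        used_slots: set[tuple[int, int, int]] = set()
        used_sentences: set[tuple[int, int]] = set()
        for _ in range(n_plants):
            entry = rng.choice(entries)
            for _attempt in range(50):
                p = rng.randrange(n_paras)
                s = rng.randrange(len(para_sents[p]))
                if len(para_sents[p][s]) < 3:
                    continue
                w = rng.randrange(1, len(para_sents[p][s]))
                if (p, s, w) in used_slots:
                    continue
                used_slots.add((p, s, w))
                used_sentences.add((p, s))
                planted.append((p, s, w, entry))
                break

        # abbreviation specials go into plant-free sentences
        for _ in range(rng.randint(0, 2)):
            p = rng.randrange(n_paras)
            s = rng.randrange(len(para_sents[p]))
            if (p, s) in used_sentences or len(para_sents[p][s]) < 3:
                continue
            w = rng.randrange(1, len(para_sents[p][s]))
            para_sents[p][s][w] = rng.choice(_SPECIALS)
            used_sentences.add((p, s))

        for p, s, w, entry in planted:
            para_sents[p][s][w] = entry[2]

        # ---- assemble blocks exactly as the converter does ------------
        def para_text(sents: list[list[str]]) -> str:
            return " ".join(" ".join(ws) + "." for ws in sents)

        blocks: list[tuple[str, str]] = [("title", title)]
        abstract_text = para_text(abstract_sents)
        blocks.append(("abstract", abstract_text))
        for p in range(n_paras):
            blocks.append((section_of_para[p], para_text(para_sents[p])))
        if caption_sents is not None:
            blocks.append(("figure", para_text(caption_sents)))

        sofa = _BLOCK_SEP.join(text for _lbl, text in blocks)

        # sentence spans, in SofA coordinates
        sentences: list[tuple[int, int]] = []
        block_offset: dict[int, int] = {}
        off = 0
        for bi, (lbl, text) in enumerate(blocks):
            block_offset[bi] = off
            if lbl == "title":
                sentences.append((off, off + len(text)))
            else:
                pos = 0
                sent_list = {
                    "abstract": abstract_sents,
                    "figure": caption_sents or [],
                }.get(lbl)
                if sent_list is None:
                    sent_list = para_sents[bi - 2]
                for ws in sent_list:
                    s_text = " ".join(ws) + "."
                    sentences.append((off + pos, off + pos + len(s_text)))
                    pos += len(s_text) + 1
            off += len(text) + len(_BLOCK_SEP)

        # plant offsets
        plants: list[Plant] = []
        for p, s, w, (cid, term_id, form) in planted:
            bi = 2 + p
            ws = para_sents[p][s]
            # each previous sentence contributes its text, its '.', and a space
            pos = sum(len(" ".join(prev)) + 2 for prev in para_sents[p][:s])
            word_off = sum(len(x) + 1 for x in ws[:w])
            begin = block_offset[bi] + pos + word_off
            plants.append(Plant(cid, term_id, form, begin, begin + len(form)))

        for pl in plants:
            if sofa[pl.begin : pl.end] != pl.surface_form:
                raise RuntimeError(
                    f"fixture self-check failed: plant {pl} vs "
                    f"{sofa[pl.begin:pl.end]!r}"
                )

        labels = sorted(
            lbl
            for lbl, pat in _default_rules_regexes()
            if any(_re.search(pat, f) for f in [title, journal, *subjects])
        )

        files[f"{accession}.nxml"] = _render_nxml(
            accession,
            title,
            journal,
            year,
            authors,
            subjects,
            abstract_text,
            [
                (section_of_para[p], para_text(para_sents[p]))
                for p in range(n_paras)
            ],
            para_text(caption_sents) if caption_sents is not None else None,
        )
        truth.docs[accession] = DocTruth(
            accession=accession,
            title=title,
            journal=journal,
            year=year,
            authors=authors,
            subjects=subjects,
            sofa=sofa,
            sentences=sentences,
            plants=sorted(plants, key=lambda p: (p.begin, p.end, p.category_id)),
            labels=labels,
            n_paragraphs=len(blocks),
        )
    return files, truth


def _render_nxml(
    accession: str,
    title: str,
    journal: str,
    year: int,
    authors: list[str],
    subjects: list[str],
    abstract: str,
    body_paras: list[tuple[str, str]],
    caption: str | None,
) -> bytes:
    E = etree.Element
    article = E("article", nsmap={"xlink": XLINK})
    article.set("article-type", "research-article")
    front = etree.SubElement(article, "front")
    jmeta = etree.SubElement(front, "journal-meta")
    jtg = etree.SubElement(jmeta, "journal-title-group")
    etree.SubElement(jtg, "journal-title").text = journal
    ameta = etree.SubElement(front, "article-meta")
    aid = etree.SubElement(ameta, "article-id")
    aid.set("pub-id-type", "pmid")
    aid.text = accession
    tg = etree.SubElement(ameta, "title-group")
    etree.SubElement(tg, "article-title").text = title
    cg = etree.SubElement(ameta, "contrib-group")
    for a in authors:
        surname, _, given = a.partition(" ")
        contrib = etree.SubElement(cg, "contrib")
        contrib.set("contrib-type", "author")
        name = etree.SubElement(contrib, "name")
        etree.SubElement(name, "surname").text = surname
        etree.SubElement(name, "given-names").text = given
    cats = etree.SubElement(ameta, "article-categories")
    sg = etree.SubElement(cats, "subj-group")
    for s in subjects:
        etree.SubElement(sg, "subject").text = s
    pd = etree.SubElement(ameta, "pub-date")
    etree.SubElement(pd, "year").text = str(year)
    ab = etree.SubElement(ameta, "abstract")
    etree.SubElement(ab, "p").text = abstract

    body = etree.SubElement(article, "body")
    current_sec = None
    current_label = None
    for label, text in body_paras:
        if label != current_label:
            current_sec = etree.SubElement(body, "sec")
            etree.SubElement(current_sec, "title").text = label
            current_label = label
        etree.SubElement(current_sec, "p").text = text
    if caption is not None:
        fig = etree.SubElement(body, "fig")
        fig.set("id", "F1")
        cap = etree.SubElement(fig, "caption")
        etree.SubElement(cap, "p").text = caption
        graphic = etree.SubElement(fig, "graphic")
        graphic.set(f"{{{XLINK}}}href", "f1.jpg")

    return etree.tostring(
        article, xml_declaration=True, encoding="UTF-8", pretty_print=False
    )


def write_fixture_tree(
    out_dir: str | Path, spec: FixtureSpec, forest_roots_depth: int = 4
) -> dict:
    """Materialize obo/, nxml/ and truth.json under ``out_dir``.

    Returns a small summary dict (counts and paths).  Used by the CLI.
    """
    from .categories import build_category_forest, parse_obo

    out = Path(out_dir)
    (out / "obo").mkdir(parents=True, exist_ok=True)
    (out / "nxml").mkdir(parents=True, exist_ok=True)

    obo_text, obo_truth = generate_obo(spec)
    (out / "obo" / "fixture.obo").write_text(obo_text, "utf-8")
    forest = build_category_forest(
        parse_obo(obo_text), [obo_truth["root"]], max_depth=forest_roots_depth
    )
    forest.save(out / "forest.json")

    files, truth = generate_corpus(spec, forest)
    for name, data in files.items():
        (out / "nxml" / name).write_bytes(data)
    truth.save(out / "truth.json")
    return {
        "n_terms": spec.n_terms,
        "n_docs": len(files),
        "obo": str(out / "obo" / "fixture.obo"),
        "forest": str(out / "forest.json"),
        "nxml_dir": str(out / "nxml"),
        "truth": str(out / "truth.json"),
    }
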