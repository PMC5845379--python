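"""Standoff-annotation document model and its JSON-backed corpus store.

A :class:`Document` couples an immutable full-text string (the *subject of
analysis*, SofA) with layers of standoff annotations that reference it only
by character offsets.  The SofA is never modified after creation; every
processing stage (tokenisation, sentence splitting, dictionary markup,
manual curation) appends annotations instead.  Offsets are 0-based,
half-open, and counted in Unicode code points.

Persistence is one JSON file per document under a manifest, which makes a
corpus lossless, diffable and dependency-free.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import InvalidInputError, NotFoundError, ParseError, ValidationError

#: The closed set of annotation layers.  ``token``..``image`` are structural
#: layers written by the converter; ``lexical`` holds dictionary matches;
#: ``manual`` holds curator-made records; ``computational`` is reserved for
#: third-party annotators (none is shipped).
LAYERS = frozenset(
    {
        "token",
        "sentence",
        "paragraph",
        "section",
        "image",
        "lexical",
        "manual",
        "computational",
    }
)

#: Layers whose annotations must not overlap one another.
_NON_OVERLAPPING_LAYERS = frozenset({"token", "sentence", "paragraph"})


@dataclass(frozen=True)
class Annotation:
    """A typed span over the SofA.

    Parameters
    ----------
    ann_id:
        Opaque identifier, unique within a document.
    layer:
        One of :data:`LAYERS`.
    begin, end:
        Character offsets into the owning SofA, 0-based half-open.
    attributes:
        Free-form string map.  Lexical annotations carry ``category_id``,
        ``matched_form`` and ``term_id``; section annotations carry
        ``label``; image annotations carry ``graphic``.
    """

    ann_id: str
    layer: str
    begin: int
    end: int
    attributes: Mapping[str, str] = field(default_factory=dict)

    def sort_key(self) -> tuple:
        return (self.begin, self.end, self.layer, self.ann_id)

    def to_json(self) -> dict:
        return {
            "ann_id": self.ann_id,
            "layer": self.layer,
            "begin": self.begin,
            "end": self.end,
            "attributes": dict(sorted(self.attributes.items())),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "Annotation":
        return cls(
            ann_id=obj["ann_id"],
            layer=obj["layer"],
            begin=obj["begin"],
            end=obj["end"],
            attributes=dict(obj.get("attributes", {})),
        )


@dataclass(frozen=True)
class Bibliography:
    """Bibliographic front matter of an article."""

    accession: str
    title: str = ""
    authors: tuple[str, ...] = ()
    journal: str = ""
    year: int | None = None
    article_type: str = ""
    subjects: tuple[str, ...] = ()
    abstract: str = ""

    def __post_init__(self):
        if not self.accession:
            raise InvalidInputError("bibliography accession must be non-empty")
        if self.year is not None and not (1000 <= self.year <= 9999):
            raise InvalidInputError(
                f"year must be a 4-digit integer or None, got {self.year!r}"
            )

    def to_json(self) -> dict:
        return {
            "accession": self.accession,
            "title": self.title,
            "authors": list(self.authors),
            "journal": self.journal,
            "year": self.year,
            "article_type": self.article_type,
            "subjects": list(self.subjects),
            "abstract": self.abstract,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "Bibliography":
        return cls(
            accession=obj["accession"],
            title=obj.get("title", ""),
            authors=tuple(obj.get("authors", ())),
            journal=obj.get("journal", ""),
            year=obj.get("year"),
            article_type=obj.get("article_type", ""),
            subjects=tuple(obj.get("subjects", ())),
            abstract=obj.get("abstract", ""),
        )


@dataclass(frozen=True)
class Document:
    """Immutable SofA plus layered standoff annotations.

    ``stage`` records pipeline progress: 0 = raw, 1 = converted (structural
    layers present), 2 = lexically annotated, 3 = computationally annotated.
    """

    doc_id: str
    sofa: str
    bibliography: Bibliography
    annotations: tuple[Annotation, ...] = ()
    subcorpora: frozenset[str] = frozenset()
    stage: int = 0

    def layer(self, name: str) -> list[Annotation]:
        """All annotations in ``name``, sorted by span."""
        return sorted(
            (a for a in self.annotations if a.layer == name),
            key=Annotation.sort_key,
        )

    def to_json(self) -> dict:
        return {
            "doc_id": self.doc_id,
            "sofa": self.sofa,
            "bibliography": self.bibliography.to_json(),
            "annotations": [
                a.to_json() for a in sorted(self.annotations, key=Annotation.sort_key)
            ],
            "subcorpora": sorted(self.subcorpora),
            "stage": self.stage,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "Document":
        return cls(
            doc_id=obj["doc_id"],
            sofa=obj["sofa"],
            bibliography=Bibliography.from_json(obj["bibliography"]),
            annotations=tuple(Annotation.from_json(a) for a in obj["annotations"]),
            subcorpora=frozenset(obj.get("subcorpora", ())),
            stage=obj.get("stage", 0),
        )


def create_document(sofa: str, bibliography: Bibliography) -> Document:
    """Create a stage-0 document around a non-empty SofA."""
    if not sofa:
        raise InvalidInputError("SofA must be non-empty")
    return Document(doc_id=bibliography.accession, sofa=sofa, bibliography=bibliography)


def _validate_annotation(ann: Annotation, sofa_len: int) -> None:
    if ann.layer not in LAYERS:
        raise ValidationError(f"annotation {ann.ann_id}: unknown layer {ann.layer!r}")
    if not (isinstance(ann.begin, int) and isinstance(ann.end, int)):
        raise ValidationError(f"annotation {ann.ann_id}: offsets must be integers")
    if not (0 <= ann.begin < ann.end <= sofa_len):
        raise ValidationError(
            f"annotation {ann.ann_id}: span [{ann.begin},{ann.end}) out of range "
            f"for SofA of length {sofa_len}"
        )
    if ann.layer == "lexical":
        for key in ("category_id", "matched_form"):
            if key not in ann.attributes:
                raise ValidationError(
                    f"lexical annotation {ann.ann_id} lacks attribute {key!r}"
                )


def _check_no_overlap(layer: str, anns: Sequence[Annotation]) -> None:
    ordered = sorted(anns, key=Annotation.sort_key)
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.begin < prev.end:
            raise ValidationError(
                f"{layer} annotations {prev.ann_id} and {cur.ann_id} overlap "
                f"([{prev.begin},{prev.end}) vs [{cur.begin},{cur.end}))"
            )


def add_annotations(doc: Document, anns: Iterable[Annotation]) -> Document:
    """Return a new document with ``anns`` appended.

    The SofA is untouched (standoff contract).  Every annotation is
    validated; token/sentence/paragraph layers are additionally checked for
    pairwise overlap against both the new and the existing annotations.
    """
    new = tuple(anns)
    for ann in new:
        _validate_annotation(ann, len(doc.sofa))
    combined = doc.annotations + new
    for lyr in _NON_OVERLAPPING_LAYERS:
        touched = [a for a in combined if a.layer == lyr]
        if touched:
            _check_no_overlap(lyr, touched)
    return dataclasses.replace(doc, annotations=combined)


def covered_text(doc: Document, ann: Annotation) -> str:
    """The SofA slice an annotation covers."""
    if ann not in doc.annotations:
        raise InvalidInputError(
            f"annotation {ann.ann_id} does not belong to document {doc.doc_id}"
        )
    return doc.sofa[ann.begin : ann.end]


class CorpusStore:
    """File-backed document store: one JSON file per article plus a manifest.

    The manifest maps doc_id to its pipeline stage and sub-corpus labels so
    the pipeline driver can skip up-to-date documents without opening them.
    """

    MANIFEST = "manifest.json"

    def __init__(self, root: str | Path):
        self.root = Path(root)
        self.docs_dir = self.root / "docs"
        self.docs_dir.mkdir(parents=True, exist_ok=True)
        self._manifest_path = self.root / self.MANIFEST
        if self._manifest_path.exists():
            try:
                self._manifest = json.loads(self._manifest_path.read_text("utf-8"))
            except json.JSONDecodeError as exc:
                raise ParseError(f"corrupted manifest: {exc}") from exc
        else:
            self._manifest = {}

    def _write_manifest(self) -> None:
        self._manifest_path.write_text(
            json.dumps(self._manifest, indent=1, sort_keys=True, ensure_ascii=False),
            "utf-8",
        )

    def doc_ids(self) -> list[str]:
        return sorted(self._manifest)

    def stage(self, doc_id: str) -> int:
        if doc_id not in self._manifest:
            raise NotFoundError(doc_id)
        return self._manifest[doc_id]["stage"]

    def __contains__(self, doc_id: str) -> bool:
        return doc_id in self._manifest

    def __len__(self) -> int:
        return len(self._manifest)

    def _doc_path(self, doc_id: str) -> Path:
        # doc_ids are accessions (PMIDs, DOIs, filename stems); keep the file
        # name filesystem-safe.
        safe = "".join(c if c.isalnum() or c in "._-" else "_" for c in doc_id)
        return self.docs_dir / f"{safe}.json"

    def save(self, doc: Document) -> None:
        path = self._doc_path(doc.doc_id)
        path.write_text(
            json.dumps(doc.to_json(), indent=1, sort_keys=True, ensure_ascii=False),
            "utf-8",
        )
        self._manifest[doc.doc_id] = {
            "stage": doc.stage,
            "subcorpora": sorted(doc.subcorpora),
            "file": path.name,
        }
        self._write_manifest()

    def load(self, doc_id: str) -> Document:
        if doc_id not in self._manifest:
            raise NotFoundError(doc_id)
        path = self.docs_dir / self._manifest[doc_id]["file"]
        try:
            obj = json.loads(path.read_text("utf-8"))
        except (OSError, json.JSONDecodeError) as exc:
            raise ParseError(f"cannot read stored document {doc_id}: {exc}") from exc
        return Document.from_json(obj)

    def iter_documents(self) -> Iterable[Document]:
        for doc_id in self.doc_ids():
            yield self.load(doc_id)
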