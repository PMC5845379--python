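"""Configurable curation forms and span-linked annotation export.

A curation form is a grid of typed fields (line edit, text area, pull-down
menu, check box).  Fields can be auto-completed and validated against
value lists, categories, regular expressions or external services, and
pre-populated from static text, the article's bibliography, or the
category terms found inside the curator's highlighted text spans.  A
filled record carries possibly non-contiguous evidence spans into the
document's SofA and exports either as a JSON object or as an RFC 3986
parameterized URI; an identity token supplied by the receiving system is
passed through verbatim so the annotation finds its place there.
"""

from __future__ import annotations

import json
import re
import urllib.parse
from dataclasses import dataclass, field
from pathlib import Path

from .categories import CategoryForest
from .errors import ExportError, InvalidInputError, SchemaError
from .model import Document

FIELD_KINDS = ("line_edit", "text_area", "pulldown", "checkbox")

_SOURCE_RE = re.compile(
    r"^(none|value_list|category:.+|external:.+|regex:.+)$", re.S
)
_PREPOP_RE = re.compile(r"^(none|static:.*|biblio:.+|span_terms:.+)$", re.S)


@dataclass(frozen=True)
class FormField:
    field_id: str
    label: str
    kind: str = "line_edit"
    row: int = 0
    col: int = 0
    #: "none" | "value_list" | "category:<id>" | "external:<url template>"
    autocomplete_source: str = "none"
    #: "none" | "value_list" | "category:<id>" | "regex:<pattern>"
    validator: str = "none"
    #: "none" | "static:<text>" | "biblio:<field>" | "span_terms:<cat id or any>"
    prepopulate: str = "none"
    required: bool = False
    #: options for value_list autocomplete/validation and pulldown menus
    options: tuple[str, ...] = ()


@dataclass(frozen=True)
class FormSchema:
    form_name: str
    fields: tuple[FormField, ...]
    target_url: str = ""
    transport: str = "json_post"  # or "parameterized_uri"

    def field_by_id(self, field_id: str) -> FormField:
        for f in self.fields:
            if f.field_id == field_id:
                return f
        raise SchemaError(f"unknown field {field_id!r}")

    def to_json(self) -> dict:
        return {
            "form_name": self.form_name,
            "target_url": self.target_url,
            "transport": self.transport,
            "fields": [
                {
                    "field_id": f.field_id,
                    "label": f.label,
                    "kind": f.kind,
                    "row": f.row,
                    "col": f.col,
                    "autocomplete_source": f.autocomplete_source,
                    "validator": f.validator,
                    "prepopulate": f.prepopulate,
                    "required": f.required,
                    "options": list(f.options),
                }
                for f in self.fields
            ],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "FormSchema":
        return cls(
            form_name=obj["form_name"],
            target_url=obj.get("target_url", ""),
            transport=obj.get("transport", "json_post"),
            fields=tuple(
                FormField(
                    field_id=f["field_id"],
                    label=f.get("label", f["field_id"]),
                    kind=f.get("kind", "line_edit"),
                    row=f.get("row", 0),
                    col=f.get("col", 0),
                    autocomplete_source=f.get("autocomplete_source", "none"),
                    validator=f.get("validator", "none"),
                    prepopulate=f.get("prepopulate", "none"),
                    required=f.get("required", False),
                    options=tuple(f.get("options", ())),
                )
                for f in obj["fields"]
            ),
        )

    @classmethod
    def load(cls, path: str | Path) -> "FormSchema":
        return cls.from_json(json.loads(Path(path).read_text("utf-8")))

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_json(), indent=1, ensure_ascii=False), "utf-8"
        )


def validate_schema(schema: FormSchema) -> list[str]:
    """Diagnostics for a form schema; empty iff the schema is usable."""
    diags: list[str] = []
    if not schema.form_name:
        diags.append("form_name is empty")
    if schema.transport not in ("json_post", "parameterized_uri"):
        diags.append(f"unknown transport {schema.transport!r}")
    seen_ids: set[str] = set()
    seen_pos: dict[tuple[int, int], str] = {}
    for f in schema.fields:
        where = f"field {f.field_id!r}"
        if f.field_id in seen_ids:
            diags.append(f"{where}: duplicate field_id")
        seen_ids.add(f.field_id)
        pos = (f.row, f.col)
        if pos in seen_pos:
            diags.append(
                f"{where}: duplicate grid position {pos} (also {seen_pos[pos]!r})"
            )
        seen_pos.setdefault(pos, f.field_id)
        if f.kind not in FIELD_KINDS:
            diags.append(f"{where}: unknown kind {f.kind!r}")
        if f.kind == "pulldown" and not f.options:
            diags.append(f"{where}: pulldown requires a value_list source")
        if not _SOURCE_RE.match(f.autocomplete_source):
            diags.append(
                f"{where}: bad autocomplete_source {f.autocomplete_source!r}"
            )
        if not _SOURCE_RE.match(f.validator):
            diags.append(f"{where}: bad validator {f.validator!r}")
        if not _PREPOP_RE.match(f.prepopulate):
            diags.append(f"{where}: bad prepopulate {f.prepopulate!r}")
        if f.validator == "value_list" and not f.options:
            diags.append(f"{where}: value_list validator without options")
        if f.validator.startswith("regex:"):
            try:
                re.compile(f.validator[len("regex:"):])
            except re.error as exc:
                diags.append(f"{where}: invalid validator regex ({exc})")
    return diags


def load_value_list(path: str | Path) -> tuple[str, ...]:
    """Value list from a delimited text file (one value per line)."""
    return tuple(
        ln.strip() for ln in Path(path).read_text("utf-8").splitlines() if ln.strip()
    )


def merge_spans(spans: list[tuple[int, int]]) -> list[tuple[int, int]]:
    """Sort spans and merge overlapping/adjacent highlight selections."""
    merged: list[list[int]] = []
    for b, e in sorted(spans):
        if b >= e:
            raise InvalidInputError(f"bad span [{b},{e})")
        if merged and b <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([b, e])
    return [(b, e) for b, e in merged]


@dataclass(frozen=True)
class CurationRecord:
    record_id: str
    doc_id: str
    spans: tuple[tuple[int, int], ...]
    field_values: dict = field(default_factory=dict)
    curator: str = ""
    timestamp: str = ""
    token: str = ""  # opaque identity token from the external system

    @classmethod
    def create(
        cls,
        record_id: str,
        doc: Document,
        spans: list[tuple[int, int]],
        field_values: dict | None = None,
        curator: str = "",
        timestamp: str = "",
        token: str = "",
    ) -> "CurationRecord":
        merged = merge_spans(spans)
        for b, e in merged:
            if not (0 <= b < e <= len(doc.sofa)):
                raise InvalidInputError(
                    f"span [{b},{e}) out of range for document {doc.doc_id}"
                )
        return cls(
            record_id=record_id,
            doc_id=doc.doc_id,
            spans=tuple(merged),
            field_values=dict(field_values or {}),
            curator=curator,
            timestamp=timestamp,
            token=token,
        )

    def to_json(self) -> dict:
        return {
            "record_id": self.record_id,
            "doc_id": self.doc_id,
            "spans": [list(s) for s in self.spans],
            "field_values": dict(self.field_values),
            "curator": self.curator,
            "timestamp": self.timestamp,
            "token": self.token,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "CurationRecord":
        return cls(
            record_id=obj["record_id"],
            doc_id=obj["doc_id"],
            spans=tuple(tuple(s) for s in obj["spans"]),
            field_values=dict(obj["field_values"]),
            curator=obj.get("curator", ""),
            timestamp=obj.get("timestamp", ""),
            token=obj.get("token", ""),
        )


_BIBLIO_FIELDS = (
    "accession",
    "title",
    "authors",
    "journal",
    "year",
    "article_type",
    "subjects",
    "abstract",
)


def _render_biblio(doc: Document, name: str) -> str:
    if name not in _BIBLIO_FIELDS:
        raise SchemaError(f"unknown bibliography field {name!r}")
    value = getattr(doc.bibliography, name)
    if value is None:
        return ""
    if isinstance(value, tuple):
        return "; ".join(value)
    return str(value)


def prepopulate(
    schema: FormSchema, doc: Document, spans: list[tuple[int, int]]
) -> dict:
    """Initial field values from static text, bibliography, or the category
    terms annotated inside the highlighted spans.

    ``span_terms`` fields list every lexical annotation of the requested
    category (or of any category for ``span_terms:any``) lying fully inside
    one of the spans, as ``surface_form [term_id]``, deduplicated, in
    document order.
    """
    spans = merge_spans(list(spans)) if spans else []
    values: dict[str, str] = {}
    for f in schema.fields:
        rule = f.prepopulate
        if rule == "none":
            values[f.field_id] = ""
        elif rule.startswith("static:"):
            values[f.field_id] = rule[len("static:"):]
        elif rule.startswith("biblio:"):
            values[f.field_id] = _render_biblio(doc, rule[len("biblio:"):])
        elif rule.startswith("span_terms:"):
            wanted = rule[len("span_terms:"):]
            items: list[str] = []
            for ann in doc.layer("lexical"):
                if not any(b <= ann.begin and ann.end <= e for b, e in spans):
                    continue
                if wanted != "any" and ann.attributes.get("category_id") != wanted:
                    continue
                term_id = ann.attributes.get("term_id") or ann.attributes.get(
                    "category_id", ""
                )
                entry = f"{ann.attributes.get('matched_form', '')} [{term_id}]"
                if entry not in items:
                    items.append(entry)
            values[f.field_id] = "; ".join(items)
        else:
            raise SchemaError(f"bad prepopulate rule {rule!r}")
    return values


_VALUE_ID_RE = re.compile(r"^(.*?)\s*\[([^\[\]]+)\]\s*$", re.S)


def validate_record(
    schema: FormSchema,
    record: CurationRecord,
    forest: CategoryForest | None = None,
) -> list[str]:
    """Diagnostics for a filled record; empty iff it is exportable."""
    diags: list[str] = []
    for f in schema.fields:
        value = str(record.field_values.get(f.field_id, "") or "")
        if f.required and not value.strip():
            diags.append(f"field {f.field_id!r}: required but empty")
            continue
        if not value.strip():
            continue
        v = f.validator
        if v == "none" or v.startswith("external:"):
            continue
        if v == "value_list":
            if value not in f.options:
                diags.append(
                    f"field {f.field_id!r}: value {value!r} not in value list"
                )
        elif v.startswith("regex:"):
            if not re.fullmatch(v[len("regex:"):], value):
                diags.append(
                    f"field {f.field_id!r}: value {value!r} fails regex validator"
                )
        elif v.startswith("category:"):
            cid = v[len("category:"):]
            if forest is None:
                diags.append(
                    f"field {f.field_id!r}: category validator needs a forest"
                )
                continue
            ids = forest.term_ids(cid, children=True)
            names = {
                form for form, _cs, _src, _origin in forest.expand_with_children(cid)
            }
            m = _VALUE_ID_RE.match(value)
            ok = False
            if m and m.group(2) in ids:
                ok = True
            elif value.strip() in names:
                ok = True
            if not ok:
                diags.append(
                    f"field {f.field_id!r}: {value!r} not found in category {cid}"
                )
    for key in record.field_values:
        try:
            schema.field_by_id(key)
        except SchemaError:
            diags.append(f"field {key!r}: not defined by schema {schema.form_name!r}")
    return diags


def build_payload(schema: FormSchema, record: CurationRecord, doc: Document) -> dict:
    """Canonical export content; evidence text is sliced from the SofA."""
    return {
        "form_name": schema.form_name,
        "accession": doc.bibliography.accession,
        "evidence": [
            {"begin": b, "end": e, "text": doc.sofa[b:e]} for b, e in record.spans
        ],
        "fields": {k: str(v) for k, v in sorted(record.field_values.items())},
        "curator": record.curator,
        "timestamp": record.timestamp,
        "token": record.token,
    }


def export(
    schema: FormSchema,
    record: CurationRecord,
    doc: Document,
    forest: CategoryForest | None = None,
    mode: str | None = None,
):
    """Export a validated record as (target_url, JSON object) or a URI.

    The identity token travels unchanged.  A record with outstanding
    diagnostics is refused, listing them.
    """
    diags = validate_record(schema, record, forest)
    if diags:
        raise ExportError("record not exportable: " + "; ".join(diags))
    if record.doc_id != doc.doc_id:
        raise ExportError(
            f"record targets {record.doc_id!r} but document is {doc.doc_id!r}"
        )
    payload = build_payload(schema, record, doc)
    mode = mode or schema.transport
    if mode == "json_post":
        return schema.target_url, payload
    if mode == "parameterized_uri":
        return encode_uri(schema.target_url, payload)
    raise ExportError(f"unknown export mode {mode!r}")


def encode_uri(target_url: str, payload: dict) -> str:
    """Percent-encoded GET URI carrying the payload; structured parts travel
    as JSON-encoded parameters so decoding is exact."""
    params = [
        ("form_name", payload["form_name"]),
        ("accession", payload["accession"]),
        ("evidence", json.dumps(payload["evidence"], ensure_ascii=False)),
        ("fields", json.dumps(payload["fields"], ensure_ascii=False, sort_keys=True)),
        ("curator", payload["curator"]),
        ("timestamp", payload["timestamp"]),
        ("token", payload["token"]),
    ]
    query = urllib.parse.urlencode(params, quote_via=urllib.parse.quote)
    return f"{target_url}?{query}"


def decode_uri(uri: str) -> dict:
    """Invert :func:`encode_uri`, recovering the exact payload."""
    split = urllib.parse.urlsplit(uri)
    pairs = urllib.parse.parse_qsl(split.query, keep_blank_values=True)
    raw = dict(pairs)
    return {
        "form_name": raw.get("form_name", ""),
        "accession": raw.get("accession", ""),
        "evidence": json.loads(raw["evidence"]) if raw.get("evidence") else [],
        "fields": json.loads(raw["fields"]) if raw.get("fields") else {},
        "curator": raw.get("curator", ""),
        "timestamp": raw.get("timestamp", ""),
        "token": raw.get("token", ""),
    }
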