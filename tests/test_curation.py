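"""Curation forms: schema validation, prepopulation, record validation,
JSON/URI export round-trips."""

import json
import random

import pytest

from litmine.categories import build_category_forest, parse_obo
from litmine.curation import (
    CurationRecord,
    FormField,
    FormSchema,
    build_payload,
    decode_uri,
    export,
    merge_spans,
    prepopulate,
    validate_record,
    validate_schema,
)
from litmine.errors import ExportError, SchemaError
from litmine.ingest import convert
from litmine.lexical import annotate, build_lexicon_tree
from litmine.model import Bibliography

GO_OBO = """[Term]
id: GO:0003824
name: catalytic activity

[Term]
id: GO:0016301
name: kinase activity
is_a: GO:0003824

[Term]
id: GO:0004674
name: protein serine/threonine kinase activity
is_a: GO:0016301
"""


@pytest.fixture(scope="module")
def go_forest():
    return build_category_forest(parse_obo(GO_OBO), ["GO:0003824"], 4)


@pytest.fixture(scope="module")
def go_doc(go_forest):
    text = (
        "ZYG-1 exhibits protein serine/threonine kinase activity in embryos. "
        "A second sentence mentions kinase activity. "
        "A third sentence has nothing."
    )
    doc = convert(
        text,
        Bibliography(
            accession="T1",
            title="Phosphorylation of SAS-6 by ZYG-1",
            authors=("Kitagawa D",),
            journal="Cell Division",
            year=2009,
        ),
    )
    return annotate(doc, build_lexicon_tree(go_forest))


def schema_of(*fields, transport="json_post"):
    return FormSchema(
        form_name="go-annotation",
        fields=tuple(fields),
        target_url="https://curation.example/submit",
        transport=transport,
    )


class TestValidateSchema:
    def test_valid_schema_has_no_diagnostics(self):
        schema = schema_of(
            FormField("gene", "Gene", row=0, col=0, required=True),
            FormField("mf", "Molecular Function", row=0, col=1,
                      validator="category:GO:0003824"),
            FormField("relation", "Relation", kind="pulldown", row=1, col=0,
                      options=("enables", "contributes_to")),
        )
        assert validate_schema(schema) == []

    def test_duplicate_grid_position(self):
        schema = schema_of(
            FormField("a", "A", row=0, col=0),
            FormField("b", "B", row=0, col=0),
        )
        assert any("duplicate grid position" in d for d in validate_schema(schema))

    def test_pulldown_without_value_list(self):
        schema = schema_of(FormField("p", "P", kind="pulldown"))
        assert any("value_list" in d for d in validate_schema(schema))

    @pytest.mark.parametrize("seed", range(10))
    def test_random_valid_schemas_pass(self, seed):
        rng = random.Random(seed)
        fields = []
        for i in range(rng.randint(1, 8)):
            kind = rng.choice(("line_edit", "text_area", "pulldown", "checkbox"))
            fields.append(
                FormField(
                    f"f{i}",
                    f"Field {i}",
                    kind=kind,
                    row=i // 3,
                    col=i % 3,
                    options=("a", "b") if kind == "pulldown" else (),
                    validator=rng.choice(("none", "regex:[a-z]+")),
                )
            )
        assert validate_schema(schema_of(*fields)) == []


class TestPrepopulate:
    def test_biblio_accession(self, go_doc):
        schema = schema_of(FormField("ref", "Ref", prepopulate="biblio:accession"))
        assert prepopulate(schema, go_doc, []) == {"ref": "T1"}

    def test_unknown_biblio_field_rejected(self, go_doc):
        schema = schema_of(FormField("x", "X", prepopulate="biblio:publisher"))
        with pytest.raises(SchemaError):
            prepopulate(schema, go_doc, [])

    def test_static_and_none(self, go_doc):
        schema = schema_of(
            FormField("s", "S", prepopulate="static:GO curation"),
            FormField("n", "N", row=1),
        )
        assert prepopulate(schema, go_doc, []) == {"s": "GO curation", "n": ""}

    def test_span_terms_with_identifier(self, go_doc):
        """The GO term found in the highlighted span is listed with its id."""
        schema = schema_of(
            FormField("mf", "MF", prepopulate="span_terms:GO:0003824")
        )
        sent = go_doc.layer("sentence")[0]
        values = prepopulate(schema, go_doc, [(sent.begin, sent.end)])
        assert values["mf"] == ""  # annotation belongs to a child category

        schema_any = schema_of(FormField("mf", "MF", prepopulate="span_terms:any"))
        values = prepopulate(schema_any, go_doc, [(sent.begin, sent.end)])
        assert (
            "protein serine/threonine kinase activity [GO:0004674]" in values["mf"]
        )

    def test_span_terms_restricted_to_spans(self, go_doc):
        schema = schema_of(FormField("mf", "MF", prepopulate="span_terms:any"))
        sents = go_doc.layer("sentence")
        both = prepopulate(
            schema, go_doc, [(sents[0].begin, sents[0].end),
                             (sents[1].begin, sents[1].end)]
        )
        third_only = prepopulate(
            schema, go_doc, [(sents[2].begin, sents[2].end)]
        )
        assert both["mf"].count("[GO:") >= 2
        assert third_only["mf"] == ""

    def test_pure_function(self, go_doc):
        schema = schema_of(FormField("mf", "MF", prepopulate="span_terms:any"))
        span = [(0, len(go_doc.sofa))]
        assert prepopulate(schema, go_doc, span) == prepopulate(schema, go_doc, span)


class TestValidateRecord:
    def test_required_empty(self, go_doc):
        schema = schema_of(FormField("gene", "Gene", required=True))
        record = CurationRecord.create("r1", go_doc, [(0, 5)], {"gene": ""})
        assert any("required" in d for d in validate_record(schema, record))

    def test_category_validator_accepts_bracketed_id(self, go_doc, go_forest):
        schema = schema_of(
            FormField("mf", "MF", validator="category:GO:0003824")
        )
        record = CurationRecord.create(
            "r1", go_doc, [(0, 5)], {"mf": "kinase activity [GO:0016301]"}
        )
        assert validate_record(schema, record, go_forest) == []

    def test_category_validator_accepts_bare_name(self, go_doc, go_forest):
        schema = schema_of(FormField("mf", "MF", validator="category:GO:0003824"))
        record = CurationRecord.create(
            "r1", go_doc, [(0, 5)], {"mf": "catalytic activity"}
        )
        assert validate_record(schema, record, go_forest) == []

    def test_category_validator_rejects_unknown(self, go_doc, go_forest):
        schema = schema_of(FormField("mf", "MF", validator="category:GO:0003824"))
        record = CurationRecord.create(
            "r1", go_doc, [(0, 5)], {"mf": "dancing activity [GO:404]"}
        )
        assert validate_record(schema, record, go_forest)

    def test_value_list_membership(self, go_doc):
        schema = schema_of(
            FormField("rel", "Rel", validator="value_list",
                      options=("enables", "part_of"))
        )
        ok = CurationRecord.create("r1", go_doc, [(0, 5)], {"rel": "enables"})
        bad = CurationRecord.create("r2", go_doc, [(0, 5)], {"rel": "causes"})
        assert validate_record(schema, ok) == []
        assert validate_record(schema, bad)


class TestMergeSpans:
    def test_overlapping_selections_merged(self):
        assert merge_spans([(10, 20), (15, 25), (40, 50)]) == [(10, 25), (40, 50)]

    def test_sorted_output(self):
        assert merge_spans([(40, 50), (10, 20)]) == [(10, 20), (40, 50)]


class TestExport:
    def make_record(self, go_doc, token="abc123"):
        sents = go_doc.layer("sentence")
        # non-contiguous evidence: first and third sentence
        return CurationRecord.create(
            "r1",
            go_doc,
            [(sents[0].begin, sents[0].end), (sents[2].begin, sents[2].end)],
            {"mf": "kinase activity [GO:0016301]", "note": "a/b &= c?"},
            curator="wormbase-curator",
            timestamp="2017-11-17T12:00:00Z",
            token=token,
        )

    def schema(self, transport="json_post"):
        return schema_of(
            FormField("mf", "MF", validator="category:GO:0003824"),
            FormField("note", "Note", row=1),
            transport=transport,
        )

    def test_json_payload_evidence_fidelity(self, go_doc, go_forest):
        url, payload = export(self.schema(), self.make_record(go_doc), go_doc,
                              go_forest)
        assert url == "https://curation.example/submit"
        for ev in payload["evidence"]:
            assert ev["text"] == go_doc.sofa[ev["begin"] : ev["end"]]
        assert len(payload["evidence"]) == 2  # non-contiguous spans preserved

    def test_token_passes_through_verbatim(self, go_doc, go_forest):
        _url, payload = export(self.schema(), self.make_record(go_doc), go_doc,
                               go_forest)
        assert payload["token"] == "abc123"
        uri = export(self.schema("parameterized_uri"), self.make_record(go_doc),
                     go_doc, go_forest)
        assert decode_uri(uri)["token"] == "abc123"

    def test_uri_percent_encoding_round_trip(self, go_doc, go_forest):
        uri = export(self.schema("parameterized_uri"), self.make_record(go_doc),
                     go_doc, go_forest)
        assert "%2F" in uri  # '/' inside field values is escaped
        decoded = decode_uri(uri)
        assert decoded["fields"]["note"] == "a/b &= c?"

    def test_uri_and_json_decode_identically(self, go_doc, go_forest):
        record = self.make_record(go_doc)
        _url, payload = export(self.schema(), record, go_doc, go_forest)
        uri = export(self.schema("parameterized_uri"), record, go_doc, go_forest)
        assert decode_uri(uri) == payload

    def test_failing_record_refused_with_diagnostics(self, go_doc, go_forest):
        record = CurationRecord.create(
            "r1", go_doc, [(0, 5)], {"mf": "nonsense [GO:404]"}
        )
        with pytest.raises(ExportError, match="GO:404|not found"):
            export(self.schema(), record, go_doc, go_forest)

    @pytest.mark.parametrize("seed", range(8))
    def test_random_record_round_trip(self, go_doc, go_forest, seed):
        """decode(encode(record)) recovers every field value and span."""
        rng = random.Random(seed)
        n = len(go_doc.sofa)
        spans = merge_spans(
            [
                (b, min(n, b + rng.randint(1, 30)))
                for b in rng.sample(range(n - 30), rng.randint(1, 4))
            ]
        )
        values = {
            f"f{i}": "".join(
                rng.choice("aé /?&=%+#\n\"'[]{}x") for _ in range(rng.randint(0, 12))
            )
            for i in range(rng.randint(1, 4))
        }
        schema = schema_of(
            *[FormField(k, k, row=i) for i, k in enumerate(sorted(values))],
            transport="parameterized_uri",
        )
        record = CurationRecord.create(
            "r", go_doc, spans, values, token=f"tok{seed}"
        )
        uri = export(schema, record, go_doc, go_forest)
        decoded = decode_uri(uri)
        assert decoded == build_payload(schema, record, go_doc)
        assert decoded["fields"] == {k: str(v) for k, v in values.items()}
        assert [(ev["begin"], ev["end"]) for ev in decoded["evidence"]] == list(
            record.spans
        )


class TestSchemaSerialization:
    def test_round_trip(self, tmp_path):
        schema = schema_of(
            FormField("a", "A", kind="pulldown", options=("x", "y")),
            FormField("b", "B", row=1, prepopulate="biblio:title"),
        )
        path = tmp_path / "schema.json"
        schema.save(path)
        assert FormSchema.load(path) == schema
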