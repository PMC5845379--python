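"""Batch pipeline driver: ingest -> compile -> annotate -> index.

Stage tracking lives in the corpus-store manifest; re-runs skip documents
that already reached the target stage unless forced, giving reproducible
batch semantics.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from .categories import CategoryForest, build_category_forest, parse_obo
from .errors import InvalidInputError
from .index import build_index
from .ingest import DEFAULT_ABBREVIATIONS, ingest_path
from .lexical import (
    DEFAULT_SUBCORPUS_RULES,
    annotate,
    apply_subcorpora,
    build_lexicon_tree,
    clear_lexical,
    load_rules,
)
from .model import CorpusStore

log = logging.getLogger("litmine.pipeline")

STEP_ORDER = ("ingest", "compile", "annotate", "index")


@dataclass
class PipelineConfig:
    store: Path
    input_dir: Path | None = None
    input_format: str = "nxml"
    obo: Path | None = None
    roots: list[str] = field(default_factory=list)
    max_depth: int = 4
    forest: Path | None = None
    rules: Path | None = None
    index: Path | None = None
    abbreviations: Path | None = None
    default_scope: str = "sentence"
    default_sort: str = "score"

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        obj = json.loads(Path(path).read_text("utf-8"))
        base = Path(path).parent

        def p(key):
            return (base / obj[key]) if key in obj and obj[key] else None

        store = p("store")
        if store is None:
            raise InvalidInputError("pipeline config needs a 'store' path")
        return cls(
            store=store,
            input_dir=p("input_dir"),
            input_format=obj.get("input_format", "nxml"),
            obo=p("obo"),
            roots=list(obj.get("roots", ())),
            max_depth=obj.get("max_depth", 4),
            forest=p("forest"),
            rules=p("rules"),
            index=p("index"),
            abbreviations=p("abbreviations"),
            default_scope=obj.get("default_scope", "sentence"),
            default_sort=obj.get("default_sort", "score"),
        )

    def abbreviation_list(self) -> tuple[str, ...]:
        if self.abbreviations is None:
            return DEFAULT_ABBREVIATIONS
        return tuple(
            ln.strip()
            for ln in self.abbreviations.read_text("utf-8").splitlines()
            if ln.strip()
        )

    def subcorpus_rules(self):
        if self.rules is None:
            return DEFAULT_SUBCORPUS_RULES
        return load_rules(self.rules)


def run_pipeline(
    config: PipelineConfig, steps: set[str], force: bool = False
) -> dict:
    """Execute the requested steps in pipeline order and report counts.

    Raises when a step's stage precondition is unmet (e.g. ``index``
    without any lexically annotated documents).
    """
    unknown = set(steps) - set(STEP_ORDER)
    if unknown:
        raise InvalidInputError(f"unknown pipeline steps: {sorted(unknown)}")
    report: dict = {"steps": {}}
    store = CorpusStore(config.store)

    for step in STEP_ORDER:
        if step not in steps:
            continue
        if step == "ingest":
            if config.input_dir is None:
                raise InvalidInputError("ingest step needs input_dir")
            abbrev = config.abbreviation_list()
            pattern = "*.txt" if config.input_format == "txt" else "*.[xn]*ml"
            n = skipped = 0
            for path in sorted(Path(config.input_dir).glob(pattern)):
                doc = ingest_path(path, config.input_format, abbrev)
                if not force and doc.doc_id in store and store.stage(doc.doc_id) >= 1:
                    skipped += 1
                    continue
                store.save(doc)
                n += 1
            report["steps"]["ingest"] = {"documents": n, "skipped": skipped}
            log.info("ingest: %d documents (%d up to date)", n, skipped)
        elif step == "compile":
            if config.obo is None or not config.roots:
                raise InvalidInputError("compile step needs obo and roots")
            forest = build_category_forest(
                parse_obo(Path(config.obo).read_text("utf-8")),
                config.roots,
                config.max_depth,
            )
            if config.forest is None:
                raise InvalidInputError("compile step needs a forest output path")
            forest.save(config.forest)
            report["steps"]["compile"] = {"categories": len(forest.nodes)}
            log.info("compile: %d categories", len(forest.nodes))
        elif step == "annotate":
            if not len(store):
                raise InvalidInputError(
                    "no documents in store; run the ingest step first"
                )
            if config.forest is None or not Path(config.forest).exists():
                raise InvalidInputError(
                    "annotate step needs a compiled category forest; "
                    "run the compile step first"
                )
            forest = CategoryForest.load(config.forest)
            tree = build_lexicon_tree(forest)
            rules = config.subcorpus_rules()
            n = skipped = 0
            for doc_id in store.doc_ids():
                if not force and store.stage(doc_id) >= 2:
                    skipped += 1
                    continue
                doc = store.load(doc_id)
                doc = annotate(clear_lexical(doc), tree)
                doc = apply_subcorpora(doc, rules)
                store.save(doc)
                n += 1
            report["steps"]["annotate"] = {"documents": n, "skipped": skipped}
            log.info("annotate: %d documents (%d up to date)", n, skipped)
        elif step == "index":
            ready = [d for d in store.doc_ids() if store.stage(d) >= 2]
            if not ready:
                raise InvalidInputError(
                    "no stage-2 documents; run the annotate step first"
                )
            if config.index is None:
                raise InvalidInputError("index step needs an index output path")
            idx = build_index(store.load(d) for d in ready)
            idx.save(config.index)
            report["steps"]["index"] = {"documents": len(ready)}
            log.info("index: %d documents", len(ready))
    return report
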