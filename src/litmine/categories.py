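"""Category compilation: OBO ontologies and word lists to a category forest.

A *category* is a named lexicon of surface forms (a term name plus its
synonyms) usable as a semantic search clause.  Categories form a shallow
forest with a maximum browsable depth of four.  Ontology terms deeper than
the cut are not discarded: their names and synonyms are folded into the
lexicon of their nearest ancestor at the maximum depth, so every term
remains reachable through some category.

Custom word lists are converted into OBO stanzas and compiled through the
same pipeline as formal ontologies, yielding a single root-level category
holding every listed term and synonym.
"""

from __future__ import annotations

import json
import re
import warnings
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, NamedTuple

from .errors import InvalidInputError, NotFoundError, ParseError
from .ingest import tokenize

DEFAULT_MAX_DEPTH = 4

_SYNONYM_RE = re.compile(r'^"((?:[^"\\]|\\.)*)"\s*(\w+)?')


@dataclass(frozen=True)
class OntologyTerm:
    term_id: str
    name: str
    synonyms: tuple[tuple[str, str], ...] = ()  # (text, scope)
    parents: tuple[str, ...] = ()  # is_a parent ids
    obsolete: bool = False


class LexEntry(NamedTuple):
    """One surface form of a category's lexicon."""

    surface_form: str
    case_sensitive: bool
    source_term_id: str


def case_sensitive_form(form: str) -> bool:
    """Case policy: a form matches case-sensitively iff it contains a digit
    or an uppercase letter anywhere after its first character.

    "ZYG-1" and "DnaK" must match exactly; "kinase" also matches "Kinase"
    at sentence start.
    """
    if any(c.isdigit() for c in form):
        return True
    return any(c.isupper() for c in form[1:])


def parse_obo(text: str) -> list[OntologyTerm]:
    """Parse ``[Term]`` stanzas of an OBO 1.2/1.4 flat file.

    Recognised tags: id, name, synonym, is_a, is_obsolete; everything else
    is ignored.  Stanzas missing id or name are skipped with a warning;
    obsolete terms are dropped.
    """
    terms: list[OntologyTerm] = []
    skipped = 0
    stanza: dict | None = None

    def flush():
        nonlocal skipped, stanza
        if stanza is None:
            return
        if not stanza.get("id") or not stanza.get("name"):
            skipped += 1
        elif not stanza["obsolete"]:
            terms.append(
                OntologyTerm(
                    term_id=stanza["id"],
                    name=stanza["name"],
                    synonyms=tuple(stanza["synonyms"]),
                    parents=tuple(stanza["parents"]),
                )
            )
        stanza = None

    in_term = False
    for raw_line in text.splitlines():
        line = raw_line.strip()
        if line.startswith("["):
            flush()
            in_term = line == "[Term]"
            if in_term:
                stanza = {"synonyms": [], "parents": [], "obsolete": False}
            continue
        if not in_term or stanza is None or not line or line.startswith("!"):
            continue
        if ":" not in line:
            continue
        tag, _, value = line.partition(":")
        tag = tag.strip()
        value = value.split("!", 1)[0].strip() if tag != "synonym" else value.strip()
        if tag == "id":
            stanza["id"] = value
        elif tag == "name":
            stanza["name"] = value
        elif tag == "is_a":
            stanza["parents"].append(value.split("!", 1)[0].strip())
        elif tag == "is_obsolete":
            stanza["obsolete"] = value.lower().startswith("true")
        elif tag == "synonym":
            m = _SYNONYM_RE.match(value)
            if m:
                syn_text = m.group(1).replace('\\"', '"')
                scope = m.group(2) or "RELATED"
                stanza["synonyms"].append((syn_text, scope))
    flush()
    if skipped:
        warnings.warn(f"skipped {skipped} OBO stanza(s) missing id or name")
    return terms


@dataclass
class CategoryNode:
    category_id: str
    name: str
    parent: str | None = None
    children: list[str] = field(default_factory=list)
    own_lexicon: list[LexEntry] = field(default_factory=list)
    depth: int = 1

    def surface_forms(self) -> set[str]:
        return {e.surface_form for e in self.own_lexicon}


@dataclass
class CategoryForest:
    """Depth-limited forest of categories with per-node lexica."""

    nodes: dict[str, CategoryNode] = field(default_factory=dict)
    roots: list[str] = field(default_factory=list)

    def node(self, category_id: str) -> CategoryNode:
        try:
            return self.nodes[category_id]
        except KeyError:
            raise NotFoundError(f"unknown category {category_id!r}") from None

    def by_name(self, name: str) -> list[CategoryNode]:
        return [n for n in self.nodes.values() if n.name == name]

    def descendants(self, category_id: str) -> list[str]:
        """category_id plus all forest descendants, preorder."""
        self.node(category_id)
        out: list[str] = []
        stack = [category_id]
        while stack:
            cid = stack.pop()
            out.append(cid)
            stack.extend(reversed(self.nodes[cid].children))
        return out

    def expand_with_children(
        self, category_id: str
    ) -> set[tuple[str, bool, str, str]]:
        """Union of own lexica over the node and all its descendants.

        Returns (surface_form, case_sensitive, source_term_id,
        origin_category_id) tuples.
        """
        out: set[tuple[str, bool, str, str]] = set()
        for cid in self.descendants(category_id):
            for entry in self.nodes[cid].own_lexicon:
                out.add((*entry, cid))
        return out

    def term_ids(self, category_id: str, children: bool = True) -> set[str]:
        cids = self.descendants(category_id) if children else [category_id]
        out: set[str] = set()
        for cid in cids:
            out.add(cid)
            out.update(e.source_term_id for e in self.nodes[cid].own_lexicon)
        return out

    # -- serialization --------------------------------------------------

    def to_json(self) -> dict:
        return {
            "roots": list(self.roots),
            "nodes": {
                cid: {
                    "name": n.name,
                    "parent": n.parent,
                    "children": list(n.children),
                    "depth": n.depth,
                    "own_lexicon": [list(e) for e in n.own_lexicon],
                }
                for cid, n in sorted(self.nodes.items())
            },
        }

    @classmethod
    def from_json(cls, obj: dict) -> "CategoryForest":
        forest = cls(roots=list(obj["roots"]))
        for cid, n in obj["nodes"].items():
            forest.nodes[cid] = CategoryNode(
                category_id=cid,
                name=n["name"],
                parent=n["parent"],
                children=list(n["children"]),
                depth=n["depth"],
                own_lexicon=[LexEntry(*e) for e in n["own_lexicon"]],
            )
        return forest

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(self.to_json(), indent=1, sort_keys=True, ensure_ascii=False),
            "utf-8",
        )

    @classmethod
    def load(cls, path: str | Path) -> "CategoryForest":
        try:
            return cls.from_json(json.loads(Path(path).read_text("utf-8")))
        except (json.JSONDecodeError, KeyError) as exc:
            raise ParseError(f"cannot read category forest {path}: {exc}") from exc

    def merge(self, other: "CategoryForest") -> None:
        clash = set(self.nodes) & set(other.nodes)
        if clash:
            raise InvalidInputError(f"duplicate category ids: {sorted(clash)}")
        self.nodes.update(other.nodes)
        self.roots.extend(other.roots)


def _add_entries(node: CategoryNode, entries: Iterable[LexEntry]) -> None:
    seen = node.surface_forms()
    for entry in entries:
        if entry.surface_form in seen:
            continue
        if not tokenize(entry.surface_form):
            warnings.warn(
                f"surface form {entry.surface_form!r} yields no tokens; skipped"
            )
            continue
        node.own_lexicon.append(entry)
        seen.add(entry.surface_form)


def _term_entries(term: OntologyTerm) -> list[LexEntry]:
    forms = [term.name] + [s for s, _ in term.synonyms]
    out, seen = [], set()
    for f in forms:
        if f and f not in seen:
            out.append(LexEntry(f, case_sensitive_form(f), term.term_id))
            seen.add(f)
    return out


def build_category_forest(
    terms: Iterable[OntologyTerm],
    roots: list[str],
    max_depth: int = DEFAULT_MAX_DEPTH,
) -> CategoryForest:
    """Compile ontology terms into a depth-limited category forest.

    Terms within ``max_depth`` of a root (root = depth 1, following is_a
    child edges) become nodes; deeper terms contribute their name and
    synonyms to the own_lexicon of their depth-``max_depth`` ancestor.
    A term with several is_a parents attaches under the parent reached
    first in a breadth-first traversal ordered by term_id, which makes the
    forest deterministic.
    """
    term_map = {t.term_id: t for t in terms}
    for r in roots:
        if r not in term_map:
            raise NotFoundError(f"unknown root term {r!r}")

    children: dict[str, list[str]] = {tid: [] for tid in term_map}
    for t in term_map.values():
        for p in t.parents:
            if p in children:
                children[p].append(t.term_id)
    for kids in children.values():
        kids.sort()

    # cycle check over the subgraph reachable from the roots
    _check_acyclic(children, roots)

    forest = CategoryForest(roots=list(roots))
    depth: dict[str, int] = {}
    # fold target: nearest ancestor node at depth == max_depth
    fold_into: dict[str, str] = {}
    queue: deque[str] = deque()
    for r in roots:
        if r in depth:
            continue
        depth[r] = 1
        forest.nodes[r] = CategoryNode(r, term_map[r].name, depth=1)
        _add_entries(forest.nodes[r], _term_entries(term_map[r]))
        queue.append(r)

    while queue:
        # breadth-first, siblings in term_id order (children lists sorted)
        tid = queue.popleft()
        d = depth[tid]
        for kid in children[tid]:
            if kid in depth:
                continue  # first reach wins
            depth[kid] = d + 1
            term = term_map[kid]
            if d + 1 <= max_depth:
                node = CategoryNode(kid, term.name, parent=tid, depth=d + 1)
                forest.nodes[tid].children.append(kid)
                forest.nodes[kid] = node
                _add_entries(node, _term_entries(term))
            else:
                target = fold_into.get(tid, tid)
                fold_into[kid] = target
                _add_entries(forest.nodes[target], _term_entries(term))
            queue.append(kid)
    return forest


def _check_acyclic(children: dict[str, list[str]], roots: list[str]) -> None:
    WHITE, GRAY, BLACK = 0, 1, 2
    color = {tid: WHITE for tid in children}
    stack_path: list[str] = []

    def dfs(start: str) -> None:
        stack = [(start, iter(children[start]))]
        color[start] = GRAY
        stack_path.append(start)
        while stack:
            node, it = stack[-1]
            advanced = False
            for kid in it:
                if color[kid] == GRAY:
                    cycle = stack_path[stack_path.index(kid):] + [kid]
                    raise InvalidInputError(
                        "cycle in is_a graph: " + " -> ".join(cycle)
                    )
                if color[kid] == WHITE:
                    color[kid] = GRAY
                    stack_path.append(kid)
                    stack.append((kid, iter(children[kid])))
                    advanced = True
                    break
            if not advanced:
                color[node] = BLACK
                stack_path.pop()
                stack.pop()

    for r in roots:
        if color[r] == WHITE:
            dfs(r)


def wordlist_category_id(ordinal: int) -> str:
    """Generated id for word-list categories, e.g. ``tpc:0000001``."""
    return f"tpc:{ordinal:07d}"


def termlist_to_obo(name: str, lines: list[str], ordinal: int = 1) -> tuple[str, str]:
    """Render a custom word list as OBO stanzas.

    One stanza per line: the first tab-separated field is the canonical
    term, the rest its synonyms; all stanzas are is_a children of a root
    stanza named ``name``.  Returns (obo_text, root_term_id).
    """
    if not name:
        raise InvalidInputError("word-list category needs a non-empty name")
    cleaned = [ln.strip() for ln in lines if ln.strip()]
    if not cleaned:
        raise InvalidInputError(f"word list {name!r} is empty")
    root_id = wordlist_category_id(ordinal)
    out = [
        "format-version: 1.2",
        "",
        "[Term]",
        f"id: {root_id}",
        f"name: {name}",
    ]
    for i, ln in enumerate(cleaned, start=1):
        fields = [f.strip() for f in ln.split("\t") if f.strip()]
        term, synonyms = fields[0], fields[1:]
        out += ["", "[Term]", f"id: {root_id}.{i:04d}", f"name: {term}"]
        for syn in synonyms:
            escaped = syn.replace('"', '\\"')
            out.append(f'synonym: "{escaped}" EXACT []')
        out.append(f"is_a: {root_id}")
    return "\n".join(out) + "\n", root_id


def category_from_termlist(
    name: str, lines: list[str], ordinal: int = 1
) -> CategoryNode:
    """Compile a word list into a single root-level category.

    The list is first rendered as OBO stanzas and then compiled through the
    ordinary forest builder with the cut placed at the root, which folds
    every listed term and synonym into one lexicon — the word-list route
    and the ontology route share one pipeline by construction.
    """
    obo_text, root_id = termlist_to_obo(name, lines, ordinal)
    forest = build_category_forest(parse_obo(obo_text), [root_id], max_depth=1)
    node = forest.node(root_id)
    # the category name labels the node; it is not itself a listed term
    node.own_lexicon = [e for e in node.own_lexicon if e.source_term_id != root_id]
    return node


def forest_from_termlist(name: str, lines: list[str], ordinal: int = 1) -> CategoryForest:
    node = category_from_termlist(name, lines, ordinal)
    return CategoryForest(nodes={node.category_id: node}, roots=[node.category_id])
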