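"""Boolean query language: Lucene-style keyword expressions plus category
clauses, scope, filters and sort order.

Grammar (AND binds tighter than OR; juxtaposition means AND)::

    expr     := or_expr
    or_expr  := and_expr (OR and_expr)*
    and_expr := not_term (AND? not_term)*
    not_term := [NOT] atom
    atom     := term | "phrase" | ( expr )

Operators are case-sensitive uppercase.  Terms are normalized with the
word tokenizer (lowercased), so query matching is case-insensitive; a term
that tokenizes to several tokens (e.g. ``poly(A)``) becomes a phrase.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

from .errors import InvalidInputError, QuerySyntaxError
from .ingest import tokenize


@dataclass(frozen=True)
class Term:
    token: str

    def __str__(self):
        return self.token


@dataclass(frozen=True)
class Phrase:
    tokens: tuple[str, ...]

    def __str__(self):
        return '"' + " ".join(self.tokens) + '"'


@dataclass(frozen=True)
class Not:
    child: "Node"

    def __str__(self):
        return f"NOT {_atomic(self.child)}"


@dataclass(frozen=True)
class And:
    children: tuple["Node", ...]

    def __str__(self):
        return " AND ".join(
            f"({c})" if isinstance(c, Or) else str(c) for c in self.children
        )


@dataclass(frozen=True)
class Or:
    children: tuple["Node", ...]

    def __str__(self):
        return " OR ".join(str(c) for c in self.children)


Node = Term | Phrase | Not | And | Or


def _atomic(node: Node) -> str:
    if isinstance(node, (And, Or)):
        return f"({node})"
    return str(node)


_TOKEN_SPLIT = re.compile(r'(\(|\)|")|\s+')


def _lex(s: str) -> list[tuple[str, str, int]]:
    """Lex into (kind, value, position) triples; kind in {punct, word}."""
    out = []
    i = 0
    while i < len(s):
        c = s[i]
        if c.isspace():
            i += 1
            continue
        if c in '()"':
            out.append(("punct", c, i))
            i += 1
            continue
        j = i
        while j < len(s) and not s[j].isspace() and s[j] not in '()"':
            j += 1
        out.append(("word", s[i:j], i))
        i = j
    return out


def _normalize_leaf(text: str, pos: int) -> Node:
    toks = [text[b:e].lower() for b, e in tokenize(text)]
    if not toks:
        raise QuerySyntaxError(f"term {text!r} contains no indexable characters", pos)
    if len(toks) == 1:
        return Term(toks[0])
    return Phrase(tuple(toks))


class _Parser:
    def __init__(self, s: str):
        self.src = s
        self.toks = _lex(s)
        self.i = 0

    def peek(self):
        return self.toks[self.i] if self.i < len(self.toks) else None

    def next(self):
        t = self.peek()
        if t is not None:
            self.i += 1
        return t

    def parse(self) -> Node:
        if not self.toks:
            raise QuerySyntaxError("empty query")
        node = self.or_expr()
        if self.peek() is not None:
            kind, val, pos = self.peek()
            raise QuerySyntaxError(f"unexpected {val!r}", pos)
        return node

    def or_expr(self) -> Node:
        parts = [self.and_expr()]
        while self.peek() and self.peek()[:2] == ("word", "OR"):
            self.next()
            parts.append(self.and_expr())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def and_expr(self) -> Node:
        parts = [self.not_term()]
        while True:
            t = self.peek()
            if t is None:
                break
            kind, val, pos = t
            if kind == "word" and val == "OR":
                break
            if kind == "punct" and val == ")":
                break
            if kind == "word" and val == "AND":
                self.next()
                t2 = self.peek()
                if t2 is None:
                    raise QuerySyntaxError("dangling AND", pos)
            parts.append(self.not_term())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def not_term(self) -> Node:
        t = self.peek()
        if t and t[:2] == ("word", "NOT"):
            self.next()
            if self.peek() is None:
                raise QuerySyntaxError("dangling NOT", t[2])
            return Not(self.atom())
        return self.atom()

    def atom(self) -> Node:
        t = self.next()
        if t is None:
            raise QuerySyntaxError("unexpected end of query")
        kind, val, pos = t
        if kind == "punct" and val == "(":
            node = self.or_expr()
            closing = self.next()
            if closing is None or closing[:2] != ("punct", ")"):
                raise QuerySyntaxError("unbalanced parenthesis", pos)
            return node
        if kind == "punct" and val == '"':
            words = []
            while True:
                t2 = self.next()
                if t2 is None:
                    raise QuerySyntaxError("unbalanced quote", pos)
                if t2[:2] == ("punct", '"'):
                    break
                if t2[0] == "punct":
                    raise QuerySyntaxError(
                        f"unexpected {t2[1]!r} inside phrase", t2[2]
                    )
                words.append(t2[1])
            if not words:
                raise QuerySyntaxError("empty phrase", pos)
            toks = []
            for w in words:
                toks.extend(w[b:e].lower() for b, e in tokenize(w))
            if not toks:
                raise QuerySyntaxError("phrase contains no indexable characters", pos)
            return Phrase(tuple(toks)) if len(toks) > 1 else Term(toks[0])
        if kind == "punct":
            raise QuerySyntaxError(f"unexpected {val!r}", pos)
        if val in ("AND", "OR"):
            raise QuerySyntaxError(f"misplaced operator {val}", pos)
        if val == "NOT":
            return Not(self.atom())
        return _normalize_leaf(val, pos)


def parse_query(s: str) -> Node:
    """Parse a keyword query string into a boolean AST."""
    if not s or not s.strip():
        raise QuerySyntaxError("empty query")
    return _Parser(s).parse()


def query_to_string(node: Node) -> str:
    """Render an AST back to query syntax; ``parse_query`` inverts this."""
    return str(node)


def positive_leaves(node: Node, negated: bool = False) -> list[Term | Phrase]:
    """Term/phrase leaves under an even number of NOTs (scoring clauses)."""
    if isinstance(node, (Term, Phrase)):
        return [] if negated else [node]
    if isinstance(node, Not):
        return positive_leaves(node.child, not negated)
    out: list[Term | Phrase] = []
    for c in node.children:
        out.extend(positive_leaves(c, negated))
    return out


def all_terms(node: Node) -> set[str]:
    if isinstance(node, Term):
        return {node.token}
    if isinstance(node, Phrase):
        return set(node.tokens)
    if isinstance(node, Not):
        return all_terms(node.child)
    out: set[str] = set()
    for c in node.children:
        out |= all_terms(c)
    return out


@dataclass(frozen=True)
class Filters:
    """Bibliographic and structural result filters.

    Author and journal are case-insensitive substring matches; accession is
    exact; year accepts a single value or an inclusive (lo, hi) range;
    section restricts hits to sentences within sections of that label.
    """

    author: str | None = None
    journal: str | None = None
    year: int | tuple[int, int] | None = None
    accession: str | None = None
    exclude: tuple[str, ...] = ()
    subcorpus: str | None = None
    section: str | None = None


@dataclass(frozen=True)
class Query:
    """A complete search request: keyword AST and/or category clauses."""

    keyword_expr: Node | None = None
    categories: tuple[tuple[str, bool], ...] = ()  # (category_id, include_children)
    scope: str = "sentence"
    filters: Filters = field(default_factory=Filters)
    sort: str = "score"

    def __post_init__(self):
        if self.keyword_expr is None and not self.categories:
            raise InvalidInputError("query needs keywords or at least one category")
        if self.scope not in ("sentence", "document"):
            raise InvalidInputError(f"unknown scope {self.scope!r}")
        if self.sort not in ("score", "year"):
            raise InvalidInputError(f"unknown sort {self.sort!r}")
        if isinstance(self.keyword_expr, Not) and not self.categories:
            raise InvalidInputError("NOT cannot be the sole top-level clause")
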