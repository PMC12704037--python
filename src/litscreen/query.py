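"""Boolean query compilation.

A resolved candidate's synonym bundle (gene name, gene synonyms, protein
names) forms one OR-group; every user keyword is AND-ed to it; an
optional date ceiling is AND-ed as a publication-date range.  A
publication therefore qualifies only if it matches at least one term of
the bundle AND all keywords.  The same logical structure is rendered in
two dialects:

* PubMed (E-utilities term syntax): quoted phrases with ``[Title]`` /
  ``[Title/Abstract]`` field tags and a ``[Date - Publication]`` range;
* PubTator (search query-string): quoted phrases with bare AND/OR, no
  field tags and no date clause (the service scopes and pages itself).

Both dialects are parsed back by this module's own grammar, which the
tests use to prove that emit→parse is the identity on every term.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass
from typing import Optional, Union

from .errors import QuerySyntaxError, VacuousQueryError
from .model import Query, ResolvedCandidate, Scope, SearchSpec, Term

# Earliest publication date used as the lower bound of a date-ceiling
# range clause (PubMed indexes nothing older).
DATE_FLOOR = "1800/01/01"

#: Terms this short cannot be meaningfully field-searched and are never
#: emitted; terms of exactly this length are emitted but flagged
#: ambiguous in the report (short symbols collide with common words).
MIN_TERM_LEN = 2


class Dialect(str, enum.Enum):
    PUBMED = "pubmed"
    PUBTATOR = "pubtator"


# ---------------------------------------------------------------------------
# AST


@dataclass(frozen=True)
class TermLeaf:
    text: str
    field: Optional[str] = None  # "Title" | "Title/Abstract" | None (pubtator)


@dataclass(frozen=True)
class DateLeaf:
    low: str
    high: str


@dataclass(frozen=True)
class OrNode:
    children: tuple["Node", ...]


@dataclass(frozen=True)
class AndNode:
    children: tuple["Node", ...]


Node = Union[TermLeaf, DateLeaf, OrNode, AndNode]


def leaf_terms(node: Node) -> list[str]:
    """All term-leaf texts under ``node``, in emission order."""
    if isinstance(node, TermLeaf):
        return [node.text]
    if isinstance(node, DateLeaf):
        return []
    return [t for child in node.children for t in leaf_terms(child)]


# ---------------------------------------------------------------------------
# Escaping

_BARE_TOKEN_RE = re.compile(r"^[0-9A-Za-z]+$")


def escape_term(term: str, dialect: Dialect) -> str:
    """Render one term in a dialect.

    Plain alphanumeric single tokens pass through unchanged; anything
    with whitespace or punctuation is phrase-quoted, with embedded
    double quotes doubled (CSV-style) so parsing recovers the original
    exactly.
    """
    if not term:
        raise ValueError("term must be non-empty")
    if dialect is Dialect.PUBMED and _BARE_TOKEN_RE.match(term):
        return term
    return '"' + term.replace('"', '""') + '"'


def _field_tag(scope: Scope) -> str:
    return "Title" if scope is Scope.TITLE_ONLY else "Title/Abstract"


# ---------------------------------------------------------------------------
# Building


def _partition_terms(cand: ResolvedCandidate) -> tuple[list[Term], list[Term]]:
    """Split the bundle into (emitted, ambiguous) per the length policy.

    Returns emitted terms (length >= MIN_TERM_LEN) and the subset of
    those flagged ambiguous (length == MIN_TERM_LEN)."""
    emitted = [t for t in cand.terms if len(t.text) >= MIN_TERM_LEN]
    ambiguous = [t for t in emitted if len(t.text) == MIN_TERM_LEN]
    return emitted, ambiguous


def _require_terms(cand: ResolvedCandidate) -> tuple[list[Term], list[Term]]:
    if not cand.is_valid:
        raise ValueError("cannot build a query for an invalid candidate")
    emitted, ambiguous = _partition_terms(cand)
    if not emitted:
        raise VacuousQueryError(
            f"candidate {cand.input.raw_id!r}: no searchable terms after normalization"
        )
    return emitted, ambiguous


def build_pubmed_query(cand: ResolvedCandidate, spec: SearchSpec) -> Query:
    """Compile the PubMed-dialect expression.

    Shape: ``(t1[f] OR t2[f] ...) AND (kw1[f]) AND ... AND (date range)``
    where ``[f]`` is ``[Title]`` under title-only scope and
    ``[Title/Abstract]`` otherwise — the scope applies to terms and
    keywords alike.
    """
    emitted, ambiguous = _require_terms(cand)
    tag = _field_tag(spec.scope)
    or_group = " OR ".join(
        f"{escape_term(t.text, Dialect.PUBMED)}[{tag}]" for t in emitted
    )
    parts = [f"({or_group})"]
    parts.extend(
        f"({escape_term(k, Dialect.PUBMED)}[{tag}])" for k in spec.keywords
    )
    if spec.max_date is not None:
        high = spec.max_date.strftime("%Y/%m/%d")
        parts.append(
            f'("{DATE_FLOOR}"[Date - Publication] : "{high}"[Date - Publication])'
        )
    return Query(
        candidate_ref=cand.input.raw_id,
        expression=" AND ".join(parts),
        terms=tuple(emitted),
        spec=spec,
        ambiguous_terms=tuple(t.text for t in ambiguous),
    )


def build_pubtator_query(cand: ResolvedCandidate, spec: SearchSpec) -> Query:
    """Compile the PubTator-dialect expression: same logical structure,
    no field tags, no date or cap clause (the service fixes its page
    size and performs its own semantic scoping)."""
    emitted, ambiguous = _require_terms(cand)
    or_group = " OR ".join(escape_term(t.text, Dialect.PUBTATOR) for t in emitted)
    parts = [f"({or_group})"]
    parts.extend(f"({escape_term(k, Dialect.PUBTATOR)})" for k in spec.keywords)
    return Query(
        candidate_ref=cand.input.raw_id,
        expression=" AND ".join(parts),
        terms=tuple(emitted),
        spec=spec,
        ambiguous_terms=tuple(t.text for t in ambiguous),
    )


def build_offline_query(cand: ResolvedCandidate, spec: SearchSpec) -> Query:
    """The offline engine executes the structured form; its expression
    is rendered in the PubMed dialect for display and round-tripping."""
    q = build_pubmed_query(cand, spec)
    return q


def build_query(cand: ResolvedCandidate, spec: SearchSpec) -> Query:
    """Dispatch on ``spec.backend``."""
    from .model import Backend

    if spec.backend is Backend.PUBTATOR:
        return build_pubtator_query(cand, spec)
    return build_pubmed_query(cand, spec)


# ---------------------------------------------------------------------------
# Parsing (the grammar the emitters target; used for round-trip checks)


class _Scanner:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos] == " ":
            self.pos += 1

    def peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def eat(self, token: str) -> bool:
        self.skip_ws()
        if self.text.startswith(token, self.pos):
            self.pos += len(token)
            return True
        return False

    def expect(self, token: str) -> None:
        if not self.eat(token):
            raise QuerySyntaxError(
                f"expected {token!r} at position {self.pos}: ...{self.text[self.pos:self.pos+30]!r}"
            )

    def quoted(self) -> str:
        """Read a double-quoted phrase; '""' decodes to one quote."""
        self.expect('"')
        out: list[str] = []
        while True:
            if self.pos >= len(self.text):
                raise QuerySyntaxError("unterminated quoted phrase")
            ch = self.text[self.pos]
            self.pos += 1
            if ch == '"':
                if self.pos < len(self.text) and self.text[self.pos] == '"':
                    out.append('"')
                    self.pos += 1
                else:
                    return "".join(out)
            else:
                out.append(ch)

    def bare_token(self) -> str:
        self.skip_ws()
        m = _BARE_TOKEN_RE.match(self.text[self.pos:].split(" ")[0].split("[")[0])
        if not m:
            raise QuerySyntaxError(f"expected a term at position {self.pos}")
        tok = m.group(0)
        self.pos += len(tok)
        return tok


def _parse_leaf(sc: _Scanner, with_fields: bool) -> TermLeaf:
    sc.skip_ws()
    text = sc.quoted() if sc.peek() == '"' else sc.bare_token()
    field = None
    if with_fields:
        sc.expect("[")
        end = sc.text.index("]", sc.pos)
        field = sc.text[sc.pos:end]
        sc.pos = end + 1
        if field not in ("Title", "Title/Abstract", "Date - Publication"):
            raise QuerySyntaxError(f"unknown field tag {field!r}")
    return TermLeaf(text, field)


def _parse_group(sc: _Scanner, with_fields: bool) -> Node:
    """A parenthesized OR-group, a date range, or a single leaf."""
    first = _parse_leaf(sc, with_fields)
    sc.skip_ws()
    if with_fields and sc.eat(":"):
        second = _parse_leaf(sc, with_fields)
        if first.field != "Date - Publication" or second.field != "Date - Publication":
            raise QuerySyntaxError("date range requires [Date - Publication] tags")
        return DateLeaf(first.text, second.text)
    children: list[Node] = [first]
    while sc.eat("OR"):
        children.append(_parse_leaf(sc, with_fields))
    return children[0] if len(children) == 1 else OrNode(tuple(children))


def _parse_expression(expr: str, with_fields: bool) -> Node:
    sc = _Scanner(expr)
    conj: list[Node] = []
    while True:
        sc.expect("(")
        conj.append(_parse_group(sc, with_fields))
        sc.expect(")")
        sc.skip_ws()
        if not sc.eat("AND"):
            break
    sc.skip_ws()
    if sc.pos != len(sc.text):
        raise QuerySyntaxError(f"trailing input at position {sc.pos}")
    return conj[0] if len(conj) == 1 else AndNode(tuple(conj))


def parse_query(expression: str, dialect: Dialect) -> Node:
    """Parse a dialect expression back into an AST.

    Raises :class:`QuerySyntaxError` on malformed input; emit→parse is
    the identity on term texts for both builders.
    """
    return _parse_expression(expression, with_fields=(dialect is Dialect.PUBMED))


def extracted_term_sets(node: Node) -> tuple[frozenset[str], frozenset[str]]:
    """(OR-group term set, AND-ed keyword set) of a parsed query.

    The first parenthesized group is the synonym OR-group; every further
    non-date conjunct contributes keywords.
    """
    if isinstance(node, (TermLeaf, OrNode)):
        return frozenset(leaf_terms(node)), frozenset()
    if isinstance(node, DateLeaf):
        return frozenset(), frozenset()
    first, *rest = node.children
    terms = frozenset(leaf_terms(first))
    keywords = frozenset(
        t for child in rest if not isinstance(child, DateLeaf) for t in leaf_terms(child)
    )
    return terms, keywords
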