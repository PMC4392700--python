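"""Manchester-like class-expression queries and the four competency queries.

Grammar (``some`` binds tighter than ``and``, which binds tighter than
``or``; ``some`` is right-associative)::

    expr     := or_expr
    or_expr  := and_expr ('or' and_expr)*
    and_expr := atom ('and' atom)*
    atom     := IDENT | IDENT 'some' atom | '(' expr ')'

Identifiers are optionally prefixed term names (``fma:``/``hco:``/``data:``).
Unprefixed names stay unresolved in the parsed expression and are resolved
against a TBox at evaluation time: ``hco`` is searched first, then ``fma``;
a name present in both namespaces is an error.

The shipped competency queries interrogate a medial-premotor (BA6) parcel set:
which parcels connect through the corticospinal tract or to precentral-gyrus
parcels (motor, SMA-like pattern); which connect to medial parietal or
orbitobasal frontal cortex (pre-SMA-like pattern); the motor pattern widened
to neighbors of the precentral gyrus; and which anatomical fiber bundles link
superior-frontal to temporal-lobe parcels.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .model import (
    And,
    ClassExpression,
    HcoParseError,
    Named,
    Or,
    Some,
    TBox,
    TermName,
    AmbiguousTermError,
    UnknownTermError,
)
from .reasoner import SaturatedKB, holds

_IDENT_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*(?::[A-Za-z_][A-Za-z0-9_]*)?")

_KEYWORDS = ("and", "or", "some")


@dataclass(frozen=True)
class _Token:
    kind: str  # 'lpar' | 'rpar' | 'ident' | 'and' | 'or' | 'some' | 'end'
    text: str
    pos: int


def _tokenize(source: str):
    tokens = []
    pos = 0
    while pos < len(source):
        ch = source[pos]
        if ch.isspace():
            pos += 1
            continue
        if ch == "(":
            tokens.append(_Token("lpar", "(", pos))
            pos += 1
            continue
        if ch == ")":
            tokens.append(_Token("rpar", ")", pos))
            pos += 1
            continue
        m = _IDENT_RE.match(source, pos)
        if m is None:
            raise HcoParseError(f"unexpected character {ch!r}", column=pos)
        text = m.group(0)
        kind = text if text in _KEYWORDS else "ident"
        tokens.append(_Token(kind, text, pos))
        pos = m.end()
    tokens.append(_Token("end", "", len(source)))
    return tokens


class _Parser:
    def __init__(self, source: str):
        self.source = source
        self.tokens = _tokenize(source)
        self.idx = 0

    @property
    def current(self) -> _Token:
        return self.tokens[self.idx]

    def advance(self) -> _Token:
        tok = self.tokens[self.idx]
        self.idx += 1
        return tok

    def fail(self, expected: str):
        tok = self.current
        what = "end of input" if tok.kind == "end" else repr(tok.text)
        raise HcoParseError(f"expected {expected}, found {what}",
                            column=tok.pos)

    def parse(self) -> ClassExpression:
        expr = self.or_expr()
        if self.current.kind != "end":
            self.fail("end of input")
        return expr

    def or_expr(self) -> ClassExpression:
        parts = [self.and_expr()]
        while self.current.kind == "or":
            self.advance()
            parts.append(self.and_expr())
        return parts[0] if len(parts) == 1 else Or(*parts)

    def and_expr(self) -> ClassExpression:
        parts = [self.atom()]
        while self.current.kind == "and":
            self.advance()
            parts.append(self.atom())
        return parts[0] if len(parts) == 1 else And(*parts)

    def atom(self) -> ClassExpression:
        tok = self.current
        if tok.kind == "lpar":
            self.advance()
            expr = self.or_expr()
            if self.current.kind != "rpar":
                self.fail("')'")
            self.advance()
            return expr
        if tok.kind == "ident":
            self.advance()
            name = TermName.parse(tok.text)
            if self.current.kind == "some":
                self.advance()
                filler = self.atom()  # right-associative
                return Some(name, filler)
            return Named(name)
        self.fail("a term name or '('")


def parse_query(text: str) -> ClassExpression:
    """Parse a Manchester-like class expression.

    ``parse_query(str(expr)) == expr`` for every parsed expression.  Unknown
    terms are only flagged at evaluation time.
    """
    return _Parser(text).parse()


def resolve_term(name: TermName, tbox: TBox) -> TermName:
    """Resolve an unprefixed name against a TBox (hco first, then fma)."""
    if name.is_resolved:
        return name
    candidates = [TermName(ns, name.name) for ns in ("hco", "fma")
                  if tbox.has_term(TermName(ns, name.name))]
    if not candidates:
        raise UnknownTermError(f"unknown term {name.name!r}")
    if len(candidates) > 1:
        raise AmbiguousTermError(
            f"{name.name!r} exists in namespaces "
            f"{[c.namespace for c in candidates]}; use a prefix")
    return candidates[0]


def resolve_expression(expr: ClassExpression, tbox: TBox) -> ClassExpression:
    """Resolve every term of an expression; errors name the offending term."""
    if isinstance(expr, Named):
        term = resolve_term(expr.term, tbox)
        if term not in tbox.classes:
            raise UnknownTermError(f"{term} is not a declared class")
        return Named(term)
    if isinstance(expr, Some):
        prop = resolve_term(expr.prop, tbox)
        if prop not in tbox.properties:
            raise UnknownTermError(f"{prop} is not a declared property")
        return Some(prop, resolve_expression(expr.filler, tbox))
    if isinstance(expr, And):
        return And(*[resolve_expression(c, tbox) for c in expr.children])
    if isinstance(expr, Or):
        return Or(*[resolve_expression(c, tbox) for c in expr.children])
    raise UnknownTermError(f"unknown expression node {expr!r}")


@dataclass(frozen=True)
class QueryResult:
    query: ClassExpression
    answers: tuple  # lexicographically sorted individual TermNames

    def answer_names(self) -> tuple:
        return tuple(str(a) for a in self.answers)


def answer_query(expr: ClassExpression, s: SaturatedKB) -> QueryResult:
    """Individuals of the saturated KB satisfying ``expr``, sorted.

    A pure function of ``(expr, s)``; adding assertions can only grow the
    answer set (the rule fragment is monotone).
    """
    resolved = resolve_expression(expr, s.kb.tbox)
    answers = tuple(sorted(
        (i for i in s.kb.abox.individuals if holds(i, resolved, s)),
        key=str))
    return QueryResult(query=resolved, answers=answers)


# ---------------------------------------------------------------------------
# Competency queries
# ---------------------------------------------------------------------------

COMPETENCY_QUERY_TEXT = {
    1: "(part_of some Right_superior_frontal_gyrus) and "
       "((is_tracto_connected some (part_of some Right_corticospinal_tract_of_brain)) "
       "or (mr_connection some (part_of some Right_precentral_gyrus)))",
    2: "(part_of some Right_superior_frontal_gyrus) and "
       "(mr_connection some ((part_of some Cortex_of_right_parietal_lobe) and "
       "(part_of some Medial_segment_of_cerebral_hemisphere)) "
       "or mr_connection some (part_of some Orbitobasal_segment_of_right_frontal_lobe))",
    3: "(part_of some Right_superior_frontal_gyrus) and "
       "((is_tracto_connected some (part_of some Right_corticospinal_tract_of_brain)) "
       "or (mr_connection some (part_of some Right_precentral_gyrus)) "
       "or (mr_connection some (continuous_with some (part_of some Right_precentral_gyrus))))",
    4: "part some ((tracto_connects some (part_of some Right_temporal_lobe)) "
       "and (tracto_connects some (part_of some Right_superior_frontal_gyrus)))",
}


def competency_query(n: int) -> ClassExpression:
    """Parsed competency query ``n`` (1-4).

    1. Superior-frontal parcels routed through the corticospinal tract or
       connected to precentral parcels (SMA-like pattern).
    2. Superior-frontal parcels connected to right medial parietal cortex
       (cortex-of-parietal-lobe AND medial-segment) or to orbitobasal
       frontal cortex (pre-SMA-like pattern).
    3. Query 1 widened by connections to neighbors of the precentral gyrus;
       its answers always contain query 1's.
    4. Fiber bundles with routes to both right-temporal and
       right-superior-frontal parcels.
    """
    if n not in COMPETENCY_QUERY_TEXT:
        raise ValueError(f"competency query index must be 1..4, got {n}")
    return parse_query(COMPETENCY_QUERY_TEXT[n])
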