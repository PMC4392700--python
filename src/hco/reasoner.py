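"""Rule-based materialization engine for the connectomics DL fragment.

Instead of a full tableau reasoner, entailments are materialized by a fixed
rule set covering exactly the fragment the schema uses: class subsumption,
defined classes built from conjunction/disjunction of existential
restrictions, a sub-property hierarchy, inverse and symmetric properties,
transitive properties, one role chain
(``is_tracto_connected o tracto_connects -> mr_connection``) and instance
realization.  The result is a least fixpoint: independent of rule application
order, sound with respect to OWL-DL semantics of the declared axioms, and not
claimed complete (no tableau branching; disjunction is handled definitionally
only).  Open-world: nothing is ever derived from the absence of a fact, and
the fragment has no negation, so every knowledge base is satisfiable.

TBox rules
    T1 reflexivity ``C <= C``; T2 equivalences unfold both ways; T3 subsumption
    transitivity; T4 definition introduction (``X`` entails the definition body
    of ``C`` => ``X <= C``); T5 existential property weakening along the
    sub-property hierarchy; T6 existential chaining over transitive
    properties; T7 existential filler weakening along subsumption.

ABox rules
    A1 type inheritance; A2 role sub-property; A3 inverses; A4 symmetry;
    A5 transitivity; A6 role chain with the two ends required *distinct*
    (a connection links two different nodes, never a node to itself);
    A7 realization against class definitions via :func:`holds`.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Optional

from .model import (
    And,
    ClassExpression,
    KnowledgeBase,
    Named,
    Or,
    Some,
    TermName,
    UnknownTermError,
)


@dataclass(frozen=True)
class TraceEntry:
    rule: str
    premises: tuple
    conclusion: tuple


@dataclass
class SaturatedKB:
    """Fixpoint of the materialization rules over a knowledge base."""

    kb: KnowledgeBase
    derived_subsumptions: set = field(default_factory=set)        # (C, D)
    derived_class_existentials: set = field(default_factory=set)  # (C, p, D)
    derived_types: set = field(default_factory=set)               # (i, C)
    derived_roles: set = field(default_factory=set)               # (p, i, j)
    trace: list = field(default_factory=list)

    # indexes (built by saturate)
    _roles_out: dict = field(default_factory=dict, repr=False)   # (p,i)->{j}
    _roles_in: dict = field(default_factory=dict, repr=False)    # (p,j)->{i}
    _types_of: dict = field(default_factory=dict, repr=False)    # i -> {C}
    _sub_up: dict = field(default_factory=dict, repr=False)      # C -> {D}
    _ex_out: dict = field(default_factory=dict, repr=False)      # (C,p)->{D}

    # -- read accessors -------------------------------------------------------
    def role_objects(self, prop: TermName, subj: TermName) -> frozenset:
        return frozenset(self._roles_out.get((prop, subj), ()))

    def types_of(self, ind: TermName) -> frozenset:
        return frozenset(self._types_of.get(ind, ()))

    def instances_of(self, cls: TermName) -> set:
        return {i for i, c in self.derived_types if c == cls}

    def has_role(self, prop: TermName, subj: TermName, obj: TermName) -> bool:
        return (prop, subj, obj) in self.derived_roles


def _super_property_closure(tbox) -> dict:
    """Reflexive-transitive closure of the declared super-property links."""
    closure = {}

    def visit(p):
        if p in closure:
            return closure[p]
        out = {p}
        closure[p] = out  # safe: hierarchy is acyclic (validated)
        for sp in tbox.properties[p].super_properties:
            out |= visit(sp)
        return out

    for p in tbox.properties:
        visit(p)
    return closure


def _tholds(x: TermName, expr: ClassExpression, sub: set, ex_out: dict) -> bool:
    """Class-level entailment check: does every instance of x fall in expr?"""
    if isinstance(expr, Named):
        return (x, expr.term) in sub
    if isinstance(expr, And):
        return all(_tholds(x, c, sub, ex_out) for c in expr.children)
    if isinstance(expr, Or):
        return any(_tholds(x, c, sub, ex_out) for c in expr.children)
    if isinstance(expr, Some):
        for d in ex_out.get((x, expr.prop), ()):
            if _tholds(d, expr.filler, sub, ex_out):
                return True
        return False
    raise UnknownTermError(f"unknown expression node {expr!r}")


def _decompose(c: TermName, expr: ClassExpression, sub: set, ex: set) -> None:
    """Seed consequences of ``c <= expr`` (conjunction elimination)."""
    if isinstance(expr, Named):
        sub.add((c, expr.term))
    elif isinstance(expr, And):
        for child in expr.children:
            _decompose(c, child, sub, ex)
    elif isinstance(expr, Some) and isinstance(expr.filler, Named):
        ex.add((c, expr.prop, expr.filler.term))
    # Or-rhs and complex fillers carry no definite named consequence


def _named_disjuncts(expr: ClassExpression) -> Optional[frozenset]:
    """The named classes of a named-or-disjunction-of-named expression."""
    if isinstance(expr, Named):
        return frozenset({expr.term})
    if isinstance(expr, Or):
        out = set()
        for c in expr.children:
            sub = _named_disjuncts(c)
            if sub is None:
                return None
            out |= sub
        return frozenset(out)
    return None


def holds(ind: TermName, expr: ClassExpression, s: SaturatedKB) -> bool:
    """Evaluate a class expression against a saturated knowledge base.

    ``Some(p, F)`` holds for ``ind`` either through an explicit role edge to
    an individual satisfying ``F``, or through a class-level existential
    ``A <= (p some D)`` on one of ``ind``'s types with ``D`` entailing ``F``
    (anonymous filler; only applicable when ``F`` reduces to named classes).
    """
    if isinstance(expr, Named):
        if expr.term not in s.kb.tbox.classes:
            raise UnknownTermError(f"unknown class {expr.term}")
        return expr.term in s._types_of.get(ind, ())
    if isinstance(expr, And):
        return all(holds(ind, c, s) for c in expr.children)
    if isinstance(expr, Or):
        return any(holds(ind, c, s) for c in expr.children)
    if isinstance(expr, Some):
        if expr.prop not in s.kb.tbox.properties:
            raise UnknownTermError(f"unknown property {expr.prop}")
        for j in s._roles_out.get((expr.prop, ind), ()):
            if holds(j, expr.filler, s):
                return True
        targets = _named_disjuncts(expr.filler)
        if targets is not None:
            for a in s._types_of.get(ind, ()):
                for d in s._ex_out.get((a, expr.prop), ()):
                    if any((d, f) in s.derived_subsumptions for f in targets):
                        return True
        return False
    raise UnknownTermError(f"unknown expression node {expr!r}")


def saturate(kb: KnowledgeBase, trace: bool = False) -> SaturatedKB:
    """Compute the least fixpoint of the rule set over ``kb``.

    The input is validated first; the closure contains its input.  Role facts
    are processed semi-naively with a worklist; TBox rules and realization
    iterate to a (small) fixpoint.
    """
    kb.validate()
    tbox, abox = kb.tbox, kb.abox
    s = SaturatedKB(kb=kb)
    superprops = _super_property_closure(tbox)

    def log(rule, premises, conclusion):
        if trace:
            s.trace.append(TraceEntry(rule, tuple(premises), conclusion))

    # ------------------------------------------------------------------ TBox
    sub = {(c, c) for c in tbox.classes}                       # T1
    ex: set = set()
    for c, rhs in tbox.subclass_axioms:
        _decompose(c, rhs, sub, ex)
    for c, rhs in tbox.equivalence_axioms:                     # T2 (c <= rhs)
        _decompose(c, rhs, sub, ex)

    ex_out: dict = {}

    def _reindex_ex():
        ex_out.clear()
        for c, p, d in ex:
            ex_out.setdefault((c, p), set()).add(d)

    changed = True
    while changed:
        changed = False
        # T3: subsumption transitivity (inner fixpoint)
        while True:
            new = {(c, e) for c, d in sub for d2, e in sub if d == d2} - sub
            if not new:
                break
            for f in new:
                log("T3", [], ("sub",) + f)
            sub |= new
        # T5: property weakening
        new_ex = {(c, q, d) for c, p, d in ex for q in superprops[p]} - ex
        # T7: filler weakening
        new_ex |= {(c, p, e) for c, p, d in ex
                   for d2, e in sub if d == d2} - ex
        # T6: chaining over transitive properties
        _reindex_ex()
        for c, p, d in ex:
            if tbox.properties[p].transitive:
                for e in ex_out.get((d, p), ()):
                    if (c, p, e) not in ex:
                        new_ex.add((c, p, e))
        if new_ex - ex:
            for f in new_ex - ex:
                log("T5/T6/T7", [], ("ex",) + f)
            ex |= new_ex
            changed = True
        _reindex_ex()
        # T4: definition introduction
        for c, rhs in tbox.equivalence_axioms:
            for x in tbox.classes:
                if (x, c) not in sub and _tholds(x, rhs, sub, ex_out):
                    sub.add((x, c))
                    log("T4", [("def", c)], ("sub", x, c))
                    changed = True

    s.derived_subsumptions = sub
    s.derived_class_existentials = ex
    s._ex_out = ex_out
    sub_up: dict = {}
    for c, d in sub:
        sub_up.setdefault(c, set()).add(d)
    s._sub_up = sub_up

    # ------------------------------------------------------------ ABox roles
    roles: set = set()
    roles_out, roles_in = s._roles_out, s._roles_in
    inverse_of = {p: d.effective_inverse() for p, d in tbox.properties.items()}
    chains_by_first: dict = {}
    chains_by_second: dict = {}
    for p, q, r in tbox.chain_axioms:
        chains_by_first.setdefault(p, []).append((q, r))
        chains_by_second.setdefault(q, []).append((p, r))

    work: deque = deque()

    def add_role(p, i, j, rule, premises):
        fact = (p, i, j)
        if fact in roles:
            return
        roles.add(fact)
        roles_out.setdefault((p, i), set()).add(j)
        roles_in.setdefault((p, j), set()).add(i)
        work.append(fact)
        if rule != "asserted":
            log(rule, premises, ("role",) + fact)

    for p, i, j in abox.role_assertions:
        add_role(p, i, j, "asserted", [])

    while work:
        p, i, j = fact = work.popleft()
        decl = tbox.properties[p]
        for q in superprops[p]:
            if q != p:
                add_role(q, i, j, "A2", [fact])
        inv = inverse_of[p]
        if inv is not None:
            add_role(inv, j, i, "A4" if decl.symmetric else "A3", [fact])
        if decl.transitive:
            for k in roles_out.get((p, j), set()).copy():
                add_role(p, i, k, "A5", [fact, (p, j, k)])
            for h in roles_in.get((p, i), set()).copy():
                add_role(p, h, j, "A5", [(p, h, i), fact])
        for q, r in chains_by_first.get(p, ()):
            for k in roles_out.get((q, j), set()).copy():
                if i != k:
                    add_role(r, i, k, "A6", [fact, (q, j, k)])
        for pp, r in chains_by_second.get(p, ()):
            for h in roles_in.get((pp, i), set()).copy():
                if h != j:
                    add_role(r, h, j, "A6", [(pp, h, i), fact])

    s.derived_roles = roles

    # ------------------------------------------------------------ ABox types
    types: set = set()
    types_of = s._types_of

    def add_type(i, c, rule, premises):
        if (i, c) in types:
            return
        types.add((i, c))
        types_of.setdefault(i, set()).add(c)
        if rule != "asserted":
            log(rule, premises, ("type", i, c))
        for d in sub_up.get(c, ()):                            # A1
            if d != c and (i, d) not in types:
                add_type(i, d, "A1", [(i, c), ("sub", c, d)])

    for i, c in abox.type_assertions:
        add_type(i, c, "asserted", [])
    s.derived_types = types

    # A7: realization loop (role closure is already final; types only grow)
    defs = sorted(tbox.equivalence_axioms, key=lambda a: str(a[0]))
    changed = True
    while changed:
        changed = False
        for ind in sorted(abox.individuals):
            for c, rhs in defs:
                if (ind, c) not in types and holds(ind, rhs, s):
                    add_type(ind, c, "A7", [("def", c)])
                    changed = True

    return s


def saturate_is_idempotent(s: SaturatedKB) -> bool:
    """Re-saturating the materialized facts adds nothing (fixpoint check)."""
    kb2 = s.kb.copy()
    kb2.abox.role_assertions = set(s.derived_roles)
    kb2.abox.type_assertions = set(s.derived_types)
    s2 = saturate(kb2)
    return (s2.derived_roles == s.derived_roles
            and s2.derived_types == s.derived_types
            and s2.derived_subsumptions == s.derived_subsumptions
            and s2.derived_class_existentials == s.derived_class_existentials)
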