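"""Core ontology data model.

The toolkit manipulates a small description-logic fragment sufficient for
connectome annotation: named classes, conjunction, disjunction and existential
restrictions on the axiom side; object properties with inverses, symmetry,
transitivity, a sub-property hierarchy and a single role chain; and an ABox of
individuals with type and role assertions.  Terms live in three namespaces:

* ``fma``  -- neuroanatomical classes and part-properties (gross anatomy),
* ``hco``  -- connectomics classes/properties and subject-scoped individuals,
* ``data`` -- free namespace for user data.

:func:`build_hco_schema` constructs the connectomics schema itself: four
classes (``Gray_matter_part``, ``White_matter_part``, ``MR_Node``,
``MR_Route``), eleven object properties, and the role chain
``is_tracto_connected o tracto_connects -> mr_connection``.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional

NAMESPACES = ("fma", "hco", "data")

#: pseudo-namespace used by the query parser for not-yet-resolved names.
#: Terms with this namespace are rejected by TBox/ABox validation.
UNRESOLVED = ""


class HcoError(Exception):
    """Base class for all toolkit errors."""


class IntegrityError(HcoError):
    """Referential-integrity violation in a TBox/ABox/FrameGraph."""


class ConflictError(HcoError):
    """Two declarations of the same term disagree."""


class HcoParseError(HcoError):
    """Malformed serialized input (carries position information)."""

    def __init__(self, message: str, line: Optional[int] = None,
                 column: Optional[int] = None):
        self.line = line
        self.column = column
        loc = ""
        if line is not None:
            loc = f" (line {line}" + (f", column {column}" if column is not None else "") + ")"
        super().__init__(message + loc)


class UnknownTermError(HcoError):
    """A term is not declared in the knowledge base at hand."""


class AmbiguousTermError(HcoError):
    """An unprefixed query name resolves in more than one namespace."""


class FixtureError(HcoError):
    """A shipped data fixture is missing or corrupted."""


# ---------------------------------------------------------------------------
# Terms
# ---------------------------------------------------------------------------

@dataclass(frozen=True, order=True)
class TermName:
    """A namespaced term, serialized as ``namespace:name``."""

    namespace: str
    name: str

    def __post_init__(self) -> None:
        if self.namespace not in NAMESPACES and self.namespace != UNRESOLVED:
            raise ValueError(f"unknown namespace {self.namespace!r}")
        if not self.name:
            raise ValueError("term name must be non-empty")
        if any(ch.isspace() for ch in self.name):
            raise ValueError(f"term name contains whitespace: {self.name!r}")

    def __str__(self) -> str:
        if self.namespace == UNRESOLVED:
            return self.name
        return f"{self.namespace}:{self.name}"

    @staticmethod
    def parse(text: str) -> "TermName":
        """Parse ``namespace:name``; a bare name becomes an unresolved term."""
        text = text.strip()
        if ":" in text:
            ns, name = text.split(":", 1)
            return TermName(ns, name)
        return TermName(UNRESOLVED, text)

    @property
    def is_resolved(self) -> bool:
        return self.namespace != UNRESOLVED


def fma(name: str) -> TermName:
    return TermName("fma", name)


def hco(name: str) -> TermName:
    return TermName("hco", name)


def data(name: str) -> TermName:
    return TermName("data", name)


# ---------------------------------------------------------------------------
# Class expressions
# ---------------------------------------------------------------------------

class ClassExpression:
    """Tree of named classes, conjunctions, disjunctions and existentials.

    And/Or children are canonically sorted by their serialization, so
    structural equality is order-insensitive.
    """

    def terms(self) -> Iterator[TermName]:
        raise NotImplementedError

    def __str__(self) -> str:  # pragma: no cover - overridden
        raise NotImplementedError


def _wrap(expr: "ClassExpression") -> str:
    if isinstance(expr, Named):
        return str(expr)
    return f"({expr})"


@dataclass(frozen=True)
class Named(ClassExpression):
    term: TermName

    def terms(self) -> Iterator[TermName]:
        yield self.term

    def __str__(self) -> str:
        return str(self.term)


@dataclass(frozen=True)
class Some(ClassExpression):
    """Existential restriction: things with a ``prop`` edge into ``filler``."""

    prop: TermName
    filler: ClassExpression

    def terms(self) -> Iterator[TermName]:
        yield self.prop
        yield from self.filler.terms()

    def __str__(self) -> str:
        return f"{self.prop} some {_wrap(self.filler)}"


def _canonical_children(children: Iterable[ClassExpression],
                        kind: str) -> tuple:
    kids = tuple(sorted(children, key=str))
    if len(kids) < 2:
        raise ValueError(f"{kind} requires at least two children")
    return kids


@dataclass(frozen=True)
class And(ClassExpression):
    children: tuple = ()

    def __init__(self, *children: ClassExpression):
        if len(children) == 1 and isinstance(children[0], (tuple, list)):
            children = tuple(children[0])
        object.__setattr__(self, "children",
                           _canonical_children(children, "And"))

    def terms(self) -> Iterator[TermName]:
        for c in self.children:
            yield from c.terms()

    def __str__(self) -> str:
        return " and ".join(_wrap(c) for c in self.children)


@dataclass(frozen=True)
class Or(ClassExpression):
    children: tuple = ()

    def __init__(self, *children: ClassExpression):
        if len(children) == 1 and isinstance(children[0], (tuple, list)):
            children = tuple(children[0])
        object.__setattr__(self, "children",
                           _canonical_children(children, "Or"))

    def terms(self) -> Iterator[TermName]:
        for c in self.children:
            yield from c.terms()

    def __str__(self) -> str:
        return " or ".join(_wrap(c) for c in self.children)


# ---------------------------------------------------------------------------
# Property declarations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PropertyDecl:
    """Declaration of an object property and its characteristics."""

    name: TermName
    inverse: Optional[TermName] = None
    transitive: bool = False
    symmetric: bool = False
    super_properties: frozenset = frozenset()
    domain: Optional[TermName] = None
    range: Optional[TermName] = None

    def __post_init__(self) -> None:
        if self.symmetric:
            if self.inverse not in (None, self.name):
                raise ValueError(
                    f"symmetric property {self.name} must be its own inverse")
            object.__setattr__(self, "inverse", self.name)

    def effective_inverse(self) -> Optional[TermName]:
        """A symmetric property acts as its own inverse."""
        if self.symmetric:
            return self.name
        return self.inverse


def merge_property_decls(a: PropertyDecl, b: PropertyDecl) -> PropertyDecl:
    """Union-merge two compatible declarations of the same property.

    Boolean characteristics are OR-ed and super-properties unioned; inverse,
    domain and range must agree whenever both sides state them.
    """
    if a.name != b.name:
        raise ValueError("cannot merge declarations of different properties")

    def _pick(x, y, what):
        if x is not None and y is not None and x != y:
            raise ConflictError(
                f"property {a.name} redeclared with different {what}: {x} vs {y}")
        return x if x is not None else y

    return PropertyDecl(
        name=a.name,
        inverse=_pick(a.inverse, b.inverse, "inverse"),
        transitive=a.transitive or b.transitive,
        symmetric=a.symmetric or b.symmetric,
        super_properties=a.super_properties | b.super_properties,
        domain=_pick(a.domain, b.domain, "domain"),
        range=_pick(a.range, b.range, "range"),
    )


# ---------------------------------------------------------------------------
# TBox / ABox / KnowledgeBase
# ---------------------------------------------------------------------------

@dataclass
class TBox:
    classes: set = field(default_factory=set)
    properties: dict = field(default_factory=dict)  # TermName -> PropertyDecl
    subclass_axioms: set = field(default_factory=set)
    equivalence_axioms: set = field(default_factory=set)
    chain_axioms: set = field(default_factory=set)  # (p, q, r): p o q <= r

    # -- construction helpers -------------------------------------------------
    def add_class(self, term: TermName) -> TermName:
        self.classes.add(term)
        return term

    def add_property(self, decl: PropertyDecl) -> PropertyDecl:
        if decl.name in self.properties and self.properties[decl.name] != decl:
            raise ConflictError(f"property {decl.name} already declared "
                                "with different characteristics")
        self.properties[decl.name] = decl
        return decl

    def add_subclass(self, sub: TermName, sup: ClassExpression) -> None:
        self.subclass_axioms.add((sub, sup))

    def add_equivalence(self, cls: TermName, expr: ClassExpression) -> None:
        self.equivalence_axioms.add((cls, expr))

    def add_chain(self, p: TermName, q: TermName, r: TermName) -> None:
        self.chain_axioms.add((p, q, r))

    # -- queries --------------------------------------------------------------
    def has_term(self, term: TermName) -> bool:
        return term in self.classes or term in self.properties

    def copy(self) -> "TBox":
        return copy.deepcopy(self)

    # -- validation -----------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`IntegrityError` on dangling references or cycles."""
        for name, decl in self.properties.items():
            if name != decl.name:
                raise IntegrityError(f"property {name} keyed under wrong name")
            if not name.is_resolved:
                raise IntegrityError(f"unresolved property name {name}")
            inv = decl.inverse
            if inv is not None and inv != name:
                if inv not in self.properties:
                    raise IntegrityError(
                        f"inverse {inv} of {name} is not declared")
                other = self.properties[inv].inverse
                if other != name:
                    raise IntegrityError(
                        f"inverse pairing of {name} and {inv} is not mutual")
            for sp in decl.super_properties:
                if sp not in self.properties:
                    raise IntegrityError(
                        f"super-property {sp} of {name} is not declared")
            for anchor in (decl.domain, decl.range):
                if anchor is not None and anchor not in self.classes:
                    raise IntegrityError(
                        f"domain/range {anchor} of {name} is not a class")
        self._check_super_property_acyclic()
        for cls in self.classes:
            if not cls.is_resolved:
                raise IntegrityError(f"unresolved class name {cls}")
        for sub, sup in self.subclass_axioms:
            self._check_axiom_terms(sub, sup)
        for cls, expr in self.equivalence_axioms:
            self._check_axiom_terms(cls, expr)
        for p, q, r in self.chain_axioms:
            for prop in (p, q, r):
                if prop not in self.properties:
                    raise IntegrityError(f"chain axiom references undeclared "
                                         f"property {prop}")

    def _check_axiom_terms(self, lhs: TermName, rhs: ClassExpression) -> None:
        if lhs not in self.classes:
            raise IntegrityError(f"axiom left-hand side {lhs} is not a class")
        self._check_expression(rhs)

    def _check_expression(self, expr: ClassExpression) -> None:
        if isinstance(expr, Named):
            if expr.term not in self.classes:
                raise IntegrityError(f"expression references undeclared class "
                                     f"{expr.term}")
        elif isinstance(expr, Some):
            if expr.prop not in self.properties:
                raise IntegrityError(f"expression references undeclared "
                                     f"property {expr.prop}")
            self._check_expression(expr.filler)
        elif isinstance(expr, (And, Or)):
            for c in expr.children:
                self._check_expression(c)
        else:  # pragma: no cover
            raise IntegrityError(f"unknown expression node {expr!r}")

    def _check_super_property_acyclic(self) -> None:
        state: dict = {}

        def visit(p: TermName) -> None:
            state[p] = "active"
            for sp in self.properties[p].super_properties:
                if state.get(sp) == "active":
                    raise IntegrityError(
                        f"super-property cycle through {sp}")
                if sp not in state:
                    visit(sp)
            state[p] = "done"

        for p in self.properties:
            if p not in state:
                visit(p)


@dataclass
class ABox:
    individuals: set = field(default_factory=set)
    type_assertions: set = field(default_factory=set)   # (individual, class)
    role_assertions: set = field(default_factory=set)   # (property, subj, obj)

    def add_individual(self, ind: TermName) -> TermName:
        self.individuals.add(ind)
        return ind

    def add_type(self, ind: TermName, cls: TermName) -> None:
        self.individuals.add(ind)
        self.type_assertions.add((ind, cls))

    def add_role(self, prop: TermName, subj: TermName, obj: TermName) -> None:
        self.individuals.add(subj)
        self.individuals.add(obj)
        self.role_assertions.add((prop, subj, obj))

    def copy(self) -> "ABox":
        return copy.deepcopy(self)

    def validate(self, tbox: TBox) -> None:
        for ind in self.individuals:
            if not ind.is_resolved:
                raise IntegrityError(f"unresolved individual name {ind}")
        for ind, cls in self.type_assertions:
            if ind not in self.individuals:
                raise IntegrityError(f"type assertion on undeclared "
                                     f"individual {ind}")
            if cls not in tbox.classes:
                raise IntegrityError(f"type assertion uses undeclared class "
                                     f"{cls}")
        for prop, subj, obj in self.role_assertions:
            if prop not in tbox.properties:
                raise IntegrityError(f"role assertion uses undeclared "
                                     f"property {prop}")
            for ind in (subj, obj):
                if ind not in self.individuals:
                    raise IntegrityError(f"role assertion on undeclared "
                                         f"individual {ind}")


@dataclass
class KnowledgeBase:
    tbox: TBox = field(default_factory=TBox)
    abox: ABox = field(default_factory=ABox)

    def validate(self) -> None:
        self.tbox.validate()
        self.abox.validate(self.tbox)

    def copy(self) -> "KnowledgeBase":
        return KnowledgeBase(self.tbox.copy(), self.abox.copy())


# ---------------------------------------------------------------------------
# The HCO schema
# ---------------------------------------------------------------------------

# classes
GRAY_MATTER_PART = hco("Gray_matter_part")
WHITE_MATTER_PART = hco("White_matter_part")
MR_NODE = hco("MR_Node")
MR_ROUTE = hco("MR_Route")

# anchor classes from the anatomy ontology
REGION_OF_CELL_PART_CLUSTER = fma("Region_of_cell_part_cluster_of_neuraxis")
GRAY_MATTER_OF_NEURAXIS = fma("Gray_matter_of_neuraxis")
WHITE_MATTER_OF_NEURAXIS = fma("White_matter_of_neuraxis")
ANATOMICAL_STRUCTURE = fma("Anatomical_structure")

# object properties
IS_TRACTO_CONNECTED = hco("is_tracto_connected")
TRACTO_CONNECTS = hco("tracto_connects")
MR_CONNECTION = hco("mr_connection")
CONTINUOUS_WITH = hco("continuous_with")
PART_OF = hco("part_of")
PART = hco("part")
REGIONAL_PART = fma("regional_part")
REGIONAL_PART_OF = fma("regional_part_of")
CONSTITUTIONAL_PART = fma("constitutional_part")
CONSTITUTIONAL_PART_OF = fma("constitutional_part_of")
ATTRIBUTED_CONTINUOUS_WITH = fma("attributed_continuous_with")


def fma_part_property_decls(with_hco_supers: bool = True) -> list:
    """Declarations for the anatomy part-properties kept in the view.

    With ``with_hco_supers`` the part properties are declared sub-properties of
    the transitive ``hco:part_of`` / ``hco:part`` umbrella properties (as in
    the full schema); without, they are standalone (as in a freshly translated
    view before merging with the HCO schema).
    """
    sup_of = frozenset({PART_OF}) if with_hco_supers else frozenset()
    sup = frozenset({PART}) if with_hco_supers else frozenset()
    return [
        PropertyDecl(REGIONAL_PART, inverse=REGIONAL_PART_OF,
                     super_properties=sup),
        PropertyDecl(REGIONAL_PART_OF, inverse=REGIONAL_PART,
                     super_properties=sup_of),
        PropertyDecl(CONSTITUTIONAL_PART, inverse=CONSTITUTIONAL_PART_OF,
                     super_properties=sup),
        PropertyDecl(CONSTITUTIONAL_PART_OF, inverse=CONSTITUTIONAL_PART,
                     super_properties=sup_of),
        PropertyDecl(ATTRIBUTED_CONTINUOUS_WITH),
    ]


def build_hco_schema() -> TBox:
    """Construct the connectomics schema (four classes, eleven properties).

    Deterministic: calling twice yields structurally identical TBoxes.
    """
    t = TBox()
    for cls in (GRAY_MATTER_PART, WHITE_MATTER_PART, MR_NODE, MR_ROUTE,
                REGION_OF_CELL_PART_CLUSTER, GRAY_MATTER_OF_NEURAXIS,
                WHITE_MATTER_OF_NEURAXIS, ANATOMICAL_STRUCTURE):
        t.add_class(cls)

    t.add_property(PropertyDecl(
        IS_TRACTO_CONNECTED, inverse=TRACTO_CONNECTS,
        domain=MR_NODE, range=MR_ROUTE))
    t.add_property(PropertyDecl(
        TRACTO_CONNECTS, inverse=IS_TRACTO_CONNECTED,
        domain=MR_ROUTE, range=MR_NODE))
    t.add_property(PropertyDecl(
        MR_CONNECTION, symmetric=True, domain=MR_NODE, range=MR_NODE))
    t.add_property(PropertyDecl(
        CONTINUOUS_WITH, symmetric=True,
        domain=ANATOMICAL_STRUCTURE, range=ANATOMICAL_STRUCTURE))
    t.add_property(PropertyDecl(
        PART_OF, transitive=True,
        domain=ANATOMICAL_STRUCTURE, range=ANATOMICAL_STRUCTURE))
    t.add_property(PropertyDecl(
        PART, transitive=True,
        domain=ANATOMICAL_STRUCTURE, range=ANATOMICAL_STRUCTURE))
    for decl in fma_part_property_decls(with_hco_supers=True):
        t.add_property(decl)

    part_of_anything = Or(
        Some(CONSTITUTIONAL_PART_OF, Named(ANATOMICAL_STRUCTURE)),
        Some(REGIONAL_PART_OF, Named(ANATOMICAL_STRUCTURE)),
    )
    t.add_subclass(GRAY_MATTER_PART, Named(REGION_OF_CELL_PART_CLUSTER))
    t.add_equivalence(GRAY_MATTER_PART,
                      And(Named(GRAY_MATTER_OF_NEURAXIS), part_of_anything))
    t.add_subclass(WHITE_MATTER_PART, Named(REGION_OF_CELL_PART_CLUSTER))
    t.add_equivalence(WHITE_MATTER_PART,
                      And(Named(WHITE_MATTER_OF_NEURAXIS), part_of_anything))
    t.add_subclass(MR_NODE, Named(GRAY_MATTER_PART))
    t.add_equivalence(MR_NODE, And(Named(GRAY_MATTER_PART),
                                   Some(IS_TRACTO_CONNECTED, Named(MR_ROUTE))))
    t.add_subclass(MR_ROUTE, Named(WHITE_MATTER_PART))
    t.add_equivalence(MR_ROUTE, And(Named(WHITE_MATTER_PART),
                                    Some(TRACTO_CONNECTS, Named(MR_NODE))))

    # a reconstructed pathway linking two *different* nodes
    t.add_chain(IS_TRACTO_CONNECTED, TRACTO_CONNECTS, MR_CONNECTION)

    t.validate()
    return t


def merge_tbox(base: TBox, extension: TBox) -> TBox:
    """Union of two TBoxes; idempotent and commutative.

    Compatible redeclarations of the same property are union-merged; an
    incompatible redeclaration raises :class:`ConflictError` naming the term.
    """
    out = TBox()
    out.classes = set(base.classes) | set(extension.classes)
    out.properties = dict(base.properties)
    for name, decl in extension.properties.items():
        if name in out.properties:
            out.properties[name] = merge_property_decls(out.properties[name],
                                                        decl)
        else:
            out.properties[name] = decl
    out.subclass_axioms = set(base.subclass_axioms) | set(extension.subclass_axioms)
    out.equivalence_axioms = (set(base.equivalence_axioms)
                              | set(extension.equivalence_axioms))
    out.chain_axioms = set(base.chain_axioms) | set(extension.chain_axioms)
    out.validate()
    return out
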