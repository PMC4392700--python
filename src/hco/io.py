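"""Deterministic readers and writers.

Three interchangeable encodings are supported for knowledge bases and frame
graphs:

* canonical JSON — the reference test format, a flat schema mirroring the
  data model exactly;
* N-Triples — one sorted statement per line;
* a Turtle subset — prefixed statements with inline blank nodes for the
  OWL restriction/intersection/union patterns used by the schema.

Writers are bespoke and emit statements in lexicographic order, so output is
bit-stable across runs and platforms.  RDF *parsing* is delegated to rdflib;
``read(write(x))`` is the identity on the data model for every format.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Union

import rdflib
from rdflib.namespace import OWL, RDF, RDFS

from .frames import SUBCLASS_OF, FrameGraph
from .model import (
    ABox,
    And,
    ClassExpression,
    HcoParseError,
    KnowledgeBase,
    Named,
    Or,
    PropertyDecl,
    Some,
    TBox,
    TermName,
)

IRI_PREFIXES = {
    "fma": "http://purl.org/sig/ont/fma/",
    "hco": "http://example.org/hco#",
    "data": "http://example.org/data#",
}

_METACLASS_MARKER = rdflib.URIRef(IRI_PREFIXES["hco"] + "__Metaclass")
_FRAME_ENTITY_MARKER = OWL.Class


def iri_for(term: TermName) -> str:
    return IRI_PREFIXES[term.namespace] + term.name


def term_for(iri: str) -> TermName:
    for ns, prefix in IRI_PREFIXES.items():
        if iri.startswith(prefix):
            return TermName(ns, iri[len(prefix):])
    raise HcoParseError(f"IRI outside the known namespaces: {iri}")


def _qname(term: TermName) -> str:
    return f"{term.namespace}:{term.name}"


# ---------------------------------------------------------------------------
# Canonical JSON
# ---------------------------------------------------------------------------

def _expr_to_json(expr: ClassExpression):
    if isinstance(expr, Named):
        return {"named": str(expr.term)}
    if isinstance(expr, Some):
        return {"some": [str(expr.prop), _expr_to_json(expr.filler)]}
    if isinstance(expr, And):
        return {"and": [_expr_to_json(c) for c in expr.children]}
    if isinstance(expr, Or):
        return {"or": [_expr_to_json(c) for c in expr.children]}
    raise ValueError(f"unknown expression node {expr!r}")


def _expr_from_json(obj) -> ClassExpression:
    if not isinstance(obj, dict) or len(obj) != 1:
        raise HcoParseError(f"malformed expression object {obj!r}")
    kind, payload = next(iter(obj.items()))
    if kind == "named":
        return Named(TermName.parse(payload))
    if kind == "some":
        prop, filler = payload
        return Some(TermName.parse(prop), _expr_from_json(filler))
    if kind == "and":
        return And(*[_expr_from_json(c) for c in payload])
    if kind == "or":
        return Or(*[_expr_from_json(c) for c in payload])
    raise HcoParseError(f"unknown expression kind {kind!r}")


def _decl_to_json(decl: PropertyDecl) -> dict:
    return {
        "name": str(decl.name),
        "inverse": None if decl.inverse is None else str(decl.inverse),
        "transitive": decl.transitive,
        "symmetric": decl.symmetric,
        "super_properties": sorted(str(p) for p in decl.super_properties),
        "domain": None if decl.domain is None else str(decl.domain),
        "range": None if decl.range is None else str(decl.range),
    }


def _decl_from_json(obj: dict) -> PropertyDecl:
    def opt(v):
        return None if v is None else TermName.parse(v)

    return PropertyDecl(
        name=TermName.parse(obj["name"]),
        inverse=opt(obj.get("inverse")),
        transitive=bool(obj.get("transitive", False)),
        symmetric=bool(obj.get("symmetric", False)),
        super_properties=frozenset(TermName.parse(p)
                                   for p in obj.get("super_properties", ())),
        domain=opt(obj.get("domain")),
        range=opt(obj.get("range")),
    )


def kb_to_json(kb: KnowledgeBase) -> str:
    def axioms(pairs):
        return sorted(([str(lhs), _expr_to_json(rhs)] for lhs, rhs in pairs),
                      key=json.dumps)

    doc = {
        "format": "hco-kb",
        "version": 1,
        "tbox": {
            "classes": sorted(str(c) for c in kb.tbox.classes),
            "properties": sorted(
                (_decl_to_json(d) for d in kb.tbox.properties.values()),
                key=lambda d: d["name"]),
            "subclass_axioms": axioms(kb.tbox.subclass_axioms),
            "equivalence_axioms": axioms(kb.tbox.equivalence_axioms),
            "chain_axioms": sorted([str(p), str(q), str(r)]
                                   for p, q, r in kb.tbox.chain_axioms),
        },
        "abox": {
            "individuals": sorted(str(i) for i in kb.abox.individuals),
            "type_assertions": sorted([str(i), str(c)]
                                      for i, c in kb.abox.type_assertions),
            "role_assertions": sorted(
                [str(p), str(s), str(o)]
                for p, s, o in kb.abox.role_assertions),
        },
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def kb_from_json(text: str) -> KnowledgeBase:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as err:
        raise HcoParseError(f"malformed JSON: {err.msg}", line=err.lineno,
                            column=err.colno) from err
    if doc.get("format") != "hco-kb":
        raise HcoParseError("not an hco-kb JSON document")
    t = doc["tbox"]
    tbox = TBox()
    for c in t.get("classes", ()):
        tbox.add_class(TermName.parse(c))
    for d in t.get("properties", ()):
        tbox.add_property(_decl_from_json(d))
    for lhs, rhs in t.get("subclass_axioms", ()):
        tbox.add_subclass(TermName.parse(lhs), _expr_from_json(rhs))
    for lhs, rhs in t.get("equivalence_axioms", ()):
        tbox.add_equivalence(TermName.parse(lhs), _expr_from_json(rhs))
    for p, q, r in t.get("chain_axioms", ()):
        tbox.add_chain(TermName.parse(p), TermName.parse(q),
                       TermName.parse(r))
    a = doc.get("abox", {})
    abox = ABox()
    for i in a.get("individuals", ()):
        abox.add_individual(TermName.parse(i))
    for i, c in a.get("type_assertions", ()):
        abox.add_type(TermName.parse(i), TermName.parse(c))
    for p, s, o in a.get("role_assertions", ()):
        abox.add_role(TermName.parse(p), TermName.parse(s),
                      TermName.parse(o))
    kb = KnowledgeBase(tbox=tbox, abox=abox)
    kb.validate()
    return kb


# ---------------------------------------------------------------------------
# RDF triples (shared by the N-Triples and Turtle writers)
# ---------------------------------------------------------------------------

class _BNodes:
    def __init__(self):
        self.n = 0

    def fresh(self) -> str:
        self.n += 1
        return f"_:b{self.n}"


_RDF_FIRST = str(RDF.first)
_RDF_REST = str(RDF.rest)
_RDF_NIL = str(RDF.nil)


def _expr_node(expr: ClassExpression, out: list, bn: _BNodes) -> str:
    """Emit triples encoding ``expr``; return its node reference."""
    if isinstance(expr, Named):
        return f"<{iri_for(expr.term)}>"
    node = bn.fresh()
    if isinstance(expr, Some):
        out.append((node, str(RDF.type), str(OWL.Restriction)))
        out.append((node, str(OWL.onProperty), f"<{iri_for(expr.prop)}>"))
        out.append((node, str(OWL.someValuesFrom),
                    _expr_node(expr.filler, out, bn)))
        return node
    if isinstance(expr, (And, Or)):
        pred = OWL.intersectionOf if isinstance(expr, And) else OWL.unionOf
        out.append((node, str(RDF.type), str(OWL.Class)))
        items = [_expr_node(c, out, bn) for c in expr.children]
        head = _rdf_list(items, out, bn)
        out.append((node, str(pred), head))
        return node
    raise ValueError(f"unknown expression node {expr!r}")


def _rdf_list(items: list, out: list, bn: _BNodes) -> str:
    head = f"<{_RDF_NIL}>"
    for item in reversed(items):
        node = bn.fresh()
        out.append((node, _RDF_FIRST, item))
        out.append((node, _RDF_REST, head))
        head = node
    return head


def _kb_triples(kb: KnowledgeBase) -> list:
    """(subject, predicate, object) references; bnodes already labeled."""
    out: list = []
    bn = _BNodes()

    def ref(term: TermName) -> str:
        return f"<{iri_for(term)}>"

    for c in sorted(kb.tbox.classes):
        out.append((ref(c), str(RDF.type), str(OWL.Class)))
    for name in sorted(kb.tbox.properties):
        decl = kb.tbox.properties[name]
        out.append((ref(name), str(RDF.type), str(OWL.ObjectProperty)))
        if decl.transitive:
            out.append((ref(name), str(RDF.type),
                        str(OWL.TransitiveProperty)))
        if decl.symmetric:
            out.append((ref(name), str(RDF.type), str(OWL.SymmetricProperty)))
        if decl.inverse is not None and decl.inverse != name:
            out.append((ref(name), str(OWL.inverseOf), ref(decl.inverse)))
        for sp in sorted(decl.super_properties):
            out.append((ref(name), str(RDFS.subPropertyOf), ref(sp)))
        if decl.domain is not None:
            out.append((ref(name), str(RDFS.domain), ref(decl.domain)))
        if decl.range is not None:
            out.append((ref(name), str(RDFS.range), ref(decl.range)))
    for lhs, rhs in sorted(kb.tbox.subclass_axioms, key=str):
        out.append((ref(lhs), str(RDFS.subClassOf),
                    _expr_node(rhs, out, bn)))
    for lhs, rhs in sorted(kb.tbox.equivalence_axioms, key=str):
        out.append((ref(lhs), str(OWL.equivalentClass),
                    _expr_node(rhs, out, bn)))
    for p, q, r in sorted(kb.tbox.chain_axioms):
        head = _rdf_list([ref(p), ref(q)], out, bn)
        out.append((ref(r), str(OWL.propertyChainAxiom), head))
    for i in sorted(kb.abox.individuals):
        out.append((ref(i), str(RDF.type), str(OWL.NamedIndividual)))
    for i, c in sorted(kb.abox.type_assertions):
        out.append((ref(i), str(RDF.type), ref(c)))
    for p, s, o in sorted(kb.abox.role_assertions):
        out.append((ref(s), iri_for(p), ref(o)))
    return out


def _triples_to_ntriples(triples: list) -> str:
    def fmt(x: str) -> str:
        if x.startswith("_:") or x.startswith("<"):
            return x
        return f"<{x}>"

    lines = sorted(f"{fmt(s)} {fmt(p)} {fmt(o)} ." for s, p, o in triples)
    return "\n".join(lines) + "\n"


def kb_to_ntriples(kb: KnowledgeBase) -> str:
    return _triples_to_ntriples(_kb_triples(kb))


# -- Turtle subset ----------------------------------------------------------

_TTL_HEADER = (
    "@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .\n"
    "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .\n"
    "@prefix owl: <http://www.w3.org/2002/07/owl#> .\n"
    + "".join(f"@prefix {ns}: <{iri}> .\n"
              for ns, iri in sorted(IRI_PREFIXES.items()))
    + "\n")


def _ttl_expr(expr: ClassExpression) -> str:
    if isinstance(expr, Named):
        return _qname(expr.term)
    if isinstance(expr, Some):
        return (f"[ a owl:Restriction ; owl:onProperty {_qname(expr.prop)} ; "
                f"owl:someValuesFrom {_ttl_expr(expr.filler)} ]")
    if isinstance(expr, (And, Or)):
        pred = "owl:intersectionOf" if isinstance(expr, And) else "owl:unionOf"
        items = " ".join(_ttl_expr(c) for c in expr.children)
        return f"[ a owl:Class ; {pred} ( {items} ) ]"
    raise ValueError(f"unknown expression node {expr!r}")


def kb_to_turtle(kb: KnowledgeBase) -> str:
    lines = [_TTL_HEADER]
    for c in sorted(kb.tbox.classes):
        lines.append(f"{_qname(c)} a owl:Class .")
    for name in sorted(kb.tbox.properties):
        decl = kb.tbox.properties[name]
        parts = [f"{_qname(name)} a owl:ObjectProperty"]
        if decl.transitive:
            parts.append("a owl:TransitiveProperty")
        if decl.symmetric:
            parts.append("a owl:SymmetricProperty")
        if decl.inverse is not None and decl.inverse != name:
            parts.append(f"owl:inverseOf {_qname(decl.inverse)}")
        for sp in sorted(decl.super_properties):
            parts.append(f"rdfs:subPropertyOf {_qname(sp)}")
        if decl.domain is not None:
            parts.append(f"rdfs:domain {_qname(decl.domain)}")
        if decl.range is not None:
            parts.append(f"rdfs:range {_qname(decl.range)}")
        lines.append(" ; ".join(parts) + " .")
    for lhs, rhs in sorted(kb.tbox.subclass_axioms, key=str):
        lines.append(f"{_qname(lhs)} rdfs:subClassOf {_ttl_expr(rhs)} .")
    for lhs, rhs in sorted(kb.tbox.equivalence_axioms, key=str):
        lines.append(f"{_qname(lhs)} owl:equivalentClass {_ttl_expr(rhs)} .")
    for p, q, r in sorted(kb.tbox.chain_axioms):
        lines.append(f"{_qname(r)} owl:propertyChainAxiom "
                     f"( {_qname(p)} {_qname(q)} ) .")
    for i in sorted(kb.abox.individuals):
        lines.append(f"{_qname(i)} a owl:NamedIndividual .")
    for i, c in sorted(kb.abox.type_assertions):
        lines.append(f"{_qname(i)} a {_qname(c)} .")
    for p, s, o in sorted(kb.abox.role_assertions):
        lines.append(f"{_qname(s)} {_qname(p)} {_qname(o)} .")
    return "\n".join(lines) + "\n"


# -- RDF reading ------------------------------------------------------------

def _parse_rdf(text: str, fmt: str) -> rdflib.Graph:
    g = rdflib.Graph()
    for ns, iri in IRI_PREFIXES.items():
        g.bind(ns, iri)
    try:
        g.parse(data=text, format=fmt)
    except Exception as err:  # rdflib raises format-specific errors
        line = getattr(err, "lines", None)
        raise HcoParseError(f"malformed {fmt} input: {err}",
                            line=line if isinstance(line, int) else None
                            ) from err
    return g


def _expr_from_node(g: rdflib.Graph, node) -> ClassExpression:
    if isinstance(node, rdflib.URIRef):
        return Named(term_for(str(node)))
    if (node, RDF.type, OWL.Restriction) in g:
        prop = g.value(node, OWL.onProperty)
        filler = g.value(node, OWL.someValuesFrom)
        if prop is None or filler is None:
            raise HcoParseError("incomplete owl:Restriction node")
        return Some(term_for(str(prop)), _expr_from_node(g, filler))
    for pred, ctor in ((OWL.intersectionOf, And), (OWL.unionOf, Or)):
        head = g.value(node, pred)
        if head is not None:
            items = [_expr_from_node(g, item)
                     for item in rdflib.collection.Collection(g, head)]
            return ctor(*items)
    raise HcoParseError(f"unsupported class-expression node {node}")


def kb_from_rdf(text: str, fmt: str) -> KnowledgeBase:
    g = _parse_rdf(text, fmt)
    tbox = TBox()
    abox = ABox()
    class_nodes = {s for s in g.subjects(RDF.type, OWL.Class)
                   if isinstance(s, rdflib.URIRef)}
    for s in class_nodes:
        tbox.add_class(term_for(str(s)))
    prop_nodes = {s for s in g.subjects(RDF.type, OWL.ObjectProperty)
                  if isinstance(s, rdflib.URIRef)}
    for s in sorted(prop_nodes):
        name = term_for(str(s))
        inverse = g.value(s, OWL.inverseOf)
        symmetric = (s, RDF.type, OWL.SymmetricProperty) in g
        tbox.add_property(PropertyDecl(
            name=name,
            inverse=(name if symmetric else
                     (term_for(str(inverse)) if inverse is not None else None)),
            transitive=(s, RDF.type, OWL.TransitiveProperty) in g,
            symmetric=symmetric,
            super_properties=frozenset(
                term_for(str(o)) for o in g.objects(s, RDFS.subPropertyOf)),
            domain=(lambda v: term_for(str(v)) if v is not None else None)(
                g.value(s, RDFS.domain)),
            range=(lambda v: term_for(str(v)) if v is not None else None)(
                g.value(s, RDFS.range)),
        ))
    for s, o in g.subject_objects(RDFS.subClassOf):
        tbox.add_subclass(term_for(str(s)), _expr_from_node(g, o))
    for s, o in g.subject_objects(OWL.equivalentClass):
        tbox.add_equivalence(term_for(str(s)), _expr_from_node(g, o))
    for s, o in g.subject_objects(OWL.propertyChainAxiom):
        chain = [term_for(str(item))
                 for item in rdflib.collection.Collection(g, o)]
        if len(chain) != 2:
            raise HcoParseError("only length-2 property chains are supported")
        tbox.add_chain(chain[0], chain[1], term_for(str(s)))
    for s in g.subjects(RDF.type, OWL.NamedIndividual):
        abox.add_individual(term_for(str(s)))
    for s, p, o in g:
        if not isinstance(s, rdflib.URIRef) or not isinstance(o, rdflib.URIRef):
            continue
        if p == RDF.type:
            term = None
            try:
                term = term_for(str(o))
            except HcoParseError:
                continue  # owl vocabulary
            if term in tbox.classes:
                abox.add_type(term_for(str(s)), term)
            continue
        try:
            prop = term_for(str(p))
        except HcoParseError:
            continue  # rdfs/owl vocabulary
        if prop in tbox.properties:
            abox.add_role(prop, term_for(str(s)), term_for(str(o)))
    kb = KnowledgeBase(tbox=tbox, abox=abox)
    kb.validate()
    return kb


# ---------------------------------------------------------------------------
# Frame graphs
# ---------------------------------------------------------------------------

def frame_to_json(graph: FrameGraph) -> str:
    doc = {
        "format": "hco-frame",
        "version": 1,
        "entities": sorted(str(e) for e in graph.entities),
        "triples": sorted([str(s), str(p), str(o)]
                          for s, p, o in graph.triples),
        "metaclass_flags": sorted(str(m) for m in graph.metaclass_flags),
    }
    return json.dumps(doc, indent=2, sort_keys=True) + "\n"


def frame_from_json(text: str) -> FrameGraph:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as err:
        raise HcoParseError(f"malformed JSON: {err.msg}", line=err.lineno,
                            column=err.colno) from err
    if doc.get("format") != "hco-frame":
        raise HcoParseError("not an hco-frame JSON document")
    g = FrameGraph(
        entities={TermName.parse(e) for e in doc.get("entities", ())},
        triples={(TermName.parse(s), TermName.parse(p), TermName.parse(o))
                 for s, p, o in doc.get("triples", ())},
        metaclass_flags={TermName.parse(m)
                         for m in doc.get("metaclass_flags", ())},
    )
    g.validate()
    return g


def frame_to_ntriples(graph: FrameGraph) -> str:
    return _triples_to_ntriples(_frame_triples(graph))


def frame_to_turtle(graph: FrameGraph) -> str:
    lines = [_TTL_HEADER]
    for e in sorted(graph.entities):
        lines.append(f"{_qname(e)} a owl:Class .")
    for m in sorted(graph.metaclass_flags):
        lines.append(f"{_qname(m)} a hco:__Metaclass .")
    for s, p, o in sorted(graph.triples):
        pred = "rdfs:subClassOf" if p == SUBCLASS_OF else _qname(p)
        lines.append(f"{_qname(s)} {pred} {_qname(o)} .")
    return "\n".join(lines) + "\n"


def _frame_triples(graph: FrameGraph) -> list:
    out = []
    for e in sorted(graph.entities):
        out.append((iri_for(e), str(RDF.type), str(OWL.Class)))
    for m in sorted(graph.metaclass_flags):
        out.append((iri_for(m), str(RDF.type), str(_METACLASS_MARKER)))
    for s, p, o in sorted(graph.triples):
        pred = str(RDFS.subClassOf) if p == SUBCLASS_OF else iri_for(p)
        out.append((iri_for(s), pred, iri_for(o)))
    return out


def frame_from_rdf(text: str, fmt: str) -> FrameGraph:
    g = _parse_rdf(text, fmt)
    graph = FrameGraph()
    entities = {term_for(str(s)) for s in g.subjects(RDF.type, OWL.Class)
                if isinstance(s, rdflib.URIRef)}
    graph.entities |= entities
    for s in g.subjects(RDF.type, _METACLASS_MARKER):
        term = term_for(str(s))
        graph.entities.add(term)
        graph.metaclass_flags.add(term)
    for s, p, o in g:
        if not isinstance(s, rdflib.URIRef) or not isinstance(o, rdflib.URIRef):
            continue
        if p == RDFS.subClassOf:
            graph.add_triple(term_for(str(s)), SUBCLASS_OF, term_for(str(o)))
        elif p == RDF.type:
            if o in (OWL.Class, _METACLASS_MARKER):
                continue
            obj = term_for(str(o))
            if obj in graph.metaclass_flags or obj in entities:
                # frame pattern: typing by another entity is subsumption
                graph.add_triple(term_for(str(s)), SUBCLASS_OF, obj)
        else:
            try:
                pred = term_for(str(p))
            except HcoParseError:
                continue
            graph.add_triple(term_for(str(s)), pred, term_for(str(o)))
    graph.validate()
    return graph


# ---------------------------------------------------------------------------
# File-level API
# ---------------------------------------------------------------------------

_FORMATS = {"json": "json", "ntriples": "ntriples", "nt": "ntriples",
            "turtle": "turtle", "ttl": "turtle", "turtle-subset": "turtle"}
_SUFFIXES = {".json": "json", ".nt": "ntriples", ".ttl": "turtle"}


def _resolve_format(path: Union[str, Path], fmt: Optional[str]) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise ValueError(f"unknown format {fmt!r}")
        return _FORMATS[fmt]
    suffix = Path(path).suffix.lower()
    if suffix in _SUFFIXES:
        return _SUFFIXES[suffix]
    raise ValueError(f"cannot infer format from {path}; pass format=")


def write_kb(kb: KnowledgeBase, path: Union[str, Path],
             format: Optional[str] = None) -> None:
    kb.validate()
    fmt = _resolve_format(path, format)
    text = {"json": kb_to_json, "ntriples": kb_to_ntriples,
            "turtle": kb_to_turtle}[fmt](kb)
    Path(path).write_text(text)


def read_kb(path: Union[str, Path],
            format: Optional[str] = None) -> KnowledgeBase:
    fmt = _resolve_format(path, format)
    text = Path(path).read_text()
    if fmt == "json":
        return kb_from_json(text)
    return kb_from_rdf(text, "nt" if fmt == "ntriples" else "turtle")


def write_frame_graph(graph: FrameGraph, path: Union[str, Path],
                      format: Optional[str] = None) -> None:
    graph.validate()
    fmt = _resolve_format(path, format)
    text = {"json": frame_to_json, "ntriples": frame_to_ntriples,
            "turtle": frame_to_turtle}[fmt](graph)
    Path(path).write_text(text)


def read_frame_graph(path: Union[str, Path],
                     format: Optional[str] = None) -> FrameGraph:
    fmt = _resolve_format(path, format)
    text = Path(path).read_text()
    if fmt == "json":
        return frame_from_json(text)
    return frame_from_rdf(text, "nt" if fmt == "ntriples" else "turtle")
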