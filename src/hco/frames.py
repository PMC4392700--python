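"""Frame-style ontology graphs and partonomy view extraction.

The source anatomy ontology stores part-whole knowledge at the *individuals'*
level: each anatomical term is simultaneously a class and an individual
(OWL-Full punning), and e.g. ``Right_precentral_gyrus regional_part_of
Right_frontal_lobe`` is an ordinary triple between those punned entities.
:func:`extract_view` carves a neuroanatomy view out of such a graph by
recursive traversal of the part-of properties from a set of seed terms,
optionally pulling in laterally adjacent entities (``attributed_continuous_with``)
and all subsuming classes, then discarding metaclasses and out-of-domain hubs
such as ``fma:Human_body``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .model import (
    ATTRIBUTED_CONTINUOUS_WITH,
    CONSTITUTIONAL_PART,
    CONSTITUTIONAL_PART_OF,
    REGIONAL_PART,
    REGIONAL_PART_OF,
    HcoError,
    IntegrityError,
    TermName,
    hco,
)

#: distinguished predicate for subsumption edges inside a frame graph
SUBCLASS_OF = hco("subClassOf")

DEFAULT_FOLLOW = (REGIONAL_PART_OF, CONSTITUTIONAL_PART_OF)
DEFAULT_LATERAL = (ATTRIBUTED_CONTINUOUS_WITH,)
DEFAULT_KEEP = (CONSTITUTIONAL_PART, REGIONAL_PART, ATTRIBUTED_CONTINUOUS_WITH,
                CONSTITUTIONAL_PART_OF, REGIONAL_PART_OF)


@dataclass
class FrameGraph:
    """Triple set over punned class-and-individual entities."""

    entities: set = field(default_factory=set)
    triples: set = field(default_factory=set)  # (subject, predicate, object)
    metaclass_flags: set = field(default_factory=set)

    def add_triple(self, s: TermName, p: TermName, o: TermName) -> None:
        self.entities.add(s)
        self.entities.add(o)
        self.triples.add((s, p, o))

    def predicates(self) -> set:
        return {p for _, p, _ in self.triples}

    def validate(self) -> None:
        for s, p, o in self.triples:
            for end in (s, o):
                if end not in self.entities:
                    raise IntegrityError(
                        f"triple endpoint {end} is not a declared entity")
        for m in self.metaclass_flags:
            if m not in self.entities:
                raise IntegrityError(f"metaclass flag on unknown entity {m}")


@dataclass(frozen=True)
class ExtractionConfig:
    seeds: frozenset = frozenset()
    follow_properties: tuple = DEFAULT_FOLLOW
    lateral_properties: frozenset = frozenset(DEFAULT_LATERAL)
    lateral_policy: str = "one_step"  # or "closed"
    exclusions: frozenset = frozenset()
    keep_properties: frozenset = frozenset(DEFAULT_KEEP)
    superclass_closure: bool = True

    def __post_init__(self):
        if self.lateral_policy not in ("one_step", "closed"):
            raise ValueError(f"unknown lateral policy {self.lateral_policy!r}")


def _reach(edges: Iterable, starts: set) -> set:
    """Entities reachable from ``starts`` (inclusive) along directed edges."""
    g = nx.DiGraph()
    g.add_edges_from(edges)
    out = set(starts)
    for s in starts:
        if s in g:
            out |= nx.descendants(g, s)
    return out


def extract_view(graph: FrameGraph, config: ExtractionConfig) -> FrameGraph:
    """Extract the partonomy view rooted at ``config.seeds``.

    Traversal is entity-to-whole only: a follow-property triple ``(x, p, y)``
    is read as "x is part of y" and pulls ``y`` into the view.  Exclusions and
    metaclass removal are applied *after* the closure so that excluded hubs do
    not truncate the traversal.  Deterministic (no randomness, iteration over
    sorted structures where order matters).
    """
    graph.validate()
    for seed in config.seeds:
        if seed not in graph.entities:
            raise HcoError(f"unknown seed term {seed}")
    known_predicates = graph.predicates() | {SUBCLASS_OF}
    for prop in (tuple(config.follow_properties)
                 + tuple(config.lateral_properties)
                 + tuple(config.keep_properties)):
        # a property never used in the graph is suspicious only if the graph
        # has triples at all; flag genuinely unknown lateral/follow properties
        if graph.triples and prop not in known_predicates \
                and prop not in DEFAULT_KEEP and prop not in DEFAULT_LATERAL \
                and prop not in DEFAULT_FOLLOW:
            raise HcoError(f"unknown property {prop} in extraction config")

    follow = set(config.follow_properties)
    follow_edges = [(s, o) for s, p, o in graph.triples if p in follow]

    # (1) + (2): seeds plus transitive whole-closure
    include = _reach(follow_edges, set(config.seeds))

    # (3) lateral expansion
    lateral_triples = [(s, p, o) for s, p, o in graph.triples
                       if p in config.lateral_properties]
    if config.lateral_policy == "one_step":
        partners = set()
        for s, _, o in lateral_triples:
            if s in include:
                partners.add(o)
            if o in include:
                partners.add(s)
        new = partners - include
        if new:
            include |= _reach(follow_edges, new)
    # "closed": no new entities; lateral triples filtered in step (6)

    # (4) superclass closure
    if config.superclass_closure:
        sub_edges = [(s, o) for s, p, o in graph.triples if p == SUBCLASS_OF]
        include = _reach(sub_edges, include)

    # (5) remove metaclasses and exclusions
    include -= set(graph.metaclass_flags)
    include -= set(config.exclusions)

    # (6) restrict triples
    allowed = {SUBCLASS_OF} | set(config.keep_properties) \
        | set(config.lateral_properties)
    kept = {(s, p, o) for s, p, o in graph.triples
            if p in allowed and s in include and o in include}

    view = FrameGraph(entities=include, triples=kept, metaclass_flags=set())
    view.validate()
    return view


@dataclass(frozen=True)
class ViewDiff:
    entities_only_in_a: tuple
    entities_only_in_b: tuple
    triples_only_in_a: tuple
    triples_only_in_b: tuple

    @property
    def empty(self) -> bool:
        return not (self.entities_only_in_a or self.entities_only_in_b
                    or self.triples_only_in_a or self.triples_only_in_b)


def diff_views(a: FrameGraph, b: FrameGraph) -> ViewDiff:
    """Symmetric difference of two views, deterministically ordered."""
    return ViewDiff(
        entities_only_in_a=tuple(sorted(a.entities - b.entities)),
        entities_only_in_b=tuple(sorted(b.entities - a.entities)),
        triples_only_in_a=tuple(sorted(a.triples - b.triples)),
        triples_only_in_b=tuple(sorted(b.triples - a.triples)),
    )


def make_config(seeds, **kwargs) -> ExtractionConfig:
    """Convenience constructor accepting any iterable of seeds."""
    return ExtractionConfig(seeds=frozenset(seeds), **kwargs)
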