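"""Independent reference implementations used only by the test suite.

Everything here is deliberately naive (repeated full scans until nothing
changes, hand-rolled BFS) and shares no code with the package's engines, so
it can serve as an oracle for them.
"""

from __future__ import annotations

import random

from hco.frames import SUBCLASS_OF, FrameGraph
from hco.model import (
    ABox,
    And,
    KnowledgeBase,
    Named,
    Or,
    PropertyDecl,
    Some,
    TBox,
    TermName,
    hco,
)


# ---------------------------------------------------------------------------
# Two-phase BFS oracle for view extraction
# ---------------------------------------------------------------------------

def bfs_view(graph: FrameGraph, config) -> FrameGraph:
    """Reference implementation of the extraction semantics."""

    def closure(starts):
        seen = set(starts)
        frontier = list(starts)
        while frontier:
            nxt = []
            for s, p, o in graph.triples:
                if p in set(config.follow_properties) and s in seen \
                        and o not in seen:
                    nxt.append(o)
            seen |= set(nxt)
            frontier = nxt
        return seen

    include = closure(set(config.seeds))
    if config.lateral_policy == "one_step":
        partners = set()
        for s, p, o in graph.triples:
            if p in config.lateral_properties:
                if s in include:
                    partners.add(o)
                if o in include:
                    partners.add(s)
        include |= closure(partners - include)
    if config.superclass_closure:
        seen = set(include)
        changed = True
        while changed:
            changed = False
            for s, p, o in graph.triples:
                if p == SUBCLASS_OF and s in seen and o not in seen:
                    seen.add(o)
                    changed = True
        include = seen
    include -= set(graph.metaclass_flags)
    include -= set(config.exclusions)
    allowed = {SUBCLASS_OF} | set(config.keep_properties) \
        | set(config.lateral_properties)
    triples = {(s, p, o) for s, p, o in graph.triples
               if p in allowed and s in include and o in include}
    return FrameGraph(entities=include, triples=triples)


def random_frame_graph(rng: random.Random, n_entities: int = 12,
                       n_triples: int = 20) -> FrameGraph:
    from hco.model import fma

    entities = [fma(f"E{i}") for i in range(n_entities)]
    props = [fma("regional_part_of"), fma("constitutional_part_of"),
             fma("attributed_continuous_with"), SUBCLASS_OF,
             fma("other_property")]
    g = FrameGraph(entities=set(entities))
    for _ in range(n_triples):
        s, o = rng.sample(entities, 2)
        g.add_triple(s, rng.choice(props), o)
    for e in entities:
        if rng.random() < 0.1:
            g.metaclass_flags.add(e)
    return g


# ---------------------------------------------------------------------------
# Naive fixpoint oracle for the reasoner
# ---------------------------------------------------------------------------

def _direct_supers(tbox: TBox, p: TermName):
    return tbox.properties[p].super_properties


def _seed(c, expr, sub, ex):
    if isinstance(expr, Named):
        sub.add((c, expr.term))
    elif isinstance(expr, And):
        for child in expr.children:
            _seed(c, child, sub, ex)
    elif isinstance(expr, Some) and isinstance(expr.filler, Named):
        ex.add((c, expr.prop, expr.filler.term))


def _oracle_tholds(x, expr, sub, ex):
    if isinstance(expr, Named):
        return (x, expr.term) in sub
    if isinstance(expr, And):
        return all(_oracle_tholds(x, c, sub, ex) for c in expr.children)
    if isinstance(expr, Or):
        return any(_oracle_tholds(x, c, sub, ex) for c in expr.children)
    if isinstance(expr, Some):
        return any(p == expr.prop and c == x
                   and _oracle_tholds(d, expr.filler, sub, ex)
                   for c, p, d in ex)
    raise AssertionError(expr)


def _named_set(expr):
    if isinstance(expr, Named):
        return {expr.term}
    if isinstance(expr, Or):
        out = set()
        for c in expr.children:
            s = _named_set(c)
            if s is None:
                return None
            out |= s
        return out
    return None


def oracle_holds(i, expr, types, roles, sub, ex):
    if isinstance(expr, Named):
        return (i, expr.term) in types
    if isinstance(expr, And):
        return all(oracle_holds(i, c, types, roles, sub, ex)
                   for c in expr.children)
    if isinstance(expr, Or):
        return any(oracle_holds(i, c, types, roles, sub, ex)
                   for c in expr.children)
    if isinstance(expr, Some):
        for p, s, o in roles:
            if p == expr.prop and s == i \
                    and oracle_holds(o, expr.filler, types, roles, sub, ex):
                return True
        targets = _named_set(expr.filler)
        if targets is not None:
            for ind, a in types:
                if ind != i:
                    continue
                for c, p, d in ex:
                    if c == a and p == expr.prop \
                            and any((d, f) in sub for f in targets):
                        return True
        return False
    raise AssertionError(expr)


def naive_saturate(kb: KnowledgeBase):
    """Apply every rule exhaustively until nothing changes."""
    tbox, abox = kb.tbox, kb.abox
    sub = {(c, c) for c in tbox.classes}
    ex = set()
    for c, rhs in tbox.subclass_axioms | tbox.equivalence_axioms:
        _seed(c, rhs, sub, ex)

    changed = True
    while changed:
        changed = False
        for c, d in list(sub):
            for d2, e in list(sub):
                if d == d2 and (c, e) not in sub:
                    sub.add((c, e))
                    changed = True
        for c, p, d in list(ex):
            for q in _direct_supers(tbox, p):
                if (c, q, d) not in ex:
                    ex.add((c, q, d))
                    changed = True
            for d2, e in list(sub):
                if d == d2 and (c, p, e) not in ex:
                    ex.add((c, p, e))
                    changed = True
            if tbox.properties[p].transitive:
                for c2, p2, e in list(ex):
                    if p2 == p and c2 == d and (c, p, e) not in ex:
                        ex.add((c, p, e))
                        changed = True
        for c, rhs in tbox.equivalence_axioms:
            for x in tbox.classes:
                if (x, c) not in sub and _oracle_tholds(x, rhs, sub, ex):
                    sub.add((x, c))
                    changed = True

    roles = set(abox.role_assertions)
    types = set(abox.type_assertions)
    changed = True
    while changed:
        changed = False
        for i, c in list(types):
            for c2, d in sub:
                if c2 == c and (i, d) not in types:
                    types.add((i, d))
                    changed = True
        for p, i, j in list(roles):
            decl = tbox.properties[p]
            for q in _direct_supers(tbox, p):
                if (q, i, j) not in roles:
                    roles.add((q, i, j))
                    changed = True
            inv = decl.effective_inverse()
            if inv is not None and (inv, j, i) not in roles:
                roles.add((inv, j, i))
                changed = True
            if decl.transitive:
                for p2, j2, k in list(roles):
                    if p2 == p and j2 == j and (p, i, k) not in roles:
                        roles.add((p, i, k))
                        changed = True
        for p, q, r in tbox.chain_axioms:
            for p1, i, x in list(roles):
                if p1 != p:
                    continue
                for q1, x2, j in list(roles):
                    if q1 == q and x2 == x and i != j \
                            and (r, i, j) not in roles:
                        roles.add((r, i, j))
                        changed = True
        for c, rhs in tbox.equivalence_axioms:
            for i in abox.individuals:
                if (i, c) not in types \
                        and oracle_holds(i, rhs, types, roles, sub, ex):
                    types.add((i, c))
                    changed = True
    return sub, ex, types, roles


# ---------------------------------------------------------------------------
# Random small knowledge bases
# ---------------------------------------------------------------------------

def random_small_kb(rng: random.Random, n_classes: int = 6,
                    n_props: int = 4, n_inds: int = 10) -> KnowledgeBase:
    tbox = TBox()
    classes = [hco(f"C{i}") for i in range(n_classes)]
    for c in classes:
        tbox.add_class(c)

    props = []
    i = 0
    while len(props) < n_props:
        name = hco(f"p{i}")
        if rng.random() < 0.3 and len(props) + 2 <= n_props:
            inv = hco(f"p{i}_inv")
            supers = frozenset(rng.sample(props, 1)) \
                if props and rng.random() < 0.4 else frozenset()
            tbox.add_property(PropertyDecl(name, inverse=inv,
                                           transitive=rng.random() < 0.3,
                                           super_properties=supers))
            tbox.add_property(PropertyDecl(inv, inverse=name))
            props.extend([name, inv])
            i += 1
        else:
            symmetric = rng.random() < 0.25
            supers = frozenset(rng.sample(props, 1)) \
                if props and rng.random() < 0.4 else frozenset()
            tbox.add_property(PropertyDecl(
                name, symmetric=symmetric,
                transitive=(not symmetric) and rng.random() < 0.3,
                super_properties=supers))
            props.append(name)
            i += 1

    def random_expr(depth: int):
        roll = rng.random()
        if depth <= 0 or roll < 0.4:
            return Named(rng.choice(classes))
        if roll < 0.6:
            return Some(rng.choice(props), random_expr(depth - 1))
        ctor = And if roll < 0.8 else Or
        return ctor(random_expr(depth - 1), random_expr(depth - 1))

    for _ in range(rng.randint(1, 4)):
        tbox.add_subclass(rng.choice(classes), random_expr(2))
    for _ in range(rng.randint(0, 2)):
        tbox.add_equivalence(rng.choice(classes), random_expr(2))
    if rng.random() < 0.5:
        tbox.add_chain(rng.choice(props), rng.choice(props),
                       rng.choice(props))

    abox = ABox()
    inds = [hco(f"i{k}") for k in range(n_inds)]
    for ind in inds:
        abox.add_individual(ind)
    for _ in range(rng.randint(0, 2 * n_inds)):
        abox.add_type(rng.choice(inds), rng.choice(classes))
    for _ in range(rng.randint(0, 3 * n_inds)):
        s, o = rng.choice(inds), rng.choice(inds)
        abox.add_role(rng.choice(props), s, o)
    kb = KnowledgeBase(tbox=tbox, abox=abox)
    kb.validate()
    return kb


def reachable(edges, start):
    """Plain BFS over a directed edge set."""
    seen = {start}
    frontier = [start]
    while frontier:
        nxt = []
        for a, b in edges:
            if a in frontier and b not in seen:
                seen.add(b)
                nxt.append(b)
        frontier = nxt
    return seen - {start}
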