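"""Translation of a frame-style view into a DL TBox.

A frame view asserts part-whole and adjacency knowledge between punned
entities at the individuals' level.  For description-logic reasoning each
entity must become a plain named class, and each individual-level triple
``(A, p, B)`` an existential class axiom ``A subClassOf (p some B)``.  The
translation removes all punning: the output declares terms as classes only.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .model import (
    Named,
    Some,
    TBox,
    fma_part_property_decls,
)
from .frames import DEFAULT_KEEP, SUBCLASS_OF, FrameGraph


def default_property_decls() -> list:
    """Standalone declarations for the kept anatomy part-properties.

    The ``hco:part_of`` / ``hco:part`` umbrella links are added later when the
    translated TBox is merged with the HCO schema.
    """
    return fma_part_property_decls(with_hco_supers=False)


@dataclass(frozen=True)
class TranslationConfig:
    keep_properties: frozenset = frozenset(DEFAULT_KEEP)
    property_decls: tuple = field(
        default_factory=lambda: tuple(default_property_decls()))


@dataclass(frozen=True)
class TranslationResult:
    tbox: TBox
    #: triples whose predicate was neither subsumption nor kept, in order
    dropped: tuple


def translate_frame_to_dl(view: FrameGraph,
                          config: TranslationConfig = TranslationConfig()
                          ) -> TranslationResult:
    """Translate ``view`` into a TBox of named classes and existential axioms.

    Every entity becomes a declared class; every subsumption triple a
    named-to-named subclass axiom; every kept-property triple ``(A, p, B)``
    the axiom ``A subClassOf (p some B)``.  Triples over other properties are
    dropped and reported, not fatal.  Deterministic: translating twice yields
    equal TBoxes.
    """
    view.validate()
    tbox = TBox()
    declared = {d.name for d in config.property_decls}
    missing = set(config.keep_properties) - declared
    if missing:
        raise ValueError("keep_properties not covered by property "
                         f"declarations: {sorted(map(str, missing))}")
    for decl in config.property_decls:
        tbox.add_property(decl)
    for entity in view.entities:
        tbox.add_class(entity)

    dropped = []
    for s, p, o in sorted(view.triples):
        if p == SUBCLASS_OF:
            tbox.add_subclass(s, Named(o))
        elif p in config.keep_properties:
            tbox.add_subclass(s, Some(p, Named(o)))
        else:
            dropped.append((s, p, o))

    tbox.validate()
    return TranslationResult(tbox=tbox, dropped=tuple(dropped))


def existential_axiom_count(tbox: TBox) -> int:
    """Number of ``A subClassOf (p some B)`` axioms in a TBox."""
    return sum(1 for _, rhs in tbox.subclass_axioms if isinstance(rhs, Some))
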