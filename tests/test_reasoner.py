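import random

import pytest

from oracles import naive_saturate, random_small_kb, reachable
from hco.model import (
    ABox,
    And,
    KnowledgeBase,
    MR_CONNECTION,
    MR_NODE,
    MR_ROUTE,
    Named,
    PART_OF,
    PropertyDecl,
    Some,
    TBox,
    build_hco_schema,
    fma,
    hco,
)
from hco.reasoner import holds, saturate, saturate_is_idempotent


def _fig_chain_kb(reference_tbox) -> KnowledgeBase:
    """A parcel hanging off the gyrus/lobe partonomy plus one route."""
    abox = ABox()
    parcel = hco("s1_gray_matter_of_right_superior_frontal_gyrus_17")
    gm = hco("s1_gray_matter_of_right_superior_frontal_gyrus")
    gyrus = hco("s1_right_superior_frontal_gyrus")
    lobe = hco("s1_right_frontal_lobe")
    other = hco("s1_gray_matter_of_left_superior_frontal_gyrus_39")
    route = hco("s1_mr_route_118")
    abox.add_type(parcel, hco("Gray_matter_part"))
    abox.add_type(other, hco("Gray_matter_part"))
    abox.add_type(gyrus, fma("Right_superior_frontal_gyrus"))
    abox.add_type(lobe, fma("Right_frontal_lobe"))
    abox.add_type(route, hco("MR_Route"))
    abox.add_role(fma("regional_part_of"), parcel, gm)
    abox.add_role(fma("constitutional_part_of"), gm, gyrus)
    abox.add_role(fma("regional_part_of"), gyrus, lobe)
    abox.add_role(hco("tracto_connects"), route, parcel)
    abox.add_role(hco("tracto_connects"), route, other)
    return KnowledgeBase(tbox=reference_tbox, abox=abox)


class TestSaturation:
    def test_partonomy_lifts_to_transitive_part_of(self, reference_tbox):
        s = saturate(_fig_chain_kb(reference_tbox))
        parcel = hco("s1_gray_matter_of_right_superior_frontal_gyrus_17")
        assert s.has_role(PART_OF, parcel, hco("s1_right_frontal_lobe"))

    def test_chain_rule_derives_symmetric_irreflexive_connection(
            self, reference_tbox):
        s = saturate(_fig_chain_kb(reference_tbox))
        n1 = hco("s1_gray_matter_of_right_superior_frontal_gyrus_17")
        n2 = hco("s1_gray_matter_of_left_superior_frontal_gyrus_39")
        assert s.has_role(MR_CONNECTION, n1, n2)
        assert s.has_role(MR_CONNECTION, n2, n1)
        assert not s.has_role(MR_CONNECTION, n1, n1)
        assert not s.has_role(MR_CONNECTION, n2, n2)

    def test_realization_types_connected_parcels_as_nodes(self,
                                                          reference_tbox):
        s = saturate(_fig_chain_kb(reference_tbox))
        n1 = hco("s1_gray_matter_of_right_superior_frontal_gyrus_17")
        assert (n1, MR_NODE) in s.derived_types
        # and the definition also holds directly
        defn = And(Named(hco("Gray_matter_part")),
                   Some(hco("is_tracto_connected"), Named(MR_ROUTE)))
        assert holds(n1, defn, s)

    def test_empty_abox_derives_nothing_at_instance_level(self, schema):
        s = saturate(KnowledgeBase(tbox=schema))
        assert s.derived_roles == set()
        assert s.derived_types == set()
        for c in schema.classes:
            assert (c, c) in s.derived_subsumptions

    def test_trace_covers_every_derived_fact(self, reference_tbox):
        kb = _fig_chain_kb(reference_tbox)
        s = saturate(kb, trace=True)
        traced = {e.conclusion for e in s.trace}
        for fact in s.derived_roles - kb.abox.role_assertions:
            assert ("role",) + fact in traced
        for fact in s.derived_types - kb.abox.type_assertions:
            assert ("type",) + fact in traced


class TestHolds:
    def test_named_with_no_types_is_false(self, schema):
        kb = KnowledgeBase(tbox=schema)
        kb.abox.add_individual(hco("lonely"))
        s = saturate(kb)
        assert not holds(hco("lonely"), Named(MR_NODE), s)

    def test_class_level_existential_with_property_weakening(self):
        # A <= (constitutional_part_of some B) entails
        # holds(i, part_of some B) for i typed A, through the sub-property
        tbox = build_hco_schema()
        tbox.add_class(fma("A"))
        tbox.add_class(fma("B"))
        tbox.add_subclass(fma("A"), Some(fma("constitutional_part_of"),
                                         Named(fma("B"))))
        abox = ABox()
        abox.add_type(hco("i"), fma("A"))
        s = saturate(KnowledgeBase(tbox=tbox, abox=abox))
        assert holds(hco("i"), Some(PART_OF, Named(fma("B"))), s)
        # the oracle agrees
        sub, ex, types, roles = naive_saturate(
            KnowledgeBase(tbox=tbox, abox=abox))
        assert (fma("A"), PART_OF, fma("B")) in ex


class TestFixpointProperties:
    @pytest.mark.parametrize("trial", range(60))
    def test_matches_naive_oracle_on_random_kbs(self, trial):
        rng = random.Random(20_000 + trial)
        kb = random_small_kb(rng)
        s = saturate(kb)
        sub, ex, types, roles = naive_saturate(kb)
        assert s.derived_subsumptions == sub
        assert s.derived_class_existentials == ex
        assert s.derived_types == types
        assert s.derived_roles == roles

    @pytest.mark.parametrize("trial", range(10))
    def test_idempotence(self, trial):
        rng = random.Random(30_000 + trial)
        s = saturate(random_small_kb(rng))
        assert saturate_is_idempotent(s)

    @pytest.mark.parametrize("trial", range(10))
    def test_monotonicity_under_added_assertions(self, trial):
        rng = random.Random(40_000 + trial)
        kb = random_small_kb(rng)
        s1 = saturate(kb)
        kb2 = kb.copy()
        inds = sorted(kb2.abox.individuals)
        props = sorted(kb2.tbox.properties)
        kb2.abox.add_role(rng.choice(props), rng.choice(inds),
                          rng.choice(inds))
        kb2.abox.add_type(rng.choice(inds),
                          rng.choice(sorted(kb2.tbox.classes)))
        s2 = saturate(kb2)
        assert s1.derived_roles <= s2.derived_roles
        assert s1.derived_types <= s2.derived_types

    def test_part_of_closure_equals_graph_reachability(self,
                                                       saturated_subject):
        s = saturated_subject
        part_edges = {(i, j) for p, i, j in s.kb.abox.role_assertions
                      if p in (fma("regional_part_of"),
                               fma("constitutional_part_of"))}
        inds = {i for i, _ in part_edges}
        for start in sorted(inds)[:40]:
            expected = reachable(part_edges, start)
            got = {j for p, i, j in s.derived_roles
                   if p == PART_OF and i == start}
            assert got == expected

    def test_mr_connection_symmetric_irreflexive_in_pipeline_output(
            self, saturated_subject):
        s = saturated_subject
        conns = {(i, j) for p, i, j in s.derived_roles
                 if p == MR_CONNECTION}
        assert conns, "pipeline produced no connections"
        for i, j in conns:
            assert i != j
            assert (j, i) in conns
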