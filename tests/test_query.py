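import random

import pytest

from oracles import naive_saturate, oracle_holds, random_small_kb
from hco.model import (
    AmbiguousTermError,
    And,
    HcoParseError,
    Named,
    Or,
    Some,
    TermName,
    UnknownTermError,
    fma,
    hco,
)
from hco.queries import (
    COMPETENCY_QUERY_TEXT,
    answer_query,
    competency_query,
    parse_query,
    resolve_expression,
    resolve_term,
)
from hco.reasoner import saturate


def _n(name):
    return Named(TermName.parse(name))


class TestParser:
    def test_bundle_query_structure(self):
        expr = parse_query(
            "part some ((tracto_connects some (part_of some "
            "Right_temporal_lobe)) and (tracto_connects some (part_of some "
            "Right_superior_frontal_gyrus)))")
        assert expr == Some(
            TermName.parse("part"),
            And(Some(TermName.parse("tracto_connects"),
                     Some(TermName.parse("part_of"),
                          _n("Right_temporal_lobe"))),
                Some(TermName.parse("tracto_connects"),
                     Some(TermName.parse("part_of"),
                          _n("Right_superior_frontal_gyrus")))))

    def test_and_binds_tighter_than_or(self):
        assert parse_query("A and B or C") \
            == Or(And(_n("A"), _n("B")), _n("C"))

    def test_some_is_right_associative(self):
        assert parse_query("p some q some C") \
            == Some(TermName.parse("p"),
                    Some(TermName.parse("q"), _n("C")))

    def test_syntax_error_reports_position(self):
        with pytest.raises(HcoParseError) as err:
            parse_query("A and (B or")
        assert err.value.column == len("A and (B or")

    @pytest.mark.parametrize("text", ["", "and B", "A B", "(A", "A )"])
    def test_malformed_inputs_raise(self, text):
        with pytest.raises(HcoParseError):
            parse_query(text)

    @pytest.mark.parametrize("n", [1, 2, 3, 4])
    def test_print_parse_round_trip(self, n):
        expr = competency_query(n)
        assert parse_query(str(expr)) == expr


class TestResolution:
    def test_unprefixed_resolves_hco_first_then_fma(self, reference_tbox):
        assert resolve_term(TermName.parse("part_of"), reference_tbox) \
            == hco("part_of")
        assert resolve_term(TermName.parse("Right_precentral_gyrus"),
                            reference_tbox) == fma("Right_precentral_gyrus")

    def test_name_in_both_namespaces_is_ambiguous(self, reference_tbox):
        tbox = reference_tbox.copy()
        tbox.add_class(hco("Right_precentral_gyrus"))
        with pytest.raises(AmbiguousTermError):
            resolve_term(TermName.parse("Right_precentral_gyrus"), tbox)

    def test_unknown_term_named_in_error(self, reference_tbox):
        with pytest.raises(UnknownTermError, match="Nonexistent_region"):
            resolve_expression(parse_query("part_of some Nonexistent_region"),
                               reference_tbox)


class TestCompetencyQueries:
    def test_all_four_resolve_against_reference_tbox(self, reference_tbox):
        for n in (1, 2, 3, 4):
            resolve_expression(competency_query(n), reference_tbox)

    def test_medial_parietal_is_a_conjunction_inside_query2(self):
        expr = competency_query(2)
        conj = And(Some(TermName.parse("part_of"),
                        _n("Cortex_of_right_parietal_lobe")),
                   Some(TermName.parse("part_of"),
                        _n("Medial_segment_of_cerebral_hemisphere")))
        found = []

        def walk(e):
            found.append(e == conj)
            for c in getattr(e, "children", ()):
                walk(c)
            if isinstance(e, Some):
                walk(e.filler)

        walk(expr)
        assert any(found)

    def test_query_text_round_trips_modulo_whitespace(self):
        for n, text in COMPETENCY_QUERY_TEXT.items():
            assert parse_query(str(competency_query(n))) \
                == parse_query(" ".join(text.split()))

    def test_out_of_range_index_rejected(self):
        with pytest.raises(ValueError):
            competency_query(5)


class TestAnswerQuery:
    def test_empty_answers_when_no_role_reaches_filler(self, schema):
        from hco.model import KnowledgeBase

        kb = KnowledgeBase(tbox=schema)
        kb.abox.add_type(hco("i"), hco("Gray_matter_part"))
        s = saturate(kb)
        result = answer_query(
            Some(hco("part_of"), Named(fma("Anatomical_structure"))), s)
        assert result.answers == ()

    def test_answers_are_sorted_and_deterministic(self, saturated_subject):
        r1 = answer_query(competency_query(1), saturated_subject)
        r2 = answer_query(competency_query(1), saturated_subject)
        assert r1.answers == r2.answers
        assert list(r1.answers) == sorted(r1.answers, key=str)

    @pytest.mark.parametrize("trial", range(25))
    def test_evaluator_matches_brute_force_oracle(self, trial):
        rng = random.Random(60_000 + trial)
        kb = random_small_kb(rng)
        s = saturate(kb)
        sub, ex, types, roles = naive_saturate(kb)
        classes = sorted(kb.tbox.classes)
        props = sorted(kb.tbox.properties)
        for _ in range(6):
            expr = _random_query(rng, classes, props)
            expected = tuple(sorted(
                (i for i in kb.abox.individuals
                 if oracle_holds(i, expr, types, roles, sub, ex)), key=str))
            assert answer_query(expr, s).answers == expected

    @pytest.mark.parametrize("trial", range(8))
    def test_answers_grow_monotonically_with_assertions(self, trial):
        rng = random.Random(70_000 + trial)
        kb = random_small_kb(rng)
        expr = _random_query(rng, sorted(kb.tbox.classes),
                             sorted(kb.tbox.properties))
        before = set(answer_query(expr, saturate(kb)).answers)
        kb2 = kb.copy()
        inds = sorted(kb2.abox.individuals)
        for _ in range(3):
            kb2.abox.add_role(rng.choice(sorted(kb2.tbox.properties)),
                              rng.choice(inds), rng.choice(inds))
            kb2.abox.add_type(rng.choice(inds),
                              rng.choice(sorted(kb2.tbox.classes)))
        after = set(answer_query(expr, saturate(kb2)).answers)
        assert before <= after


def _random_query(rng, classes, props, depth=2):
    roll = rng.random()
    if depth <= 0 or roll < 0.35:
        return Named(rng.choice(classes))
    if roll < 0.6:
        return Some(rng.choice(props),
                    _random_query(rng, classes, props, depth - 1))
    ctor = And if roll < 0.8 else Or
    return ctor(_random_query(rng, classes, props, depth - 1),
                _random_query(rng, classes, props, depth - 1))
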