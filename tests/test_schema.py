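"""Schema dialect and graph-pattern matching, checked against a brute-force
subgraph-isomorphism oracle."""

import itertools
import random

import pytest

from semantic_units import vocab
from semantic_units.errors import SchemaError
from semantic_units.model import DataGraph, Literal, Triple
from semantic_units.schema import (
    Binding,
    StatementUnitSchema,
    builtin_schemas,
    dump_schemas,
    is_var,
    load_schemas,
    match_schema,
)

EX = "https://example.org/"


def brute_force_match(schema, graph, anchor):
    """Exhaustive subgraph enumeration: try every assignment of graph triples
    to the schema's (required) templates and keep the consistent ones.
    Independent of the matcher's join order and indexing."""
    triples = list(graph)
    templates = schema.required_templates()
    solutions = set()
    for combo in itertools.product(triples, repeat=len(templates)):
        env = {schema.subject_var: anchor}
        ok = True
        for template, triple in zip(templates, combo):
            for slot, term in zip(template, triple.terms()):
                if is_var(slot):
                    if slot in env:
                        if env[slot] != term:
                            ok = False
                            break
                    else:
                        env[slot] = term
                else:
                    if slot != term:
                        ok = False
                        break
            if not ok:
                break
        if ok:
            solutions.add(
                (
                    tuple(sorted((v, str(t)) for v, t in env.items())),
                    frozenset(combo),
                )
            )
    return solutions


def projection(bindings):
    return {
        (
            tuple(sorted((v, str(t)) for v, t in b.mapping)),
            b.matched_triples,
        )
        for b in bindings
    }


class TestDialect:
    def test_empty_file_gives_empty_list(self):
        assert load_schemas("") == []

    def test_load_dump_round_trip_bit_exact(self):
        text = dump_schemas(builtin_schemas())
        assert dump_schemas(load_schemas(text)) == text

    def test_unbound_object_var_is_schema_error(self):
        bad = StatementUnitSchema(
            class_upri=EX + "Bad",
            label="bad",
            subject_var="?s",
            object_vars=[("?ghost", True)],
            triple_templates=[("?s", EX + "p", "?o")],
        )
        with pytest.raises(SchemaError):
            bad.validate()

    def test_binary_property_needs_single_template(self):
        bad = StatementUnitSchema(
            class_upri=EX + "Bad",
            label="bad",
            subject_var="?s",
            object_vars=[("?o", True)],
            triple_templates=[("?s", EX + "p", "?o"), ("?s", EX + "q", "?o")],
            relation_kind="binary-property",
        )
        with pytest.raises(SchemaError):
            bad.validate()

    def test_duplicate_class_rejected(self):
        text = dump_schemas([builtin_schemas()[0]] * 1)
        doc = text + text.split("schemas:\n")[1]
        # simpler: duplicate within one document
        dup = dump_schemas(builtin_schemas()[:1] + builtin_schemas()[:1])
        with pytest.raises(SchemaError, match="duplicate"):
            load_schemas(dup)

    def test_curie_expansion(self):
        text = """
prefixes:
  ex: https://example.org/
schemas:
  - class: ex:PartSchema
    label: part
    kind: binary-property
    subject: "?s"
    objects: ["?o"]
    templates:
      - ["?s", obo:BFO_0000051, "?o"]
"""
        (schema,) = load_schemas(text)
        assert schema.class_upri == EX + "PartSchema"
        assert schema.triple_templates[0][1] == vocab.HAS_PART


class TestBuiltins:
    def test_has_part_is_single_template_binary(self):
        by_class = {s.class_upri: s for s in builtin_schemas()}
        has_part = by_class[vocab.HAS_PART_STATEMENT_UNIT]
        assert len(has_part.triple_templates) == 1
        assert has_part.relation_kind == "binary-property"

    def test_located_in_at_time_needs_two_triples(self):
        by_class = {s.class_upri: s for s in builtin_schemas()}
        located = by_class[vocab.LOCATED_IN_AT_TIME_STATEMENT_UNIT]
        assert len(located.triple_templates) >= 2

    def test_all_builtins_validate(self):
        for schema in builtin_schemas():
            schema.validate()  # no exception

    def test_expected_library_present(self):
        classes = {s.class_upri for s in builtin_schemas()}
        assert {
            vocab.HAS_PART_STATEMENT_UNIT,
            vocab.TYPE_STATEMENT_UNIT,
            vocab.METRIC_MEASUREMENT_STATEMENT_UNIT,
            vocab.LOCATED_IN_AT_TIME_STATEMENT_UNIT,
            vocab.IS_ABOUT_STATEMENT_UNIT,
            vocab.LIST_MEMBERSHIP_STATEMENT_UNIT,
            vocab.ASSERTS_STATEMENT_UNIT,
        } <= classes


class TestMatching:
    def test_anchor_missing_is_precondition_violation(self):
        schema = builtin_schemas()[0]
        with pytest.raises(ValueError, match="anchor"):
            match_schema(schema, DataGraph(), EX + "nothing")

    def test_single_planted_measurement(self):
        from semantic_units.fixtures import weight_schema, _measurement

        g = DataGraph()
        triples = _measurement(g, EX + "apple", EX + "m/", "204.56", EX + "gram")
        bindings = match_schema(weight_schema(), g, EX + "apple")
        assert len(bindings) == 1
        assert bindings[0]["?value"] == Literal("204.56", vocab.XSD_DECIMAL)
        assert bindings[0]["?unit"] == EX + "gram"
        assert bindings[0].matched_triples == frozenset(triples)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_equal_brute_force_on_random_graphs(self, seed):
        """Two planted pattern instances on distinct anchors plus noise:
        bindings equal exhaustive enumeration (oracle graphs kept small —
        the oracle is O(|graph|^templates))."""
        from semantic_units.fixtures import weight_schema, _measurement

        rng = random.Random(seed)
        g = DataGraph()
        anchors = []
        for k in range(2):
            anchor = EX + f"subj{k}"
            anchors.append(anchor)
            _measurement(g, anchor, EX + f"m{k}/", f"{k}.5", EX + f"unit{k}")
        for k in range(2):  # noise triples reusing pattern predicates
            g.add(
                Triple(
                    EX + f"n{rng.randint(0, 3)}",
                    rng.choice([vocab.HAS_QUALITY, EX + "p"]),
                    EX + f"n{rng.randint(0, 3)}",
                )
            )
        schema = weight_schema()
        for anchor in anchors + [EX + "n0"]:
            if anchor not in g.terms():
                continue
            got = projection(match_schema(schema, g, anchor))
            expected = brute_force_match(schema, g, anchor)
            assert got == expected, anchor

    @pytest.mark.parametrize("seed", range(4))
    def test_binary_schema_equals_brute_force(self, seed):
        rng = random.Random(100 + seed)
        by_class = {s.class_upri: s for s in builtin_schemas()}
        schema = by_class[vocab.HAS_PART_STATEMENT_UNIT]
        g = DataGraph()
        for _ in range(12):
            g.add(
                Triple(
                    EX + f"n{rng.randint(0, 5)}",
                    rng.choice([vocab.HAS_PART, EX + "p"]),
                    EX + f"n{rng.randint(0, 5)}",
                )
            )
        for anchor in sorted(g.subjects()):
            assert projection(match_schema(schema, g, anchor)) == brute_force_match(
                schema, g, anchor
            )

    def test_optional_variable_bound_when_matchable(self):
        schema = StatementUnitSchema(
            class_upri=EX + "Opt",
            label="optional",
            subject_var="?s",
            object_vars=[("?o", True), ("?extra", False)],
            triple_templates=[
                ("?s", EX + "p", "?o"),
                ("?s", EX + "q", "?extra"),
            ],
        )
        schema.validate()
        g = DataGraph([Triple(EX + "a", EX + "p", EX + "b")])
        (b1,) = match_schema(schema, g, EX + "a")
        assert "?extra" not in b1.as_dict()
        g.add(Triple(EX + "a", EX + "q", EX + "c"))
        (b2,) = match_schema(schema, g, EX + "a")
        assert b2["?extra"] == EX + "c"
        assert len(b2.matched_triples) == 2

    def test_matching_is_anchor_local(self):
        """Adding triples that mention no bound term leaves bindings unchanged."""
        from semantic_units.fixtures import weight_schema, _measurement

        g = DataGraph()
        _measurement(g, EX + "a", EX + "m/", "1.0", EX + "u")
        before = match_schema(weight_schema(), g, EX + "a")
        g.add(Triple(EX + "far", EX + "away", EX + "triple"))
        g.add(Triple(EX + "far2", EX + "p", Literal("x")))
        after = match_schema(weight_schema(), g, EX + "a")
        assert before == after

    def test_no_match_returns_empty_list(self):
        g = DataGraph([Triple(EX + "a", EX + "p", EX + "b")])
        by_class = {s.class_upri: s for s in builtin_schemas()}
        assert match_schema(
            by_class[vocab.METRIC_MEASUREMENT_STATEMENT_UNIT], g, EX + "a"
        ) == []
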