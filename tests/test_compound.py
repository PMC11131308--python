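"""Compound-unit builders, display patterns, profiling and redaction."""

import pytest

from semantic_units import vocab
from semantic_units.compound import (
    ContextUnit,
    GranularItemGroupUnit,
    GranularityTreeUnit,
    ItemGroupUnit,
    ItemUnit,
    ListUnit,
    TypedStatementUnit,
    build_context_units,
    build_granular_item_group,
    build_granularity_trees,
    build_item_group_units,
    build_item_units,
    build_typed_statement_unit,
    compound_all,
    granularity_levels,
    make_dataset_unit,
    make_list_unit,
    redact,
    render_dynamic_label,
    render_mind_map,
)
from semantic_units.errors import (
    CardinalityViolation,
    UniquenessViolation,
    UnresolvedMemberError,
)
from semantic_units.fixtures import FixtureSpec, generate_store
from semantic_units.model import (
    DataGraph,
    KnowledgeGraphStore,
    Literal,
    StatementUnit,
    Triple,
)
from semantic_units.partition import organize
from semantic_units.schema import builtin_schemas

EX = "https://example.org/"
ID_CLASSES = vocab.IDENTIFICATION_UNIT_CLASSES


class TestTypedStatementUnit:
    def test_apple_typed_unit_has_six_members(self, apple):
        store, _, _ = apple
        (tsu,) = [
            u for u in store.compound_units() if isinstance(u, TypedStatementUnit)
        ]
        assert len(tsu.associated_units) == 6
        assert len(tsu.identification_units) == 5
        ref = store.get(tsu.reference_unit)
        assert ref.unit_class == vocab.WEIGHT_STATEMENT_UNIT
        assert tsu.subject == ref.subject

    def test_identification_unit_rejected_as_reference(self, apple):
        store, _, _ = apple
        id_unit = next(
            u for u in store.statement_units() if u.unit_class in ID_CLASSES
        )
        with pytest.raises(ValueError):
            build_typed_statement_unit(id_unit, store)

    def test_missing_identifications_reported(self):
        g = DataGraph([Triple(EX + "a", EX + "p", EX + "b")])
        store, _ = organize(g, [])
        (ref,) = store.statement_units()
        tsu = build_typed_statement_unit(ref, store)
        assert len(tsu.associated_units) == 1
        assert set(tsu.missing_identifications) == {EX + "a", EX + "b"}

    def test_members_equal_exhaustive_identification_scan(self, small_random):
        store = small_random[0]
        id_by_resource = {}
        for u in store.statement_units():
            if u.unit_class in ID_CLASSES:
                id_by_resource.setdefault(u.subject, set()).add(u.upri)
        for tsu in store.compound_units():
            if not isinstance(tsu, TypedStatementUnit):
                continue
            ref = store.get(tsu.reference_unit)
            expected = set()
            for r in ref.data_graph.resources():
                expected |= id_by_resource.get(r, set())
            assert set(tsu.identification_units) == expected


class TestDisplayPatterns:
    def test_dynamic_label_from_template(self, apple):
        store, _, _ = apple
        (tsu,) = [
            u for u in store.compound_units() if isinstance(u, TypedStatementUnit)
        ]
        assert render_dynamic_label(tsu, store) == "apple X has weight 204.56 gram"

    def test_template_without_placeholders_verbatim(self, apple):
        store, _, _ = apple
        (tsu,) = [
            u for u in store.compound_units() if isinstance(u, TypedStatementUnit)
        ]
        schema = store.schemas[vocab.WEIGHT_STATEMENT_UNIT]
        original = schema.dynamic_label_template
        try:
            schema.dynamic_label_template = "a fixed label"
            assert render_dynamic_label(tsu, store) == "a fixed label"
        finally:
            schema.dynamic_label_template = original

    def test_unlabeled_resource_falls_back_to_curie(self):
        g = DataGraph()
        from semantic_units.fixtures import _measurement, weight_schema

        _measurement(g, vocab.OBO + "X_1", EX + "m/", "1.0", vocab.OBO + "UO_0000021")
        store, _ = organize(g, [weight_schema()])
        (ref,) = [
            u for u in store.statement_units() if u.unit_class not in ID_CLASSES
        ]
        tsu = build_typed_statement_unit(ref, store)
        label = render_dynamic_label(tsu, store)
        assert "obo:X_1" in label and "obo:UO_0000021" in label

    def test_mind_map_is_valid_dot_with_expected_nodes(self, apple):
        store, _, _ = apple
        (tsu,) = [
            u for u in store.compound_units() if isinstance(u, TypedStatementUnit)
        ]
        dot = render_mind_map(tsu, store)
        assert dot.startswith("digraph") and dot.rstrip().endswith("}")
        assert '"apple X"' in dot and '"204.56"' in dot and '"gram"' in dot
        assert dot.count("->") == 2

    def test_mind_map_node_count_equals_bound_slots(self, small_random):
        store = small_random[0]
        for tsu in store.compound_units():
            if not isinstance(tsu, TypedStatementUnit):
                continue
            ref = store.get(tsu.reference_unit)
            schema = store.schemas.get(ref.schema_ref)
            if schema is None or not schema.mind_map_template:
                continue
            bound_slots = [v for v, _ in schema.object_vars if v in ref.bindings]
            dot = render_mind_map(tsu, store)
            assert dot.count("->") == len(bound_slots)


class TestItemUnits:
    def test_one_item_unit_per_subject(self, apple):
        store, truth, _ = apple
        items = [u for u in store.compound_units() if isinstance(u, ItemUnit)]
        assert {i.subject for i in items} == set(truth.item_units)

    def test_grouping_equals_brute_force_group_by(self, small_random):
        store = small_random[0]
        expected = {}
        for u in store.statement_units():
            if u.unit_class in ID_CLASSES or u.subject in store.units:
                continue
            expected.setdefault(u.subject, set()).add(u.upri)
        items = {
            u.subject: set(u.associated_units)
            for u in store.compound_units()
            if isinstance(u, ItemUnit)
        }
        assert items == expected

    def test_item_units_partition_non_identification_units(self, small_random):
        store = small_random[0]
        counts = {}
        for item in store.compound_units():
            if isinstance(item, ItemUnit):
                for m in item.associated_units:
                    counts[m] = counts.get(m, 0) + 1
        groupable = [
            u.upri
            for u in store.statement_units()
            if u.unit_class not in ID_CLASSES and u.subject not in store.units
        ]
        assert sorted(counts) == sorted(groupable)
        assert all(c == 1 for c in counts.values())


class TestItemGroupUnits:
    def test_two_items_bridged_by_has_part(self):
        g = DataGraph()
        for name in ("hand", "thumb"):
            g.add(Triple(EX + name, vocab.RDF_TYPE, EX + "Part"))
            g.add(Triple(EX + name, vocab.RDFS_LABEL, Literal(name)))
        g.add(Triple(EX + "hand", vocab.HAS_PART, EX + "thumb"))
        g.add(Triple(EX + "thumb", EX + "touches", EX + "hand"))
        store, _ = organize(g, builtin_schemas())
        build_item_units(store)
        groups = build_item_group_units(store)
        assert len(groups) == 1
        assert len(groups[0].item_units) == 2
        merged = store.merged_data_graph(groups[0])
        assert len(merged) > 0

    def test_no_bridges_no_groups(self):
        g = DataGraph(
            [
                Triple(EX + "a", EX + "p", Literal("1")),
                Triple(EX + "b", EX + "q", Literal("2")),
            ]
        )
        store, _ = organize(g, builtin_schemas())
        build_item_units(store)
        assert build_item_group_units(store) == []

    def test_groups_equal_connected_components_oracle(self, small_random):
        store, truth, _, summary = small_random
        # brute-force edge enumeration over bridging units
        item_subjects = {
            u.subject for u in store.compound_units() if isinstance(u, ItemUnit)
        }
        parent = {s: s for s in item_subjects}

        def find(x):
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for u in store.statement_units():
            if u.unit_class in ID_CLASSES or u.subject not in item_subjects:
                continue
            for obj in u.objects:
                if isinstance(obj, Literal) or obj not in item_subjects:
                    continue
                ra, rb = find(u.subject), find(obj)
                if ra != rb:
                    parent[ra] = rb
        comps = {}
        for s in item_subjects:
            comps.setdefault(find(s), set()).add(s)
        expected = {frozenset(c) for c in comps.values() if len(c) >= 2}
        got = {
            frozenset(store.units[m].subject for m in u.item_units)
            for u in store.compound_units()
            if isinstance(u, ItemGroupUnit)
        }
        assert got == expected == truth.item_groups

    def test_group_merged_graph_weakly_connected(self, publication):
        store, _, _ = publication
        import networkx as nx

        for group in store.compound_units():
            if not isinstance(group, ItemGroupUnit):
                continue
            merged = store.merged_data_graph(group)
            g = nx.Graph()
            for t in merged:
                obj = t.object if isinstance(t.object, str) else ("lit", str(t.object))
                g.add_edge(t.subject, obj)
            assert nx.is_connected(g)


class TestGranularityTrees:
    def test_parthood_chain_gives_rooted_tree(self):
        g = DataGraph()
        for a, b in [("organism", "head"), ("head", "eye")]:
            g.add(Triple(EX + a, vocab.HAS_PART, EX + b))
        store, _ = organize(g, builtin_schemas())
        trees, rejections = build_granularity_trees(store, [vocab.HAS_PART])
        assert rejections == []
        (tree,) = trees
        assert tree.root == EX + "organism"
        assert tree.parents == {EX + "head": EX + "organism", EX + "eye": EX + "head"}

    def test_single_unit_tree_root_is_subject(self):
        g = DataGraph([Triple(EX + "a", vocab.HAS_PART, EX + "b")])
        store, _ = organize(g, builtin_schemas())
        (tree,), _ = build_granularity_trees(store, [vocab.HAS_PART])
        assert tree.root == EX + "a" and tree.nodes() == {EX + "a", EX + "b"}

    def test_cycle_component_rejected_acyclic_kept(self):
        store, truth, _ = generate_store(FixtureSpec(seed=5, plant_cycle=True))
        trees, rejections = build_granularity_trees(store, [vocab.HAS_PART])
        assert {frozenset(r["nodes"]) for r in rejections} == (
            truth.rejected_tree_components
        )
        got = {
            (t.relation, t.root, frozenset((p, c) for c, p in t.parents.items()))
            for t in trees
        }
        assert got == truth.trees

    def test_multi_parent_rejected(self):
        g = DataGraph(
            [
                Triple(EX + "a", vocab.HAS_PART, EX + "c"),
                Triple(EX + "b", vocab.HAS_PART, EX + "c"),
            ]
        )
        store, _ = organize(g, builtin_schemas())
        trees, rejections = build_granularity_trees(store, [vocab.HAS_PART])
        assert trees == [] and len(rejections) == 1

    def test_accepted_trees_are_trees(self, small_random):
        store = small_random[0]
        for tree in store.compound_units():
            if not isinstance(tree, GranularityTreeUnit):
                continue
            nodes = tree.nodes()
            edges = list(tree.parents.items())
            assert len(edges) == len(nodes) - 1
            roots = nodes - set(tree.parents)
            assert roots == {tree.root}


class TestGranularItemGroup:
    def test_nesting_follows_tree(self):
        g = DataGraph()
        for a, b in [("organism", "head"), ("head", "eye")]:
            g.add(Triple(EX + a, vocab.HAS_PART, EX + b))
        g.add(Triple(EX + "eye", EX + "sees", Literal("light")))
        store, _ = organize(g, builtin_schemas())
        build_item_units(store)
        (tree,), _ = build_granularity_trees(store, [vocab.HAS_PART])
        gig = build_granular_item_group(tree, store)
        items = {
            u.subject: u.upri
            for u in store.compound_units()
            if isinstance(u, ItemUnit)
        }
        # organism and head are item subjects (parthood units), eye too (sees)
        assert gig.nesting[items[EX + "organism"]] is None
        assert gig.nesting[items[EX + "head"]] == items[EX + "organism"]
        assert gig.nesting[items[EX + "eye"]] == items[EX + "head"]

    def test_nesting_equals_ancestor_ordering_oracle(self, small_random):
        store = small_random[0]
        for gig in store.compound_units():
            if not isinstance(gig, GranularItemGroupUnit):
                continue
            tree = store.get(gig.tree)
            items_by_subject = {
                u.subject: u.upri
                for u in store.compound_units()
                if isinstance(u, ItemUnit)
            }

            def nearest_item_ancestor(node):
                cur = tree.parents.get(node)
                while cur is not None and cur not in items_by_subject:
                    cur = tree.parents.get(cur)
                return items_by_subject.get(cur) if cur else None

            for item_upri, parent_upri in gig.nesting.items():
                subject = store.get(item_upri).subject
                assert parent_upri == nearest_item_ancestor(subject)


class TestContextUnits:
    def test_publication_store_splits_at_is_about(self, publication):
        store, truth, _ = publication
        contexts = [u for u in store.compound_units() if isinstance(u, ContextUnit)]
        assert len(contexts) >= 2
        assert len(contexts) == truth.n_context_units
        frames = {c.frame for c in contexts}
        assert "discursive" in frames and "ontological" in frames

    def test_no_is_about_single_context(self, apple):
        store, _, _ = apple
        contexts = [u for u in store.compound_units() if isinstance(u, ContextUnit)]
        assert len(contexts) == 1

    def test_link_table_joins_two_regions(self, publication):
        store, _, _ = publication
        store2 = store.copy_shallow()
        contexts, links = build_context_units(store2)
        assert len(links) == 1
        (_, region_a, region_b) = links[0]
        assert region_a is not None and region_b is not None
        assert region_a != region_b

    def test_regions_equal_components_oracle(self, small_random):
        store, truth, _, summary = small_random
        contexts = summary["context_units"]
        assert len(contexts) == truth.n_context_units
        # every non-is-about statement unit in exactly one context unit
        counted = {}
        for c in contexts:
            for m in c.associated_units:
                counted[m] = counted.get(m, 0) + 1
        non_is_about = [
            u.upri
            for u in store.statement_units()
            if u.unit_class != vocab.IS_ABOUT_STATEMENT_UNIT
        ]
        assert sorted(counted) == sorted(non_is_about)
        assert all(v == 1 for v in counted.values())


class TestDatasetAndListUnits:
    def test_dataset_preserves_order(self, apple):
        store, _, _ = apple
        store = store.copy_shallow()
        members = [u.upri for u in store.statement_units()[:3]]
        ds = make_dataset_unit(members, store)
        assert ds.associated_units == members

    def test_dataset_empty_rejected(self, apple):
        store, _, _ = apple
        with pytest.raises(ValueError):
            make_dataset_unit([], store.copy_shallow())

    def test_dataset_dangling_member_rejected(self, apple):
        store, _, _ = apple
        with pytest.raises(UnresolvedMemberError):
            make_dataset_unit([EX + "ghost"], store.copy_shallow())

    def test_ordered_list_indices_one_to_n(self):
        store = KnowledgeGraphStore()
        lu = make_list_unit([EX + "A", EX + "B"], "ordered", store)
        assert sorted(lu.indices.values()) == [1, 2]
        first = store.get(lu.associated_units[0])
        assert first.unit_class == vocab.LIST_MEMBERSHIP_STATEMENT_UNIT
        assert lu.indices[lu.associated_units[0]] == 1
        # index literals live in the semantic-units layer
        index_triples = [
            t
            for t in store.semantic_units_layer
            if t.predicate == store.namespace.index
        ]
        assert len(index_triples) == 2

    def test_set_duplicate_rejected(self):
        store = KnowledgeGraphStore()
        with pytest.raises(UniquenessViolation):
            make_list_unit([EX + "A", EX + "A"], "set", store)

    def test_cardinality_bracket_enforced(self):
        store = KnowledgeGraphStore()
        with pytest.raises(CardinalityViolation):
            make_list_unit(
                [EX + "A", EX + "B", EX + "C"], "ordered", store, cardinality=(2, 2)
            )
        make_list_unit([EX + "A", EX + "B"], "unordered", store, cardinality=(2, 2))


class TestGranularityLevels:
    def test_empty_store(self):
        assert granularity_levels(KnowledgeGraphStore()) == []

    def test_statement_units_only(self):
        g = DataGraph([Triple(EX + "s", EX + "p", EX + "o")])
        store, _ = organize(g, [])
        assert granularity_levels(store) == [
            "triple",
            "statement_unit",
            "knowledge_graph",
        ]

    def test_fully_organized_has_all_five(self, publication):
        store, _, _ = publication
        assert granularity_levels(store) == [
            "triple",
            "statement_unit",
            "item_unit",
            "item_group_unit",
            "knowledge_graph",
        ]


class TestRedact:
    def test_empty_restriction_is_identity(self, apple):
        store, _, _ = apple
        view = redact(store, set())
        assert view.data_layer == store.data_layer
        assert set(view.units) == set(store.units)

    def test_weight_class_redacted_identifications_remain(self, apple):
        store, _, _ = apple
        view = redact(store, {vocab.WEIGHT_STATEMENT_UNIT})
        assert not view.units_of_class(vocab.WEIGHT_STATEMENT_UNIT)
        assert view.units_of_class(vocab.NAMED_INDIVIDUAL_IDENTIFICATION_UNIT)
        (weight,) = store.units_of_class(vocab.WEIGHT_STATEMENT_UNIT)
        for t in weight.data_graph:
            assert t not in view.data_layer
        # original untouched
        assert store.units_of_class(vocab.WEIGHT_STATEMENT_UNIT)

    def test_remaining_triples_equal_set_difference_oracle(self, small_random):
        store = small_random[0]
        cls = vocab.METRIC_MEASUREMENT_STATEMENT_UNIT
        view = redact(store, {cls})
        removed = set()
        for u in store.statement_units():
            if u.unit_class == cls:
                removed |= set(u.data_graph.as_set())
        assert view.data_layer.as_set() == store.data_layer.as_set() - removed

    def test_merge_back_reproduces_original(self, small_random):
        store = small_random[0]
        cls = vocab.HAS_PART_STATEMENT_UNIT
        view = redact(store, {cls})
        removed_units = {
            upri for upri in store.units if upri not in view.units
        }
        removed_triples = set()
        for upri in removed_units:
            u = store.units[upri]
            if isinstance(u, StatementUnit):
                removed_triples |= set(u.data_graph.as_set())
        assert (
            view.data_layer.as_set() | removed_triples
            == store.data_layer.as_set()
        )
        assert set(view.units) | removed_units == set(store.units)


def test_compound_all_is_idempotent(apple):
    store, _, _ = apple
    store = store.copy_shallow()
    first = compound_all(store)
    second = compound_all(store)
    assert len(first["item_units"]) == len(second["item_units"])
    assert len(store.units) == len(
        {u.upri for u in store.units.values()}
    )
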