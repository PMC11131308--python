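"""Compound units: containers built on top of the statement-unit partition.

Implements the full taxonomy of compound-unit subcategories — typed
statement units (with dynamic labels and mind maps), item units, item group
units, granularity tree units, granular item groups, context units, dataset
units and list units — plus the five-level granularity profile and
class-based redaction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx

from . import vocab
from .errors import (
    CardinalityViolation,
    UniquenessViolation,
    UnresolvedMemberError,
    UnsupportedOperation,
)
from .model import (
    CompoundUnit,
    DataGraph,
    KnowledgeGraphStore,
    Literal,
    StatementUnit,
    Term,
    Triple,
    UPRI,
)
__all__ = [
    "TypedStatementUnit",
    "ItemUnit",
    "ItemGroupUnit",
    "GranularityTreeUnit",
    "GranularItemGroupUnit",
    "ContextUnit",
    "DatasetUnit",
    "ListUnit",
    "build_typed_statement_unit",
    "render_dynamic_label",
    "render_mind_map",
    "build_item_units",
    "build_item_group_units",
    "build_granularity_trees",
    "build_granular_item_group",
    "build_context_units",
    "make_dataset_unit",
    "make_list_unit",
    "granularity_levels",
    "redact",
    "compound_all",
]

_ID_CLASSES = vocab.IDENTIFICATION_UNIT_CLASSES


# ---------------------------------------------------------------------------
# compound-unit subtypes


@dataclass
class TypedStatementUnit(CompoundUnit):
    reference_unit: UPRI = ""
    identification_units: list[UPRI] = field(default_factory=list)
    missing_identifications: list[UPRI] = field(default_factory=list)


@dataclass
class ItemUnit(CompoundUnit):
    """All non-identification statement units sharing one subject."""


@dataclass
class ItemGroupUnit(CompoundUnit):
    item_units: list[UPRI] = field(default_factory=list)
    bridge_units: list[UPRI] = field(default_factory=list)


@dataclass
class GranularityTreeUnit(CompoundUnit):
    relation: UPRI = ""
    root: UPRI = ""
    #: node -> parent node, over the resources of the tree
    parents: dict[UPRI, UPRI] = field(default_factory=dict)

    def nodes(self) -> set[UPRI]:
        out = set(self.parents)
        out.update(self.parents.values())
        return out


@dataclass
class GranularItemGroupUnit(CompoundUnit):
    tree: UPRI = ""
    #: item-unit UPRI -> parent item-unit UPRI (None for the root's item unit)
    nesting: dict[UPRI, Optional[UPRI]] = field(default_factory=dict)


@dataclass
class ContextUnit(CompoundUnit):
    frame: str = "ontological"  # ontological | discursive | a named frame


@dataclass
class DatasetUnit(CompoundUnit):
    """Ordered set of semantic units; order is the associated_units order."""


@dataclass
class ListUnit(CompoundUnit):
    kind: str = "unordered"  # ordered | unordered | set
    member_resources: list[UPRI] = field(default_factory=list)
    #: membership-unit UPRI -> 1-based index (ordered lists only)
    indices: dict[UPRI, int] = field(default_factory=dict)
    cardinality: Optional[tuple[int, int]] = None


# ---------------------------------------------------------------------------
# typed statement units, dynamic labels, mind maps


def _put(store: KnowledgeGraphStore, unit: CompoundUnit) -> bool:
    """Register a builder-derived unit; replace in place when re-building an
    already-compounded store (builders mint deterministic UPRIs)."""
    if unit.upri in store.units:
        store.units[unit.upri] = unit
        return True
    store.register(unit)
    return False




def _identification_index(store: KnowledgeGraphStore) -> dict[UPRI, list[StatementUnit]]:
    out: dict[UPRI, list[StatementUnit]] = {}
    for unit in store.statement_units():
        if unit.unit_class in _ID_CLASSES:
            out.setdefault(unit.subject, []).append(unit)
    return out


def build_typed_statement_unit(
    ref: StatementUnit,
    store: KnowledgeGraphStore,
    _index: dict[UPRI, list[StatementUnit]] | None = None,
) -> TypedStatementUnit:
    """Compound of a reference statement unit plus the identification units
    of every resource its data graph mentions."""
    if ref.unit_class in _ID_CLASSES:
        raise ValueError("reference unit must not be an identification unit")
    upri = store.namespace.mint("typed-statement-unit", ref.upri)
    if upri in store.units:  # idempotent: one typed unit per reference unit
        existing = store.units[upri]
        assert isinstance(existing, TypedStatementUnit)
        return existing
    index = _index if _index is not None else _identification_index(store)
    id_units: list[UPRI] = []
    missing: list[UPRI] = []
    for resource in sorted(ref.data_graph.resources()):
        found = index.get(resource, [])
        if found:
            id_units.extend(u.upri for u in found)
        else:
            missing.append(resource)
    id_units = sorted(set(id_units))
    tsu = TypedStatementUnit(
        upri=upri,
        provenance=store.new_provenance(),
        unit_class=vocab.TYPED_STATEMENT_UNIT,
        subject=ref.subject,
        associated_units=[ref.upri] + id_units,
        reference_unit=ref.upri,
        identification_units=id_units,
        missing_identifications=missing,
    )
    tsu.validate()
    store.register(tsu)
    return tsu


def label_of(term: Term, store: KnowledgeGraphStore) -> str:
    """Human-readable label of a term: literal lexical form, the label
    carried by the term's identification unit, or a CURIE fallback."""
    if isinstance(term, Literal):
        return term.lexical
    for unit in store.statement_units():
        if unit.unit_class in _ID_CLASSES and unit.subject == term:
            for t in unit.data_graph:
                if t.predicate == vocab.RDFS_LABEL and isinstance(t.object, Literal):
                    return t.object.lexical
    return vocab.compact_iri(term)


class _TemplateMap(dict):
    def __missing__(self, key: str) -> str:  # leave unknown placeholders intact
        return "{" + key + "}"


def _template_values(
    tsu: TypedStatementUnit, store: KnowledgeGraphStore
) -> _TemplateMap:
    ref = store.get(tsu.reference_unit)
    assert isinstance(ref, StatementUnit)
    values = _TemplateMap()
    values["subject"] = label_of(ref.subject, store)
    for i, obj in enumerate(ref.objects, start=1):
        values[f"object{i}"] = label_of(obj, store)
    for var, term in ref.bindings.items():
        values[var.lstrip("?")] = label_of(term, store)
    return values


def _schema_for(tsu: TypedStatementUnit, store: KnowledgeGraphStore):
    ref = store.get(tsu.reference_unit)
    return store.schemas.get(getattr(ref, "schema_ref", None))


def render_dynamic_label(tsu: TypedStatementUnit, store: KnowledgeGraphStore) -> str:
    """Fill the reference unit's display template with labels drawn from the
    typed unit's identification units; deterministic."""
    schema = _schema_for(tsu, store)
    if schema is None or not schema.dynamic_label_template:
        raise UnsupportedOperation("reference unit schema has no dynamic label")
    return schema.dynamic_label_template.format_map(_template_values(tsu, store))


def render_mind_map(tsu: TypedStatementUnit, store: KnowledgeGraphStore) -> str:
    """DOT digraph of the reference statement: subject node connected to one
    node per bound object slot."""
    schema = _schema_for(tsu, store)
    if schema is None or not schema.mind_map_template:
        raise UnsupportedOperation("reference unit schema has no mind map template")
    ref = store.get(tsu.reference_unit)
    assert isinstance(ref, StatementUnit)
    subject_label = label_of(ref.subject, store)
    lines = ["digraph mindmap {"]
    lines.append(f'  "{_dot_escape(subject_label)}";')
    edges = []
    for var, required in schema.object_vars:
        if var not in ref.bindings:
            continue
        obj_label = label_of(ref.bindings[var], store)
        lines.append(f'  "{_dot_escape(obj_label)}";')
        edges.append(
            f'  "{_dot_escape(subject_label)}" -> "{_dot_escape(obj_label)}" '
            f'[label="{var.lstrip("?")}"];'
        )
    lines.extend(edges)
    lines.append("}")
    return "\n".join(lines)


def _dot_escape(text: str) -> str:
    return text.replace("\\", "\\\\").replace('"', '\\"')


# ---------------------------------------------------------------------------
# item units and item group units


def _groupable_units(store: KnowledgeGraphStore) -> list[StatementUnit]:
    """Statement units that participate in item grouping: everything except
    identification units and meta-level units whose subject is itself a
    registered semantic unit (e.g. list membership units)."""
    return [
        u
        for u in store.statement_units()
        if u.unit_class not in _ID_CLASSES and u.subject not in store.units
    ]


def build_item_units(store: KnowledgeGraphStore) -> list[ItemUnit]:
    """One item unit per distinct statement-unit subject; members partition
    the non-identification statement units by subject."""
    by_subject: dict[UPRI, list[UPRI]] = {}
    for unit in _groupable_units(store):
        by_subject.setdefault(unit.subject, []).append(unit.upri)
    out = []
    dirty = False
    for subject in sorted(by_subject):
        members = sorted(by_subject[subject])
        item = ItemUnit(
            upri=store.namespace.mint("item-unit", subject),
            provenance=store.new_provenance(),
            unit_class=vocab.ITEM_UNIT,
            subject=subject,
            associated_units=members,
        )
        item.validate()
        dirty |= _put(store, item)
        out.append(item)
    if dirty:
        store.rebuild_semantic_units_layer()
    return out


def build_item_group_units(store: KnowledgeGraphStore) -> list[ItemGroupUnit]:
    """Group item units connected by bridging statement units (units whose
    subject is one item subject and one of whose objects is another's).
    Groups are connected components with >=2 item units; bridges become
    members alongside the item units they connect."""
    items = {
        u.subject: u for u in store.compound_units() if isinstance(u, ItemUnit)
    }
    graph = nx.Graph()
    graph.add_nodes_from(items)
    bridges_by_pair: dict[tuple[UPRI, UPRI], list[UPRI]] = {}
    for unit in _groupable_units(store):
        if unit.subject not in items:
            continue
        for obj in unit.objects:
            if isinstance(obj, Literal) or obj == unit.subject:
                continue
            if obj in items:
                pair = tuple(sorted((unit.subject, obj)))
                graph.add_edge(*pair)
                bridges_by_pair.setdefault(pair, []).append(unit.upri)
    out = []
    dirty = False
    for component in sorted(nx.connected_components(graph), key=lambda c: sorted(c)[0]):
        if len(component) < 2:
            continue
        subjects = sorted(component)
        item_upris = [items[s].upri for s in subjects]
        bridge_upris = sorted(
            {
                b
                for pair, bs in bridges_by_pair.items()
                if pair[0] in component
                for b in bs
            }
        )
        group = ItemGroupUnit(
            upri=store.namespace.mint("item-group-unit", "\n".join(subjects)),
            provenance=store.new_provenance(),
            unit_class=vocab.ITEM_GROUP_UNIT,
            associated_units=sorted(set(item_upris + bridge_upris)),
            item_units=item_upris,
            bridge_units=bridge_upris,
        )
        group.validate()
        dirty |= _put(store, group)
        out.append(group)
    if dirty:
        store.rebuild_semantic_units_layer()
    return out


# ---------------------------------------------------------------------------
# granularity trees


def build_granularity_trees(
    store: KnowledgeGraphStore, partial_order_predicates: Sequence[UPRI]
) -> tuple[list[GranularityTreeUnit], list[dict]]:
    """Per partial-order predicate, per weakly-connected component of its
    statement units: a rooted tree unit.  The root is the node that occurs
    as an object of no member unit.  Components with cycles or multiple
    parents are rejected with a diagnostic, never silently treed.
    Reflexive self-loops are dropped before tree building."""
    trees: list[GranularityTreeUnit] = []
    rejections: list[dict] = []
    dirty = False
    for predicate in partial_order_predicates:
        members_by_edge: dict[tuple[UPRI, UPRI], UPRI] = {}
        digraph = nx.DiGraph()
        for unit in store.statement_units():
            if unit.unit_class in _ID_CLASSES or len(unit.data_graph) != 1:
                continue
            (triple,) = list(unit.data_graph)
            if triple.predicate != predicate or isinstance(triple.object, Literal):
                continue
            if triple.subject == triple.object:
                continue  # reflexive statement carries no tree information
            digraph.add_edge(triple.subject, triple.object)
            members_by_edge[(triple.subject, triple.object)] = unit.upri
        for component in sorted(
            nx.weakly_connected_components(digraph), key=lambda c: sorted(c)[0]
        ):
            sub = digraph.subgraph(component)
            roots = [n for n in sub.nodes if sub.in_degree(n) == 0]
            multi_parent = [n for n in sub.nodes if sub.in_degree(n) > 1]
            acyclic = nx.is_directed_acyclic_graph(sub)
            if len(roots) != 1 or multi_parent or not acyclic:
                rejections.append(
                    {
                        "predicate": predicate,
                        "nodes": sorted(component),
                        "roots": sorted(roots),
                        "multi_parent": sorted(multi_parent),
                        "acyclic": acyclic,
                    }
                )
                continue
            root = roots[0]
            parents = {child: parent for parent, child in sub.edges}
            unit_members = sorted(
                members_by_edge[(p, c)] for p, c in sub.edges
            )
            tree = GranularityTreeUnit(
                upri=store.namespace.mint(
                    "granularity-tree-unit", predicate + "\n" + "\n".join(sorted(component))
                ),
                provenance=store.new_provenance(),
                unit_class=vocab.GRANULARITY_TREE_UNIT,
                subject=root,
                associated_units=unit_members,
                relation=predicate,
                root=root,
                parents=parents,
            )
            tree.validate()
            dirty |= _put(store, tree)
            trees.append(tree)
    if dirty:
        store.rebuild_semantic_units_layer()
    return trees, rejections


def build_granular_item_group(
    tree: GranularityTreeUnit, store: KnowledgeGraphStore
) -> GranularItemGroupUnit:
    """Item units whose subjects are tree nodes, nested per the tree."""
    items = {
        u.subject: u for u in store.compound_units() if isinstance(u, ItemUnit)
    }
    nodes = tree.nodes()
    member_items = {s: items[s] for s in sorted(nodes) if s in items}
    nesting: dict[UPRI, Optional[UPRI]] = {}
    for subject, item in member_items.items():
        parent_subject = tree.parents.get(subject)
        while parent_subject is not None and parent_subject not in member_items:
            parent_subject = tree.parents.get(parent_subject)
        nesting[item.upri] = (
            member_items[parent_subject].upri if parent_subject else None
        )
    members = sorted(u.upri for u in member_items.values())
    unit = GranularItemGroupUnit(
        upri=store.namespace.mint("granular-item-group-unit", tree.upri),
        provenance=store.new_provenance(),
        unit_class=vocab.GRANULAR_ITEM_GROUP_UNIT,
        subject=tree.root,
        associated_units=members or [tree.upri],
        tree=tree.upri,
        nesting=nesting,
    )
    unit.validate()
    if _put(store, unit):
        store.rebuild_semantic_units_layer()
    return unit


# ---------------------------------------------------------------------------
# context units


def _unit_adjacency(
    units: list[StatementUnit], store: KnowledgeGraphStore
) -> nx.Graph:
    graph = nx.Graph()
    graph.add_nodes_from(u.upri for u in units)
    by_resource: dict[UPRI, list[UPRI]] = {}
    for u in units:
        for r in u.data_graph.resources():
            by_resource.setdefault(r, []).append(u.upri)
    for upris in by_resource.values():
        for other in upris[1:]:
            graph.add_edge(upris[0], other)
    # a unit whose data graph mentions another unit's UPRI is adjacent to it
    member_upris = {u.upri for u in units}
    for u in units:
        for r in u.data_graph.resources():
            if r in member_upris and r != u.upri:
                graph.add_edge(u.upri, r)
    return graph


def build_context_units(
    store: KnowledgeGraphStore,
) -> tuple[list[ContextUnit], list[tuple[UPRI, Optional[UPRI], Optional[UPRI]]]]:
    """Split the statement-unit graph at is-about units.

    Removing the is-about statement units, the remaining statement units fall
    into connected regions; each region becomes a context unit.  The link
    table records which is-about unit joins which two context units.  A
    region whose units make statements about other semantic units (their
    data graphs reference registered unit UPRIs) is tagged discursive,
    otherwise ontological.
    """
    statement_units = store.statement_units()
    is_about = [
        u for u in statement_units if u.unit_class == vocab.IS_ABOUT_STATEMENT_UNIT
    ]
    rest = [
        u for u in statement_units if u.unit_class != vocab.IS_ABOUT_STATEMENT_UNIT
    ]
    adjacency = _unit_adjacency(rest, store)
    contexts: list[ContextUnit] = []
    dirty = False
    region_of_term: dict[UPRI, UPRI] = {}
    rest_by_upri = {u.upri: u for u in rest}
    for component in sorted(
        nx.connected_components(adjacency), key=lambda c: sorted(c)[0]
    ):
        members = sorted(component)
        discursive = any(
            r in store.units
            for m in members
            for r in rest_by_upri[m].data_graph.resources()
        )
        unit = ContextUnit(
            upri=store.namespace.mint("context-unit", "\n".join(members)),
            provenance=store.new_provenance(),
            unit_class=vocab.CONTEXT_UNIT,
            associated_units=members,
            frame="discursive" if discursive else "ontological",
        )
        unit.validate()
        dirty |= _put(store, unit)
        contexts.append(unit)
        for m in members:
            region_of_term[m] = unit.upri
            for r in rest_by_upri[m].data_graph.resources():
                region_of_term.setdefault(r, unit.upri)
    if dirty:
        store.rebuild_semantic_units_layer()
    links = []
    for unit in sorted(is_about, key=lambda u: u.upri):
        subject_region = region_of_term.get(unit.subject)
        object_region = None
        for obj in unit.objects:
            if not isinstance(obj, Literal):
                object_region = region_of_term.get(obj)
                break
        links.append((unit.upri, subject_region, object_region))
    return contexts, links


# ---------------------------------------------------------------------------
# dataset and list units


def make_dataset_unit(
    member_upris: Sequence[UPRI], store: KnowledgeGraphStore
) -> DatasetUnit:
    if not member_upris:
        raise ValueError("dataset unit requires a non-empty member sequence")
    for m in member_upris:
        if m not in store.units:
            raise UnresolvedMemberError(f"dataset member not registered: {m}")
    unit = DatasetUnit(
        upri=store.namespace.mint("dataset-unit", "\n".join(member_upris)),
        provenance=store.new_provenance(),
        unit_class=vocab.DATASET_UNIT,
        associated_units=list(member_upris),
    )
    unit.validate()
    store.register(unit)
    return unit


def make_list_unit(
    members: Sequence[UPRI],
    kind: str,
    store: KnowledgeGraphStore,
    cardinality: Optional[tuple[int, int]] = None,
) -> ListUnit:
    """Collection of resources as a list unit.

    Membership statement units link the list's UPRI to each resource via the
    child relation; ordered lists index the membership units 1..n; set lists
    reject duplicate resources; a declared cardinality must bracket the
    member count.
    """
    if kind not in ("ordered", "unordered", "set"):
        raise ValueError(f"unknown list kind: {kind}")
    if not members:
        raise ValueError("list unit requires at least one member")
    if kind == "set" and len(set(members)) != len(members):
        raise UniquenessViolation("set list unit members must be pairwise distinct")
    if cardinality is not None:
        lo, hi = cardinality
        if not (lo <= len(members) <= hi):
            raise CardinalityViolation(
                f"member count {len(members)} outside cardinality [{lo}, {hi}]"
            )
    unit_class = {
        "ordered": vocab.ORDERED_LIST_UNIT,
        "unordered": vocab.UNORDERED_LIST_UNIT,
        "set": vocab.SET_UNIT,
    }[kind]
    list_upri = store.namespace.mint(
        "list-unit", kind + "\n" + "\n".join(members)
    )
    membership_upris = []
    indices: dict[UPRI, int] = {}
    for i, member in enumerate(members, start=1):
        triple = Triple(list_upri, store.namespace.child, member)
        mu = StatementUnit(
            upri=store.namespace.mint(
                "statement-unit", f"membership\n{list_upri}\n{i}\n{member}"
            ),
            provenance=store.new_provenance(),
            unit_class=vocab.LIST_MEMBERSHIP_STATEMENT_UNIT,
            subject=list_upri,
            objects=[member],
            data_graph=DataGraph([triple]),
            schema_ref=vocab.LIST_MEMBERSHIP_STATEMENT_UNIT,
        )
        mu.validate()
        store.register(mu)
        # membership triples live in the semantic-units layer: their subject
        # is a semantic-unit resource
        store.semantic_units_layer.add(triple)
        membership_upris.append(mu.upri)
        if kind == "ordered":
            indices[mu.upri] = i
    unit = ListUnit(
        upri=list_upri,
        provenance=store.new_provenance(),
        unit_class=unit_class,
        associated_units=membership_upris,
        kind=kind,
        member_resources=list(members),
        indices=indices,
        cardinality=cardinality,
    )
    unit.validate()
    store.register(unit)
    return unit


# ---------------------------------------------------------------------------
# profiling and redaction


LEVELS = ["triple", "statement_unit", "item_unit", "item_group_unit", "knowledge_graph"]


def granularity_levels(store: KnowledgeGraphStore) -> list[str]:
    """Which of the five representational-granularity levels are instantiated,
    in fine-to-coarse order."""
    present = []
    if len(store.data_layer):
        present.append("triple")
    if any(isinstance(u, StatementUnit) for u in store.units.values()):
        present.append("statement_unit")
    if any(isinstance(u, ItemUnit) for u in store.units.values()):
        present.append("item_unit")
    if any(isinstance(u, ItemGroupUnit) for u in store.units.values()):
        present.append("item_group_unit")
    if len(store.data_layer) or store.units:
        present.append("knowledge_graph")
    return present


def redact(
    store: KnowledgeGraphStore, restricted_classes: set[UPRI]
) -> KnowledgeGraphStore:
    """View of the store without units of the restricted classes.

    Excluded: the units themselves, their data-graph triples, and their
    semantic-units-layer triples.  Compounds lose redacted members (and are
    dropped entirely if nothing remains).  The original store is unmodified.
    """
    from dataclasses import replace as dc_replace

    view = KnowledgeGraphStore(store.namespace)
    view.schemas = dict(store.schemas)
    removed: set[UPRI] = {
        upri
        for upri, unit in store.units.items()
        if unit.unit_class in restricted_classes
    }
    removed_triples: set[Triple] = set()
    for upri in removed:
        unit = store.units[upri]
        if isinstance(unit, StatementUnit):
            removed_triples.update(unit.data_graph.as_set())
    view.data_layer = DataGraph(
        t for t in store.data_layer if t not in removed_triples
    )
    kept: dict[UPRI, object] = {}
    for upri, unit in sorted(store.units.items()):
        if upri in removed:
            continue
        if isinstance(unit, CompoundUnit):
            new_assoc = [m for m in unit.associated_units if m not in removed]
            if not new_assoc:
                removed.add(upri)
                continue
            unit = dc_replace(
                unit,
                associated_units=new_assoc,
                linked_units=[m for m in unit.linked_units if m not in removed],
            )
        kept[upri] = unit
    # second pass: compounds referencing compounds dropped above
    changed = True
    while changed:
        changed = False
        for upri, unit in list(kept.items()):
            if isinstance(unit, CompoundUnit):
                new_assoc = [m for m in unit.associated_units if m not in removed]
                if new_assoc != unit.associated_units:
                    if not new_assoc:
                        removed.add(upri)
                        del kept[upri]
                    else:
                        kept[upri] = dc_replace(unit, associated_units=new_assoc)
                    changed = True
    for upri, unit in sorted(kept.items()):
        view.units[upri] = unit
    view.rebuild_semantic_units_layer()
    # re-add meta-level membership triples for surviving list units
    for unit in view.units.values():
        if isinstance(unit, ListUnit):
            for member in unit.member_resources:
                view.semantic_units_layer.add(
                    Triple(unit.upri, view.namespace.child, member)
                )
    return view


def compound_all(
    store: KnowledgeGraphStore,
    partial_order_predicates: Sequence[UPRI] = (vocab.HAS_PART,),
) -> dict:
    """Run every automated compounding builder; returns a summary dict."""
    typed = []
    id_index = _identification_index(store)
    for unit in store.statement_units():
        if (
            unit.unit_class not in _ID_CLASSES
            and unit.schema_ref in store.schemas
        ):
            typed.append(build_typed_statement_unit(unit, store, _index=id_index))
    items = build_item_units(store)
    groups = build_item_group_units(store)
    trees, rejections = build_granularity_trees(store, partial_order_predicates)
    granular = [build_granular_item_group(tree, store) for tree in trees]
    contexts, links = build_context_units(store)
    return {
        "typed_statement_units": typed,
        "item_units": items,
        "item_group_units": groups,
        "granularity_trees": trees,
        "tree_rejections": rejections,
        "granular_item_groups": granular,
        "context_units": contexts,
        "is_about_links": links,
        "levels": granularity_levels(store),
    }
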