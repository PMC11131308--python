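"""Programmatic fixtures: the worked examples and seeded random stores.

Two kinds of fixtures, both fully in-memory:

* :func:`apple_example` and :func:`publication_example` reconstruct the
  worked examples — a single weight measurement (an apple weighing
  204.56 grams, modelled with the OBI measurement pattern) and a scholarly-
  publication graph with a research-activity chain, an is-about boundary
  between discursive and ontological regions, a parthood granularity tree,
  and a contextual assertion (an author asserting a melting-point
  measurement of 327.5 °C).

* :func:`generate_store` draws a seeded random store from a
  :class:`FixtureSpec` and returns it together with its exact
  :class:`GroundTruth` (the intended statement unit of every triple, the
  intended item units, item groups, trees and context split), so recovery
  of planted structure can be checked unit-for-unit.

Ontology identifiers (NCIT, PATO, IAO, OBI, UBERON, SIO) are used as opaque
IRIs; no ontology files are fetched.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from . import vocab
from .compound import build_typed_statement_unit, compound_all
from .model import (
    DataGraph,
    KnowledgeGraphStore,
    Literal,
    NamespaceConfig,
    ProvenanceMetadata,
    StatementUnit,
    Triple,
    UPRI,
    canonical_graph_key,
    mint_upri,
)
from .partition import PartitionReport, organize
from .schema import StatementUnitSchema, builtin_schemas

__all__ = [
    "FixtureSpec",
    "GroundTruth",
    "weight_schema",
    "apple_example",
    "publication_example",
    "generate_store",
]

UnitKey = tuple[UPRI, frozenset]  # (unit class, data-graph triple set)

#: fixed timestamp so fixture exports are byte-identical across runs
FIXTURE_PROVENANCE = ProvenanceMetadata(
    creator="semantic-units",
    created="2024-01-01T00:00:00+00:00",
    application="semantic-units/0.1.0",
)


@dataclass
class GroundTruth:
    """Exact expected structure of a generated store, by construction."""

    #: every expected statement unit as (class, frozen data graph)
    units: set[UnitKey] = field(default_factory=set)
    #: triple -> the unit key it must belong to
    membership: dict[Triple, UnitKey] = field(default_factory=dict)
    #: subject -> set of member unit keys of its item unit
    item_units: dict[UPRI, set[UnitKey]] = field(default_factory=dict)
    #: expected item groups as frozensets of item subjects
    item_groups: set[frozenset] = field(default_factory=set)
    #: accepted trees: (predicate, root, frozenset of (parent, child) edges)
    trees: set[tuple] = field(default_factory=set)
    #: components expected to be rejected (cycles / multi-parent), as node sets
    rejected_tree_components: set[frozenset] = field(default_factory=set)
    n_context_units: int = 0
    restricted_classes: list[UPRI] = field(default_factory=list)

    def add_unit(self, unit_class: UPRI, triples: list[Triple]) -> UnitKey:
        key = (unit_class, frozenset(triples))
        self.units.add(key)
        for t in triples:
            self.membership[t] = key
        return key


@dataclass
class FixtureSpec:
    """Knobs of the random store generator (defaults give a small,
    fully-recoverable store exercising every builder)."""

    seed: int = 0
    n_subjects: int = 6
    units_per_subject: tuple[int, int] = (1, 3)
    schema_mix: dict[str, float] = field(
        default_factory=lambda: {
            "measurement": 2.0,
            "has_part": 2.0,
            "located_at": 1.0,
            "generic": 1.0,
        }
    )
    n_item_groups: int = 2
    tree_depth: tuple[int, int] = (0, 2)
    p_is_about: float = 0.5
    p_restricted: float = 0.0
    plant_cycle: bool = False

    def validate(self) -> None:
        if self.n_subjects < 0 or self.n_item_groups < 0:
            raise ValueError("counts must be >= 0")
        for p in (self.p_is_about, self.p_restricted):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.units_per_subject[0] > self.units_per_subject[1] or (
            self.tree_depth[0] > self.tree_depth[1]
        ):
            raise ValueError("ranges must be (low, high) with low <= high")
        if not self.schema_mix or all(w <= 0 for w in self.schema_mix.values()):
            raise ValueError("schema_mix needs at least one positive weight")


# ---------------------------------------------------------------------------
# worked example: the apple weight measurement

_EX = "https://example.org/apple/"
NCIT_APPLE = vocab.OBO + "NCIT_C71985"  # opaque identifier, no ontology fetched
PATO_WEIGHT = vocab.OBO + "PATO_0000128"
IAO_SCALAR_MEASUREMENT_DATUM = vocab.OBO + "IAO_0000032"
OBI_VALUE_SPECIFICATION = vocab.OBO + "OBI_0001933"
UO_GRAM = vocab.OBO + "UO_0000021"
UO_DEGREE_CELSIUS = vocab.OBO + "UO_0000027"


def weight_schema() -> StatementUnitSchema:
    """Weight-specific variant of the measurement pattern (value + unit
    objects reached through quality, datum and value-specification nodes)."""
    schema = StatementUnitSchema(
        class_upri=vocab.WEIGHT_STATEMENT_UNIT,
        label="weight statement unit",
        subject_var="?s",
        object_vars=[("?value", True), ("?unit", True)],
        triple_templates=[
            ("?s", vocab.HAS_QUALITY, "?quality"),
            ("?quality", vocab.IS_QUALITY_MEASURED_AS, "?datum"),
            ("?datum", vocab.HAS_VALUE_SPECIFICATION, "?vspec"),
            ("?vspec", vocab.HAS_SPECIFIED_NUMERIC_VALUE, "?value"),
            ("?vspec", vocab.HAS_MEASUREMENT_UNIT_LABEL, "?unit"),
        ],
        relation_kind="nary-instance",
        dynamic_label_template="{subject} has weight {value} {unit}",
        mind_map_template="{subject} -> {value}; {subject} -> {unit}",
        priority=70,
    )
    schema.validate()
    return schema


def _individual(
    graph: DataGraph, iri: UPRI, type_iri: UPRI, label: str
) -> list[Triple]:
    triples = [
        Triple(iri, vocab.RDF_TYPE, type_iri),
        Triple(iri, vocab.RDFS_LABEL, Literal(label)),
    ]
    for t in triples:
        graph.add(t)
    return triples


def _measurement(
    graph: DataGraph,
    subject: UPRI,
    prefix: str,
    value: str,
    unit_iri: UPRI,
) -> list[Triple]:
    quality, datum, vspec = (
        prefix + "quality",
        prefix + "datum",
        prefix + "vspec",
    )
    triples = [
        Triple(subject, vocab.HAS_QUALITY, quality),
        Triple(quality, vocab.IS_QUALITY_MEASURED_AS, datum),
        Triple(datum, vocab.HAS_VALUE_SPECIFICATION, vspec),
        Triple(vspec, vocab.HAS_SPECIFIED_NUMERIC_VALUE, Literal(value, vocab.XSD_DECIMAL)),
        Triple(vspec, vocab.HAS_MEASUREMENT_UNIT_LABEL, unit_iri),
    ]
    for t in triples:
        graph.add(t)
    return triples


def apple_example() -> tuple[KnowledgeGraphStore, GroundTruth, PartitionReport]:
    """Store for the apple-weight worked example.

    One weight statement unit (subject 'apple X', objects: the 204.56
    decimal literal and the gram unit resource), five named-individual
    identification units, one class identification unit for the apple
    class, an item unit for 'apple X', and a typed statement unit with six
    members (the reference weight unit plus the five identification units).
    """
    truth = GroundTruth()
    g = DataGraph()
    apple = _EX + "apple-x"
    gram = _EX + "gram-x"
    measurement = _measurement(g, apple, _EX + "weight-", "204.56", gram)
    truth.add_unit(vocab.WEIGHT_STATEMENT_UNIT, measurement)
    for iri, type_iri, label in [
        (apple, NCIT_APPLE, "apple X"),
        (_EX + "weight-quality", PATO_WEIGHT, "weight X"),
        (_EX + "weight-datum", IAO_SCALAR_MEASUREMENT_DATUM, "scalar measurement datum X"),
        (_EX + "weight-vspec", OBI_VALUE_SPECIFICATION, "value specification X"),
        (gram, UO_GRAM, "gram"),
    ]:
        triples = _individual(g, iri, type_iri, label)
        truth.add_unit(vocab.NAMED_INDIVIDUAL_IDENTIFICATION_UNIT, triples)
    class_triples = [
        Triple(NCIT_APPLE, vocab.RDFS_LABEL, Literal("apple")),
        Triple(NCIT_APPLE, vocab.DCTERMS_IDENTIFIER, Literal("NCIT:C71985")),
    ]
    for t in class_triples:
        g.add(t)
    truth.add_unit(vocab.CLASS_IDENTIFICATION_UNIT, class_triples)

    truth.item_units[apple] = {(vocab.WEIGHT_STATEMENT_UNIT, frozenset(measurement))}
    truth.n_context_units = 1

    schemas = [weight_schema()] + builtin_schemas()
    store, report = organize(g, schemas, provenance=FIXTURE_PROVENANCE)
    weight_unit = store.units_of_class(vocab.WEIGHT_STATEMENT_UNIT)[0]
    assert isinstance(weight_unit, StatementUnit)
    build_typed_statement_unit(weight_unit, store)
    compound_all(store)
    return store, truth, report


# ---------------------------------------------------------------------------
# worked example: scholarly publication

_PUB = "https://example.org/publication/"
IAO_JOURNAL_ARTICLE = vocab.OBO + "IAO_0000013"
OBI_INVESTIGATION = vocab.OBO + "OBI_0000066"
IAO_DATA_SET = vocab.OBO + "IAO_0000100"
SIO_DESCRIPTION = "http://semanticscience.org/resource/SIO_000136"
UBERON_ORGANISM = vocab.OBO + "UBERON_0000468"
UBERON_HEAD = vocab.OBO + "UBERON_0000033"
UBERON_EYE = vocab.OBO + "UBERON_0000970"
PATO_MELTING_POINT = vocab.OBO + "PATO_0000033"
NCIT_PERSON = vocab.OBO + "NCIT_C25190"
NCIT_LEAD = vocab.OBO + "NCIT_C44396"
DESCRIBES = vocab.OBO + "IAO_0000219"  # denotes
HAS_SPECIFIED_OUTPUT = vocab.OBO + "OBI_0000299"
HAS_COMPONENT = vocab.OBO + "RO_0002180"


def publication_example() -> tuple[KnowledgeGraphStore, GroundTruth, PartitionReport]:
    """Store for the scholarly-publication worked example.

    A publication resource denotes an investigation whose specified output
    is a data set with a description component; the description *is about* a
    multicellular organism, which roots a parthood granularity tree
    (organism → head → eye).  A melting-point measurement of 327.5 °C on a
    lead sample, asserted by an author through an asserts statement unit,
    provides the contextual statement-about-a-statement.  Partitioning and
    compounding yields a publication item group and at least two context
    units either side of the is-about boundary.
    """
    truth = GroundTruth()
    g = DataGraph()
    pub, inv, ds, desc = (
        _PUB + "article-x",
        _PUB + "investigation-x",
        _PUB + "dataset-x",
        _PUB + "description-x",
    )
    organism, head, eye = (
        _PUB + "organism-x",
        _PUB + "head-x",
        _PUB + "eye-x",
    )
    author, lead, celsius = _PUB + "author-a", _PUB + "lead-x", _PUB + "celsius-x"

    for iri, type_iri, label in [
        (pub, IAO_JOURNAL_ARTICLE, "publication X"),
        (inv, OBI_INVESTIGATION, "investigation X"),
        (ds, IAO_DATA_SET, "data set X"),
        (desc, SIO_DESCRIPTION, "description X"),
        (organism, UBERON_ORGANISM, "multicellular organism X"),
        (head, UBERON_HEAD, "head X"),
        (eye, UBERON_EYE, "eye X"),
        (author, NCIT_PERSON, "Author A"),
        (lead, NCIT_LEAD, "lead X"),
        (celsius, UO_DEGREE_CELSIUS, "degree Celsius"),
        (_PUB + "melting-quality", PATO_MELTING_POINT, "melting point X"),
        (_PUB + "melting-datum", IAO_SCALAR_MEASUREMENT_DATUM, "scalar measurement datum Y"),
        (_PUB + "melting-vspec", OBI_VALUE_SPECIFICATION, "value specification Y"),
    ]:
        truth.add_unit(
            vocab.NAMED_INDIVIDUAL_IDENTIFICATION_UNIT, _individual(g, iri, type_iri, label)
        )

    def single(subject: UPRI, predicate: UPRI, obj, unit_class: UPRI) -> Triple:
        t = Triple(subject, predicate, obj)
        g.add(t)
        truth.add_unit(unit_class, [t])
        return t

    single(pub, DESCRIBES, inv, vocab.GENERIC_STATEMENT_UNIT)
    single(inv, HAS_SPECIFIED_OUTPUT, ds, vocab.GENERIC_STATEMENT_UNIT)
    single(ds, HAS_COMPONENT, desc, vocab.GENERIC_STATEMENT_UNIT)
    single(desc, vocab.IS_ABOUT, organism, vocab.IS_ABOUT_STATEMENT_UNIT)
    single(organism, vocab.HAS_PART, head, vocab.HAS_PART_STATEMENT_UNIT)
    single(head, vocab.HAS_PART, eye, vocab.HAS_PART_STATEMENT_UNIT)

    melting = _measurement(g, lead, _PUB + "melting-", "327.5", celsius)
    truth.add_unit(vocab.METRIC_MEASUREMENT_STATEMENT_UNIT, melting)
    # the author asserts the melting-point unit: the object of the asserts
    # triple is the measurement unit's (deterministically minted) UPRI
    melting_upri = mint_upri(
        "statement-unit",
        vocab.METRIC_MEASUREMENT_STATEMENT_UNIT + "\n" + canonical_graph_key(melting),
    )
    single(author, vocab.ASSERTS, melting_upri, vocab.ASSERTS_STATEMENT_UNIT)

    truth.trees.add(
        (vocab.HAS_PART, organism, frozenset({(organism, head), (head, eye)}))
    )
    # regions after removing the is-about unit: the publication chain, the
    # organism parthood region, and the discursive assertion + measurement
    truth.n_context_units = 3
    truth.item_groups.add(frozenset({pub, inv, ds, desc, organism, head}))

    store, report = organize(g, builtin_schemas(), provenance=FIXTURE_PROVENANCE)
    compound_all(store)
    return store, truth, report


# ---------------------------------------------------------------------------
# seeded random stores


def generate_store(
    spec: FixtureSpec,
) -> tuple[KnowledgeGraphStore, GroundTruth, PartitionReport]:
    """Seeded random store with exact planted ground truth.

    The generator builds clusters of subjects chained by parthood bridges
    (the intended item groups and granularity trees), hangs a random mix of
    measurement / parthood / location / generic statement units off every
    subject, and optionally joins consecutive clusters with is-about units.
    Every triple is tagged with its intended statement unit; trees are
    acyclic by construction unless a cycle is explicitly planted.
    """
    spec.validate()
    rng = random.Random(spec.seed)
    truth = GroundTruth()
    g = DataGraph()
    base = f"https://example.org/gen/{spec.seed}/"

    subjects = [base + f"s{i}" for i in range(spec.n_subjects)]

    # clusters -> intended item groups and context regions; ontology classes
    # are minted per cluster so regions do not merge through shared classes
    clusters: list[list[UPRI]] = []
    if spec.n_subjects and spec.n_item_groups:
        n_clusters = min(spec.n_item_groups, max(1, spec.n_subjects // 2))
        clusters = [[] for _ in range(n_clusters)]
        for i, s in enumerate(subjects):
            clusters[i % n_clusters].append(s)
    elif spec.n_subjects:
        clusters = [[s] for s in subjects]

    cluster_of: dict[UPRI, int] = {
        s: c for c, cluster in enumerate(clusters) for s in cluster
    }
    cluster_classes: dict[int, list[UPRI]] = {}

    def classes_for(cluster_idx: int) -> list[UPRI]:
        if cluster_idx not in cluster_classes:
            cls_list = [base + f"class/{cluster_idx}/c{k}" for k in range(3)]
            for k, cls in enumerate(cls_list):
                triples = [
                    Triple(cls, vocab.RDFS_LABEL, Literal(f"class {cluster_idx}.{k}")),
                    Triple(
                        cls,
                        vocab.DCTERMS_IDENTIFIER,
                        Literal(f"GEN:{cluster_idx:02d}{k:02d}"),
                    ),
                ]
                for t in triples:
                    g.add(t)
                truth.add_unit(vocab.CLASS_IDENTIFICATION_UNIT, triples)
            cluster_classes[cluster_idx] = cls_list
        return cluster_classes[cluster_idx]

    def fresh_individual(iri: UPRI, cluster_idx: int, cls_index: int, label: str) -> None:
        cls_list = classes_for(cluster_idx)
        truth.add_unit(
            vocab.NAMED_INDIVIDUAL_IDENTIFICATION_UNIT,
            _individual(g, iri, cls_list[cls_index % len(cls_list)], label),
        )

    for i, s in enumerate(subjects):
        fresh_individual(s, cluster_of[s], i, f"subject {i}")
        truth.item_units.setdefault(s, set())

    bridge_edges: list[tuple[UPRI, UPRI]] = []  # subject-to-subject bridges
    haspart_edges: dict[UPRI, set[tuple[UPRI, UPRI]]] = {}  # component head -> edges
    for cluster in clusters:
        head_subject = cluster[0]
        edges: set[tuple[UPRI, UPRI]] = set()
        for a, b in zip(cluster, cluster[1:]):
            t = Triple(a, vocab.HAS_PART, b)
            g.add(t)
            key = truth.add_unit(vocab.HAS_PART_STATEMENT_UNIT, [t])
            truth.item_units.setdefault(a, set()).add(key)
            edges.add((a, b))
            bridge_edges.append((a, b))
        if edges:
            haspart_edges[head_subject] = edges

    kinds = sorted(spec.schema_mix)
    weights = [spec.schema_mix[k] for k in kinds]
    generic_counter = 0
    for i, s in enumerate(subjects):
        c_idx = cluster_of[s]
        located_used = False
        n_units = rng.randint(*spec.units_per_subject)
        for j in range(n_units):
            kind = rng.choices(kinds, weights=weights, k=1)[0]
            if kind == "located_at" and located_used:
                kind = "generic"
            prefix = base + f"s{i}/u{j}/"
            if kind == "measurement":
                unit_iri = prefix + "unit"
                fresh_individual(prefix + "quality", c_idx, j, f"quality {i}.{j}")
                fresh_individual(prefix + "datum", c_idx, j + 1, f"datum {i}.{j}")
                fresh_individual(prefix + "vspec", c_idx, j + 2, f"vspec {i}.{j}")
                fresh_individual(unit_iri, c_idx, j, f"unit {i}.{j}")
                value = f"{rng.uniform(0.1, 999.9):.2f}"
                key = truth.add_unit(
                    vocab.METRIC_MEASUREMENT_STATEMENT_UNIT,
                    _measurement(g, s, prefix, value, unit_iri),
                )
            elif kind == "has_part":
                part = prefix + "part"
                fresh_individual(part, c_idx, j, f"part {i}.{j}")
                t = Triple(s, vocab.HAS_PART, part)
                g.add(t)
                key = truth.add_unit(vocab.HAS_PART_STATEMENT_UNIT, [t])
                comp = clusters[c_idx][0]
                haspart_edges.setdefault(comp, set()).add((s, part))
            elif kind == "located_at":
                located_used = True
                place = prefix + "place"
                fresh_individual(place, c_idx, j, f"place {i}.{j}")
                triples = [
                    Triple(s, vocab.LOCATED_IN, place),
                    Triple(
                        s,
                        vocab.AT_TIME,
                        Literal(f"2022-06-{(i % 28) + 1:02d}", vocab.XSD_STRING),
                    ),
                ]
                for t in triples:
                    g.add(t)
                key = truth.add_unit(
                    vocab.LOCATED_IN_AT_TIME_STATEMENT_UNIT, triples
                )
            else:  # generic: unmatched predicate -> fallback single-triple unit
                generic_counter += 1
                pred = base + f"p/generic{generic_counter}"
                if rng.random() < 0.5:
                    obj = Literal(f"note {generic_counter}")
                else:
                    obj = prefix + "thing"  # bare resource, no identification
                t = Triple(s, pred, obj)
                g.add(t)
                key = truth.add_unit(vocab.GENERIC_STATEMENT_UNIT, [t])
            truth.item_units.setdefault(s, set()).add(key)

    # deep part chains below each cluster head (granularity-tree depth)
    for c_idx, cluster in enumerate(clusters):
        depth = rng.randint(*spec.tree_depth)
        parent = cluster[0]
        for d in range(depth):
            node = base + f"chain/{c_idx}/d{d}"
            fresh_individual(node, c_idx, d, f"chain node {c_idx}.{d}")
            t = Triple(parent, vocab.HAS_PART, node)
            g.add(t)
            key = truth.add_unit(vocab.HAS_PART_STATEMENT_UNIT, [t])
            haspart_edges.setdefault(cluster[0], set()).add((parent, node))
            truth.item_units.setdefault(parent, set()).add(key)
            # when a chain node itself acquires units it becomes an item
            # subject and this edge bridges it into the cluster's group
            bridge_edges.append((parent, node))
            parent = node

    if spec.plant_cycle and clusters and len(clusters[0]) >= 2:
        a, b = clusters[0][0], clusters[0][-1]
        t = Triple(b, vocab.HAS_PART, a)  # closes a cycle in the first component
        g.add(t)
        key = truth.add_unit(vocab.HAS_PART_STATEMENT_UNIT, [t])
        truth.item_units.setdefault(b, set()).add(key)
        haspart_edges[clusters[0][0]].add((b, a))
        bridge_edges.append((b, a))

    # expected trees: per parthood component, accepted iff unique root,
    # single parents, acyclic (cycles have no root, so they fall through)
    for head_subject, edges in sorted(haspart_edges.items()):
        nodes = {n for e in edges for n in e}
        children = [c for _, c in edges]
        multi_parent = len(set(children)) < len(children)
        roots = nodes - set(children)
        if len(roots) == 1 and not multi_parent:
            truth.trees.add((vocab.HAS_PART, next(iter(roots)), frozenset(edges)))
        else:
            truth.rejected_tree_components.add(frozenset(nodes))

    # is-about bridges between consecutive clusters (they also bridge item
    # groups, so grouping is computed after all edges are known)
    for k in range(0, len(clusters) - 1, 2):
        if rng.random() < spec.p_is_about:
            a_head, b_head = clusters[k][0], clusters[k + 1][0]
            t = Triple(a_head, vocab.IS_ABOUT, b_head)
            g.add(t)
            key = truth.add_unit(vocab.IS_ABOUT_STATEMENT_UNIT, [t])
            truth.item_units.setdefault(a_head, set()).add(key)
            bridge_edges.append((a_head, b_head))
    truth.n_context_units = len(clusters)

    # prune item units for subjects that ended up with no members, then
    # derive the expected item groups from the surviving bridge graph
    truth.item_units = {s: ks for s, ks in truth.item_units.items() if ks}
    parent: dict[UPRI, UPRI] = {s: s for s in truth.item_units}

    def find(x: UPRI) -> UPRI:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for a, b in bridge_edges:
        if a in parent and b in parent:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[ra] = rb
    components: dict[UPRI, set[UPRI]] = {}
    for s in parent:
        components.setdefault(find(s), set()).add(s)
    truth.item_groups = {
        frozenset(c) for c in components.values() if len(c) >= 2
    }

    if spec.p_restricted > 0 and rng.random() < spec.p_restricted:
        truth.restricted_classes = [vocab.METRIC_MEASUREMENT_STATEMENT_UNIT]

    store, report = organize(
        g,
        builtin_schemas(),
        NamespaceConfig(base=base + "unit/"),
        provenance=FIXTURE_PROVENANCE,
    )
    return store, truth, report
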