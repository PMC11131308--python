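"""Decompose a data graph into statement units.

The partition property is the heart of the framework: every triple of the
data graph layer belongs to exactly one statement unit, and merging all
statement-unit data graphs reproduces the data graph.  The pass order is

1. identification units (type/label of named individuals, label/identifier
   of class resources) — built first so n-ary pattern matches cannot swallow
   the labelling triples;
2. schema matches, in descending priority (ties by class IRI), each accepted
   binding consuming its matched triples (first claim wins);
3. a generic single-triple fallback unit for every still-unclaimed triple.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace

from . import vocab
from .errors import NotFoundError
from .model import (
    DataGraph,
    KnowledgeGraphStore,
    Literal,
    NamespaceConfig,
    ProvenanceMetadata,
    SemanticUnit,
    StatementUnit,
    CompoundUnit,
    Triple,
    UPRI,
    canonical_graph_key,
    triple_sort_key,
)
from .schema import GraphIndex, StatementUnitSchema, match_schema

log = logging.getLogger(__name__)

__all__ = [
    "PartitionReport",
    "NamedIndividualIdentificationUnit",
    "ClassIdentificationUnit",
    "IdentificationConfig",
    "build_identification_units",
    "partition",
    "subject_of",
    "emit_semantic_units_layer",
    "verify_partition",
    "organize",
]


@dataclass
class PartitionReport:
    n_triples: int = 0
    n_units: int = 0
    per_class: dict[UPRI, int] = field(default_factory=dict)
    orphan_triples: frozenset[Triple] = frozenset()
    coverage_ok: bool = False
    disjoint_ok: bool = False

    def to_dict(self) -> dict:
        return {
            "n_triples": self.n_triples,
            "n_units": self.n_units,
            "per_class": dict(sorted(self.per_class.items())),
            "n_orphans_prefallback": len(self.orphan_triples),
            "coverage_ok": self.coverage_ok,
            "disjoint_ok": self.disjoint_ok,
        }


@dataclass
class NamedIndividualIdentificationUnit(StatementUnit):
    """Type and label triples of one named individual (its identity card)."""


@dataclass
class ClassIdentificationUnit(StatementUnit):
    """Label/identifier (optionally ontology and version IRIs) of a class."""


@dataclass(frozen=True)
class IdentificationConfig:
    """Predicates that route triples into identification units."""

    label_predicates: frozenset[str] = frozenset({vocab.RDFS_LABEL})
    identifier_predicates: frozenset[str] = frozenset({vocab.DCTERMS_IDENTIFIER})
    ontology_predicates: frozenset[str] = frozenset(
        {vocab.RDFS_IS_DEFINED_BY, vocab.OWL_VERSION_IRI}
    )


def build_identification_units(
    graph: DataGraph,
    namespace: NamespaceConfig | None = None,
    config: IdentificationConfig | None = None,
    provenance=None,
) -> tuple[list[StatementUnit], set[Triple]]:
    """Identification units plus the set of triples they consume.

    A resource counts as a *class resource* when it occurs as the object of
    an rdf:type triple anywhere in the graph; it gets a class identification
    unit collecting its label/identifier/ontology triples.  Every other
    subject bearing type or label triples gets a named-individual
    identification unit over exactly those triples.
    """
    ns = namespace or NamespaceConfig()
    cfg = config or IdentificationConfig()
    class_resources = {
        t.object
        for t in graph
        if t.predicate == vocab.RDF_TYPE and not isinstance(t.object, Literal)
    }
    by_subject: dict[UPRI, list[Triple]] = {}
    for t in graph:
        by_subject.setdefault(t.subject, []).append(t)

    units: list[StatementUnit] = []
    consumed: set[Triple] = set()
    id_predicates = (
        cfg.label_predicates | cfg.identifier_predicates | cfg.ontology_predicates
    )
    for subject in sorted(by_subject):
        triples = by_subject[subject]
        if subject in class_resources:
            picked = [
                t
                for t in triples
                if t.predicate in id_predicates or t.predicate == vocab.RDF_TYPE
            ]
            cls = ClassIdentificationUnit
            unit_class = vocab.CLASS_IDENTIFICATION_UNIT
        else:
            picked = [
                t
                for t in triples
                if t.predicate == vocab.RDF_TYPE
                or t.predicate in cfg.label_predicates
                or (t.predicate in id_predicates and isinstance(t.object, Literal))
            ]
            cls = NamedIndividualIdentificationUnit
            unit_class = vocab.NAMED_INDIVIDUAL_IDENTIFICATION_UNIT
        if not picked:
            continue
        dg = DataGraph(picked)
        unit = cls(
            upri=ns.mint("statement-unit", canonical_graph_key(picked)),
            unit_class=unit_class,
            provenance=dc_replace(provenance) if provenance else ProvenanceMetadata(),
            subject=subject,
            objects=sorted(
                (t.object for t in picked),
                key=lambda o: (isinstance(o, Literal), str(o)),
            ),
            data_graph=dg,
            schema_ref=vocab.GENERIC_SCHEMA_MARKER,
        )
        unit.validate()
        units.append(unit)
        consumed.update(picked)
    return units, consumed


def partition(
    graph: DataGraph,
    schemas: list[StatementUnitSchema],
    namespace: NamespaceConfig | None = None,
    id_config: IdentificationConfig | None = None,
    provenance: ProvenanceMetadata | None = None,
) -> tuple[list[StatementUnit], PartitionReport]:
    """Partition ``graph`` into statement units; total, disjoint, deterministic.

    ``provenance``, when given, stamps every created unit with a copy of the
    same metadata (used by fixtures for reproducible exports).
    """
    ns = namespace or NamespaceConfig()
    units, consumed = build_identification_units(graph, ns, id_config, provenance)
    pool = graph.difference(DataGraph(consumed))

    ordered = sorted(schemas, key=lambda s: (-s.priority, s.class_upri))
    for schema in ordered:
        # index built once per schema pass; claims within the pass are
        # validated against the live pool (first claim wins)
        index = GraphIndex(pool)
        anchors = sorted(pool.subjects())
        for anchor in anchors:
            if anchor not in index.terms:
                continue
            for binding in match_schema(schema, pool, anchor, index=index):
                if not binding.matched_triples:
                    continue
                if not all(t in pool for t in binding.matched_triples):
                    if any(t in pool for t in binding.matched_triples):
                        log.warning(
                            "schema %s binding at %s overlaps an earlier claim; "
                            "first claim wins",
                            schema.class_upri,
                            anchor,
                        )
                    continue
                env = binding.as_dict()
                objects = [
                    env[v] for v, _ in schema.object_vars if v in env
                ]
                unit = StatementUnit(
                    upri=ns.mint(
                        "statement-unit",
                        schema.class_upri
                        + "\n"
                        + canonical_graph_key(binding.matched_triples),
                    ),
                    unit_class=schema.class_upri,
                    provenance=dc_replace(provenance)
                    if provenance
                    else ProvenanceMetadata(),
                    subject=anchor,
                    objects=objects,
                    data_graph=DataGraph(binding.matched_triples),
                    schema_ref=schema.class_upri,
                    bindings=env,
                )
                unit.validate()
                units.append(unit)
                for t in binding.matched_triples:
                    pool.discard(t)

    orphans = pool.as_set()
    for t in sorted(orphans, key=triple_sort_key):
        unit = StatementUnit(
            upri=ns.mint("statement-unit", canonical_graph_key([t])),
            unit_class=vocab.GENERIC_STATEMENT_UNIT,
            provenance=dc_replace(provenance) if provenance else ProvenanceMetadata(),
            subject=t.subject,
            objects=[t.object],
            data_graph=DataGraph([t]),
            schema_ref=vocab.GENERIC_SCHEMA_MARKER,
        )
        unit.validate()
        units.append(unit)

    report = verify_partition(units, graph)
    report.orphan_triples = frozenset(orphans)
    return units, report


def subject_of(store: KnowledgeGraphStore, upri: UPRI) -> UPRI:
    """Subject of a registered statement unit (mirrors the subject triple
    recorded in the semantic-units layer)."""
    unit = store.get(upri)
    if not isinstance(unit, StatementUnit):
        raise NotFoundError(f"{upri} is not a statement unit")
    return unit.subject


def emit_semantic_units_layer(
    units: list[SemanticUnit], namespace: NamespaceConfig | None = None
) -> DataGraph:
    """Triples describing the given units (the discursive layer content)."""
    ns = namespace or NamespaceConfig()
    out = DataGraph()
    for unit in units:
        out.add(Triple(unit.upri, vocab.RDF_TYPE, unit.unit_class))
        if unit.subject:
            out.add(Triple(unit.upri, ns.has_subject, unit.subject))
        if isinstance(unit, CompoundUnit):
            for member in unit.associated_units:
                out.add(Triple(unit.upri, ns.has_associated, member))
            for linked in unit.linked_units:
                out.add(Triple(unit.upri, ns.has_linked, linked))
            indices = getattr(unit, "indices", None)
            if indices:
                for member, idx in sorted(indices.items()):
                    out.add(
                        Triple(
                            member,
                            ns.index,
                            Literal(str(idx), vocab.XSD_INTEGER),
                        )
                    )
    return out


def verify_partition(
    units: list[StatementUnit], graph: DataGraph
) -> PartitionReport:
    """Recompute coverage and disjointness by exhaustive membership counting."""
    counts: dict[Triple, int] = {t: 0 for t in graph}
    extra = 0
    per_class: dict[UPRI, int] = {}
    for unit in units:
        per_class[unit.unit_class] = per_class.get(unit.unit_class, 0) + 1
        for t in unit.data_graph:
            if t in counts:
                counts[t] += 1
            else:
                extra += 1
    orphans = frozenset(t for t, c in counts.items() if c == 0)
    coverage_ok = not orphans and extra == 0
    disjoint_ok = all(c <= 1 for c in counts.values())
    return PartitionReport(
        n_triples=len(graph),
        n_units=len(units),
        per_class=per_class,
        orphan_triples=orphans,
        coverage_ok=coverage_ok,
        disjoint_ok=disjoint_ok,
    )


def organize(
    graph: DataGraph,
    schemas: list[StatementUnitSchema],
    namespace: NamespaceConfig | None = None,
    id_config: IdentificationConfig | None = None,
    provenance: ProvenanceMetadata | None = None,
) -> tuple[KnowledgeGraphStore, PartitionReport]:
    """Convenience: partition a graph and register everything in a store."""
    store = KnowledgeGraphStore(namespace)
    store.data_layer = graph.copy()
    store.schemas = {s.class_upri: s for s in schemas}
    store.default_provenance = provenance
    units, report = partition(graph, schemas, store.namespace, id_config, provenance)
    for unit in units:
        store.register(unit)
    return store, report
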