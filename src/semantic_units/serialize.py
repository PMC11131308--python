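"""Serialization: standard RDF in, nanopublication quads / LPG records out.

Three surfaces:

* :func:`import_rdf` — Turtle / N-Triples / TriG into a blank-node-free
  :class:`~semantic_units.model.DataGraph` (blank nodes are skolemized
  deterministically via RDF graph canonicalization, so the same document
  always yields the same skolem IRIs);
* :func:`export_nanopub` / :func:`import_nanopub` — the four-named-graph
  nanopublication mapping: head, assertion, provenance, publication info.
  A statement unit's data graph becomes the assertion graph (named by the
  unit's UPRI); a compound unit's assertion graph is empty and its head
  lists the associated units;
* :func:`export_lpg` — labeled-property-graph records plus bulk-import CSV,
  where every node and relationship carries its UPRI and the UPRI of the
  statement unit (and compound units) it belongs to.

All writers emit canonically ordered bytes so exports are reproducible.
"""

from __future__ import annotations

import csv
import io
import json
from dataclasses import dataclass, field, fields as dc_fields

import rdflib
from rdflib.compare import to_canonical_graph

from . import vocab
from .compound import (
    ContextUnit,
    DatasetUnit,
    GranularItemGroupUnit,
    GranularityTreeUnit,
    ItemGroupUnit,
    ItemUnit,
    ListUnit,
    TypedStatementUnit,
)
from .errors import FormatError, NotFoundError, StateError
from .model import (
    AccessMetadata,
    CompoundUnit,
    DataGraph,
    KnowledgeGraphStore,
    Literal,
    NamespaceConfig,
    ProvenanceMetadata,
    SemanticUnit,
    StatementUnit,
    Term,
    Triple,
    UPRI,
    mint_upri,
    triple_sort_key,
)
from .partition import (
    ClassIdentificationUnit,
    NamedIndividualIdentificationUnit,
)
from .schema import schema_from_dict, schema_to_dict

__all__ = [
    "NanopubRecord",
    "LpgRecord",
    "import_rdf",
    "export_turtle",
    "export_nanopub",
    "import_nanopub",
    "export_lpg",
    "export_registry_json",
    "import_registry_json",
    "units_equivalent",
    "stores_equivalent",
]


# ---------------------------------------------------------------------------
# rdflib bridge


def _to_rdflib_term(term: Term):
    if isinstance(term, Literal):
        if term.language:
            return rdflib.Literal(term.lexical, lang=term.language)
        if term.datatype == vocab.XSD_STRING:
            return rdflib.Literal(term.lexical)
        return rdflib.Literal(term.lexical, datatype=rdflib.URIRef(term.datatype))
    return rdflib.URIRef(term)


def _from_rdflib_term(term) -> Term:
    if isinstance(term, rdflib.Literal):
        if term.language:
            return Literal(str(term), vocab.RDF_LANGSTRING, term.language)
        datatype = str(term.datatype) if term.datatype else vocab.XSD_STRING
        return Literal(str(term), datatype)
    return str(term)


def to_rdflib(graph: DataGraph) -> rdflib.Graph:
    g = rdflib.Graph()
    for t in graph:
        g.add(
            (
                rdflib.URIRef(t.subject),
                rdflib.URIRef(t.predicate),
                _to_rdflib_term(t.object),
            )
        )
    return g


def from_rdflib(g: rdflib.Graph, namespace: NamespaceConfig | None = None) -> DataGraph:
    """Convert, skolemizing blank nodes into the configured namespace.

    Skolem IRIs are derived from the canonical blank-node labels of the
    graph's canonical form, so identical documents always skolemize
    identically, independent of parse order.
    """
    ns = namespace or NamespaceConfig()
    has_bnodes = any(
        isinstance(x, rdflib.BNode) for triple in g for x in triple
    )
    if has_bnodes:
        g = to_canonical_graph(g)

    def conv(term) -> Term:
        if isinstance(term, rdflib.BNode):
            return mint_upri("genid", str(term), ns.base)
        return _from_rdflib_term(term)

    out = DataGraph()
    for s, p, o in g:
        subject, predicate, obj = conv(s), conv(p), conv(o)
        assert isinstance(subject, str) and isinstance(predicate, str)
        out.add(Triple(subject, predicate, obj))
    return out


_DIALECTS = {"turtle": "turtle", "ntriples": "nt", "trig": "trig"}


def import_rdf(
    content: str, dialect: str = "turtle", namespace: NamespaceConfig | None = None
) -> DataGraph:
    if dialect not in _DIALECTS:
        raise FormatError(f"unknown dialect {dialect!r}; use turtle|ntriples|trig")
    g = rdflib.ConjunctiveGraph() if dialect == "trig" else rdflib.Graph()
    try:
        g.parse(data=content, format=_DIALECTS[dialect])
    except Exception as exc:  # rdflib raises assorted parser exceptions
        raise FormatError(f"{dialect} parse failure: {exc}") from exc
    if dialect == "trig":
        flat = rdflib.Graph()
        for t in g.quads():
            flat.add(t[:3])
        g = flat
    return from_rdflib(g, namespace)


def export_turtle(graph: DataGraph) -> str:
    """Canonical N-Triples-compatible Turtle (sorted, one triple per line)."""
    return "".join(
        f"{_nt_term(t.subject)} {_nt_term(t.predicate)} {_nt_term(t.object)} .\n"
        for t in sorted(graph, key=triple_sort_key)
    )


def _nt_escape(text: str) -> str:
    return (
        text.replace("\\", "\\\\")
        .replace('"', '\\"')
        .replace("\n", "\\n")
        .replace("\r", "\\r")
        .replace("\t", "\\t")
    )


def _nt_term(term: Term) -> str:
    if isinstance(term, Literal):
        body = f'"{_nt_escape(term.lexical)}"'
        if term.language:
            return f"{body}@{term.language}"
        if term.datatype != vocab.XSD_STRING:
            return f"{body}^^<{term.datatype}>"
        return body
    return f"<{term}>"


# ---------------------------------------------------------------------------
# nanopublications


@dataclass
class NanopubRecord:
    """One unit as a four-named-graph nanopublication."""

    nanopub_upri: UPRI
    head_upri: UPRI
    assertion_upri: UPRI
    provenance_upri: UPRI
    pubinfo_upri: UPRI
    head: DataGraph = field(default_factory=DataGraph)
    assertion: DataGraph = field(default_factory=DataGraph)
    provenance: DataGraph = field(default_factory=DataGraph)
    pubinfo: DataGraph = field(default_factory=DataGraph)

    def graphs(self) -> dict[UPRI, DataGraph]:
        return {
            self.head_upri: self.head,
            self.assertion_upri: self.assertion,
            self.provenance_upri: self.provenance,
            self.pubinfo_upri: self.pubinfo,
        }


def export_nanopub(
    unit: SemanticUnit, store: KnowledgeGraphStore
) -> tuple[NanopubRecord, str]:
    """Four named graphs + canonical TriG text for one registered unit."""
    if unit.upri not in store.units:
        raise NotFoundError(f"unit not registered: {unit.upri}")
    np_upri = unit.upri + "/np"
    record = NanopubRecord(
        nanopub_upri=np_upri,
        head_upri=np_upri + "/head",
        assertion_upri=unit.upri,  # the unit's UPRI names its data graph
        provenance_upri=np_upri + "/provenance",
        pubinfo_upri=np_upri + "/pubinfo",
    )
    head = record.head
    head.add(Triple(np_upri, vocab.RDF_TYPE, vocab.NP_NANOPUBLICATION))
    head.add(Triple(np_upri, vocab.NP_HAS_ASSERTION, record.assertion_upri))
    head.add(Triple(np_upri, vocab.NP_HAS_PROVENANCE, record.provenance_upri))
    head.add(Triple(np_upri, vocab.NP_HAS_PUBLICATION_INFO, record.pubinfo_upri))
    head.add(Triple(unit.upri, vocab.RDF_TYPE, unit.unit_class))
    if unit.subject:
        head.add(Triple(unit.upri, store.namespace.has_subject, unit.subject))
    if isinstance(unit, StatementUnit):
        record.assertion = unit.data_graph.copy()
        if unit.schema_ref != vocab.GENERIC_SCHEMA_MARKER:
            head.add(Triple(unit.upri, vocab.HAS_SCHEMA, unit.schema_ref))
        for i, obj in enumerate(unit.objects, start=1):
            head.add(Triple(unit.upri, f"{vocab.RDF}_{i}", obj))
    elif isinstance(unit, CompoundUnit):
        # assertion deliberately left empty: the head lists the members
        for member in unit.associated_units:
            head.add(Triple(unit.upri, store.namespace.has_associated, member))
        for linked in unit.linked_units:
            head.add(Triple(unit.upri, store.namespace.has_linked, linked))

    prov = unit.provenance
    record.provenance.add(
        Triple(unit.upri, vocab.DCTERMS_CREATOR, Literal(prov.creator))
    )
    record.provenance.add(
        Triple(
            unit.upri,
            vocab.PROV_GENERATED_AT_TIME,
            Literal(prov.created, vocab.XSD_DATETIME),
        )
    )
    record.provenance.add(
        Triple(unit.upri, vocab.APPLICATION, Literal(prov.application))
    )
    info = record.pubinfo
    info.add(
        Triple(
            np_upri,
            vocab.DCTERMS_MODIFIED,
            Literal(prov.last_update, vocab.XSD_DATETIME),
        )
    )
    if prov.title:
        info.add(Triple(np_upri, vocab.DCTERMS_TITLE, Literal(prov.title)))
    for contributor in prov.contributors:
        info.add(Triple(np_upri, vocab.DCTERMS_CONTRIBUTOR, Literal(contributor)))
    if unit.access.license:
        info.add(Triple(np_upri, vocab.DCTERMS_LICENSE, unit.access.license))
    if unit.access.restricted:
        info.add(
            Triple(np_upri, vocab.RESTRICTED, Literal("true", vocab.XSD_BOOLEAN))
        )
        if unit.access.restriction_note:
            info.add(
                Triple(
                    np_upri,
                    vocab.RESTRICTION_NOTE,
                    Literal(unit.access.restriction_note),
                )
            )
    return record, write_trig(record)


def write_trig(record: NanopubRecord) -> str:
    """Canonical TriG: graphs sorted by name, triples in canonical order."""
    blocks = []
    for name, graph in sorted(record.graphs().items()):
        lines = [f"<{name}> {{"]
        for t in sorted(graph, key=triple_sort_key):
            lines.append(
                f"  {_nt_term(t.subject)} {_nt_term(t.predicate)} "
                f"{_nt_term(t.object)} ."
            )
        lines.append("}")
        blocks.append("\n".join(lines))
    return "\n".join(blocks) + "\n"


def _pop_values(graph: DataGraph, subject: UPRI, predicate: UPRI) -> list[Term]:
    return [
        t.object
        for t in sorted(graph, key=triple_sort_key)
        if t.subject == subject and t.predicate == predicate
    ]


def import_nanopub(trig: str, namespace: NamespaceConfig | None = None) -> SemanticUnit:
    """Reconstruct a unit from its nanopublication TriG."""
    ds = rdflib.ConjunctiveGraph()
    try:
        ds.parse(data=trig, format="trig")
    except Exception as exc:
        raise FormatError(f"TriG parse failure: {exc}") from exc
    contexts = {
        str(ctx.identifier): from_rdflib(ctx, namespace)
        for ctx in ds.contexts()
        if len(ctx)
    }
    # the head names the other graphs; locate it via np:hasAssertion
    head_upri = None
    for name, graph in contexts.items():
        if any(t.predicate == vocab.NP_HAS_ASSERTION for t in graph):
            head_upri = name
    if head_upri is None:
        raise FormatError("no head graph (np:hasAssertion missing)")
    head = contexts[head_upri]
    np_candidates = [t.subject for t in head if t.predicate == vocab.NP_HAS_ASSERTION]
    np_upri = np_candidates[0]
    try:
        assertion_upri = _pop_values(head, np_upri, vocab.NP_HAS_ASSERTION)[0]
        provenance_upri = _pop_values(head, np_upri, vocab.NP_HAS_PROVENANCE)[0]
        pubinfo_upri = _pop_values(head, np_upri, vocab.NP_HAS_PUBLICATION_INFO)[0]
    except IndexError:
        raise FormatError(
            "head does not link all of assertion/provenance/pubinfo"
        ) from None
    declared = {head_upri, str(assertion_upri), str(provenance_upri), str(pubinfo_upri)}
    present = set(contexts)
    # the assertion graph may be legitimately empty (compound units)
    if not present <= declared or len(declared) != 4:
        raise FormatError(
            f"expected exactly the four nanopublication graphs, got {sorted(present)}"
        )
    assertion = contexts.get(str(assertion_upri), DataGraph())
    provenance = contexts.get(str(provenance_upri), DataGraph())
    pubinfo = contexts.get(str(pubinfo_upri), DataGraph())

    unit_upri = str(assertion_upri)
    classes = [
        t.object
        for t in head
        if t.subject == unit_upri and t.predicate == vocab.RDF_TYPE
    ]
    if not classes:
        raise FormatError("head does not type the unit resource")
    unit_class = str(classes[0])
    subjects = _pop_values(head, unit_upri, NamespaceConfig().has_subject)
    subject = str(subjects[0]) if subjects else None

    def _lex(values: list[Term], default: str = "") -> str:
        for v in values:
            if isinstance(v, Literal):
                return v.lexical
        return default

    prov_meta = ProvenanceMetadata(
        creator=_lex(_pop_values(provenance, unit_upri, vocab.DCTERMS_CREATOR)),
        created=_lex(_pop_values(provenance, unit_upri, vocab.PROV_GENERATED_AT_TIME)),
        application=_lex(_pop_values(provenance, unit_upri, vocab.APPLICATION)),
        title=_lex(_pop_values(pubinfo, np_upri, vocab.DCTERMS_TITLE)),
        contributors=[
            v.lexical
            for v in _pop_values(pubinfo, np_upri, vocab.DCTERMS_CONTRIBUTOR)
            if isinstance(v, Literal)
        ],
        last_update=_lex(_pop_values(pubinfo, np_upri, vocab.DCTERMS_MODIFIED)),
    )
    licenses = _pop_values(pubinfo, np_upri, vocab.DCTERMS_LICENSE)
    restricted = bool(_pop_values(pubinfo, np_upri, vocab.RESTRICTED))
    note = _lex(_pop_values(pubinfo, np_upri, vocab.RESTRICTION_NOTE)) or None
    access = AccessMetadata(
        license=str(licenses[0]) if licenses else None,
        restricted=restricted,
        restriction_note=note if restricted else None,
    )

    if len(assertion):
        objects: list[Term] = []
        i = 1
        while True:
            vals = _pop_values(head, unit_upri, f"{vocab.RDF}_{i}")
            if not vals:
                break
            objects.append(vals[0])
            i += 1
        schema_refs = _pop_values(head, unit_upri, vocab.HAS_SCHEMA)
        unit: SemanticUnit = StatementUnit(
            upri=unit_upri,
            unit_class=unit_class,
            provenance=prov_meta,
            access=access,
            subject=subject or "",
            objects=objects,
            data_graph=assertion,
            schema_ref=str(schema_refs[0])
            if schema_refs
            else vocab.GENERIC_SCHEMA_MARKER,
        )
    else:
        ns = namespace or NamespaceConfig()
        unit = CompoundUnit(
            upri=unit_upri,
            unit_class=unit_class,
            provenance=prov_meta,
            access=access,
            subject=subject,
            associated_units=[
                str(v) for v in _pop_values(head, unit_upri, ns.has_associated)
            ],
            linked_units=[
                str(v) for v in _pop_values(head, unit_upri, ns.has_linked)
            ],
        )
    return unit


def units_equivalent(a: SemanticUnit, b: SemanticUnit) -> bool:
    """Structural equality across Python subtypes (nanopub import returns
    base classes).  Compares identity, class, subject, content, members and
    metadata; ignores display bindings and builder-internal caches."""
    if (a.upri, a.unit_class, a.subject) != (b.upri, b.unit_class, b.subject):
        return False
    if (a.provenance, a.access) != (b.provenance, b.access):
        return False
    if isinstance(a, StatementUnit) != isinstance(b, StatementUnit):
        return False
    if isinstance(a, StatementUnit):
        assert isinstance(b, StatementUnit)
        return (
            a.data_graph == b.data_graph
            and a.objects == b.objects
            and a.schema_ref == b.schema_ref
        )
    if isinstance(a, CompoundUnit):
        assert isinstance(b, CompoundUnit)
        return (
            sorted(a.associated_units) == sorted(b.associated_units)
            and sorted(a.linked_units) == sorted(b.linked_units)
        )
    return True


def stores_equivalent(a: KnowledgeGraphStore, b: KnowledgeGraphStore) -> bool:
    if a.data_layer != b.data_layer:
        return False
    if set(a.units) != set(b.units):
        return False
    return all(units_equivalent(a.units[k], b.units[k]) for k in a.units)


# ---------------------------------------------------------------------------
# labeled property graph


@dataclass
class LpgRecord:
    kind: str  # node | relationship
    element_id: str
    properties: dict


def _triple_claims(store: KnowledgeGraphStore) -> dict[Triple, UPRI]:
    claims: dict[Triple, UPRI] = {}
    for unit in store.statement_units():
        for t in unit.data_graph:
            if t in store.data_layer:
                claims.setdefault(t, unit.upri)
    return claims


def _compound_memberships(store: KnowledgeGraphStore) -> dict[UPRI, list[UPRI]]:
    """statement-unit UPRI -> sorted compound UPRIs transitively containing it."""
    out: dict[UPRI, set[UPRI]] = {}
    direct: dict[UPRI, set[UPRI]] = {}
    for unit in store.compound_units():
        for member in unit.associated_units:
            direct.setdefault(member, set()).add(unit.upri)

    def containers(upri: UPRI, seen: frozenset = frozenset()) -> set[UPRI]:
        result = set()
        for parent in direct.get(upri, ()):  # walk up the containment DAG
            if parent in seen:
                continue
            result.add(parent)
            result |= containers(parent, seen | {parent})
        return result

    for unit in store.statement_units():
        out[unit.upri] = containers(unit.upri)
    return {k: sorted(v) for k, v in out.items()}


def export_lpg(
    store: KnowledgeGraphStore,
) -> tuple[list[LpgRecord], str, str]:
    """LPG records plus node/relationship CSV in bulk-import layout.

    One node per data-layer resource, one relationship per data-layer triple.
    Every element carries its UPRI and the UPRI of its statement unit; array
    properties (compound memberships) are ';'-joined in the CSV.
    """
    claims = _triple_claims(store)
    unclaimed = [t for t in store.data_layer if t not in claims]
    if unclaimed:
        raise StateError(
            f"store not fully partitioned: {len(unclaimed)} unclaimed triples"
        )
    memberships = _compound_memberships(store)

    resources = sorted(store.data_layer.resources())
    node_ids = {r: f"n{i}" for i, r in enumerate(resources)}
    # a node's statement unit: the unit claiming the first triple in which
    # the node is subject; fallback, the first triple mentioning it
    node_unit: dict[UPRI, UPRI] = {}
    for t in store.data_layer:
        claim = claims[t]
        node_unit.setdefault(t.subject, claim)
    for t in store.data_layer:
        if not isinstance(t.object, Literal):
            node_unit.setdefault(t.object, claims[t])

    records: list[LpgRecord] = []
    for r in resources:
        su = node_unit[r]
        records.append(
            LpgRecord(
                kind="node",
                element_id=node_ids[r],
                properties={
                    "UPRI": r,
                    "statement_unit_UPRI": su,
                    "compound_unit_UPRI": memberships.get(su, []),
                },
            )
        )
    for i, t in enumerate(sorted(store.data_layer, key=triple_sort_key)):
        su = claims[t]
        props = {
            "UPRI": mint_upri(
                "relationship",
                f"{t.subject}\n{t.predicate}\n{_nt_term(t.object)}",
                store.namespace.base,
            ),
            "type": t.predicate,
            "start": node_ids[t.subject],
            "statement_unit_UPRI": su,
            "compound_unit_UPRI": memberships.get(su, []),
        }
        if isinstance(t.object, Literal):
            props["end"] = ""
            props["value"] = t.object.lexical
            props["value_datatype"] = t.object.datatype
        else:
            props["end"] = node_ids[t.object]
            props["value"] = ""
            props["value_datatype"] = ""
        records.append(LpgRecord(kind="relationship", element_id=f"r{i}", properties=props))

    nodes_csv = io.StringIO()
    w = csv.writer(nodes_csv, lineterminator="\n")
    w.writerow(["nodeId:ID", "UPRI", "statement_unit_UPRI", "compound_unit_UPRI"])
    for rec in records:
        if rec.kind == "node":
            p = rec.properties
            w.writerow(
                [
                    rec.element_id,
                    p["UPRI"],
                    p["statement_unit_UPRI"],
                    ";".join(p["compound_unit_UPRI"]),
                ]
            )
    rels_csv = io.StringIO()
    w = csv.writer(rels_csv, lineterminator="\n")
    w.writerow(
        [
            ":START_ID",
            ":END_ID",
            ":TYPE",
            "UPRI",
            "value",
            "value_datatype",
            "statement_unit_UPRI",
            "compound_unit_UPRI",
        ]
    )
    for rec in records:
        if rec.kind == "relationship":
            p = rec.properties
            w.writerow(
                [
                    p["start"],
                    p["end"],
                    p["type"],
                    p["UPRI"],
                    p["value"],
                    p["value_datatype"],
                    p["statement_unit_UPRI"],
                    ";".join(p["compound_unit_UPRI"]),
                ]
            )
    return records, nodes_csv.getvalue(), rels_csv.getvalue()


# ---------------------------------------------------------------------------
# registry JSON

_REGISTRY_VERSION = 1

_UNIT_KINDS = {
    cls.__name__: cls
    for cls in (
        StatementUnit,
        NamedIndividualIdentificationUnit,
        ClassIdentificationUnit,
        CompoundUnit,
        TypedStatementUnit,
        ItemUnit,
        ItemGroupUnit,
        GranularityTreeUnit,
        GranularItemGroupUnit,
        ContextUnit,
        DatasetUnit,
        ListUnit,
    )
}


def _term_to_json(term: Term):
    if isinstance(term, Literal):
        out = {"lexical": term.lexical, "datatype": term.datatype}
        if term.language:
            out["language"] = term.language
        return out
    return term


def _term_from_json(raw) -> Term:
    if isinstance(raw, dict):
        return Literal(raw["lexical"], raw["datatype"], raw.get("language"))
    return raw


def _triples_to_json(graph: DataGraph) -> list:
    return [
        [t.subject, t.predicate, _term_to_json(t.object)]
        for t in sorted(graph, key=triple_sort_key)
    ]


def _triples_from_json(raw: list) -> DataGraph:
    return DataGraph(Triple(s, p, _term_from_json(o)) for s, p, o in raw)


def _unit_to_json(unit: SemanticUnit) -> dict:
    out: dict = {"unit_type": type(unit).__name__}
    for f in dc_fields(unit):
        value = getattr(unit, f.name)
        if f.name == "provenance":
            value = value.__dict__.copy()
        elif f.name == "access":
            value = value.__dict__.copy()
        elif isinstance(value, DataGraph):
            value = _triples_to_json(value)
        elif f.name == "objects":
            value = [_term_to_json(v) for v in value]
        elif f.name == "bindings":
            value = {k: _term_to_json(v) for k, v in sorted(value.items())}
        elif f.name == "cardinality" and value is not None:
            value = list(value)
        out[f.name] = value
    return out


def _unit_from_json(raw: dict) -> SemanticUnit:
    kind = raw.get("unit_type")
    cls = _UNIT_KINDS.get(kind)
    if cls is None:
        raise FormatError(f"unknown unit type: {kind!r}")
    kwargs = {}
    for f in dc_fields(cls):
        if f.name not in raw:
            continue
        value = raw[f.name]
        if f.name == "provenance":
            value = ProvenanceMetadata(**value)
        elif f.name == "access":
            value = AccessMetadata(**value)
        elif f.name == "data_graph":
            value = _triples_from_json(value)
        elif f.name == "objects":
            value = [_term_from_json(v) for v in value]
        elif f.name == "bindings":
            value = {k: _term_from_json(v) for k, v in value.items()}
        elif f.name == "cardinality" and value is not None:
            value = tuple(value)
        elif f.name == "indices":
            value = {k: int(v) for k, v in value.items()}
        kwargs[f.name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"malformed unit record: {exc}") from exc


def export_registry_json(store: KnowledgeGraphStore) -> str:
    doc = {
        "format": "semantic-units-registry",
        "version": _REGISTRY_VERSION,
        "namespace": store.namespace.__dict__.copy(),
        "default_provenance": store.default_provenance.__dict__.copy()
        if store.default_provenance
        else None,
        "data_layer": _triples_to_json(store.data_layer),
        "semantic_units_layer": _triples_to_json(store.semantic_units_layer),
        "schemas": [schema_to_dict(s) for _, s in sorted(store.schemas.items())],
        "units": [_unit_to_json(u) for _, u in sorted(store.units.items())],
    }
    return json.dumps(doc, sort_keys=True, indent=1, ensure_ascii=False) + "\n"


def import_registry_json(text: str) -> KnowledgeGraphStore:
    try:
        doc = json.loads(text)
    except json.JSONDecodeError as exc:
        raise FormatError(f"registry JSON does not parse: {exc}") from exc
    if doc.get("format") != "semantic-units-registry":
        raise FormatError("not a semantic-units registry document")
    if doc.get("version") != _REGISTRY_VERSION:
        raise FormatError(f"unsupported registry version: {doc.get('version')}")
    try:
        store = KnowledgeGraphStore(NamespaceConfig(**doc["namespace"]))
        raw_prov = doc.get("default_provenance")
        if raw_prov:
            store.default_provenance = ProvenanceMetadata(**raw_prov)
        store.data_layer = _triples_from_json(doc["data_layer"])
        for raw in doc["units"]:
            unit = _unit_from_json(raw)
            store.units[unit.upri] = unit
        store.semantic_units_layer = _triples_from_json(doc["semantic_units_layer"])
        store.schemas = {
            s.class_upri: s
            for s in (schema_from_dict(raw, {}) for raw in doc.get("schemas", []))
        }
    except (KeyError, TypeError) as exc:
        raise FormatError(f"malformed registry document: {exc}") from exc
    return store
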