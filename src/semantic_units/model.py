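"""Core domain model: the two-layer knowledge-graph architecture.

A knowledge graph is split into a *data graph layer* (the original
subject–predicate–object triples) and a *semantic-units graph layer* (the
triples that describe the units themselves).  Every semantic unit is a
subgraph identified by its own resource, a UPRI (Unique Persistent and
Resolvable Identifier), which simultaneously names the unit and the unit's
data graph.  Statement units are the atoms: the partition of the data layer.
Compound units are containers of other units; their data graph is the merge
of their members' data graphs.
"""

from __future__ import annotations

import hashlib
import re
from dataclasses import dataclass, field, replace
from datetime import datetime, timezone
from typing import Iterable, Iterator, Optional, Union

from . import vocab
from .errors import CycleError, NotFoundError, UnresolvedMemberError

__all__ = [
    "UPRI",
    "Literal",
    "Triple",
    "DataGraph",
    "ProvenanceMetadata",
    "AccessMetadata",
    "SemanticUnit",
    "StatementUnit",
    "CompoundUnit",
    "KnowledgeGraphStore",
    "NamespaceConfig",
    "mint_upri",
    "is_absolute_iri",
    "triple_sort_key",
]

#: a UPRI is an absolute IRI string; kept as ``str`` so units interoperate
#: directly with rdflib and plain-dict JSON.
UPRI = str

_ABSOLUTE_IRI = re.compile(r"^[A-Za-z][A-Za-z0-9+.-]*:\S+$")


def is_absolute_iri(value: str) -> bool:
    return bool(_ABSOLUTE_IRI.match(value)) and " " not in value


@dataclass(frozen=True)
class Literal:
    """An RDF literal: lexical form plus datatype, optional language tag."""

    lexical: str
    datatype: str = vocab.XSD_STRING
    language: Optional[str] = None

    def __post_init__(self) -> None:
        if self.language is not None and self.datatype != vocab.RDF_LANGSTRING:
            raise ValueError(
                "language tag requires the rdf:langString datatype, "
                f"got {self.datatype!r}"
            )


Term = Union[UPRI, Literal]


@dataclass(frozen=True)
class Triple:
    """A single statement.  Subject and predicate are always resources."""

    subject: UPRI
    predicate: UPRI
    object: Term

    def __post_init__(self) -> None:
        for role, term in (("subject", self.subject), ("predicate", self.predicate)):
            if isinstance(term, Literal):
                raise ValueError(f"{role} must be a resource, not a literal")
            if not is_absolute_iri(term):
                raise ValueError(f"{role} is not an absolute IRI: {term!r}")

    def terms(self) -> tuple[Term, Term, Term]:
        return (self.subject, self.predicate, self.object)


def _term_key(term: Term) -> tuple:
    if isinstance(term, Literal):
        return (1, term.lexical, term.datatype, term.language or "")
    return (0, term)


def triple_sort_key(t: Triple) -> tuple:
    """Canonical ordering used everywhere a reproducible byte stream matters."""
    return (t.subject, t.predicate, _term_key(t.object))


class DataGraph:
    """A blank-node-free set of triples with set semantics.

    Thin wrapper over ``set[Triple]`` adding canonical iteration and the
    term/resource views the partitioner and compounders need.
    """

    __slots__ = ("_triples",)

    def __init__(self, triples: Iterable[Triple] = ()) -> None:
        self._triples: set[Triple] = set(triples)

    # -- set protocol -------------------------------------------------------
    def __len__(self) -> int:
        return len(self._triples)

    def __iter__(self) -> Iterator[Triple]:
        return iter(sorted(self._triples, key=triple_sort_key))

    def __contains__(self, triple: Triple) -> bool:
        return triple in self._triples

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, DataGraph):
            return NotImplemented
        return self._triples == other._triples

    def __hash__(self) -> int:  # frozen-ish: hash of frozenset snapshot
        return hash(frozenset(self._triples))

    def __repr__(self) -> str:
        return f"DataGraph({len(self._triples)} triples)"

    def add(self, triple: Triple) -> None:
        self._triples.add(triple)

    def update(self, triples: Iterable[Triple]) -> None:
        self._triples.update(triples)

    def discard(self, triple: Triple) -> None:
        self._triples.discard(triple)

    def copy(self) -> "DataGraph":
        return DataGraph(self._triples)

    def union(self, other: "DataGraph") -> "DataGraph":
        return DataGraph(self._triples | other._triples)

    def intersection(self, other: "DataGraph") -> "DataGraph":
        return DataGraph(self._triples & other._triples)

    def difference(self, other: "DataGraph") -> "DataGraph":
        return DataGraph(self._triples - other._triples)

    def as_set(self) -> frozenset[Triple]:
        return frozenset(self._triples)

    # -- views --------------------------------------------------------------
    def subjects(self) -> set[UPRI]:
        return {t.subject for t in self._triples}

    def resources(self) -> set[UPRI]:
        """All IRIs in subject or object position (predicates excluded)."""
        out = {t.subject for t in self._triples}
        out.update(t.object for t in self._triples if not isinstance(t.object, Literal))
        return out

    def terms(self) -> set[Term]:
        out: set[Term] = set()
        for t in self._triples:
            out.update(t.terms())
        return out

    def triples_with_subject(self, subject: UPRI) -> list[Triple]:
        return sorted(
            (t for t in self._triples if t.subject == subject), key=triple_sort_key
        )


def canonical_graph_key(triples: Iterable[Triple]) -> str:
    """Stable serialization of a triple set, used as UPRI content key."""
    parts = []
    for t in sorted(triples, key=triple_sort_key):
        o = t.object
        if isinstance(o, Literal):
            obj = f'"{o.lexical}"^^{o.datatype}@{o.language or ""}'
        else:
            obj = f"<{o}>"
        parts.append(f"<{t.subject}> <{t.predicate}> {obj}")
    return "\n".join(parts)


def mint_upri(
    kind: str, content_key: str, namespace: str = vocab.DEFAULT_BASE
) -> UPRI:
    """Deterministic, content-addressed IRI under the configured namespace.

    Same ``(kind, content_key, namespace)`` always mints the same IRI;
    distinct keys mint distinct IRIs (SHA-256 content hash, 20 hex chars).
    """
    if not content_key:
        raise ValueError("content_key must be non-empty")
    if not kind:
        raise ValueError("kind must be non-empty")
    digest = hashlib.sha256(
        f"{kind}\x00{content_key}".encode("utf-8")
    ).hexdigest()[:20]
    return f"{namespace}{kind}/{digest}"


def _now_iso() -> str:
    # +00:00 offset form: stable under xsd:dateTime lexical normalization
    return datetime.now(timezone.utc).isoformat(timespec="seconds")


@dataclass
class ProvenanceMetadata:
    """Who made the unit, when, and with what application."""

    creator: str = "semantic-units"
    created: str = field(default_factory=_now_iso)
    application: str = "semantic-units/0.1.0"
    title: str = ""
    contributors: list[str] = field(default_factory=list)
    last_update: str = ""

    def __post_init__(self) -> None:
        if not self.last_update:
            self.last_update = self.created
        if self.last_update < self.created:
            raise ValueError("last_update must not precede created")


@dataclass
class AccessMetadata:
    license: Optional[str] = None
    restricted: bool = False
    restriction_note: Optional[str] = None

    def __post_init__(self) -> None:
        if self.restriction_note is not None and not self.restricted:
            raise ValueError("restriction_note requires restricted=True")


@dataclass
class SemanticUnit:
    """Abstract base: an identifiable subgraph represented by its own resource.

    The UPRI doubles as the identifier of the unit's data graph, so triples
    elsewhere in the graph can reference the unit's content as a whole.
    """

    upri: UPRI
    unit_class: UPRI
    provenance: ProvenanceMetadata = field(default_factory=ProvenanceMetadata)
    access: AccessMetadata = field(default_factory=AccessMetadata)

    @property
    def subject(self) -> Optional[UPRI]:
        return None


@dataclass
class StatementUnit(SemanticUnit):
    """Smallest independent proposition: one subject, one or more objects.

    The data graph holds 1..n triples depending on the arity of the relation
    underlying the proposition: a binary relation (e.g. parthood) needs a
    single triple, an n-ary one (e.g. a measurement with value and unit)
    needs several, connected through instance resources.
    """

    subject: UPRI = ""
    objects: list[Term] = field(default_factory=list)
    data_graph: DataGraph = field(default_factory=DataGraph)
    schema_ref: UPRI = vocab.GENERIC_SCHEMA_MARKER
    #: variable -> bound term, retained for display-pattern rendering
    bindings: dict[str, Term] = field(default_factory=dict)

    def validate(self) -> None:
        if not self.objects:
            raise ValueError("statement unit requires at least one object")
        if len(self.data_graph) == 0:
            raise ValueError("statement unit data graph must be non-empty")
        if self.subject not in self.data_graph.subjects():
            raise ValueError("subject must occur in the data graph")
        terms = self.data_graph.terms()
        for obj in self.objects:
            if obj not in terms:
                raise ValueError(f"object {obj!r} does not occur in the data graph")
        if not _weakly_connected(self.data_graph):
            raise ValueError("statement unit data graph must be weakly connected")


def _weakly_connected(graph: DataGraph) -> bool:
    triples = list(graph)
    if len(triples) <= 1:
        return True
    # union-find over subject/object terms (predicates do not connect)
    parent: dict = {}

    def find(x):
        while parent.setdefault(x, x) != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for t in triples:
        a, b = find(_term_key(t.subject)), find(_term_key(t.object))
        if a != b:
            parent[a] = b
    roots = {find(_term_key(t.subject)) for t in triples}
    return len(roots) == 1


@dataclass
class CompoundUnit(SemanticUnit):
    """Container of associated semantic units.

    The data graph of a compound unit is not stored: it is the merge of the
    data graphs of its associated units (recursively), materialized on demand
    by :meth:`KnowledgeGraphStore.merged_data_graph`.
    """

    associated_units: list[UPRI] = field(default_factory=list)
    linked_units: list[UPRI] = field(default_factory=list)
    subject: Optional[UPRI] = None

    def validate(self) -> None:
        if not self.associated_units:
            raise ValueError("compound unit requires at least one associated unit")


@dataclass(frozen=True)
class NamespaceConfig:
    """Base namespace and overridable vocabulary IRIs for one store."""

    base: str = vocab.DEFAULT_BASE
    has_subject: str = vocab.HAS_SEMANTIC_UNIT_SUBJECT
    has_associated: str = vocab.HAS_ASSOCIATED_SEMANTIC_UNIT
    has_linked: str = vocab.HAS_LINKED_SEMANTIC_UNIT
    child: str = vocab.CHILD
    index: str = vocab.INDEX

    def mint(self, kind: str, content_key: str) -> UPRI:
        return mint_upri(kind, content_key, self.base)


class KnowledgeGraphStore:
    """Registry of semantic units plus the two graph layers.

    Invariants maintained here: the layers are disjoint triple sets; every
    registered unit has its instantiation triple in the semantic-units layer;
    no two distinct units share a UPRI.
    """

    def __init__(self, namespace: NamespaceConfig | None = None) -> None:
        self.namespace = namespace or NamespaceConfig()
        self.data_layer = DataGraph()
        self.units: dict[UPRI, SemanticUnit] = {}
        self.semantic_units_layer = DataGraph()
        #: schema registry (class UPRI -> StatementUnitSchema), filled by organize()
        self.schemas: dict = {}
        #: when set, builders stamp new units with a copy of this metadata
        #: instead of wall-clock defaults (fixtures use this for reproducible
        #: byte-identical exports)
        self.default_provenance: ProvenanceMetadata | None = None

    def new_provenance(self) -> ProvenanceMetadata:
        if self.default_provenance is not None:
            return replace(self.default_provenance)
        return ProvenanceMetadata()

    # -- registry -----------------------------------------------------------
    def register(self, unit: SemanticUnit) -> None:
        existing = self.units.get(unit.upri)
        if existing is not None and existing is not unit:
            raise ValueError(f"UPRI already registered: {unit.upri}")
        self.units[unit.upri] = unit
        from .partition import emit_semantic_units_layer  # cycle-free at call time

        self.semantic_units_layer.update(
            emit_semantic_units_layer([unit], self.namespace)
        )

    def get(self, upri: UPRI) -> SemanticUnit:
        try:
            return self.units[upri]
        except KeyError:
            raise NotFoundError(f"no unit registered for {upri}") from None

    def statement_units(self) -> list[StatementUnit]:
        return [
            u
            for _, u in sorted(self.units.items())
            if isinstance(u, StatementUnit)
        ]

    def compound_units(self) -> list[CompoundUnit]:
        return [
            u for _, u in sorted(self.units.items()) if isinstance(u, CompoundUnit)
        ]

    def units_of_class(self, unit_class: UPRI) -> list[SemanticUnit]:
        return [
            u for _, u in sorted(self.units.items()) if u.unit_class == unit_class
        ]

    # -- layers -------------------------------------------------------------
    def layer_of(self, triple: Triple) -> str:
        """Which layer holds the triple: ``"data"`` or ``"semantic_units"``."""
        in_data = triple in self.data_layer
        in_units = triple in self.semantic_units_layer
        if in_data and in_units:
            raise ValueError("layer invariant violated: triple present in both layers")
        if in_data:
            return "data"
        if in_units:
            return "semantic_units"
        raise NotFoundError("triple present in neither layer")

    def rebuild_semantic_units_layer(self) -> None:
        from .partition import emit_semantic_units_layer

        self.semantic_units_layer = emit_semantic_units_layer(
            [u for _, u in sorted(self.units.items())], self.namespace
        )
        # list units keep their membership triples in this layer (their
        # subject is a unit resource, not a data-layer resource)
        for _, unit in sorted(self.units.items()):
            members = getattr(unit, "member_resources", None)
            if members:
                for member in members:
                    self.semantic_units_layer.add(
                        Triple(unit.upri, self.namespace.child, member)
                    )

    # -- compound data graphs ------------------------------------------------
    def merged_data_graph(self, unit: SemanticUnit) -> DataGraph:
        """Union of member data graphs, recursing through nested compounds.

        Raises :class:`CycleError` on cyclic membership and
        :class:`UnresolvedMemberError` on dangling member UPRIs.
        """
        out = DataGraph()
        self._merge_into(unit, out, visiting=set())
        return out

    def _merge_into(
        self, unit: SemanticUnit, out: DataGraph, visiting: set[UPRI]
    ) -> None:
        if unit.upri in visiting:
            raise CycleError(f"cyclic compound membership at {unit.upri}")
        if isinstance(unit, StatementUnit):
            out.update(unit.data_graph)
            return
        if isinstance(unit, CompoundUnit):
            visiting.add(unit.upri)
            for member in unit.associated_units:
                if member not in self.units:
                    raise UnresolvedMemberError(
                        f"compound {unit.upri} references unregistered {member}"
                    )
                self._merge_into(self.units[member], out, visiting)
            visiting.discard(unit.upri)

    def copy_shallow(self) -> "KnowledgeGraphStore":
        clone = KnowledgeGraphStore(self.namespace)
        clone.data_layer = self.data_layer.copy()
        clone.units = dict(self.units)
        clone.semantic_units_layer = self.semantic_units_layer.copy()
        clone.schemas = dict(self.schemas)
        clone.default_provenance = self.default_provenance
        return clone


def touch(unit: SemanticUnit) -> SemanticUnit:
    """Return a copy with ``last_update`` set to now (units are value-like)."""
    prov = replace(unit.provenance, last_update=_now_iso())
    unit.provenance = prov
    return unit
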