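"""Vocabulary table: IRIs used across the two graph layers.

All semantic-unit classes and properties live under the SEMUNIT namespace;
they can be overridden per-store via :class:`semantic_units.model.NamespaceConfig`.
Well-known external IRIs (RDF, RDFS, OBO Relation Ontology, IAO) are plain
string constants so that the data model stays independent of any RDF library.
"""

# -- base namespaces ---------------------------------------------------------

SEMUNIT = "https://w3id.org/semunit/"
SEMUNIT_VOCAB = SEMUNIT + "vocab/"
DEFAULT_BASE = "https://w3id.org/semunit/id/"

RDF = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
RDFS = "http://www.w3.org/2000/01/rdf-schema#"
OWL = "http://www.w3.org/2002/07/owl#"
XSD = "http://www.w3.org/2001/XMLSchema#"
DCTERMS = "http://purl.org/dc/terms/"
PROV = "http://www.w3.org/ns/prov#"
NP = "http://www.nanopub.org/nschema#"
OBO = "http://purl.obolibrary.org/obo/"

RDF_TYPE = RDF + "type"
RDF_LANGSTRING = RDF + "langString"
RDFS_LABEL = RDFS + "label"
RDFS_IS_DEFINED_BY = RDFS + "isDefinedBy"
OWL_VERSION_IRI = OWL + "versionIRI"
DCTERMS_IDENTIFIER = DCTERMS + "identifier"

XSD_STRING = XSD + "string"
XSD_DECIMAL = XSD + "decimal"
XSD_INTEGER = XSD + "integer"
XSD_BOOLEAN = XSD + "boolean"
XSD_DATETIME = XSD + "dateTime"

# -- SEMUNIT properties ------------------------------------------------------

HAS_SEMANTIC_UNIT_SUBJECT = SEMUNIT_VOCAB + "hasSemanticUnitSubject"
HAS_ASSOCIATED_SEMANTIC_UNIT = SEMUNIT_VOCAB + "hasAssociatedSemanticUnit"
HAS_LINKED_SEMANTIC_UNIT = SEMUNIT_VOCAB + "hasLinkedSemanticUnit"
CHILD = SEMUNIT_VOCAB + "child"
INDEX = SEMUNIT_VOCAB + "index"
HAS_SCHEMA = SEMUNIT_VOCAB + "hasSchema"
ASSERTS = SEMUNIT_VOCAB + "asserts"
AT_TIME = SEMUNIT_VOCAB + "atTime"
RESTRICTED = SEMUNIT_VOCAB + "restricted"
RESTRICTION_NOTE = SEMUNIT_VOCAB + "restrictionNote"

# -- SEMUNIT unit classes (Fig-5-style taxonomy) -----------------------------

STATEMENT_UNIT = SEMUNIT + "StatementUnit"
GENERIC_STATEMENT_UNIT = SEMUNIT + "GenericStatementUnit"  # single-triple fallback
NAMED_INDIVIDUAL_IDENTIFICATION_UNIT = SEMUNIT + "NamedIndividualIdentificationUnit"
CLASS_IDENTIFICATION_UNIT = SEMUNIT + "ClassIdentificationUnit"

COMPOUND_UNIT = SEMUNIT + "CompoundUnit"
TYPED_STATEMENT_UNIT = SEMUNIT + "TypedStatementUnit"
ITEM_UNIT = SEMUNIT + "ItemUnit"
ITEM_GROUP_UNIT = SEMUNIT + "ItemGroupUnit"
GRANULARITY_TREE_UNIT = SEMUNIT + "GranularityTreeUnit"
GRANULAR_ITEM_GROUP_UNIT = SEMUNIT + "GranularItemGroupUnit"
CONTEXT_UNIT = SEMUNIT + "ContextUnit"
DATASET_UNIT = SEMUNIT + "DatasetUnit"
LIST_UNIT = SEMUNIT + "ListUnit"
ORDERED_LIST_UNIT = SEMUNIT + "OrderedListUnit"
UNORDERED_LIST_UNIT = SEMUNIT + "UnorderedListUnit"
SET_UNIT = SEMUNIT + "SetUnit"
LIST_MEMBERSHIP_STATEMENT_UNIT = SEMUNIT + "ListMembershipStatementUnit"

# statement-unit classes shipped with the builtin schema library
HAS_PART_STATEMENT_UNIT = SEMUNIT + "HasPartStatementUnit"
TYPE_STATEMENT_UNIT = SEMUNIT + "TypeStatementUnit"
WEIGHT_STATEMENT_UNIT = SEMUNIT + "WeightStatementUnit"
METRIC_MEASUREMENT_STATEMENT_UNIT = SEMUNIT + "MetricMeasurementStatementUnit"
LOCATED_IN_AT_TIME_STATEMENT_UNIT = SEMUNIT + "LocatedInAtTimeStatementUnit"
IS_ABOUT_STATEMENT_UNIT = SEMUNIT + "IsAboutStatementUnit"
ASSERTS_STATEMENT_UNIT = SEMUNIT + "AssertsStatementUnit"

GENERIC_SCHEMA_MARKER = SEMUNIT_VOCAB + "generic-fallback"

# -- external IRIs used by builtin schemas and fixtures ----------------------

HAS_QUALITY = OBO + "RO_0000086"
IS_QUALITY_MEASURED_AS = OBO + "IAO_0000417"
HAS_VALUE_SPECIFICATION = OBO + "OBI_0001938"
HAS_SPECIFIED_NUMERIC_VALUE = OBO + "OBI_0001937"
HAS_MEASUREMENT_UNIT_LABEL = OBO + "IAO_0000039"
HAS_PART = OBO + "BFO_0000051"
LOCATED_IN = OBO + "RO_0001025"
IS_ABOUT = OBO + "IAO_0000136"

IDENTIFICATION_UNIT_CLASSES = frozenset(
    {NAMED_INDIVIDUAL_IDENTIFICATION_UNIT, CLASS_IDENTIFICATION_UNIT}
)

#: default CURIE prefix map for schema files and display fallbacks
PREFIXES = {
    "rdf": RDF,
    "rdfs": RDFS,
    "owl": OWL,
    "xsd": XSD,
    "dcterms": DCTERMS,
    "prov": PROV,
    "np": NP,
    "obo": OBO,
    "semunit": SEMUNIT,
    "semunitv": SEMUNIT_VOCAB,
}


def expand_curie(term: str, prefixes: dict[str, str] | None = None) -> str:
    """Expand ``prefix:local`` against a prefix map; full IRIs pass through."""
    table = dict(PREFIXES)
    if prefixes:
        table.update(prefixes)
    if "://" in term or term.startswith("urn:"):
        return term
    if ":" in term:
        prefix, local = term.split(":", 1)
        if prefix in table:
            return table[prefix] + local
    return term


def compact_iri(iri: str, prefixes: dict[str, str] | None = None) -> str:
    """Best-effort CURIE for display; returns the IRI itself when no prefix fits."""
    table = dict(PREFIXES)
    if prefixes:
        table.update(prefixes)
    best = ""
    best_prefix = None
    for prefix, base in table.items():
        if iri.startswith(base) and len(base) > len(best):
            best, best_prefix = base, prefix
    if best_prefix is None:
        return iri
    return f"{best_prefix}:{iri[len(best):]}"


# -- provenance / pubinfo predicates used by the nanopublication mapping -----

NP_NANOPUBLICATION = NP + "Nanopublication"
NP_HAS_ASSERTION = NP + "hasAssertion"
NP_HAS_PROVENANCE = NP + "hasProvenance"
NP_HAS_PUBLICATION_INFO = NP + "hasPublicationInfo"

DCTERMS_CREATOR = DCTERMS + "creator"
DCTERMS_TITLE = DCTERMS + "title"
DCTERMS_CONTRIBUTOR = DCTERMS + "contributor"
DCTERMS_MODIFIED = DCTERMS + "modified"
DCTERMS_LICENSE = DCTERMS + "license"
PROV_GENERATED_AT_TIME = PROV + "generatedAtTime"
APPLICATION = SEMUNIT_VOCAB + "application"
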