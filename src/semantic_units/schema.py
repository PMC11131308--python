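"""Declarative statement-unit schemas: graph patterns with variables.

Each statement-unit class is defined by a schema — an ordered list of triple
templates over variables and constants.  Matching a schema against a data
graph at an anchor resource yields bindings; the triples a binding
instantiates become the data graph of one statement unit.  The dialect is a
small YAML format (one ``schemas:`` list per file) with a CURIE prefix map;
it is deliberately less expressive than SHACL/ShEx: conjunctive patterns
with required and optional variables only, no recursion, no negation.

Variables are spelled ``?name``.  Constants may be full IRIs, CURIEs
(expanded against the file's prefix map merged over the builtin one), or
literals written as ``{"value": ..., "datatype": ...}``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Union

import yaml

from . import vocab
from .errors import SchemaError
from .model import DataGraph, Literal, Term, Triple, UPRI, triple_sort_key

__all__ = [
    "StatementUnitSchema",
    "Binding",
    "load_schemas",
    "dump_schemas",
    "match_schema",
    "builtin_schemas",
]

TemplateTerm = Union[str, Literal]  # "?var", constant IRI, or Literal
Template = tuple[TemplateTerm, str, TemplateTerm]  # predicate: IRI or "?var"


def is_var(term: TemplateTerm) -> bool:
    return isinstance(term, str) and term.startswith("?")


@dataclass
class StatementUnitSchema:
    """Graph pattern defining one statement-unit class."""

    class_upri: UPRI
    label: str
    subject_var: str
    object_vars: list[tuple[str, bool]]  # (variable, required)
    triple_templates: list[Template]
    relation_kind: str = "nary-instance"  # or "binary-property"
    partial_order: bool = False
    dynamic_label_template: str = ""
    mind_map_template: Optional[str] = None
    priority: int = 0

    @property
    def arity(self) -> int:
        return len(self.object_vars)

    def variables(self) -> set[str]:
        out = set()
        for s, p, o in self.triple_templates:
            for term in (s, p, o):
                if is_var(term):
                    out.add(term)
        return out

    def required_variables(self) -> set[str]:
        optional = {v for v, required in self.object_vars if not required}
        return self.variables() - optional

    def validate(self) -> None:
        if self.arity < 1:
            raise SchemaError(f"{self.class_upri}: needs at least one object slot")
        if not any(req for _, req in self.object_vars):
            raise SchemaError(f"{self.class_upri}: needs >=1 required object")
        tvars = self.variables()
        if self.subject_var not in tvars:
            raise SchemaError(
                f"{self.class_upri}: subject variable {self.subject_var} "
                "does not occur in any template"
            )
        for v, _ in self.object_vars:
            if v not in tvars:
                raise SchemaError(
                    f"{self.class_upri}: object variable {v} "
                    "does not occur in any template"
                )
        if self.relation_kind == "binary-property" and len(self.triple_templates) != 1:
            raise SchemaError(
                f"{self.class_upri}: binary-property schemas have exactly one "
                "triple template"
            )
        if self.relation_kind not in ("binary-property", "nary-instance"):
            raise SchemaError(f"{self.class_upri}: unknown kind {self.relation_kind}")

    #: templates every match must instantiate (no optional variable involved)
    def required_templates(self) -> list[Template]:
        optional = {v for v, req in self.object_vars if not req}
        return [
            t
            for t in self.triple_templates
            if not any(is_var(x) and x in optional for x in t)
        ]

    def optional_templates(self) -> list[Template]:
        required = set(map(tuple, self.required_templates()))
        return [t for t in self.triple_templates if tuple(t) not in required]


@dataclass(frozen=True)
class Binding:
    """One match of a schema: variable assignment + the triples it claims."""

    mapping: tuple[tuple[str, Term], ...]  # sorted (var, term) pairs
    matched_triples: frozenset[Triple]

    def as_dict(self) -> dict[str, Term]:
        return dict(self.mapping)

    def __getitem__(self, var: str) -> Term:
        return dict(self.mapping)[var]


# ---------------------------------------------------------------------------
# matching


def _instantiate(template: Template, env: dict[str, Term]) -> Optional[Triple]:
    """Ground a template under env; None if any variable is unbound."""
    out = []
    for term in template:
        if is_var(term):
            if term not in env:
                return None
            term = env[term]
        out.append(term)
    s, p, o = out
    if isinstance(s, Literal) or isinstance(p, Literal):
        return None
    return Triple(s, p, o)


class GraphIndex:
    """Predicate index over a data graph; lets the matcher touch only the
    triples that can instantiate a template.  Rebuild after mutating the
    indexed graph (the partitioner rebuilds per schema pass)."""

    def __init__(self, graph: DataGraph) -> None:
        self.by_predicate: dict[str, list[Triple]] = {}
        self.by_subject: dict[str, list[Triple]] = {}
        for t in graph:  # canonical order, so candidate order is stable
            self.by_predicate.setdefault(t.predicate, []).append(t)
            self.by_subject.setdefault(t.subject, []).append(t)
        self.all: list[Triple] = sorted(graph, key=triple_sort_key)
        self.terms: set = set()
        for t in self.all:
            self.terms.update(t.terms())

    def candidates(self, template: Template, env: dict[str, Term]) -> list[Triple]:
        s, p, o = template
        if not is_var(p):
            return self.by_predicate.get(p, [])
        subject = env.get(s) if is_var(s) else s
        if isinstance(subject, str):
            return self.by_subject.get(subject, [])
        return self.all


def _match_templates(
    templates: list[Template], index: GraphIndex, env: dict[str, Term]
) -> Iterable[dict[str, Term]]:
    """Backtracking join over the templates, yielding all consistent envs."""
    if not templates:
        yield dict(env)
        return
    head, rest = templates[0], templates[1:]
    for triple in index.candidates(head, env):
        trial = dict(env)
        ok = True
        for slot, term in zip(head, triple.terms()):
            if is_var(slot):
                if slot in trial:
                    if trial[slot] != term:
                        ok = False
                        break
                else:
                    trial[slot] = term
            else:
                if slot != term:
                    ok = False
                    break
        if ok:
            yield from _match_templates(rest, index, trial)


def _binding_sort_key(b: Binding) -> tuple:
    return (
        tuple((v, _term_text(t)) for v, t in b.mapping),
        tuple(sorted(map(triple_sort_key, b.matched_triples))),
    )


def _term_text(term: Term) -> str:
    if isinstance(term, Literal):
        return f'"{term.lexical}"^^{term.datatype}@{term.language or ""}'
    return term


def match_schema(
    schema: StatementUnitSchema,
    graph: DataGraph,
    anchor: UPRI,
    index: GraphIndex | None = None,
) -> list[Binding]:
    """All bindings of ``schema`` in ``graph`` with the subject bound to ``anchor``.

    Bindings are exhaustive for the anchor and deterministic (canonically
    sorted).  Optional variables are bound whenever their templates can be
    matched consistently; unmatched optional templates are simply dropped
    from the claimed triple set.  Pass a prebuilt :class:`GraphIndex` to
    amortize indexing over many anchors.
    """
    idx = index if index is not None else GraphIndex(graph)
    if anchor not in idx.terms:
        raise ValueError(f"anchor {anchor} does not occur in the graph")
    env0 = {schema.subject_var: anchor}
    solutions: dict[tuple, Binding] = {}
    for env in _match_templates(schema.required_templates(), idx, env0):
        # extend with optional templates in template order; each optional
        # template contributes its canonically-smallest consistent extension
        for templ in schema.optional_templates():
            extensions = sorted(
                _match_templates([templ], idx, env),
                key=lambda e: tuple(sorted((v, _term_text(t)) for v, t in e.items())),
            )
            if extensions:
                env = extensions[0]
        matched = frozenset(
            t
            for templ in schema.triple_templates
            if (t := _instantiate(templ, env)) is not None and t in graph
        )
        key = tuple(sorted((v, _term_text(t)) for v, t in env.items()))
        solutions[key] = Binding(
            mapping=tuple(sorted(env.items(), key=lambda kv: kv[0])),
            matched_triples=matched,
        )
    return sorted(solutions.values(), key=_binding_sort_key)


# ---------------------------------------------------------------------------
# YAML dialect

_FIELD_ORDER = [
    "class",
    "label",
    "kind",
    "priority",
    "partial_order",
    "subject",
    "objects",
    "templates",
    "dynamic_label",
    "mind_map",
]


def _term_to_yaml(term: TemplateTerm, prefixes: dict[str, str]) -> object:
    if isinstance(term, Literal):
        d: dict = {"value": term.lexical}
        if term.datatype != vocab.XSD_STRING:
            d["datatype"] = term.datatype
        if term.language:
            d["language"] = term.language
        return d
    return term


def _term_from_yaml(raw: object, prefixes: dict[str, str]) -> TemplateTerm:
    if isinstance(raw, dict):
        datatype = vocab.expand_curie(raw.get("datatype", vocab.XSD_STRING), prefixes)
        language = raw.get("language")
        if language:
            datatype = vocab.RDF_LANGSTRING
        return Literal(str(raw["value"]), datatype, language)
    if isinstance(raw, (int, float)):
        return Literal(str(raw), vocab.XSD_DECIMAL)
    text = str(raw)
    if text.startswith("?"):
        return text
    return vocab.expand_curie(text, prefixes)


def schema_to_dict(schema: StatementUnitSchema) -> dict:
    prefixes = vocab.PREFIXES
    return {
        "class": schema.class_upri,
        "label": schema.label,
        "kind": schema.relation_kind,
        "priority": schema.priority,
        "partial_order": schema.partial_order,
        "subject": schema.subject_var,
        "objects": [
            {"var": v, "required": req} for v, req in schema.object_vars
        ],
        "templates": [
            [_term_to_yaml(s, prefixes), _term_to_yaml(p, prefixes), _term_to_yaml(o, prefixes)]
            for s, p, o in schema.triple_templates
        ],
        "dynamic_label": schema.dynamic_label_template,
        "mind_map": schema.mind_map_template,
    }


def schema_from_dict(raw: dict, prefixes: dict[str, str]) -> StatementUnitSchema:
    try:
        templates = []
        for row in raw["templates"]:
            if len(row) != 3:
                raise SchemaError(f"template must have 3 slots: {row!r}")
            s = _term_from_yaml(row[0], prefixes)
            p = _term_from_yaml(row[1], prefixes)
            o = _term_from_yaml(row[2], prefixes)
            if isinstance(p, Literal):
                raise SchemaError("template predicate cannot be a literal")
            templates.append((s, p, o))
        objects = []
        for obj in raw["objects"]:
            if isinstance(obj, str):
                objects.append((obj, True))
            else:
                objects.append((obj["var"], bool(obj.get("required", True))))
        schema = StatementUnitSchema(
            class_upri=vocab.expand_curie(str(raw["class"]), prefixes),
            label=str(raw.get("label", "")),
            subject_var=str(raw["subject"]),
            object_vars=objects,
            triple_templates=templates,
            relation_kind=str(raw.get("kind", "nary-instance")),
            partial_order=bool(raw.get("partial_order", False)),
            dynamic_label_template=str(raw.get("dynamic_label", "") or ""),
            mind_map_template=raw.get("mind_map"),
            priority=int(raw.get("priority", 0)),
        )
    except KeyError as exc:
        raise SchemaError(f"schema missing field {exc}") from exc
    schema.validate()
    return schema


def load_schemas(text: str) -> list[StatementUnitSchema]:
    """Parse a schema file; validates every schema and the uniqueness of
    class IRIs; returns schemas in stable order (priority desc, class IRI)."""
    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise SchemaError(f"schema file does not parse: {exc}") from exc
    if doc is None:
        return []
    if not isinstance(doc, dict):
        raise SchemaError("schema file must be a mapping with a 'schemas' list")
    prefixes = {str(k): str(v) for k, v in (doc.get("prefixes") or {}).items()}
    schemas = [schema_from_dict(raw, prefixes) for raw in doc.get("schemas") or []]
    seen: set[str] = set()
    for s in schemas:
        if s.class_upri in seen:
            raise SchemaError(f"duplicate schema class: {s.class_upri}")
        seen.add(s.class_upri)
    return sorted(schemas, key=lambda s: (-s.priority, s.class_upri))


def dump_schemas(schemas: list[StatementUnitSchema]) -> str:
    doc = {
        "prefixes": dict(sorted(vocab.PREFIXES.items())),
        "schemas": [schema_to_dict(s) for s in schemas],
    }
    return yaml.safe_dump(doc, sort_keys=False, allow_unicode=True)


# ---------------------------------------------------------------------------
# builtin schema library (mirrors the worked measurement / parthood /
# location / aboutness / membership / assertion patterns)


def _measurement_templates(subject_var: str = "?s") -> list[Template]:
    return [
        (subject_var, vocab.HAS_QUALITY, "?quality"),
        ("?quality", vocab.IS_QUALITY_MEASURED_AS, "?datum"),
        ("?datum", vocab.HAS_VALUE_SPECIFICATION, "?vspec"),
        ("?vspec", vocab.HAS_SPECIFIED_NUMERIC_VALUE, "?value"),
        ("?vspec", vocab.HAS_MEASUREMENT_UNIT_LABEL, "?unit"),
    ]


def builtin_schemas() -> list[StatementUnitSchema]:
    """The shipped statement-unit class library.

    Covers the common binary subcategories (has-part, type, aboutness,
    list membership, assertion) plus the two worked n-ary patterns: the
    scalar measurement (value + unit objects) and located-in-at-time.
    """
    schemas = [
        StatementUnitSchema(
            class_upri=vocab.METRIC_MEASUREMENT_STATEMENT_UNIT,
            label="metric measurement statement unit",
            subject_var="?s",
            object_vars=[("?value", True), ("?unit", True)],
            triple_templates=_measurement_templates(),
            relation_kind="nary-instance",
            dynamic_label_template="{subject} measures {value} {unit}",
            mind_map_template="{subject} -> {value}; {subject} -> {unit}",
            priority=60,
        ),
        StatementUnitSchema(
            class_upri=vocab.LOCATED_IN_AT_TIME_STATEMENT_UNIT,
            label="located-in-at-time statement unit",
            subject_var="?s",
            object_vars=[("?place", True), ("?time", True)],
            triple_templates=[
                ("?s", vocab.LOCATED_IN, "?place"),
                ("?s", vocab.AT_TIME, "?time"),
            ],
            relation_kind="nary-instance",
            dynamic_label_template="{subject} located in {place} at {time}",
            priority=40,
        ),
        StatementUnitSchema(
            class_upri=vocab.IS_ABOUT_STATEMENT_UNIT,
            label="is-about statement unit",
            subject_var="?s",
            object_vars=[("?o", True)],
            triple_templates=[("?s", vocab.IS_ABOUT, "?o")],
            relation_kind="binary-property",
            dynamic_label_template="{subject} is about {o}",
            priority=30,
        ),
        StatementUnitSchema(
            class_upri=vocab.ASSERTS_STATEMENT_UNIT,
            label="asserts statement unit",
            subject_var="?s",
            object_vars=[("?o", True)],  # object is a semantic-unit resource
            triple_templates=[("?s", vocab.ASSERTS, "?o")],
            relation_kind="binary-property",
            dynamic_label_template="{subject} asserts {o}",
            priority=28,
        ),
        StatementUnitSchema(
            class_upri=vocab.LIST_MEMBERSHIP_STATEMENT_UNIT,
            label="list membership statement unit",
            subject_var="?s",
            object_vars=[("?member", True)],
            triple_templates=[("?s", vocab.CHILD, "?member")],
            relation_kind="binary-property",
            dynamic_label_template="{subject} has child {member}",
            priority=25,
        ),
        StatementUnitSchema(
            class_upri=vocab.HAS_PART_STATEMENT_UNIT,
            label="has-part statement unit",
            subject_var="?s",
            object_vars=[("?part", True)],
            triple_templates=[("?s", vocab.HAS_PART, "?part")],
            relation_kind="binary-property",
            partial_order=True,
            dynamic_label_template="{subject} has part {part}",
            mind_map_template="{subject} -> {part}",
            priority=20,
        ),
        StatementUnitSchema(
            class_upri=vocab.TYPE_STATEMENT_UNIT,
            label="type statement unit",
            subject_var="?s",
            object_vars=[("?class", True)],
            triple_templates=[("?s", vocab.RDF_TYPE, "?class")],
            relation_kind="binary-property",
            dynamic_label_template="{subject} is a {class}",
            priority=5,
        ),
    ]
    for s in schemas:
        s.validate()
    return sorted(schemas, key=lambda s: (-s.priority, s.class_upri))
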