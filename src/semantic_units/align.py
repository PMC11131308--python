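"""Unit-level alignment of two stores and single-store profiling.

Alignment proceeds stepwise through the levels of representational
granularity: item group units are compared by the multiset of their member
item units' signatures, item units by (subject class, multiset of member
statement-unit classes), statement units by unit class, and finally the
triples of matched statement units are diffed.  The similarity score is the
Jaccard index over the compared class multisets and the matcher is greedy
maximum-score with deterministic UPRI tie-breaks; both are deliberately
simple and swappable.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Callable, Optional

from . import vocab
from .compound import ItemGroupUnit, ItemUnit, granularity_levels
from .errors import StateError
from .model import (
    KnowledgeGraphStore,
    Literal,
    StatementUnit,
    UPRI,
)

__all__ = ["AlignmentReport", "ProfileReport", "align", "profile", "ALIGNMENT_LEVELS"]

ALIGNMENT_LEVELS = ["item_group", "item", "statement", "triple"]


@dataclass
class AlignmentReport:
    level: str
    pairs: list[tuple[UPRI, UPRI, float]] = field(default_factory=list)
    unmatched_a: list[UPRI] = field(default_factory=list)
    unmatched_b: list[UPRI] = field(default_factory=list)

    def score_of(self, a: UPRI) -> Optional[float]:
        for ua, _, s in self.pairs:
            if ua == a:
                return s
        return None

    def to_dict(self) -> dict:
        return {
            "level": self.level,
            "pairs": [[a, b, s] for a, b, s in self.pairs],
            "unmatched_a": self.unmatched_a,
            "unmatched_b": self.unmatched_b,
        }


@dataclass
class ProfileReport:
    per_class: dict[UPRI, int] = field(default_factory=dict)
    per_level: dict[str, int] = field(default_factory=dict)
    levels_present: list[str] = field(default_factory=list)
    n_data_triples: int = 0
    n_unclaimed_triples: int = 0
    n_resources_without_identification: int = 0

    def to_dict(self) -> dict:
        return {
            "per_class": dict(sorted(self.per_class.items())),
            "per_level": self.per_level,
            "levels_present": self.levels_present,
            "n_data_triples": self.n_data_triples,
            "n_unclaimed_triples": self.n_unclaimed_triples,
            "n_resources_without_identification": self.n_resources_without_identification,
        }


def jaccard_multiset(a: Counter, b: Counter) -> float:
    """Jaccard similarity of two multisets (1.0 for two empty multisets)."""
    if not a and not b:
        return 1.0
    inter = sum((a & b).values())
    union = sum((a | b).values())
    return inter / union if union else 0.0


def _subject_class(store: KnowledgeGraphStore, subject: Optional[UPRI]) -> str:
    if subject is None:
        return ""
    for t in store.data_layer.triples_with_subject(subject):
        if t.predicate == vocab.RDF_TYPE and not isinstance(t.object, Literal):
            return t.object
    return ""


def _statement_signature(store: KnowledgeGraphStore, upri: UPRI) -> Counter:
    return Counter([store.units[upri].unit_class])


def _item_signature(store: KnowledgeGraphStore, upri: UPRI) -> Counter:
    unit = store.units[upri]
    assert isinstance(unit, ItemUnit)
    sig = Counter()
    sig[("subject_class", _subject_class(store, unit.subject))] += 1
    for member in unit.associated_units:
        sig[("member_class", store.units[member].unit_class)] += 1
    return sig


def _item_group_signature(store: KnowledgeGraphStore, upri: UPRI) -> Counter:
    unit = store.units[upri]
    assert isinstance(unit, ItemGroupUnit)
    sig = Counter()
    for member in unit.item_units:
        item = store.units[member]
        sig[("item_subject_class", _subject_class(store, item.subject))] += 1
    return sig


def _triple_signature(store: KnowledgeGraphStore, upri: UPRI) -> Counter:
    """Typed skeletons of the unit's triples: instance IRIs are abstracted to
    their classes so equivalent statements about different individuals align."""
    unit = store.units[upri]
    assert isinstance(unit, StatementUnit)

    def skel_term(term) -> str:
        if isinstance(term, Literal):
            return f"lit:{term.lexical}"
        cls = _subject_class(store, term)
        return f"cls:{cls}" if cls else "res"

    return Counter(
        (skel_term(t.subject), t.predicate, skel_term(t.object))
        for t in unit.data_graph
    )


def _units_at_level(store: KnowledgeGraphStore, level: str) -> list[UPRI]:
    if level in ("statement", "triple"):
        return [u.upri for u in store.statement_units()]
    if level == "item":
        return sorted(
            u.upri for u in store.compound_units() if isinstance(u, ItemUnit)
        )
    if level == "item_group":
        return sorted(
            u.upri for u in store.compound_units() if isinstance(u, ItemGroupUnit)
        )
    raise ValueError(f"unknown level {level!r}; use {'|'.join(ALIGNMENT_LEVELS)}")


_SIGNATURES: dict[str, Callable] = {
    "statement": _statement_signature,
    "item": _item_signature,
    "item_group": _item_group_signature,
    "triple": _triple_signature,
}

_LEVEL_REQUIRES = {
    "statement": "statement_unit",
    "triple": "statement_unit",
    "item": "item_unit",
    "item_group": "item_group_unit",
}


def greedy_match(
    scores: dict[tuple[UPRI, UPRI], float]
) -> list[tuple[UPRI, UPRI, float]]:
    """Greedy maximum-score partial matching; ties broken by UPRI pair."""
    pairs = []
    used_a: set[UPRI] = set()
    used_b: set[UPRI] = set()
    for (a, b), s in sorted(scores.items(), key=lambda kv: (-kv[1], kv[0])):
        if s <= 0.0 or a in used_a or b in used_b:
            continue
        pairs.append((a, b, s))
        used_a.add(a)
        used_b.add(b)
    return sorted(pairs)


def align(
    store_a: KnowledgeGraphStore, store_b: KnowledgeGraphStore, level: str
) -> AlignmentReport:
    """Partial matching of the two stores' units at one granularity level."""
    if level not in ALIGNMENT_LEVELS:
        raise ValueError(f"unknown level {level!r}; use {'|'.join(ALIGNMENT_LEVELS)}")
    for store in (store_a, store_b):
        if (
            (len(store.data_layer) or store.units)
            and _LEVEL_REQUIRES[level] not in granularity_levels(store)
        ):
            raise StateError(
                f"store has no {_LEVEL_REQUIRES[level]}s; build them before aligning"
            )
    sig = _SIGNATURES[level]
    units_a = _units_at_level(store_a, level)
    units_b = _units_at_level(store_b, level)
    sigs_a = {u: sig(store_a, u) for u in units_a}
    sigs_b = {u: sig(store_b, u) for u in units_b}
    scores = {
        (a, b): jaccard_multiset(sigs_a[a], sigs_b[b])
        for a in units_a
        for b in units_b
    }
    pairs = greedy_match(scores)
    matched_a = {a for a, _, _ in pairs}
    matched_b = {b for _, b, _ in pairs}
    return AlignmentReport(
        level=level,
        pairs=pairs,
        unmatched_a=[u for u in units_a if u not in matched_a],
        unmatched_b=[u for u in units_b if u not in matched_b],
    )


def profile(store: KnowledgeGraphStore) -> ProfileReport:
    """Exact per-class and per-level counts by exhaustive registry scan."""
    per_class: dict[UPRI, int] = {}
    for _, unit in sorted(store.units.items()):
        per_class[unit.unit_class] = per_class.get(unit.unit_class, 0) + 1
    claimed = set()
    id_subjects = set()
    for unit in store.statement_units():
        claimed.update(t for t in unit.data_graph if t in store.data_layer)
        if unit.unit_class in vocab.IDENTIFICATION_UNIT_CLASSES:
            id_subjects.add(unit.subject)
    n_statement = len(store.statement_units())
    n_item = sum(1 for u in store.units.values() if isinstance(u, ItemUnit))
    n_group = sum(1 for u in store.units.values() if isinstance(u, ItemGroupUnit))
    per_level = {
        "triple": len(store.data_layer),
        "statement_unit": n_statement,
        "item_unit": n_item,
        "item_group_unit": n_group,
        "knowledge_graph": 1 if (len(store.data_layer) or store.units) else 0,
    }
    return ProfileReport(
        per_class=per_class,
        per_level=per_level,
        levels_present=granularity_levels(store),
        n_data_triples=len(store.data_layer),
        n_unclaimed_triples=len(store.data_layer) - len(claimed),
        n_resources_without_identification=len(
            store.data_layer.resources() - id_subjects
        ),
    )
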