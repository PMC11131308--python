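# Methods

## The two-layer model

A knowledge graph is represented as two disjoint triple sets.  The **data
graph layer** holds the original subject–predicate–object statements
(blank-node free; imported RDF is skolemized).  The **semantic-units graph
layer** holds every triple whose subject or object is a semantic-unit
resource: the instantiation triple (`unit rdf:type <unit class>`), the
subject link (`unit hasSemanticUnitSubject s`), compound membership
(`hasAssociatedSemanticUnit`) and cross-links (`hasLinkedSemanticUnit`),
plus list-membership (`child`) and ordering (`index`) triples.  A unit's
UPRI names both the unit and its data graph; UPRIs are content-addressed
(SHA-256 over a canonical serialization of the unit's content, under a
configurable base namespace), so rebuilding the same store always mints the
same identifiers and exports are byte-reproducible.

## Statement-unit schemas and the partition

A statement-unit class is defined by a schema: an ordered list of triple
templates over variables (`?name`) and constants, one subject variable, and
one or more object variables (required or optional).  Binary relations use
a single template; n-ary relations (a measurement with value and unit, a
location with a time) use several templates joined through instance
resources.  The dialect is deliberately small — conjunctive patterns, no
recursion or negation — and is stored as YAML with a CURIE prefix map; it
stands where a SHACL/LinkML shape would in a production stack.

Matching is an indexed backtracking join: for an anchor resource bound to
the subject variable, all consistent template instantiations are
enumerated, deduplicated and canonically sorted.  Optional templates extend
a solution greedily with the canonically smallest consistent extension.
The matcher is verified against an independent brute-force oracle that
enumerates every assignment of graph triples to templates (kept to graphs
of ≤ ~12 triples, since the oracle is O(|G|^templates)).

The partition runs in three passes:

1. **Identification units.** A resource occurring as the object of an
   `rdf:type` triple is treated as a class resource; its label, identifier
   and ontology triples form a class identification unit.  Every other
   subject with type or label triples gets a named-individual
   identification unit over exactly those triples.  Running this pass first
   keeps labelling triples out of n-ary pattern matches.
2. **Schema matching** in descending priority (ties broken by class IRI).
   Each accepted binding consumes its matched triples; a binding that
   overlaps an earlier claim is skipped with a logged warning (first claim
   wins).  The match index is rebuilt once per schema pass; claims are
   validated against the live pool.
3. **Generic fallback.** Every still-unclaimed triple becomes a
   single-triple generic statement unit, so coverage is total by
   construction; disjointness and coverage are nevertheless re-verified by
   exhaustive membership counting (`verify_partition`).

The shipped schema library covers the patterns the worked examples need:
the scalar measurement pattern (quality → datum → value specification →
value/unit; arity 2), located-in-at-time (two templates), has-part
(partial order), is-about, list membership, assertion, and a low-priority
type schema.

## Compound units

* **Typed statement unit** — one reference statement unit plus the
  identification units of every resource in its data graph; resources
  without one are reported, identification units are shared between typed
  units rather than duplicated.  Dynamic labels fill the schema's template
  (`{subject}`, `{objectK}`, or variable names) with labels drawn from
  identification units; a resource without a label falls back to its CURIE.
  Mind maps are emitted as plain DOT digraphs, one edge per bound object
  slot.
* **Item units** group the non-identification statement units by subject
  (meta-level units whose subject is itself a unit resource, such as list
  membership units, are excluded).  The grouping is a partition of those
  units.
* **Item group units** are found as connected components over bridging
  statement units — units whose subject is one item subject and one of
  whose objects is another.  Components need ≥ 2 item units; bridges become
  members alongside the item units they connect.  The discovery algorithm
  (connected components) is a design choice; the membership condition
  defines only which units bridge.
* **Granularity tree units** are built per declared partial-order predicate
  (default: parthood) from the binary statement units of that predicate:
  per weakly connected component, the component is accepted as a tree iff
  it has exactly one root (a node that is the object of no member unit),
  every other node has exactly one parent, and it is acyclic.  Reflexive
  self-loops are dropped before tree building: the textbook partial-order
  reading (reflexive + antisymmetric + transitive) makes self-edges
  uninformative for tree construction, and a strict reading forbids them
  outright.  Cyclic or multi-parent components are rejected with a
  diagnostic, never silently treed.
* **Granular item group units** collect the item units whose subjects are
  tree nodes and nest them by nearest item-bearing tree ancestor.
* **Context units** are the connected regions of the statement-unit
  adjacency graph (units adjacent when their data graphs share a resource,
  or when one mentions the other's UPRI) after removing the is-about units;
  each is-about unit is recorded as the link between the two regions its
  subject and object fall into.  A region whose units reference other
  units' UPRIs (statements about statements) is tagged *discursive*, the
  rest *ontological*; named frames can be assigned by the caller.
* **Dataset units** preserve an explicit member order; **list units** come
  in ordered / unordered / set flavours, implemented as membership
  statement units via the `child` relation, with 1-based `index` literals
  for ordered lists (RDF container convention), uniqueness enforcement for
  sets, and optional (min, max) cardinality brackets.

**Redaction** removes all units of the restricted classes from a view:
their data-graph triples leave the data layer, their layer triples
disappear, and compounds lose the redacted members (compounds left empty
are dropped).  The original store is untouched, and view ∪ removed
reconstructs it exactly.

## Serialization

* **Nanopublications.** A unit exports as four named graphs: *assertion* =
  the unit's data graph, named by the unit's UPRI (empty for compound
  units); *head* links the nanopublication resource to the three other
  graphs and carries the unit's semantic-units triples (class, subject,
  members, schema reference, and `rdf:_n` triples preserving object
  order); *provenance* carries creator / creation time / application;
  *publication info* carries title, contributors, last update, license and
  restriction flags.  The TriG writer sorts graphs and triples canonically
  so export → import → export is byte-identical.  Timestamps are written in
  `+00:00` offset form, the lexical form rdflib's `xsd:dateTime`
  normalization preserves.
* **LPG.** One node record per data-layer resource, one relationship
  record per triple, in bulk-import CSV.  Relationships carry exactly one
  `statement_unit_UPRI` (the partition guarantees uniqueness).  Nodes occur
  in several units in general, so a node's statement unit is defined
  deterministically as the unit claiming the canonically first triple in
  which the node is subject (fallback: first triple mentioning it);
  `compound_unit_UPRI` holds the ';'-joined transitive compound
  memberships of that unit.  Literal-valued triples become relationship
  records with `value`/`value_datatype` fields and no end node.
* **Registry JSON** is a versioned, lossless, canonically ordered dump of
  namespace, both layers, schemas and all units.
* **Blank nodes** in imported RDF are skolemized through RDF graph
  canonicalization: the canonical blank-node labels are hashed into
  `genid/` IRIs, so identical documents skolemize identically across runs.

## Alignment and profiling

Alignment is stepwise across granularity levels.  Signatures: statement
units compare by unit class; item units by (subject class, multiset of
member unit classes); item group units by the multiset of their item
units' subject classes; the triple level re-scores matched statement units
on typed triple skeletons (instance IRIs abstracted to their classes).
The score is the Jaccard index over the compared multisets and the matcher
is greedy maximum-score with lexicographic UPRI tie-breaks.  Both are the
simplest faithful instantiation and sit behind a small interface
(`jaccard_multiset`, `greedy_match`) so they can be swapped.  With 0/1
scores (class equality, as at the statement level) greedy matching attains
the exhaustive optimum; with fractional scores it guarantees a maximal,
not necessarily maximum, matching — a known property of greedy matching
that the tests document.  Profiling reports exact per-class and per-level
counts plus orphan statistics by full registry scan.

## Synthetic stores and what they do (not) show

`generate_store(FixtureSpec)` draws a seeded random store with exact
planted ground truth.  Subjects are partitioned into clusters chained by
parthood bridges (the intended item groups and granularity trees, with
per-cluster ontology classes so context regions stay separable); each
subject receives 1–3 statement units drawn from a weighted mix of
measurement (weight 2), parthood (2), located-at (1) and generic/unmatched
(1) patterns; consecutive clusters are joined by is-about units with
probability 0.5.  These defaults give stores of roughly 80–150 triples
that exercise every builder; the scale runs use 450 subjects with 2–4
units each (~10⁴ triples).  A `plant_cycle` flag closes a parthood cycle
for negative tree tests.  Every generated triple is tagged with its
intended unit, so recovery is checked unit-for-unit, not just by counts.

The generator emulates structure, not messiness: it produces no schema
violations, no overlapping pattern instances, no multilingual labels, no
blank nodes and no contradictory statements.  Passing recovery therefore
shows the pipeline is exact on well-formed graphs that follow the declared
patterns; on real data, triples not matching any schema fall into
single-triple generic units (by design), and pattern instances sharing
intermediate nodes would be resolved by first-claim-wins rather than
semantics.

The worked-example fixtures reconstruct the printed examples: the apple
weight measurement (204.56 g; the five-resource OBI chain, so the typed
statement unit has its six members) and the scholarly-publication store
(publication → investigation → data set → description chain, is-about
boundary to the organism region, organism → head → eye parthood tree, and
an author asserting a melting-point measurement of 327.5 °C as the
statement-about-a-statement).  Ontology CURIEs (NCIT, PATO, IAO, OBI,
UBERON, SIO, UO) are used as opaque identifiers; no ontology files are
fetched, and the value literal is typed `xsd:decimal`.

## Numerical and degenerate-input choices

Canonical ordering everywhere bytes matter: triples sort by (subject,
predicate, object-kind, object), graphs by name, JSON keys
lexicographically.  Empty graphs partition to zero units with a vacuously
true report; an empty store has no granularity levels; aligning empty
levels raises a state error rather than returning an empty perfect match.
Jaccard of two empty multisets is defined as 1.0 (self-alignment of
degenerate signatures).  Ordered-list indices are 1-based.  All internal
counts are plain integers; scores are floats in [0, 1].

## Known limitations

* One meta-layer: semantic-units-layer triples are not themselves
  partitioned into statement units (the regress stops after one level).
* Schema expressiveness is conjunctive; no value constraints, cardinality
  in patterns, or recursion — SHACL/ShEx import is out of scope.
* Item-group discovery treats any subject-to-subject statement unit as a
  bridge, including is-about units; context units, not item groups, are
  the mechanism that separates frames of reference.
* The greedy aligner is order-optimal only for 0/1 scores (see above).
* No persistence beyond file export; the registry is in-memory.
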