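# semantic-units

Organize an RDF knowledge graph into **semantic units**: identifiable,
semantically meaningful subgraphs, each represented in the graph by its own
resource (a UPRI — Unique Persistent and Resolvable Identifier).

The package is aimed at knowledge-graph engineers and data stewards in the
life sciences who need FAIR, modular graphs: instead of working with bare
triples, the data graph is **partitioned into statement units** — the
smallest independent propositions, defined per class by a declarative graph
pattern — and the statement units are organized into a taxonomy of
**compound units** (item units, item group units, granularity tree units,
granular item groups, context units, dataset units, list units).  The units
and the triples that describe them form a second graph layer (the
*semantic-units graph layer*) on top of the original *data graph layer*.

Core guarantees:

* **Partition.** Every triple of the data layer belongs to exactly one
  statement unit, and the union of all statement-unit data graphs is the
  data layer: for units *u₁ … uₙ* with data graphs *G(uᵢ)* over data layer
  *D*, `⋃ᵢ G(uᵢ) = D` and `G(uᵢ) ∩ G(uⱼ) = ∅` for *i ≠ j*.
* **Identity.** A unit's UPRI simultaneously names the unit and its data
  graph, so triples elsewhere can make statements about the statement
  (e.g. `authorA asserts <unit>`).
* **Serializations.** Each unit exports as a nanopublication — four named
  graphs (head, assertion, provenance, publication info) in TriG — and a
  whole store exports as labeled-property-graph records (bulk-import CSV
  where every node and relationship carries `UPRI`, `statement_unit_UPRI`
  and a `compound_unit_UPRI` array) or as a lossless JSON registry.
* **Operations on units.** Five-level granularity profiling
  (triples → statement units → item units → item group units → knowledge
  graph), stepwise alignment of two stores, and class-based redaction of
  sensitive subgraphs.

## Worked example

```python
from semantic_units import apple_example
from semantic_units.compound import TypedStatementUnit, render_dynamic_label, render_mind_map

store, truth, report = apple_example()
print(report.to_dict()["n_units"], report.to_dict()["coverage_ok"])
tsu = [u for u in store.compound_units() if isinstance(u, TypedStatementUnit)][0]
print(len(tsu.associated_units))
print(render_dynamic_label(tsu, store))
```

prints

```
7 True
6
apple X has weight 204.56 gram
```

The fixture is a single measurement — an apple weighing 204.56 grams,
modelled with the OBI measurement pattern (subject → quality → measurement
datum → value specification → value/unit).  Partitioning its 17 triples
yields 7 statement units: one *weight statement unit* (subject `apple X`,
two objects: the decimal value and the gram resource), five
named-individual identification units (the type and label triples of each
resource), and one class identification unit for the apple class.  The
*typed statement unit* bundles the reference weight unit with the five
identification units — 6 members — and its schema's display template
renders the human-readable dynamic label shown above (a DOT mind map is
available via `render_mind_map`).

The same pipeline runs from the shell:

```
semunits run --fixture apple --out-dir out/
semunits partition --graph mygraph.ttl --schemas schemas.yaml --out units.json --report report.json
semunits align --a a.json --b b.json --level statement --out alignment.json
```

`semunits run` writes the registry JSON, a Turtle dump of the data layer,
nanopublication TriG, LPG CSV files and a profiling report; it exits 0
exactly when the partition check (full coverage, pairwise disjoint) passes.

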