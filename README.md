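# termserve

A desk-scale clinical terminology engine — the computational core of a
syndicated terminology server, as a Python library and a `termserve` CLI.

Clinical systems that capture coded data (SNOMED CT, local extensions,
OWL-based ontologies) need a handful of recurring services: look up a
concept's labels and neighbours, decide whether one code subsumes another,
resolve a value set to its member codes, check that a stored display still
matches a real designation, rank autocomplete candidates as a clinician
types, and keep all of that content up to date as new releases ship.
`termserve` implements those services end to end over in-memory code
systems with file-backed persistence — no database, no network — which
makes it suitable for pipelines, QA tooling and tests that need
terminology semantics without standing up a server.

## What it implements

* **RF2 snapshot import** — concepts, descriptions, relationships, simple
  reference sets and the Module Dependency Reference Set, with
  snapshot-state resolution (newest effective row per component wins) and
  referential/acyclicity validation.
* **Terminology operations** — `lookup`, `subsumes`, `translate`
  (concept maps), `validate-code` with display checking, and an
  incremental client-side **closure** table kept equal to the subsumption
  relation restricted to its members.
* **Expression Constraint Language** — a parser/evaluator for the ECL
  subset used by value-set filters: the six focus operators
  (`<`, `<<`, `>`, `>>`, `^`, self), `AND`/`OR`/`MINUS`, parentheses and
  one level of attribute refinement with optional grouping.
* **Value sets** — implicit URL shapes
  (`?fhir_vs`, `?fhir_vs=isa/…`, `?fhir_vs=refset/…`, plus an
  `?fhir_vs=ecl/…` extension), explicit include/exclude compose rules with
  filters and imports, windowed expansion and text-filtered expansion.
* **Autocomplete search** — the standard breadth-first (SBF) baseline and
  multi-prefix matching (MPM) with the ranking score

  σ(F) = (1/n) · Σ_{i=1..m} |q_i| / |F(q_i)|

  where q_1…q_m are the query prefixes, F injectively assigns each prefix
  to a distinct word of the n-word label it prefixes, and the
  score-maximising assignment is computed exactly (max-weight bipartite
  matching). Injectivity is what makes a duplicated query such as
  `pne pne` match *Pneumococcal pneumonia* but not *Pneumonia*.
* **OWL-EL transformation** — classification of EL ontologies
  (completion-rule saturation) and transformation of an ontology plus its
  whole imports closure into one code system with per-ontology value
  sets, `parent`/`root`/`deprecated` concept properties, and the standard
  element mapping (IRI → url, version else `"NA"`, first `rdfs:label` →
  name, status `ACTIVE`, hierarchy meaning `SUBSUMES`).
* **Syndication** — Atom feeds describing releases as checksummed binary
  indexes (this engine's prebuilt serialization) or source archives, with
  the strict installation preference *compatible binary index → source →
  fail*, SHA-256 integrity verification, and server/client chaining.

A deterministic fixture generator (`termserve.fixtures`) produces RF2
snapshots, EL ontology bundles and a small hand-built finding hierarchy,
each with a ground-truth ledger, so everything above is testable offline.

## Worked example

```bash
$ termserve --store ./store fixtures demo
{"loaded": {"concepts": 7, "url": "http://snomed.info/sct", "version": "20240101"}}

$ termserve --store ./store search "ac app" --system http://snomed.info/sct
85189001        0.3250  Acute appendicitis
286967008       0.2167  Acute focal appendicitis
47693006        0.1625  Acute appendicitis with peritonitis
```

The three scores are the MPM σ values: for *acute appendicitis* the
prefixes `ac` and `app` cover 2/5 and 3/12 of their matched words, so
σ = (1/2)(2/5 + 3/12) = 0.325; the longer labels dilute the same coverage
over 3 and 4 words (0.2167 and 0.1625), so the shortest fully-covered
label ranks first.

```bash
$ termserve --store ./store subsumes http://snomed.info/sct 404684003 47693006
{"outcome": "subsumes"}

$ termserve --store ./store expand "http://snomed.info/sct?fhir_vs=isa/74400008" --filter "ac app"
{"expansion": {"total": 3, "contains": [
  {"code": "85189001", "display": "Acute appendicitis", "score": 0.325, ...},
  {"code": "286967008", "display": "Acute focal appendicitis", "score": 0.216667, ...},
  {"code": "47693006", "display": "Acute appendicitis with peritonitis", "score": 0.1625, ...}]}}
```

`subsumes` reports that the clinical-finding root transitively subsumes
*Acute appendicitis with peritonitis*; the filtered expansion combines an
implicit is-a value set with MPM ranking, which is exactly how an
autocomplete widget drives a terminology server.

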