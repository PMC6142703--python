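# Methods

This note records the semantics the engine implements, the defaults it
chooses where terminology-server practice leaves room, and what the
synthetic fixtures do and do not establish.

## Code systems, subsumption, closure

A code system is a map of concept entries (code, active flag,
designations, direct parents, grouped defining relationships, free-form
properties) plus refset membership sets, keyed in a store by
`(url, version)`. Subsumption is the reflexive-free transitive closure of
the direct-parent relation, computed by DFS with cycle detection and
cached per record; records are treated as immutable once stored.
`subsumes(a, b)` returns *equivalent* for equal codes, *subsumes* /
*subsumed-by* from the closure, otherwise *not-subsumed*. Codings from
different systems never subsume one another.

Defaults worth knowing:

* **Latest version** is the maximum version string under numeric-aware
  lexicographic comparison (digit runs compare as integers), so
  `20170131 < 20180131` and `2 < 10`. Callers can always pin a version.
* **Inactive concepts** stay visible to `lookup` and, by default, to
  `subsumes` (historical data safety, switchable via `include_inactive`),
  but are excluded from value-set expansion, ECL evaluation and search.
* The incremental **closure table** keeps `pairs` equal to the strict
  subsumption relation restricted to its members; updates return exactly
  the added pairs, re-adding a member is a no-op, and the final state is
  independent of insertion order (the suite checks this by permutation).

## RF2 snapshots

Snapshot semantics: for each component id the row with the maximum
`effectiveTime` defines current state; ties prefer `active=1`, then the
later row in input order (append-style release assembly). Only snapshot
releases are supported — Full/Delta history views are out of scope. The
RF2 magic codes (is-a `116680003`, description types for FSN/synonym/
definition, the MDRS refset id) are collected in one constants table in
`rf2.py`. Language/acceptability refsets are ignored; a concept's display
is its first active synonym, falling back to the FSN. Refset member rows
with extra columns (the concrete-domains pattern) are parsed generically
and surfaced as concept properties named by refset id, with no predicate
semantics attached. Imports with unsatisfied module dependencies fail by
default; the CLI's `--force` downgrades that to a warning.

The writer (`record_to_bundle`/`write_rf2_snapshot`) inverts the importer
up to the RF2-representable part of a record: free-form `properties`
have no RF2 carrier and are not round-tripped.

## ECL subset

The grammar covers the six focus operators over a code or `*`, `AND` /
`OR` / `MINUS` (left-associative; `MINUS` binds loosest, matching the
brief-syntax precedence), parentheses, `|term|` annotations (ignored),
and one refinement level: comma-separated attribute constraints with at
most one `{ … }` group. Cardinalities, dotted/reverse attributes, nested
groups and member-field filters raise `UnsupportedEclFeature` by name.
Evaluation is set algebra over the cached closure, active concepts only;
attribute expressions resolve through the same is-a closure as focus
concepts (attribute types are ordinary concepts). Grouped constraints
must all be satisfied by relationships sharing one group number > 0;
ungrouped constraints may be satisfied anywhere. `^` returns only active
members of the refset. `render_ecl` is a strict inverse modulo
whitespace: `parse(render(ast)) == ast`.

Wildcard corner cases are defined (and oracle-checked) as: `* `, `<< *`,
`>> *` = all active codes; `< *` = codes with at least one ancestor;
`> *` = codes with at least one descendant.

## MPM ranking

Queries tokenize by lowercasing and splitting on runs of
non-alphanumerics; the trailing partial token is a prefix like any other
and there is no minimum prefix length. A match requires an injective
assignment F of all m prefixes to distinct words of the n-word label with
each prefix a prefix of its word; σ(F) = (1/n) Σ |q_i|/|F(q_i)|. The
engine maximises σ exactly via `scipy.optimize.linear_sum_assignment` on
the m×n coverage matrix (infeasible cells get a large negative weight and
solutions using one are rejected); the test suite cross-checks against
exhaustive enumeration of injective assignments. Consequences asserted as
properties: 0 < σ ≤ m/n ≤ 1, σ = 1 exactly when the query tokens are the
label's words as a multiset, σ invariant under prefix permutation, and
every SBF-accepted pair is MPM-accepted.

Ranking ties break by fewer label words, then shorter label, then code
ascending — shortest-useful-label-first, fully deterministic. The prefix
index is a sorted (word, entry) table scanned per prefix with binary
search, candidates intersected across prefixes, then scored identically
to a linear scan; one result per concept (its best-scoring designation).
σ is computed against the designation that matched, which is also the
label reported, even when it differs from the preferred display.

## OWL-EL transformation

Class expressions are limited to named classes, intersections and
existential restrictions. Classification normalises axioms to the four
EL normal forms (fresh auxiliary names for complex subexpressions) and
saturates subsumer sets and role-successor relations under the standard
completion rules to fixpoint; equivalence appears as mutual subsumption.
The suite checks this against an independent saturation oracle that works
on raw, un-normalised expressions.

The transformation flattens the imports closure (each ontology visited
once, cycles tolerated) into one code system and emits one value set per
ontology document — the main ontology's value set excludes its imports —
so scoped search remains possible. Element mapping: url ← IRI (absent IRI
stops the transformation), version ← ontology version else `"NA"`, name ←
first `rdfs:label` else the IRI, publisher/description ← configurable
annotation properties, status `ACTIVE`, hierarchy meaning `SUBSUMES`,
canonical value set ← the IRI. Per concept: `parent` (direct subsumers
after transitive reduction), `root`, `deprecated`. Equivalent named
classes merge into a single concept whose code is the lexicographically
smallest IRI, other labels becoming extra designations; labels map to
synonym designations with the first as display (the designation-use
mapping for ontology labels is this package's choice — no standard
dictates one). Concept codes are full class IRIs; CURIE compression is
deliberately avoided to sidestep prefix-map ambiguity. Input is the
normalized ontology-JSON exchange format, with a best-effort reader for
OWL functional syntax covering the EL constructs and label/deprecation
annotations.

## Value sets

Within one compose rule, explicit codes, each filter and each imported
value set intersect; rules of the same include/exclude list union; all
excludes are subtracted after all includes. Supported filters:
`concept is-a` (descendant-or-self), `concept in` (refset), `constraint`
(ECL). Implicit kinds map to `all` / `<< c` / `^ r` / a raw ECL
expression; the `ecl` URL kind is an extension beyond the three canonical
shapes so the constraint language is reachable by URL. Unfiltered
expansions order by (system, code) ascending — an arbitrary but
documented total order, which makes page concatenation exact. Text
filtering ranks members by MPM over their active designations and drops
non-matchers; `total` counts members before windowing. `validate_code`
compares a supplied display case-insensitively against the concept's
active designations, flagging edited labels while accepting any genuine
designation, not just the preferred one.

## Syndication

Feed entries carry content kind (Atom category), content identity and
version, index format version and SHA-256 checksum (custom namespace
elements). Entries missing or malforming any of these parse but are
flagged unusable and never selected. Selection prefers a binary index
whose format version equals the one this build writes — equality rather
than a compatibility range, deliberately strict — then any source entry,
then fails. The binary index is canonical JSON (sorted keys, fixed
separators) of the record, its full transitive closure and its prefix
index table, so serialization is checksum-stable and round-trips the
record exactly. RF2 source payloads are ZIP archives of a projected
snapshot; ontology sources are the ontology-JSON bundle with embedded
imports. Installation verifies the checksum before any store mutation,
is idempotent per (url, version), and the transport abstraction resolves
links against local directories or in-memory maps, so chains of
publish→pull→republish run without a network.

## Synthetic fixtures and what tests show

`generate_code_system`/`generate_rf2` build DAGs whose node *i* draws
parents only from nodes < *i* (acyclic by construction; defaults: 100
concepts, ≤ 3 parents, 2 refsets at density 0.2, 2 attribute types,
multi-word labels from a 40-word clinical lexicon — sized so hierarchies
have depth, refsets are non-trivial, and MPM queries have prefix
structure). `generate_ontologies` emits an import chain where every
document contains at least one equivalence and one existential axiom, so
classification is exercised beyond told edges. All generators are pure
functions of (spec, seed) and return ledgers of exact counts. The
hand-built fixture pins a seven-concept finding hierarchy with the
classic appendicitis/pneumonia autocomplete labels and one refset.

These fixtures emulate structure, not content: real RF2 releases are
orders of magnitude larger, carry language refsets, version histories and
concrete-domain refsets with semantics this engine deliberately does not
interpret, and real description text is far messier than a sampled
lexicon. Passing tests therefore establish the algorithms' correctness
contracts (oracle equivalence, round trips, protocol preference), not
performance or content fidelity at national-release scale.

## Problem sizes and numerics

The oracle suites run at: 100 random ECL expressions over 20 DAGs of 150
nodes; 100 random DAGs up to 200 nodes for closure; 50 random EL
ontologies up to 60 classes for classification; 50 corrupted payload
trials for integrity — sizes at which brute-force oracles remain exact
yet the whole suite completes in seconds. Score comparisons use absolute
tolerance 1e-9 (σ is a short sum of small rationals; the bipartite
matching is exact, so only float summation order contributes error).
Degenerate inputs are defined, not rejected: empty queries return empty
results, single-concept systems have empty closures, `Refined(base, [])`
equals its base, an empty feed is valid.

## Known limitations

No LOINC import, no RF2 Full/Delta views, no post-coordinated
expressions in the closure operation, no fuzzy matching or value-set
score boosting in search, no ECL cardinalities/dotted attributes, no
non-EL OWL profiles or ABox individuals, no authentication on feeds, and
no HTTP server — the store, library functions and CLI are the interface.
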