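"""Deterministic synthetic fixtures: RF2 snapshots, EL ontologies, a tiny
hand-built code system.

Every generator is a pure function of its :class:`FixtureSpec` — byte-
identical output on re-runs with the same seed — and returns a ground-truth
ledger (codes, edges, refset members, told subsumptions) so tests can
assert exact counts against what the importer reconstructs.

Fixture concept codes are numeric strings drawn from a reserved range
(prefix ``9890``) that does not collide with real SNOMED CT identifiers.
"""
from __future__ import annotations

import json
import random
from dataclasses import dataclass, field
from pathlib import Path

from . import rf2 as _rf2
from .model import CodeSystemRecord, ConceptEntry, Designation
from .owl import (
    EquivalentClasses,
    IntersectionOf,
    Named,
    OntologyDocument,
    SomeValuesFrom,
    SubClassOf,
)

# compact clinical-flavoured lexicon so multi-word labels give MPM queries
# realistic prefix structure
DEFAULT_LEXICON = [
    "acute", "chronic", "severe", "mild", "focal", "diffuse", "primary",
    "secondary", "left", "right", "upper", "lower", "anterior", "posterior",
    "appendicitis", "pneumonia", "fracture", "infection", "lesion",
    "carcinoma", "syndrome", "disorder", "injury", "ulcer", "stenosis",
    "hepatitis", "nephritis", "dermatitis", "arthritis", "anaemia",
    "femur", "tibia", "humerus", "kidney", "liver", "lung", "heart",
    "skin", "bone", "joint",
]

MODULE_ID = "989000001"
ATTRIBUTE_BASE = 9890100000


@dataclass
class FixtureSpec:
    seed: int = 0
    n_concepts: int = 100
    max_parents: int = 3
    n_refsets: int = 2
    refset_density: float = 0.2
    attribute_types: int = 2
    label_lexicon: list[str] = field(default_factory=lambda: list(DEFAULT_LEXICON))
    n_ontologies: int = 3
    import_depth: int = 2

    def __post_init__(self):
        if self.n_concepts < 1:
            raise ValueError("n_concepts must be >= 1")
        if not 0.0 <= self.refset_density <= 1.0:
            raise ValueError("refset_density must lie in [0, 1]")


def _code(i: int) -> str:
    return str(9890000000 + i)


def generate_code_system(
    spec: FixtureSpec, system_url: str = "http://example.org/fixture/sct",
    version: str = "20240101",
) -> tuple[CodeSystemRecord, dict]:
    """Random DAG code system + ground-truth ledger (no files touched).

    Concept ``i`` draws its parents from earlier concepts only, so the
    is-a graph is a DAG by construction; concept 0 is the sole root.
    """
    rng = random.Random(spec.seed)
    record = CodeSystemRecord(url=system_url, version=version)
    edges: list[tuple[str, str]] = []

    attr_types = [str(ATTRIBUTE_BASE + t) for t in range(spec.attribute_types)]

    codes = [_code(i) for i in range(spec.n_concepts)]
    labels: dict[str, str] = {}
    for i, code in enumerate(codes):
        n_words = rng.randint(1, 4)
        label = " ".join(rng.choice(spec.label_lexicon) for _ in range(n_words))
        labels[code] = label
        parents: set[str] = set()
        if i > 0:
            k = rng.randint(1, min(spec.max_parents, i))
            parents = set(rng.sample(codes[:i], k))
        record.concepts[code] = ConceptEntry(
            code=code,
            active=True,
            designations=[
                Designation(value=f"{label} (finding)", use="fully-specified-name"),
                Designation(value=label, use="synonym"),
            ],
            parents=parents,
        )
        edges.extend((code, p) for p in sorted(parents))

    # attribute-type concepts so ECL refinements resolve inside the record
    for t, attr in enumerate(attr_types):
        record.concepts[attr] = ConceptEntry(
            code=attr,
            active=True,
            designations=[Designation(value=f"attribute {t}", use="synonym")],
            parents={codes[0]} if codes else set(),
        )
        edges.append((attr, codes[0]))

    n_rel = 0
    for code in codes[1:]:
        if rng.random() < 0.4 and attr_types:
            group = rng.choice([0, 0, 1])
            record.concepts[code].defining_relationships.append(
                (group, rng.choice(attr_types), rng.choice(codes))
            )
            n_rel += 1

    refsets: dict[str, list[str]] = {}
    for r in range(spec.n_refsets):
        rid = str(9890500000 + r)
        members = [c for c in codes if rng.random() < spec.refset_density]
        record.refsets[rid] = set(members)
        refsets[rid] = members

    ledger = {
        "seed": spec.seed,
        "codes": codes,
        "attributeTypes": attr_types,
        "labels": labels,
        "edges": [list(e) for e in edges],
        "nConcepts": len(record.concepts),
        "nIsAEdges": len(edges),
        "nDefiningRelationships": n_rel,
        "refsets": refsets,
    }
    return record, ledger


def generate_rf2(spec: FixtureSpec, out_dir) -> dict:
    """Write an RF2 snapshot directory plus its ground-truth ledger.

    The snapshot includes a module-dependency refset row so MDRS handling
    is exercised; the ledger is also written as ``ledger.json``.
    """
    record, ledger = generate_code_system(spec)
    bundle = _rf2.record_to_bundle(record, module_id=MODULE_ID)
    bundle.module_dependency_rows.append({
        "id": "989900001",
        "effectiveTime": "20240101",
        "active": "1",
        "moduleId": MODULE_ID,
        "refsetId": _rf2.MDRS_REFSET,
        "referencedComponentId": "900000000000207008",
        "sourceEffectiveTime": "20240101",
        "targetEffectiveTime": "20240101",
    })
    out_dir = Path(out_dir)
    _rf2.write_rf2_snapshot(bundle, out_dir)
    (out_dir / "ledger.json").write_text(
        json.dumps(ledger, indent=1, sort_keys=True), encoding="utf-8"
    )
    return ledger


def generate_ontologies(spec: FixtureSpec) -> tuple[list[OntologyDocument], dict]:
    """A main ontology plus imports (chain of depth ``import_depth``).

    Each document carries at least one equivalence and one existential
    axiom so classification is exercised beyond told is-a edges. Returns
    (documents, ledger); documents[0] is the main ontology and the ledger
    records the told subsumptions (every one of which must be entailed).
    """
    rng = random.Random(spec.seed)
    n = max(1, spec.n_ontologies)
    docs: list[OntologyDocument] = []
    told: list[tuple[str, str]] = []

    base = "http://example.org/onto"
    per_ontology = 6
    for o in range(n):
        iri = f"{base}/{o}"
        doc = OntologyDocument(
            iri=iri,
            version=f"2024.{o + 1}" if o % 2 == 0 else None,
            annotations=[
                ("http://www.w3.org/2000/01/rdf-schema#label", f"Ontology {o}"),
                ("http://purl.org/dc/elements/1.1/publisher", "Fixture Works"),
            ],
        )
        classes = [f"{iri}#C{k}" for k in range(per_ontology)]
        for k, c in enumerate(classes):
            doc.declare_class(c, label=f"o{o} class {k}",
                              deprecated=(k == per_ontology - 1))
        # told hierarchy inside the document
        for k in range(1, per_ontology):
            parent = classes[rng.randrange(k)]
            doc.axioms.append(SubClassOf(Named(classes[k]), Named(parent)))
            told.append((classes[k], parent))
        # one equivalence with a conjunction, one existential axiom
        doc.axioms.append(
            EquivalentClasses(
                Named(classes[1]),
                IntersectionOf((Named(classes[0]),
                                SomeValuesFrom(f"{iri}#r", Named(classes[2])))),
            )
        )
        doc.axioms.append(
            SubClassOf(
                SomeValuesFrom(f"{iri}#r", Named(classes[2])),
                Named(classes[0]),
            )
        )
        docs.append(doc)

    # import chain: doc 0 imports 1, 1 imports 2, ... up to import_depth,
    # remaining documents import directly from the main ontology
    for o in range(1, n):
        importer = docs[o - 1] if o <= spec.import_depth else docs[0]
        importer.imports.append(docs[o].iri)
        # a cross-ontology bridge axiom so hierarchies interlock
        importer.axioms.append(
            SubClassOf(Named(f"{importer.iri}#C3"), Named(f"{docs[o].iri}#C0"))
        )
        told.append((f"{importer.iri}#C3", f"{docs[o].iri}#C0"))

    ledger = {
        "seed": spec.seed,
        "nOntologies": n,
        "classesPerOntology": per_ontology,
        "toldSubsumptions": [list(t) for t in told],
    }
    return docs, ledger


# -- tiny hand-built record ---------------------------------------------------

CLINICAL_FINDING = "404684003"
ED_REFSET = "171881000036108"

_FIXTURE_CONCEPTS = [
    # (code, label, parents)
    (CLINICAL_FINDING, "Clinical finding", []),
    ("74400008", "Appendicitis", [CLINICAL_FINDING]),
    ("233604007", "Pneumonia", [CLINICAL_FINDING]),
    ("85189001", "Acute appendicitis", ["74400008"]),
    ("47693006", "Acute appendicitis with peritonitis", ["85189001"]),
    ("286967008", "Acute focal appendicitis", ["85189001"]),
    ("681470061", "Pneumococcal pneumonia", ["233604007"]),
]


def demo_fixture(
    system_url: str = "http://snomed.info/sct", version: str = "20240101"
) -> CodeSystemRecord:
    """A small finding hierarchy with the classic autocomplete labels.

    Three appendicitis concepts and two pneumonia concepts under a
    clinical-finding root (three hierarchy levels), plus an
    emergency-department reference set; stable codes, so suites can pin
    expectations against it.
    """
    record = CodeSystemRecord(url=system_url, version=version)
    for code, label, parents in _FIXTURE_CONCEPTS:
        record.concepts[code] = ConceptEntry(
            code=code,
            active=True,
            designations=[
                Designation(value=f"{label} (finding)", use="fully-specified-name"),
                Designation(value=label, use="synonym"),
            ],
            parents=set(parents),
        )
    record.refsets[ED_REFSET] = {"85189001", "47693006", "681470061"}
    record.validate()
    return record
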