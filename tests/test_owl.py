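"""EL classification against a naive fixpoint oracle; code-system transform."""
import random

import pytest

from termserve.errors import MissingIriError, UnsupportedAxiomError
from termserve.fixtures import FixtureSpec, generate_ontologies
from termserve.model import transitive_closure
from termserve.owl import (
    DC_PUBLISHER,
    RDFS_LABEL,
    EquivalentClasses,
    IntersectionOf,
    Named,
    OntologyDocument,
    SomeValuesFrom,
    SubClassOf,
    TransformConfig,
    classify,
    parse_functional_syntax,
    to_code_system,
)


def el_oracle(axioms, named):
    """Entailed named subsumptions via naive rule saturation on raw
    (un-normalized) expressions over the subexpression closure.

    Rules: reflexivity, told axioms, transitivity, conjunction
    introduction/elimination, existential monotonicity.
    """
    exprs = set()

    def collect(e):
        exprs.add(e)
        if isinstance(e, IntersectionOf):
            for o in e.operands:
                collect(o)
        elif isinstance(e, SomeValuesFrom):
            collect(e.filler)

    flat = []
    for ax in axioms:
        if isinstance(ax, SubClassOf):
            flat.append((ax.sub, ax.sup))
        else:
            flat.append((ax.a, ax.b))
            flat.append((ax.b, ax.a))
    for a, b in flat:
        collect(a)
        collect(b)
    for c in named:
        exprs.add(Named(c))

    sub = {(e, e) for e in exprs} | set(flat)
    changed = True
    while changed:
        changed = False
        add = set()
        bysub = {}
        bysup = {}
        for a, b in sub:
            bysub.setdefault(a, set()).add(b)
            bysup.setdefault(b, set()).add(a)
        # transitivity
        for a, b in sub:
            for c in bysub.get(b, ()):
                if (a, c) not in sub:
                    add.add((a, c))
        for e in exprs:
            # conjunction elimination / introduction
            if isinstance(e, IntersectionOf):
                for x in bysup.get(e, ()):
                    for o in e.operands:
                        if (x, o) not in sub:
                            add.add((x, o))
                for x in exprs:
                    if all((x, o) in sub for o in e.operands) \
                            and (x, e) not in sub:
                        add.add((x, e))
            # existential monotonicity
            if isinstance(e, SomeValuesFrom):
                for f in exprs:
                    if isinstance(f, SomeValuesFrom) and f.prop == e.prop \
                            and (e.filler, f.filler) in sub \
                            and (e, f) not in sub:
                        add.add((e, f))
        if add:
            sub |= add
            changed = True
    return {
        (a.iri, b.iri)
        for a, b in sub
        if isinstance(a, Named) and isinstance(b, Named)
        and a.iri != b.iri and a.iri in named and b.iri in named
    }


def random_el_ontology(rng, n_classes=30):
    doc = OntologyDocument(iri="http://example.org/rand")
    classes = [f"http://example.org/rand#C{k}" for k in range(n_classes)]
    props = [f"http://example.org/rand#r{k}" for k in range(3)]
    for c in classes:
        doc.declare_class(c, label=c.rsplit("#", 1)[1])

    def rand_expr(depth=0):
        roll = rng.random()
        if depth >= 2 or roll < 0.55:
            return Named(rng.choice(classes))
        if roll < 0.8:
            k = rng.randint(2, 3)
            return IntersectionOf(tuple(rand_expr(depth + 1) for _ in range(k)))
        return SomeValuesFrom(rng.choice(props), rand_expr(depth + 1))

    for _ in range(rng.randint(8, 20)):
        if rng.random() < 0.15:
            doc.axioms.append(EquivalentClasses(Named(rng.choice(classes)),
                                                rand_expr()))
        else:
            doc.axioms.append(SubClassOf(rand_expr(), rand_expr()))
    return doc, set(classes)


class TestClassify:
    def test_told_transitivity(self):
        doc = OntologyDocument(iri="http://x")
        a, b, c = Named("A"), Named("B"), Named("C")
        for iri in "ABC":
            doc.declare_class(iri)
        doc.axioms = [SubClassOf(a, b), SubClassOf(b, c)]
        assert ("A", "C") in classify([doc])

    def test_equivalence_with_conjunction(self):
        doc = OntologyDocument(iri="http://x")
        for iri in "ABCD":
            doc.declare_class(iri)
        doc.axioms = [
            EquivalentClasses(Named("A"),
                              IntersectionOf((Named("B"), Named("C")))),
            SubClassOf(Named("D"), Named("B")),
            SubClassOf(Named("D"), Named("C")),
        ]
        entailed = classify([doc])
        assert ("D", "A") in entailed
        assert entailed == el_oracle(doc.axioms, {"A", "B", "C", "D"})

    def test_existential_elimination(self):
        doc = OntologyDocument(iri="http://x")
        for iri in "XYD":
            doc.declare_class(iri)
        doc.axioms = [
            SubClassOf(SomeValuesFrom("r", Named("X")), Named("Y")),
            SubClassOf(Named("D"), SomeValuesFrom("r", Named("X"))),
        ]
        entailed = classify([doc])
        assert ("D", "Y") in entailed
        assert entailed == el_oracle(doc.axioms, {"X", "Y", "D"})

    def test_matches_fixpoint_oracle_on_random_ontologies(self):
        rng = random.Random(79)
        for trial in range(50):
            doc, named = random_el_ontology(rng, n_classes=rng.randint(10, 60))
            assert classify([doc]) == el_oracle(doc.axioms, named), \
                f"trial {trial}"

    def test_generated_told_axioms_are_entailed(self):
        docs, ledger = generate_ontologies(FixtureSpec(seed=5, n_ontologies=3))
        entailed = classify(docs)
        for sub, sup in ledger["toldSubsumptions"]:
            assert (sub, sup) in entailed


class TestTransform:
    def make_main(self, version="v1", labels=("Main Ontology", "Second Label")):
        doc = OntologyDocument(
            iri="http://example.org/main", version=version,
            annotations=[(RDFS_LABEL, lbl) for lbl in labels]
            + [(DC_PUBLISHER, "ACME")],
        )
        doc.declare_class("http://example.org/main#Root", label="root")
        doc.declare_class("http://example.org/main#Child", label="child")
        doc.declare_class("http://example.org/main#Old", label="old",
                          deprecated=True)
        doc.axioms = [
            SubClassOf(Named("http://example.org/main#Child"),
                       Named("http://example.org/main#Root")),
            SubClassOf(Named("http://example.org/main#Old"),
                       Named("http://example.org/main#Root")),
        ]
        return doc

    def test_missing_iri_stops_transformation(self):
        doc = self.make_main()
        doc.iri = None
        with pytest.raises(MissingIriError):
            to_code_system(doc, lambda iri: None, TransformConfig(id="t"))

    def test_missing_version_defaults_to_na(self):
        doc = self.make_main(version=None)
        record, _ = to_code_system(doc, lambda iri: None, TransformConfig(id="t"))
        assert record.version == "NA"

    def test_first_label_is_name(self):
        record, _ = to_code_system(self.make_main(), lambda iri: None,
                                   TransformConfig(id="t"))
        assert record.name == "Main Ontology"

    def test_iri_is_name_without_label(self):
        doc = self.make_main(labels=())
        record, _ = to_code_system(doc, lambda iri: None, TransformConfig(id="t"))
        assert record.name == "http://example.org/main"

    def test_fixed_status_and_hierarchy_meaning(self):
        record, _ = to_code_system(self.make_main(), lambda iri: None,
                                   TransformConfig(id="t"))
        assert record.status == "ACTIVE"
        assert record.hierarchy_meaning == "SUBSUMES"
        assert record.url == "http://example.org/main"
        assert record.canonical_value_set_url == "http://example.org/main"

    def test_parent_root_deprecated_properties(self):
        record, _ = to_code_system(self.make_main(), lambda iri: None,
                                   TransformConfig(id="t"))
        root = record.concepts["http://example.org/main#Root"]
        child = record.concepts["http://example.org/main#Child"]
        old = record.concepts["http://example.org/main#Old"]
        assert root.properties["root"] is True
        assert root.properties["parent"] == []
        assert child.properties["root"] is False
        assert child.properties["parent"] == ["http://example.org/main#Root"]
        assert old.properties["deprecated"] is True
        assert child.properties["deprecated"] is False

    def test_imports_closure_value_sets_cover_concepts(self):
        docs, _ = generate_ontologies(FixtureSpec(seed=9, n_ontologies=3,
                                                  import_depth=2))
        by_iri = {d.iri: d for d in docs}
        record, value_sets = to_code_system(
            docs[0], by_iri.get, TransformConfig(id="t")
        )
        assert len(value_sets) == 3  # main + 2 imports
        union = set()
        for vs in value_sets:
            union |= set(vs.includes[0].codes)
        assert union == set(record.concepts)

    def test_unresolvable_import_raises(self):
        doc = self.make_main()
        doc.imports = ["http://example.org/missing"]
        from termserve.errors import ImportResolutionError
        with pytest.raises(ImportResolutionError):
            to_code_system(doc, lambda iri: None, TransformConfig(id="t"))

    def test_equivalent_classes_merge_into_one_concept(self):
        doc = self.make_main()
        doc.declare_class("http://example.org/main#Alias", label="alias")
        doc.axioms.append(EquivalentClasses(
            Named("http://example.org/main#Alias"),
            Named("http://example.org/main#Child"),
        ))
        record, _ = to_code_system(doc, lambda iri: None, TransformConfig(id="t"))
        assert "http://example.org/main#Child" not in record.concepts
        merged = record.concepts["http://example.org/main#Alias"]
        values = {d.value for d in merged.designations}
        assert {"alias", "child"} <= values

    def test_resulting_hierarchy_is_acyclic_with_reachable_roots(self):
        docs, _ = generate_ontologies(FixtureSpec(seed=13, n_ontologies=4,
                                                  import_depth=3))
        by_iri = {d.iri: d for d in docs}
        record, _ = to_code_system(docs[0], by_iri.get, TransformConfig(id="t"))
        closure = transitive_closure(record)  # raises on a cycle
        roots = {c for c, e in record.concepts.items()
                 if e.properties["root"]}
        assert roots
        for code, entry in record.concepts.items():
            if code in roots:
                continue
            assert any((r, code) in closure for r in roots)


class TestFunctionalSyntax:
    DOC = """
    Prefix(:=<http://example.org/fs#>)
    Prefix(rdfs:=<http://www.w3.org/2000/01/rdf-schema#>)
    Ontology(<http://example.org/fs> <http://example.org/fs/1.2>
      Import(<http://example.org/other>)
      Annotation(rdfs:label "FS Ontology")
      Declaration(Class(:A))
      Declaration(Class(:B))
      Declaration(Class(:C))
      AnnotationAssertion(rdfs:label :A "class a")
      SubClassOf(:A :B)
      SubClassOf(ObjectSomeValuesFrom(:r :C) :B)
      EquivalentClasses(:C ObjectIntersectionOf(:A :B))
    )
    """

    def test_reads_header_axioms_and_labels(self):
        doc = parse_functional_syntax(self.DOC)
        assert doc.iri == "http://example.org/fs"
        assert doc.version == "http://example.org/fs/1.2"
        assert doc.imports == ["http://example.org/other"]
        assert ("http://www.w3.org/2000/01/rdf-schema#label",
                "FS Ontology") in doc.annotations
        assert doc.classes["http://example.org/fs#A"]["labels"] == ["class a"]
        kinds = [type(ax).__name__ for ax in doc.axioms]
        assert kinds == ["SubClassOf", "SubClassOf", "EquivalentClasses"]

    def test_non_el_construct_rejected(self):
        bad = "Ontology(<http://x> SubClassOf(:A ObjectUnionOf(:B :C)))"
        with pytest.raises(UnsupportedAxiomError):
            parse_functional_syntax(bad)
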