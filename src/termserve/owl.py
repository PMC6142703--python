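"""OWL EL ontologies: classification and transformation to a code system.

The input is a normalized axiom exchange document (a JSON serialization of
:class:`OntologyDocument`); a best-effort reader for OWL functional syntax
is also provided. Class expressions are limited to the EL subset — named
class, intersection, existential restriction over a named property — which
admits polynomial-time classification by completion-rule saturation.

The transformation merges the main ontology with its whole imports
closure into one code system (code systems have no module mechanism, so
OWL modularity is flattened), and emits one value set per ontology
document so searches can still be scoped to a single ontology. Element
mapping: url <- ontology IRI (mandatory — the transformation stops without
it); version <- ontology version, else "NA"; name <- first rdfs:label,
else the IRI; publisher and description <- configurable annotation
properties; status ACTIVE and hierarchyMeaning SUBSUMES always. Per
concept, the properties ``parent`` (direct parents), ``root`` and
``deprecated`` are materialized from the classification.
"""
from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, field
from typing import Callable, Optional, Union

from .errors import (
    ImportResolutionError,
    MissingIriError,
    UnsupportedAxiomError,
)
from .model import CodeSystemRecord, ConceptEntry, Designation

RDFS_LABEL = "http://www.w3.org/2000/01/rdf-schema#label"
RDFS_COMMENT = "http://www.w3.org/2000/01/rdf-schema#comment"
OWL_DEPRECATED = "http://www.w3.org/2002/07/owl#deprecated"
DC_PUBLISHER = "http://purl.org/dc/elements/1.1/publisher"
DC_SUBJECT = "http://purl.org/dc/elements/1.1/subject"


# -- class expressions --------------------------------------------------------

@dataclass(frozen=True)
class Named:
    iri: str


@dataclass(frozen=True)
class IntersectionOf:
    operands: tuple["ClassExpr", ...]


@dataclass(frozen=True)
class SomeValuesFrom:
    prop: str
    filler: "ClassExpr"


ClassExpr = Union[Named, IntersectionOf, SomeValuesFrom]


@dataclass(frozen=True)
class SubClassOf:
    sub: ClassExpr
    sup: ClassExpr


@dataclass(frozen=True)
class EquivalentClasses:
    a: ClassExpr
    b: ClassExpr


Axiom = Union[SubClassOf, EquivalentClasses]


def _expr_to_json(e: ClassExpr):
    if isinstance(e, Named):
        return {"class": e.iri}
    if isinstance(e, IntersectionOf):
        return {"and": [_expr_to_json(o) for o in e.operands]}
    if isinstance(e, SomeValuesFrom):
        return {"some": [e.prop, _expr_to_json(e.filler)]}
    raise UnsupportedAxiomError(f"not an EL class expression: {e!r}")


def _expr_from_json(data) -> ClassExpr:
    if "class" in data:
        return Named(data["class"])
    if "and" in data:
        return IntersectionOf(tuple(_expr_from_json(o) for o in data["and"]))
    if "some" in data:
        prop, filler = data["some"]
        return SomeValuesFrom(prop, _expr_from_json(filler))
    raise UnsupportedAxiomError(f"unknown class expression: {data!r}")


@dataclass
class OntologyDocument:
    """One ontology: classes, EL axioms, annotations, import declarations."""

    iri: Optional[str] = None
    version: Optional[str] = None
    annotations: list[tuple[str, str]] = field(default_factory=list)
    # class IRI -> {"labels": [...], "deprecated": bool}
    classes: dict[str, dict] = field(default_factory=dict)
    axioms: list[Axiom] = field(default_factory=list)
    imports: list[str] = field(default_factory=list)

    def declare_class(self, iri: str, label: Optional[str] = None,
                      deprecated: bool = False) -> None:
        info = self.classes.setdefault(iri, {"labels": [], "deprecated": False})
        if label and label not in info["labels"]:
            info["labels"].append(label)
        if deprecated:
            info["deprecated"] = True

    def to_dict(self) -> dict:
        def axiom_json(ax):
            if isinstance(ax, SubClassOf):
                return {"subClassOf": [_expr_to_json(ax.sub), _expr_to_json(ax.sup)]}
            return {"equivalentClasses": [_expr_to_json(ax.a), _expr_to_json(ax.b)]}

        return {
            "iri": self.iri,
            "version": self.version,
            "annotations": [list(a) for a in self.annotations],
            "classes": self.classes,
            "axioms": [axiom_json(ax) for ax in self.axioms],
            "imports": list(self.imports),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "OntologyDocument":
        doc = cls(
            iri=data.get("iri"),
            version=data.get("version"),
            annotations=[tuple(a) for a in data.get("annotations", [])],
            imports=list(data.get("imports", [])),
        )
        for iri, info in data.get("classes", {}).items():
            doc.classes[iri] = {
                "labels": list(info.get("labels", [])),
                "deprecated": bool(info.get("deprecated", False)),
            }
        for ax in data.get("axioms", []):
            if "subClassOf" in ax:
                sub, sup = ax["subClassOf"]
                doc.axioms.append(
                    SubClassOf(_expr_from_json(sub), _expr_from_json(sup))
                )
            elif "equivalentClasses" in ax:
                a, b = ax["equivalentClasses"]
                doc.axioms.append(
                    EquivalentClasses(_expr_from_json(a), _expr_from_json(b))
                )
            else:
                raise UnsupportedAxiomError(f"unknown axiom: {ax!r}")
        return doc

    @classmethod
    def from_json(cls, text: str) -> "OntologyDocument":
        return cls.from_dict(json.loads(text))

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=1, sort_keys=True)


# -- classification -----------------------------------------------------------

def _normalize(axioms) -> tuple[list, list, list, list]:
    """Normalize EL axioms to the four completion normal forms.

    NF1: A subclass B; NF2: A1 and A2 subclass B; NF3: A subclass some r.B;
    NF4: some r.A subclass B — A, B named (fresh names introduced for
    complex subexpressions).
    """
    counter = itertools.count()
    nf1, nf2, nf3, nf4 = [], [], [], []

    def fresh() -> Named:
        return Named(f"urn:termserve:aux#{next(counter)}")

    def emit_sub(sub, sup_named: Named):
        # sub (possibly complex) subclass sup_named
        if isinstance(sub, Named):
            nf1.append((sub.iri, sup_named.iri))
        elif isinstance(sub, IntersectionOf):
            ops = [name_both(o) for o in sub.operands]
            if len(ops) == 1:
                nf1.append((ops[0].iri, sup_named.iri))
                return
            cur = ops[0]
            for other in ops[1:-1]:
                x = fresh()
                nf2.append((cur.iri, other.iri, x.iri))
                cur = x
            nf2.append((cur.iri, ops[-1].iri, sup_named.iri))
        elif isinstance(sub, SomeValuesFrom):
            filler = name_both(sub.filler)
            nf4.append((sub.prop, filler.iri, sup_named.iri))
        else:
            raise UnsupportedAxiomError(f"non-EL expression: {sub!r}")

    def emit_sup(sub_named: Named, sup):
        # sub_named subclass sup (possibly complex)
        if isinstance(sup, Named):
            nf1.append((sub_named.iri, sup.iri))
        elif isinstance(sup, IntersectionOf):
            for o in sup.operands:
                emit_sup(sub_named, o)
        elif isinstance(sup, SomeValuesFrom):
            filler = name_both(sup.filler)
            nf3.append((sub_named.iri, sup.prop, filler.iri))
        else:
            raise UnsupportedAxiomError(f"non-EL expression: {sup!r}")

    def name_both(expr) -> Named:
        """Fresh name X with X equivalent to expr (both directions)."""
        if isinstance(expr, Named):
            return expr
        x = fresh()
        emit_sub(expr, x)
        emit_sup(x, expr)
        return x

    flat = []
    for ax in axioms:
        if isinstance(ax, SubClassOf):
            flat.append((ax.sub, ax.sup))
        elif isinstance(ax, EquivalentClasses):
            flat.append((ax.a, ax.b))
            flat.append((ax.b, ax.a))
        else:
            raise UnsupportedAxiomError(f"unknown axiom: {ax!r}")
    for sub, sup in flat:
        sup_named = name_both(sup) if not isinstance(sup, Named) else sup
        emit_sub(sub, sup_named)
    return nf1, nf2, nf3, nf4


def classify(docs: list[OntologyDocument]) -> set[tuple[str, str]]:
    """Entailed subsumptions between named classes, reflexive pairs excluded.

    Standard EL completion-rule saturation: subsumer sets S(C) and role
    successor relations R(r) are grown to fixpoint under the four rules
    (told subsumption, conjunction, existential introduction and
    existential elimination). Equivalence shows up as mutual subsumption.
    """
    axioms = [ax for doc in docs for ax in doc.axioms]
    named = {iri for doc in docs for iri in doc.classes}
    for doc in docs:
        for ax in doc.axioms:
            named |= _named_in_axiom(ax)

    nf1, nf2, nf3, nf4 = _normalize(axioms)
    all_classes = set(named)
    for a, b in nf1:
        all_classes |= {a, b}
    for a, b, c in nf2:
        all_classes |= {a, b, c}
    for a, r, b in nf3:
        all_classes |= {a, b}
    for r, a, b in nf4:
        all_classes |= {a, b}

    S: dict[str, set[str]] = {c: {c} for c in all_classes}
    R: dict[str, set[tuple[str, str]]] = {}

    nf1_by_sub: dict[str, list[str]] = {}
    for a, b in nf1:
        nf1_by_sub.setdefault(a, []).append(b)
    nf2_by_pair: dict[tuple[str, str], list[str]] = {}
    for a, b, c in nf2:
        nf2_by_pair.setdefault((a, b), []).append(c)
        nf2_by_pair.setdefault((b, a), []).append(c)
    nf3_by_sub: dict[str, list[tuple[str, str]]] = {}
    for a, r, b in nf3:
        nf3_by_sub.setdefault(a, []).append((r, b))
    nf4_by_role: dict[str, list[tuple[str, str]]] = {}
    for r, a, b in nf4:
        nf4_by_role.setdefault(r, []).append((a, b))

    changed = True
    while changed:
        changed = False
        for c in all_classes:
            sc = S[c]
            add = set()
            for a in sc:
                for b in nf1_by_sub.get(a, ()):  # CR1
                    if b not in sc:
                        add.add(b)
            for a1, a2 in itertools.product(sc, sc):  # CR2
                for b in nf2_by_pair.get((a1, a2), ()):
                    if b not in sc:
                        add.add(b)
            if add:
                sc |= add
                changed = True
            for a in list(sc):  # CR3
                for r, b in nf3_by_sub.get(a, ()):
                    rel = R.setdefault(r, set())
                    if (c, b) not in rel:
                        rel.add((c, b))
                        changed = True
        for r, rel in R.items():  # CR4
            for (c, d) in list(rel):
                for a, b in nf4_by_role.get(r, ()):
                    if a in S[d] and b not in S[c]:
                        S[c].add(b)
                        changed = True

    return {
        (sub, sup)
        for sub in named
        for sup in S.get(sub, ())
        if sup != sub and sup in named
    }


def _named_in_axiom(ax) -> set[str]:
    out = set()

    def walk(e):
        if isinstance(e, Named):
            out.add(e.iri)
        elif isinstance(e, IntersectionOf):
            for o in e.operands:
                walk(o)
        elif isinstance(e, SomeValuesFrom):
            walk(e.filler)

    if isinstance(ax, SubClassOf):
        walk(ax.sub)
        walk(ax.sup)
    else:
        walk(ax.a)
        walk(ax.b)
    return out


# -- transformation -----------------------------------------------------------

@dataclass
class TransformConfig:
    id: str
    publisher_property: str = DC_PUBLISHER
    description_properties: tuple[str, ...] = (DC_SUBJECT, RDFS_COMMENT)
    name_override: Optional[str] = None

    def __post_init__(self):
        if not self.id:
            raise ValueError("TransformConfig.id must be non-empty")


def imports_closure(
    main: OntologyDocument,
    resolver: Callable[[str], Optional[OntologyDocument]],
) -> list[OntologyDocument]:
    """Main ontology plus every transitively imported one, each visited once."""
    ordered = [main]
    seen = {main.iri}
    queue = list(main.imports)
    while queue:
        iri = queue.pop(0)
        if iri in seen:
            continue
        seen.add(iri)
        doc = resolver(iri)
        if doc is None:
            raise ImportResolutionError(iri)
        ordered.append(doc)
        queue.extend(doc.imports)
    return ordered


def to_code_system(
    main: OntologyDocument,
    resolver: Callable[[str], Optional[OntologyDocument]],
    config: TransformConfig,
):
    """Transform an ontology (with imports) into a code system + value sets.

    Returns ``(CodeSystemRecord, list of ValueSetDefinition)`` — one value
    set for the main ontology (excluding its imports) and one per imported
    ontology; equivalent named classes merge into a single concept whose
    code is the lexicographically smallest IRI of the equivalence class,
    with the other classes' labels carried over as extra designations.
    """
    from .valuesets import ComposeRule, ValueSetDefinition

    if not main.iri:
        raise MissingIriError("the main ontology has no IRI; transformation stops")

    docs = imports_closure(main, resolver)
    entailed = classify(docs)

    declared: dict[str, dict] = {}
    for doc in docs:
        for iri, info in doc.classes.items():
            held = declared.setdefault(iri, {"labels": [], "deprecated": False})
            for lbl in info["labels"]:
                if lbl not in held["labels"]:
                    held["labels"].append(lbl)
            held["deprecated"] = held["deprecated"] or info["deprecated"]
    for a, b in entailed:
        for iri in (a, b):
            declared.setdefault(iri, {"labels": [], "deprecated": False})
    all_iris = set(declared)

    # collapse equivalence cycles (mutual subsumption) into one concept
    mutual = {(a, b) for (a, b) in entailed if (b, a) in entailed}
    rep: dict[str, str] = {iri: iri for iri in all_iris}
    for a, b in mutual:
        ra, rb = rep[a], rep[b]
        if ra != rb:
            keep, drop = min(ra, rb), max(ra, rb)
            for iri, r in rep.items():
                if r == drop:
                    rep[iri] = keep
    groups: dict[str, list[str]] = {}
    for iri, r in rep.items():
        groups.setdefault(r, []).append(iri)

    # strict subsumption between representative concepts
    strict: set[tuple[str, str]] = set()
    for a, b in entailed:
        ra, rb = rep[a], rep[b]
        if ra != rb:
            strict.add((ra, rb))  # ra subclass of rb

    # direct parents: transitive reduction of the strict order
    supers: dict[str, set[str]] = {r: set() for r in groups}
    for sub, sup in strict:
        supers[sub].add(sup)
    direct: dict[str, set[str]] = {}
    for sub, sups in supers.items():
        direct[sub] = {
            s for s in sups
            if not any(s in supers[t] for t in sups if t != s)
        }

    record = CodeSystemRecord(
        url=main.iri,
        version=main.version if main.version else "NA",
        status="ACTIVE",
        hierarchy_meaning="SUBSUMES",
        canonical_value_set_url=main.iri,
    )
    labels = [v for p, v in main.annotations if p == RDFS_LABEL]
    if config.name_override:
        record.name = config.name_override
    else:
        record.name = labels[0] if labels else main.iri

    def local_name(iri: str) -> str:
        return re.split(r"[#/]", iri)[-1] or iri

    for code in sorted(groups):
        members = sorted(groups[code], key=lambda i: (i != code, i))
        designations = []
        deprecated = False
        for iri in members:
            info = declared[iri]
            deprecated = deprecated or info["deprecated"]
            for lbl in info["labels"]:
                designations.append(Designation(value=lbl, use="synonym"))
        if not designations:
            designations.append(Designation(value=local_name(code), use="synonym"))
        parents = {p for p in direct[code]}
        record.concepts[code] = ConceptEntry(
            code=code,
            active=True,
            designations=designations,
            parents=parents,
            properties={
                "parent": sorted(parents),
                "root": not parents,
                "deprecated": deprecated,
            },
        )
    record.validate()

    value_sets = []
    for doc in docs:
        if not doc.iri:
            raise MissingIriError(f"imported ontology without IRI (via {main.iri})")
        codes = sorted({rep[iri] for iri in doc.classes if iri in rep})
        doc_labels = [v for p, v in doc.annotations if p == RDFS_LABEL]
        value_sets.append(
            ValueSetDefinition(
                url=doc.iri if doc is not main else main.iri + "?vs=main",
                name=(doc_labels[0] if doc_labels else doc.iri),
                includes=[ComposeRule(system=main.iri, codes=codes)],
            )
        )
    # resource-level metadata carried alongside the record for CLI emission
    publisher = [v for p, v in main.annotations if p == config.publisher_property]
    descriptions = [
        v for p, v in main.annotations if p in config.description_properties
    ]
    record.metadata = {  # type: ignore[attr-defined]
        "publisher": publisher[0] if publisher else None,
        "description": descriptions[0] if descriptions else None,
        "id": config.id,
    }
    return record, value_sets


# -- OWL functional syntax (best effort) --------------------------------------

_FS_TOKEN = re.compile(
    r"<[^>]*>|\"(?:[^\"\\]|\\.)*\"|[A-Za-z][\w.-]*(?::[\w.-]+)?|:[\w.-]*|[()=]"
)


def parse_functional_syntax(text: str) -> OntologyDocument:
    """Best-effort reader for OWL functional-syntax documents.

    Understands Prefix declarations, the Ontology header (IRI + version
    IRI), Import, Declaration(Class(...)), SubClassOf, EquivalentClasses,
    ObjectIntersectionOf, ObjectSomeValuesFrom and AnnotationAssertion for
    rdfs:label / owl:deprecated / ontology annotations. Anything else
    raises :class:`UnsupportedAxiomError`.
    """
    tokens = _FS_TOKEN.findall(text)
    prefixes: dict[str, str] = {
        "rdfs:": "http://www.w3.org/2000/01/rdf-schema#",
        "owl:": "http://www.w3.org/2002/07/owl#",
        "xsd:": "http://www.w3.org/2001/XMLSchema#",
    }
    doc = OntologyDocument()
    pos = 0

    def expand(tok: str) -> str:
        if tok.startswith("<"):
            return tok[1:-1]
        if ":" in tok:
            pre, local = tok.split(":", 1)
            base = prefixes.get(pre + ":")
            if base:
                return base + local
        return tok

    def literal(tok: str) -> str:
        return tok[1:-1].replace('\\"', '"') if tok.startswith('"') else tok

    def parse_expr() -> ClassExpr:
        nonlocal pos
        tok = tokens[pos]
        if tok == "ObjectIntersectionOf":
            pos += 2  # name, "("
            ops = []
            while tokens[pos] != ")":
                ops.append(parse_expr())
            pos += 1
            return IntersectionOf(tuple(ops))
        if tok == "ObjectSomeValuesFrom":
            pos += 2
            prop = expand(tokens[pos]); pos += 1
            filler = parse_expr()
            pos += 1  # ")"
            return SomeValuesFrom(prop, filler)
        if tok in ("ObjectUnionOf", "ObjectComplementOf", "ObjectAllValuesFrom",
                   "DataSomeValuesFrom", "ObjectOneOf"):
            raise UnsupportedAxiomError(f"{tok} is outside the EL subset")
        pos += 1
        return Named(expand(tok))

    while pos < len(tokens):
        tok = tokens[pos]
        if tok == "Prefix":
            # Prefix ( pre : = <iri> )  — prefix name may lex as 1 or 2 tokens
            j = pos + 2
            pre = ""
            while not tokens[j].startswith("<"):
                if tokens[j] not in ("=", ")"):
                    pre += tokens[j]
                j += 1
            prefixes[pre if pre.endswith(":") else pre + ":"] = tokens[j][1:-1]
            pos = j + 2
        elif tok == "Ontology":
            pos += 2
            if pos < len(tokens) and tokens[pos].startswith("<"):
                doc.iri = expand(tokens[pos]); pos += 1
                if pos < len(tokens) and tokens[pos].startswith("<"):
                    doc.version = expand(tokens[pos]); pos += 1
        elif tok == "Import":
            doc.imports.append(expand(tokens[pos + 2]))
            pos += 4
        elif tok == "Declaration":
            if tokens[pos + 2] == "Class":
                doc.declare_class(expand(tokens[pos + 4]))
                pos += 7
            else:
                # skip Declaration( Thing( <iri> ) )
                pos += 7
        elif tok == "Annotation":
            prop = expand(tokens[pos + 2])
            val = literal(tokens[pos + 3])
            doc.annotations.append((prop, val))
            pos += 5
        elif tok == "AnnotationAssertion":
            prop = expand(tokens[pos + 2])
            subject = expand(tokens[pos + 3])
            val = literal(tokens[pos + 4])
            if prop == RDFS_LABEL:
                doc.declare_class(subject, label=val)
            elif prop == OWL_DEPRECATED and val in ("true", "1"):
                doc.declare_class(subject, deprecated=True)
            else:
                doc.annotations.append((prop, val))
            pos += 6
        elif tok == "SubClassOf":
            pos += 2
            sub = parse_expr()
            sup = parse_expr()
            pos += 1
            doc.axioms.append(SubClassOf(sub, sup))
        elif tok == "EquivalentClasses":
            pos += 2
            a = parse_expr()
            b = parse_expr()
            pos += 1
            doc.axioms.append(EquivalentClasses(a, b))
        elif tok == ")":
            pos += 1
        else:
            pos += 1
    return doc
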