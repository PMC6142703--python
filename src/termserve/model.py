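"""Core terminology data model and the FHIR-defined operations.

This module holds the in-memory representation of a code system (concepts
with designations, an is-a hierarchy and defining relationships), the store
that keys records by ``(url, version)``, and the classic terminology-server
operations: ``lookup``, ``subsumes``, ``translate`` and the incremental
``closure`` table.

Subsumption is computed from the reflexive-free transitive closure of the
direct-parent relation; the closure is cached on the record and invalidated
implicitly by rebuilding the record (records are treated as immutable once
loaded into a store).
"""
from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Optional

from .errors import (
    ClosureNotFound,
    CodeNotFound,
    CycleError,
    DanglingReferenceError,
    SystemNotFound,
)

# Designation use values follow the FHIR designation-use code system.
DESIGNATION_USES = ("fully-specified-name", "synonym", "definition")


@dataclass(frozen=True)
class Coding:
    """A code taken from a code system, optionally version- and display-qualified."""

    system: str
    code: str
    version: Optional[str] = None
    display: Optional[str] = None

    def __post_init__(self):
        if not self.code:
            raise ValueError("Coding.code must be non-empty")
        if not self.system:
            raise ValueError("Coding.system must be non-empty")


@dataclass(frozen=True)
class Designation:
    value: str
    use: str = "synonym"
    language: str = "en"
    active: bool = True

    def __post_init__(self):
        if not self.value:
            raise ValueError("Designation.value must be non-empty")
        if self.use not in DESIGNATION_USES:
            raise ValueError(f"unknown designation use: {self.use}")


@dataclass
class ConceptEntry:
    """One concept: designations, direct parents, defining relationships, properties.

    ``defining_relationships`` are (group, type_code, target_code) triples;
    group 0 means ungrouped, matching RF2 relationship-group semantics.
    """

    code: str
    active: bool = True
    designations: list[Designation] = field(default_factory=list)
    parents: set[str] = field(default_factory=set)
    defining_relationships: list[tuple[int, str, str]] = field(default_factory=list)
    properties: dict = field(default_factory=dict)

    def display(self) -> Optional[str]:
        """First active synonym, else the FSN, else any designation."""
        for use in ("synonym", "fully-specified-name"):
            for d in self.designations:
                if d.active and d.use == use:
                    return d.value
        return self.designations[0].value if self.designations else None


class SubsumptionOutcome(str, Enum):
    EQUIVALENT = "equivalent"
    SUBSUMES = "subsumes"
    SUBSUMED_BY = "subsumed-by"
    NOT_SUBSUMED = "not-subsumed"


@dataclass
class CodeSystemRecord:
    """A versioned code system: concepts, is-a graph, refset memberships."""

    url: str
    version: str
    name: str = ""
    status: str = "ACTIVE"
    hierarchy_meaning: str = "SUBSUMES"
    concepts: dict[str, ConceptEntry] = field(default_factory=dict)
    refsets: dict[str, set[str]] = field(default_factory=dict)
    canonical_value_set_url: str = ""
    _closure_cache: dict = field(default_factory=dict, repr=False, compare=False)

    def __post_init__(self):
        if not self.canonical_value_set_url:
            self.canonical_value_set_url = self.url + "?fhir_vs"

    # -- derived views -----------------------------------------------------

    def active_codes(self) -> set[str]:
        return {c for c, e in self.concepts.items() if e.active}

    def children_of(self, code: str) -> set[str]:
        return {c for c, e in self.concepts.items() if code in e.parents}

    def validate(self) -> None:
        """Check referential integrity and acyclicity; raise on violation."""
        dangling = set()
        for entry in self.concepts.values():
            for p in entry.parents:
                if p not in self.concepts:
                    dangling.add(p)
                if p == entry.code:
                    raise CycleError([entry.code, entry.code])
            for _, type_code, target in entry.defining_relationships:
                if type_code not in self.concepts:
                    dangling.add(type_code)
                if target not in self.concepts:
                    dangling.add(target)
        if dangling:
            raise DanglingReferenceError(dangling)
        transitive_closure(self)  # raises CycleError on a cycle

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "url": self.url,
            "version": self.version,
            "name": self.name,
            "status": self.status,
            "hierarchyMeaning": self.hierarchy_meaning,
            "canonicalValueSetUrl": self.canonical_value_set_url,
            "concepts": [
                {
                    "code": e.code,
                    "active": e.active,
                    "designations": [
                        {
                            "value": d.value,
                            "use": d.use,
                            "language": d.language,
                            "active": d.active,
                        }
                        for d in e.designations
                    ],
                    "parents": sorted(e.parents),
                    "definingRelationships": [
                        list(r) for r in e.defining_relationships
                    ],
                    "properties": e.properties,
                }
                for e in sorted(self.concepts.values(), key=lambda e: e.code)
            ],
            "refsets": {k: sorted(v) for k, v in sorted(self.refsets.items())},
        }

    @classmethod
    def from_dict(cls, data: dict) -> "CodeSystemRecord":
        rec = cls(
            url=data["url"],
            version=data["version"],
            name=data.get("name", ""),
            status=data.get("status", "ACTIVE"),
            hierarchy_meaning=data.get("hierarchyMeaning", "SUBSUMES"),
            canonical_value_set_url=data.get("canonicalValueSetUrl", ""),
        )
        for c in data.get("concepts", []):
            rec.concepts[c["code"]] = ConceptEntry(
                code=c["code"],
                active=c.get("active", True),
                designations=[
                    Designation(
                        value=d["value"],
                        use=d.get("use", "synonym"),
                        language=d.get("language", "en"),
                        active=d.get("active", True),
                    )
                    for d in c.get("designations", [])
                ],
                parents=set(c.get("parents", [])),
                defining_relationships=[
                    (int(g), t, tg) for g, t, tg in c.get("definingRelationships", [])
                ],
                properties=dict(c.get("properties", {})),
            )
        for rid, members in data.get("refsets", {}).items():
            rec.refsets[rid] = set(members)
        return rec


def transitive_closure(
    cs: CodeSystemRecord, include_inactive: bool = False
) -> frozenset[tuple[str, str]]:
    """Reflexive-free transitive closure of the parent relation.

    Returns ``(ancestor, descendant)`` pairs over active concepts (all
    concepts when ``include_inactive``). Cached on the record. Raises
    :class:`CycleError` naming one cycle if the is-a graph is cyclic.
    """
    key = "full" if include_inactive else "active"
    cached = cs._closure_cache.get(key)
    if cached is not None:
        return cached

    if include_inactive:
        codes = set(cs.concepts)
    else:
        codes = cs.active_codes()

    # iterative DFS with cycle detection (WHITE/GREY/BLACK colouring);
    # ancestors accumulated in topological (post-order) fashion
    WHITE, GREY, BLACK = 0, 1, 2
    colour = {c: WHITE for c in codes}
    ancestors: dict[str, set[str]] = {}

    for start in codes:
        if colour[start] != WHITE:
            continue
        stack: list[tuple[str, bool]] = [(start, False)]
        path: list[str] = []
        while stack:
            node, processed = stack.pop()
            if processed:
                acc: set[str] = set()
                for p in cs.concepts[node].parents:
                    if p in codes:
                        acc.add(p)
                        acc |= ancestors[p]
                ancestors[node] = acc
                colour[node] = BLACK
                path.pop()
                continue
            if colour[node] == BLACK:
                continue
            if colour[node] == GREY:
                i = path.index(node)
                raise CycleError(path[i:] + [node])
            colour[node] = GREY
            path.append(node)
            stack.append((node, True))
            for p in cs.concepts[node].parents:
                if p in codes:
                    if colour[p] == GREY:
                        i = path.index(p)
                        raise CycleError(path[i:] + [p])
                    if colour[p] == WHITE:
                        stack.append((p, False))

    pairs = frozenset(
        (anc, desc) for desc, ancs in ancestors.items() for anc in ancs
    )
    cs._closure_cache[key] = pairs
    return pairs


def ancestor_map(
    cs: CodeSystemRecord, include_inactive: bool = False
) -> dict[str, set[str]]:
    """Code -> set of strict ancestors, derived from the cached closure."""
    out: dict[str, set[str]] = {
        c: set()
        for c in (cs.concepts if include_inactive else cs.active_codes())
    }
    for anc, desc in transitive_closure(cs, include_inactive):
        out[desc].add(anc)
    return out


def descendant_map(
    cs: CodeSystemRecord, include_inactive: bool = False
) -> dict[str, set[str]]:
    out: dict[str, set[str]] = {
        c: set()
        for c in (cs.concepts if include_inactive else cs.active_codes())
    }
    for anc, desc in transitive_closure(cs, include_inactive):
        out[anc].add(desc)
    return out


# -- version ordering -------------------------------------------------------

def version_key(version: str):
    """Numeric-aware lexicographic sort key: digit runs compare as integers.

    "Latest version" in a store is the maximum under this ordering, so
    "2" < "10" and "20170131" < "20180131" behave as expected.
    """
    parts = re.split(r"(\d+)", version)
    return tuple((0, int(p)) if p.isdigit() else (1, p) for p in parts if p != "")


# -- store ------------------------------------------------------------------

@dataclass
class ClosureTable:
    """Client-side incremental subsumption table over a set of codings."""

    name: str
    members: set[Coding] = field(default_factory=set)
    pairs: set[tuple[str, str]] = field(default_factory=set)


class TerminologyStore:
    """In-process store of code systems keyed by (url, version).

    File-backed persistence writes one JSON document per record; closure
    tables are kept in memory only (they are client-session state).
    """

    def __init__(self):
        self.code_systems: dict[tuple[str, str], CodeSystemRecord] = {}
        self.closures: dict[str, ClosureTable] = {}

    def add(self, record: CodeSystemRecord, validate: bool = True) -> None:
        if validate:
            record.validate()
        self.code_systems[(record.url, record.version)] = record

    def versions(self, system: str) -> list[str]:
        return sorted(
            (v for (u, v) in self.code_systems if u == system), key=version_key
        )

    def get(self, system: str, version: Optional[str] = None) -> CodeSystemRecord:
        if version is not None:
            try:
                return self.code_systems[(system, version)]
            except KeyError:
                raise SystemNotFound(f"{system} version {version}")
        versions = self.versions(system)
        if not versions:
            raise SystemNotFound(system)
        return self.code_systems[(system, versions[-1])]

    def __contains__(self, key: tuple[str, str]) -> bool:
        return key in self.code_systems

    # -- persistence -------------------------------------------------------

    def save(self, directory) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for i, rec in enumerate(self.code_systems.values()):
            path = directory / f"codesystem-{i:04d}.json"
            path.write_text(
                json.dumps(rec.to_dict(), indent=1, sort_keys=True), encoding="utf-8"
            )

    @classmethod
    def load(cls, directory) -> "TerminologyStore":
        store = cls()
        directory = Path(directory)
        if directory.is_dir():
            for path in sorted(directory.glob("codesystem-*.json")):
                rec = CodeSystemRecord.from_dict(
                    json.loads(path.read_text(encoding="utf-8"))
                )
                store.add(rec, validate=False)
        return store


# -- operations -------------------------------------------------------------

@dataclass
class ConceptDetails:
    """Result of ``lookup``: full concept state plus direct neighbourhood."""

    system: str
    version: str
    code: str
    active: bool
    display: Optional[str]
    designations: list[Designation]
    properties: dict
    parents: list[str]
    children: list[str]


def lookup(
    store: TerminologyStore,
    system: str,
    code: str,
    version: Optional[str] = None,
) -> ConceptDetails:
    """Retrieve details about a concept (inactive concepts included, flagged)."""
    cs = store.get(system, version)
    entry = cs.concepts.get(code)
    if entry is None:
        raise CodeNotFound(f"{code} in {system}|{cs.version}")
    return ConceptDetails(
        system=cs.url,
        version=cs.version,
        code=code,
        active=entry.active,
        display=entry.display(),
        designations=list(entry.designations),
        properties=dict(entry.properties),
        parents=sorted(entry.parents),
        children=sorted(cs.children_of(code)),
    )


def subsumes(
    store: TerminologyStore,
    code_a: str,
    code_b: str,
    system: str,
    version: Optional[str] = None,
    include_inactive: bool = True,
) -> SubsumptionOutcome:
    """Relationship of ``code_a`` to ``code_b``: does A subsume B?

    ``include_inactive`` controls whether inactive concepts take part in the
    hierarchy walk (historical data safety; on by default).
    """
    cs = store.get(system, version)
    for c in (code_a, code_b):
        if c not in cs.concepts:
            raise CodeNotFound(f"{c} in {system}|{cs.version}")
        if not include_inactive and not cs.concepts[c].active:
            raise CodeNotFound(f"{c} is inactive in {system}|{cs.version}")
    if code_a == code_b:
        return SubsumptionOutcome.EQUIVALENT
    closure = transitive_closure(cs, include_inactive=include_inactive)
    if (code_a, code_b) in closure:
        return SubsumptionOutcome.SUBSUMES
    if (code_b, code_a) in closure:
        return SubsumptionOutcome.SUBSUMED_BY
    return SubsumptionOutcome.NOT_SUBSUMED


# -- concept maps -----------------------------------------------------------

EQUIVALENCES = ("equivalent", "wider", "narrower", "inexact", "unmatched")


@dataclass
class ConceptMapRecord:
    """A mapping between a source and a target value set."""

    url: str
    source_value_set: str
    target_value_set: str
    entries: list[tuple[str, str, str]] = field(default_factory=list)

    def __post_init__(self):
        seen = set()
        for src, tgt, eq in self.entries:
            if (src, tgt) in seen:
                raise ValueError(f"duplicate concept-map entry ({src}, {tgt})")
            seen.add((src, tgt))
            if eq not in EQUIVALENCES:
                raise ValueError(f"unknown equivalence: {eq}")

    def to_dict(self) -> dict:
        return {
            "url": self.url,
            "sourceValueSet": self.source_value_set,
            "targetValueSet": self.target_value_set,
            "entries": [
                {"sourceCode": s, "targetCode": t, "equivalence": e}
                for s, t, e in self.entries
            ],
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ConceptMapRecord":
        return cls(
            url=data["url"],
            source_value_set=data.get("sourceValueSet", ""),
            target_value_set=data.get("targetValueSet", ""),
            entries=[
                (e["sourceCode"], e["targetCode"], e["equivalence"])
                for e in data.get("entries", [])
            ],
        )


def translate(
    cmap: ConceptMapRecord, coding: Coding, reverse: bool = False
) -> list[tuple[str, str]]:
    """All (target_code, equivalence) entries matching the coding's code.

    With ``reverse`` the map is read target-to-source. An unmatched code is
    a valid empty result, not an error.
    """
    out = []
    for src, tgt, eq in cmap.entries:
        if reverse:
            if tgt == coding.code:
                out.append((src, eq))
        else:
            if src == coding.code:
                out.append((tgt, eq))
    return out


# -- incremental closure ----------------------------------------------------

def closure_init(store: TerminologyStore, name: str) -> ClosureTable:
    table = ClosureTable(name=name)
    store.closures[name] = table
    return table


def closure_update(
    table_or_name,
    new_codings: Iterable[Coding],
    store: TerminologyStore,
) -> set[tuple[str, str]]:
    """Grow a closure table by codings; return exactly the pairs added.

    The table's ``pairs`` stay equal to the (reflexive-free) subsumption
    relation restricted to its members; re-adding a member is a no-op.
    Codings from different systems never relate.
    """
    if isinstance(table_or_name, ClosureTable):
        table = table_or_name
    else:
        table = store.closures.get(table_or_name)
        if table is None:
            raise ClosureNotFound(str(table_or_name))

    fresh = []
    for coding in new_codings:
        cs = store.get(coding.system, coding.version)
        if coding.code not in cs.concepts:
            raise CodeNotFound(f"{coding.code} in {coding.system}")
        if coding not in table.members:
            fresh.append(coding)

    delta: set[tuple[str, str]] = set()
    for coding in fresh:
        cs = store.get(coding.system, coding.version)
        closure = transitive_closure(cs, include_inactive=True)
        for other in table.members | set(fresh):
            if other == coding or other.system != coding.system:
                continue
            if other.code == coding.code:
                continue
            if (other.code, coding.code) in closure:
                delta.add((other.code, coding.code))
            if (coding.code, other.code) in closure:
                delta.add((coding.code, other.code))
    delta -= table.pairs
    table.members |= set(fresh)
    table.pairs |= delta
    return delta
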