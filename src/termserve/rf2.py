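"""RF2 snapshot reading and writing.

RF2 is the tab-separated distribution format of SNOMED CT. A snapshot
release carries one current row per component in each of the core files
(concepts, descriptions, relationships) plus reference-set member files.
This module parses those files into an :class:`Rf2Bundle`, resolves
snapshot state (newest row per component id wins), and builds a
:class:`~termserve.model.CodeSystemRecord` from the effective rows.

RF2 magic codes used here (fixed by the RF2 standard, collected in one
place):

========================  ====================================
is-a relationship type    116680003
FSN description type      900000000000003001
synonym description type  900000000000013009
definition descr. type    900000000000550004
module-dependency refset  900000000000534007
========================  ====================================
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from .errors import MissingCoreFile, ParseError
from .model import CodeSystemRecord, ConceptEntry, Designation

IS_A = "116680003"
FSN_TYPE = "900000000000003001"
SYNONYM_TYPE = "900000000000013009"
DEFINITION_TYPE = "900000000000550004"
MDRS_REFSET = "900000000000534007"

DESCRIPTION_TYPE_TO_USE = {
    FSN_TYPE: "fully-specified-name",
    SYNONYM_TYPE: "synonym",
    DEFINITION_TYPE: "definition",
}
USE_TO_DESCRIPTION_TYPE = {v: k for k, v in DESCRIPTION_TYPE_TO_USE.items()}

CONCEPT_COLUMNS = ["id", "effectiveTime", "active", "moduleId", "definitionStatusId"]
DESCRIPTION_COLUMNS = [
    "id", "effectiveTime", "active", "moduleId", "conceptId",
    "languageCode", "typeId", "term", "caseSignificanceId",
]
RELATIONSHIP_COLUMNS = [
    "id", "effectiveTime", "active", "moduleId", "sourceId", "destinationId",
    "relationshipGroup", "typeId", "characteristicTypeId", "modifierId",
]
SIMPLE_REFSET_COLUMNS = [
    "id", "effectiveTime", "active", "moduleId", "refsetId",
    "referencedComponentId",
]
MDRS_COLUMNS = SIMPLE_REFSET_COLUMNS + ["sourceEffectiveTime", "targetEffectiveTime"]

_DATE_RE = re.compile(r"^\d{8}$")


@dataclass
class ModuleDependency:
    module_id: str
    depends_on_module_id: str
    source_effective_time: str
    target_effective_time: str

    def __post_init__(self):
        if self.module_id == self.depends_on_module_id:
            raise ValueError("a module cannot depend on itself")


@dataclass
class Rf2Bundle:
    """Parsed rows of one snapshot, column schema preserved as dicts."""

    concept_rows: list[dict] = field(default_factory=list)
    description_rows: list[dict] = field(default_factory=list)
    relationship_rows: list[dict] = field(default_factory=list)
    refset_member_rows: list[dict] = field(default_factory=list)
    module_dependency_rows: list[dict] = field(default_factory=list)

    def module_dependencies(self) -> list[ModuleDependency]:
        return [
            ModuleDependency(
                module_id=r["moduleId"],
                depends_on_module_id=r["referencedComponentId"],
                source_effective_time=r["sourceEffectiveTime"],
                target_effective_time=r["targetEffectiveTime"],
            )
            for r in resolve_snapshot_state(self.module_dependency_rows)
            if r["active"] == "1"
        ]


def _read_table(path: Path, expected_columns: Optional[list[str]] = None) -> list[dict]:
    rows = []
    with open(path, encoding="utf-8", newline="") as fh:
        header_line = fh.readline()
        if not header_line:
            raise ParseError("empty RF2 file", file=path.name, line=1)
        header = header_line.rstrip("\r\n").split("\t")
        if expected_columns is not None and header != expected_columns:
            raise ParseError(
                f"unexpected header {header!r}, expected {expected_columns!r}",
                file=path.name, line=1,
            )
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\r\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ParseError(
                    f"expected {len(header)} columns, found {len(fields)}",
                    file=path.name, line=lineno,
                )
            row = dict(zip(header, fields))
            if not row["id"]:
                raise ParseError("empty component id", file=path.name, line=lineno)
            if not _DATE_RE.match(row.get("effectiveTime", "")):
                raise ParseError(
                    f"effectiveTime {row.get('effectiveTime')!r} is not YYYYMMDD",
                    file=path.name, line=lineno,
                )
            rows.append(row)
    return rows


def read_rf2_snapshot(directory) -> Rf2Bundle:
    """Parse an RF2 snapshot directory into a bundle.

    Files are located by the RF2 naming pattern (``sct2_Concept_*``,
    ``sct2_Description_*``, ``sct2_Relationship_*``, ``der2_*Refset_*``).
    Unknown refset schemas are preserved as generic member rows.
    """
    directory = Path(directory)
    bundle = Rf2Bundle()

    concept_files = sorted(directory.glob("sct2_Concept_*"))
    if not concept_files:
        raise MissingCoreFile(f"no sct2_Concept_* file in {directory}")
    for path in concept_files:
        bundle.concept_rows.extend(_read_table(path, CONCEPT_COLUMNS))
    for path in sorted(directory.glob("sct2_Description_*")):
        bundle.description_rows.extend(_read_table(path, DESCRIPTION_COLUMNS))
    for path in sorted(directory.glob("sct2_Relationship_*")):
        bundle.relationship_rows.extend(_read_table(path, RELATIONSHIP_COLUMNS))
    for path in sorted(directory.glob("der2_*Refset_*")):
        rows = _read_table(path)  # header drives the schema; refsets vary
        for row in rows:
            if "refsetId" not in row or "referencedComponentId" not in row:
                raise ParseError(
                    "refset file lacks refsetId/referencedComponentId columns",
                    file=path.name, line=1,
                )
            if row["refsetId"] == MDRS_REFSET:
                if "sourceEffectiveTime" not in row or "targetEffectiveTime" not in row:
                    raise ParseError(
                        "module-dependency row lacks source/target effective times",
                        file=path.name, line=1,
                    )
                bundle.module_dependency_rows.append(row)
            else:
                bundle.refset_member_rows.append(row)
    return bundle


def resolve_snapshot_state(rows: list[dict]) -> list[dict]:
    """Current state per component id: newest effectiveTime wins.

    Ties are broken by preferring active=1, then by input order (later rows
    win, matching append-style release assembly).
    """
    best: dict[str, tuple[tuple, dict]] = {}
    for order, row in enumerate(rows):
        key = (row["effectiveTime"], row["active"] == "1", order)
        held = best.get(row["id"])
        if held is None or key >= held[0]:
            best[row["id"]] = (key, row)
    # preserve first-appearance order of ids
    seen = set()
    out = []
    for row in rows:
        if row["id"] not in seen:
            seen.add(row["id"])
            out.append(best[row["id"]][1])
    return out


def build_code_system(
    bundle: Rf2Bundle, system_url: str, version: str
) -> CodeSystemRecord:
    """Assemble a code system record from the bundle's effective rows.

    Active is-a relationship rows become parent edges; other active
    relationship rows become defining relationships (keeping their RF2
    relationship group). Description type ids map to designation uses per
    the module-level constants table. Simple refset member rows populate
    ``refsets`` keyed by refsetId; rows of refsets with extra columns are
    additionally surfaced as concept properties named by the refsetId (the
    concrete-domains pattern), with no predicate semantics attached.
    """
    record = CodeSystemRecord(url=system_url, version=version)

    for row in resolve_snapshot_state(bundle.concept_rows):
        record.concepts[row["id"]] = ConceptEntry(
            code=row["id"], active=row["active"] == "1"
        )

    for row in resolve_snapshot_state(bundle.description_rows):
        if row["active"] != "1":
            continue
        entry = record.concepts.get(row["conceptId"])
        if entry is None:
            continue  # description of a concept outside this snapshot
        use = DESCRIPTION_TYPE_TO_USE.get(row["typeId"], "synonym")
        entry.designations.append(
            Designation(value=row["term"], use=use, language=row["languageCode"])
        )

    for row in resolve_snapshot_state(bundle.relationship_rows):
        if row["active"] != "1":
            continue
        src, dst = row["sourceId"], row["destinationId"]
        if src not in record.concepts or dst not in record.concepts:
            from .errors import DanglingReferenceError
            raise DanglingReferenceError([c for c in (src, dst)
                                          if c not in record.concepts])
        if row["typeId"] == IS_A:
            record.concepts[src].parents.add(dst)
        else:
            record.concepts[src].defining_relationships.append(
                (int(row["relationshipGroup"]), row["typeId"], dst)
            )

    for row in resolve_snapshot_state(bundle.refset_member_rows):
        if row["active"] != "1":
            continue
        rid = row["refsetId"]
        member = row["referencedComponentId"]
        record.refsets.setdefault(rid, set()).add(member)
        extra = {
            k: v for k, v in row.items()
            if k not in SIMPLE_REFSET_COLUMNS
        }
        if extra and member in record.concepts:
            record.concepts[member].properties.setdefault(rid, []).append(extra)

    record.validate()
    return record


def check_module_dependencies(
    bundle: Rf2Bundle, available_versions: dict[str, set[str]]
) -> list[ModuleDependency]:
    """Dependencies whose target module version is not available.

    An empty result means the bundle is importable against the given
    inventory of (moduleId -> installed effectiveTimes).
    """
    unsatisfied = []
    for dep in bundle.module_dependencies():
        have = available_versions.get(dep.depends_on_module_id, set())
        if dep.target_effective_time not in have:
            unsatisfied.append(dep)
    return unsatisfied


# -- writing ----------------------------------------------------------------

def record_to_bundle(
    record: CodeSystemRecord,
    module_id: str = "900062011000036108",
    effective_time: str = "20240101",
) -> Rf2Bundle:
    """Project a record onto RF2 rows (component ids synthesized).

    The inverse of :func:`build_code_system` up to the RF2-representable
    part of a record: free-form concept properties have no RF2 carrier.
    """
    bundle = Rf2Bundle()
    next_id = [100]

    def fresh(partition: str) -> str:
        next_id[0] += 1
        return f"{next_id[0]}{partition}"

    for code in sorted(record.concepts):
        entry = record.concepts[code]
        bundle.concept_rows.append({
            "id": code,
            "effectiveTime": effective_time,
            "active": "1" if entry.active else "0",
            "moduleId": module_id,
            "definitionStatusId": "900000000000074008",
        })
        for d in entry.designations:
            if not d.active:
                continue
            bundle.description_rows.append({
                "id": fresh("011"),
                "effectiveTime": effective_time,
                "active": "1",
                "moduleId": module_id,
                "conceptId": code,
                "languageCode": d.language,
                "typeId": USE_TO_DESCRIPTION_TYPE[d.use],
                "term": d.value,
                "caseSignificanceId": "900000000000448009",
            })
        for parent in sorted(entry.parents):
            bundle.relationship_rows.append({
                "id": fresh("021"),
                "effectiveTime": effective_time,
                "active": "1",
                "moduleId": module_id,
                "sourceId": code,
                "destinationId": parent,
                "relationshipGroup": "0",
                "typeId": IS_A,
                "characteristicTypeId": "900000000000011006",
                "modifierId": "900000000000451002",
            })
        for group, type_code, target in entry.defining_relationships:
            bundle.relationship_rows.append({
                "id": fresh("021"),
                "effectiveTime": effective_time,
                "active": "1",
                "moduleId": module_id,
                "sourceId": code,
                "destinationId": target,
                "relationshipGroup": str(group),
                "typeId": type_code,
                "characteristicTypeId": "900000000000011006",
                "modifierId": "900000000000451002",
            })
    for rid in sorted(record.refsets):
        for member in sorted(record.refsets[rid]):
            bundle.refset_member_rows.append({
                "id": fresh("031"),
                "effectiveTime": effective_time,
                "active": "1",
                "moduleId": module_id,
                "refsetId": rid,
                "referencedComponentId": member,
            })
    return bundle


def _write_table(path: Path, columns: list[str], rows: list[dict]) -> None:
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write("\t".join(columns) + "\r\n")
        for row in rows:
            fh.write("\t".join(row[c] for c in columns) + "\r\n")


def write_rf2_snapshot(bundle: Rf2Bundle, directory, release_tag="INT_20240101") -> None:
    """Write a bundle as a snapshot directory (UTF-8, tab-separated, CRLF)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    _write_table(
        directory / f"sct2_Concept_Snapshot_{release_tag}.txt",
        CONCEPT_COLUMNS, bundle.concept_rows,
    )
    _write_table(
        directory / f"sct2_Description_Snapshot_{release_tag}.txt",
        DESCRIPTION_COLUMNS, bundle.description_rows,
    )
    _write_table(
        directory / f"sct2_Relationship_Snapshot_{release_tag}.txt",
        RELATIONSHIP_COLUMNS, bundle.relationship_rows,
    )
    _write_table(
        directory / f"der2_Refset_SimpleSnapshot_{release_tag}.txt",
        SIMPLE_REFSET_COLUMNS, bundle.refset_member_rows,
    )
    if bundle.module_dependency_rows:
        _write_table(
            directory / f"der2_ssRefset_ModuleDependencySnapshot_{release_tag}.txt",
            MDRS_COLUMNS, bundle.module_dependency_rows,
        )
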