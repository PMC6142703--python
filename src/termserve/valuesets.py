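"""Value sets: implicit URL parsing, compose evaluation, expand, validate-code.

A value set is a subset of codes drawn from one or more code systems.
Implicit value sets are identified purely by URL shape over a code
system's own semantics::

    <system>?fhir_vs              all concepts
    <system>?fhir_vs=isa/<code>   the code and all its descendants
    <system>?fhir_vs=refset/<id>  members of a reference set
    <system>?fhir_vs=ecl/<expr>   an ECL expression (URL-encoded)

The ``ecl`` kind is an extension beyond the canonical three shapes so the
constraint language is reachable by URL.

Explicit definitions compose include/exclude rules: within one rule the
explicit codes, the filters and the imported value sets intersect; across
rules of the same list they union; all excludes are subtracted after all
includes (FHIR compose semantics). Expansions only ever contain active
concepts. With a text filter, members are ranked by the multi-prefix
matching score and non-matching members are dropped; without one, the
expansion is ordered by code ascending.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Optional, Union
from urllib.parse import unquote

from . import ecl as _ecl
from . import search as _search
from .errors import (
    ImportCycleError,
    UnsupportedImplicitValueSet,
    ValueSetNotFound,
)
from .model import Coding, TerminologyStore


@dataclass(frozen=True)
class ImplicitValueSetSpec:
    system: str
    kind: str  # all | isa | refset | ecl
    argument: Optional[str] = None

    def __post_init__(self):
        if self.kind not in ("all", "isa", "refset", "ecl"):
            raise ValueError(f"unknown implicit value-set kind: {self.kind}")
        if (self.argument is None) != (self.kind == "all"):
            raise ValueError("argument present iff kind != all")


@dataclass
class Filter:
    property: str  # "concept" or "constraint"
    op: str        # "is-a", "in", "="
    value: str


@dataclass
class ComposeRule:
    system: Optional[str] = None
    version: Optional[str] = None
    codes: Optional[list[str]] = None
    filters: Optional[list[Filter]] = None
    imported_value_sets: Optional[list[str]] = None

    def __post_init__(self):
        if not (self.codes or self.filters or self.imported_value_sets):
            raise ValueError(
                "a compose rule needs at least one of codes/filters/imports"
            )


@dataclass
class ValueSetDefinition:
    url: str
    name: str = ""
    includes: list[ComposeRule] = field(default_factory=list)
    excludes: list[ComposeRule] = field(default_factory=list)

    def to_dict(self) -> dict:
        def rule_dict(r: ComposeRule) -> dict:
            d: dict = {}
            if r.system:
                d["system"] = r.system
            if r.version:
                d["version"] = r.version
            if r.codes is not None:
                d["concept"] = [{"code": c} for c in r.codes]
            if r.filters:
                d["filter"] = [
                    {"property": f.property, "op": f.op, "value": f.value}
                    for f in r.filters
                ]
            if r.imported_value_sets:
                d["valueSet"] = list(r.imported_value_sets)
            return d

        return {
            "url": self.url,
            "name": self.name,
            "compose": {
                "include": [rule_dict(r) for r in self.includes],
                "exclude": [rule_dict(r) for r in self.excludes],
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ValueSetDefinition":
        def rule(d: dict) -> ComposeRule:
            return ComposeRule(
                system=d.get("system"),
                version=d.get("version"),
                codes=[c["code"] for c in d["concept"]] if "concept" in d else None,
                filters=[
                    Filter(f["property"], f["op"], f["value"])
                    for f in d.get("filter", [])
                ] or None,
                imported_value_sets=d.get("valueSet") or None,
            )

        compose = data.get("compose", {})
        return cls(
            url=data["url"],
            name=data.get("name", ""),
            includes=[rule(r) for r in compose.get("include", [])],
            excludes=[rule(r) for r in compose.get("exclude", [])],
        )


@dataclass
class Expansion:
    total: int
    contains: list[Coding]
    timestamp: str
    scores: Optional[list[float]] = None  # sigma per entry when text-filtered

    def to_dict(self) -> dict:
        out = {
            "timestamp": self.timestamp,
            "total": self.total,
            "contains": [
                {
                    "system": c.system,
                    "code": c.code,
                    **({"display": c.display} if c.display else {}),
                }
                for c in self.contains
            ],
        }
        if self.scores is not None:
            for entry, s in zip(out["contains"], self.scores):
                entry["score"] = round(s, 6)
        return out


def parse_implicit_url(url: str) -> ImplicitValueSetSpec:
    """Parse an implicit value-set URL into its spec."""
    if "?" not in url:
        raise UnsupportedImplicitValueSet(f"no query part in {url!r}")
    system, query = url.split("?", 1)
    if query == "fhir_vs":
        return ImplicitValueSetSpec(system=system, kind="all")
    if not query.startswith("fhir_vs="):
        raise UnsupportedImplicitValueSet(f"unknown query {query!r}")
    body = query[len("fhir_vs="):]
    if "/" not in body:
        raise UnsupportedImplicitValueSet(f"unknown fhir_vs kind {body!r}")
    kind, argument = body.split("/", 1)
    argument = unquote(argument)
    if kind not in ("isa", "refset", "ecl") or not argument:
        raise UnsupportedImplicitValueSet(f"unknown fhir_vs kind {kind!r}")
    return ImplicitValueSetSpec(system=system, kind=kind, argument=argument)


ExpandTarget = Union[ValueSetDefinition, ImplicitValueSetSpec, str]


class _Expander:
    def __init__(self, store: TerminologyStore,
                 definitions: Optional[dict[str, ValueSetDefinition]] = None):
        self.store = store
        self.definitions = definitions or {}
        self._visiting: set[str] = set()

    def members(self, target: ExpandTarget) -> set[tuple[str, str]]:
        if isinstance(target, str):
            if target in self.definitions:
                return self._definition_members(self.definitions[target])
            return self._implicit_members(parse_implicit_url(target))
        if isinstance(target, ImplicitValueSetSpec):
            return self._implicit_members(target)
        return self._definition_members(target)

    def _implicit_members(self, spec: ImplicitValueSetSpec) -> set[tuple[str, str]]:
        cs = self.store.get(spec.system)
        if spec.kind == "all":
            codes = cs.active_codes()
        elif spec.kind == "isa":
            codes = _ecl.evaluate_ecl(f"<< {spec.argument}", cs)
        elif spec.kind == "refset":
            codes = _ecl.evaluate_ecl(f"^ {spec.argument}", cs)
        else:  # ecl
            codes = _ecl.evaluate_ecl(spec.argument, cs)
        return {(cs.url, c) for c in codes}

    def _definition_members(self, vs: ValueSetDefinition) -> set[tuple[str, str]]:
        if vs.url in self._visiting:
            raise ImportCycleError(f"value-set import cycle through {vs.url}")
        self._visiting.add(vs.url)
        try:
            included: set[tuple[str, str]] = set()
            for rule in vs.includes:
                included |= self._rule_members(rule)
            for rule in vs.excludes:
                included -= self._rule_members(rule)
            return included
        finally:
            self._visiting.discard(vs.url)

    def _rule_members(self, rule: ComposeRule) -> set[tuple[str, str]]:
        sets: list[set[tuple[str, str]]] = []
        if rule.codes is not None or rule.filters:
            if not rule.system:
                raise ValueSetNotFound("compose rule with codes/filters needs a system")
            cs = self.store.get(rule.system, rule.version)
            active = cs.active_codes()
            if rule.codes is not None:
                sets.append({(cs.url, c) for c in rule.codes if c in active})
            for f in rule.filters or []:
                sets.append({(cs.url, c) for c in self._filter_codes(f, cs)})
        for url in rule.imported_value_sets or []:
            if url in self.definitions:
                sets.append(self._definition_members(self.definitions[url]))
            else:
                try:
                    sets.append(self._implicit_members(parse_implicit_url(url)))
                except UnsupportedImplicitValueSet:
                    raise ValueSetNotFound(url)
        out = sets[0]
        for s in sets[1:]:
            out &= s
        return out

    def _filter_codes(self, f: Filter, cs) -> set[str]:
        if f.property == "concept" and f.op == "is-a":
            return _ecl.evaluate_ecl(f"<< {f.value}", cs)
        if f.property == "concept" and f.op == "in":
            return _ecl.evaluate_ecl(f"^ {f.value}", cs)
        if f.property == "constraint":
            return _ecl.evaluate_ecl(f.value, cs)
        raise ValueSetNotFound(
            f"unsupported filter {f.property!r} {f.op!r}"
        )


def expand(
    target: ExpandTarget,
    store: TerminologyStore,
    filter_text: Optional[str] = None,
    offset: int = 0,
    count: Optional[int] = None,
    definitions: Optional[dict[str, ValueSetDefinition]] = None,
) -> Expansion:
    """Resolve a value set's members; optionally text-filter and window.

    ``definitions`` resolves imported explicit value sets by URL. ``total``
    reflects the member count before offset/count windowing.
    """
    expander = _Expander(store, definitions)
    members = expander.members(target)

    def display_of(system: str, code: str) -> Optional[str]:
        return store.get(system).concepts[code].display()

    scores: Optional[list[float]] = None
    if filter_text is not None and filter_text.strip():
        candidates = []
        for system, code in members:
            entry = store.get(system).concepts[code]
            for d in entry.designations:
                if d.active:
                    candidates.append(((system, code), d.value))
        ranked = _search.rank(filter_text, [(str(k), lbl) for k, lbl in candidates])
        # rank keys are stringified (system, code); keep best per concept
        key_map = {str(k): k for k, _ in candidates}
        seen = set()
        ordered: list[tuple[str, str]] = []
        sigma: list[float] = []
        labels: list[str] = []
        for key_str, label, s in ranked:
            key = key_map[key_str]
            if key in seen:
                continue
            seen.add(key)
            ordered.append(key)
            sigma.append(s)
            labels.append(label)
        contains = [
            Coding(system=sys, code=code, display=label)
            for (sys, code), label in zip(ordered, labels)
        ]
        scores = sigma
    else:
        ordered = sorted(members, key=lambda t: (t[0], t[1]))
        contains = [
            Coding(system=sys, code=code, display=display_of(sys, code))
            for sys, code in ordered
        ]

    total = len(contains)
    window = contains[offset: offset + count if count is not None else None]
    if scores is not None:
        scores = scores[offset: offset + count if count is not None else None]
    return Expansion(
        total=total,
        contains=window,
        timestamp=_dt.datetime.now(_dt.timezone.utc).isoformat(timespec="seconds"),
        scores=scores,
    )


def validate_code(
    target: ExpandTarget,
    store: TerminologyStore,
    coding: Coding,
    definitions: Optional[dict[str, ValueSetDefinition]] = None,
) -> tuple[bool, Optional[bool], str]:
    """Membership check, plus display verification when a display is given.

    ``display_valid`` is a case-insensitive comparison of the supplied
    display against the concept's active designations — the check used to
    spot code labels end users have edited away from any original label.
    """
    expander = _Expander(store, definitions)
    members = expander.members(target)
    key = (coding.system, coding.code)
    if key not in members:
        return False, None, f"{coding.code} is not in the value set"
    display_valid: Optional[bool] = None
    message = f"{coding.code} is a member"
    if coding.display:
        entry = store.get(coding.system).concepts[coding.code]
        wanted = coding.display.strip().lower()
        display_valid = any(
            d.active and d.value.strip().lower() == wanted
            for d in entry.designations
        )
        if not display_valid:
            message += "; display does not match any active designation"
    return True, display_valid, message
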