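"""Expression Constraint Language: parsing, rendering, evaluation.

ECL is SNOMED CT's set-valued query language. The subset implemented here
covers the constructs a terminology server needs for value-set filters and
implicit value-set URLs:

* focus constraints with the six operators — self, ``<`` (descendants),
  ``<<`` (descendant-or-self), ``>`` (ancestors), ``>>``
  (ancestor-or-self), ``^`` (refset members) — over a concept code or the
  ``*`` wildcard;
* ``AND`` / ``OR`` / ``MINUS`` compounds (left-associative; ``MINUS``
  binds loosest, per the ECL brief-syntax precedence) and parentheses;
* one refinement level introduced by ``:`` — comma-separated attribute
  constraints, optionally wrapped in a single ``{ ... }`` attribute group;
  attribute and value sides may themselves be constrained expressions;
* ``|term|`` annotations, which are ignored.

Cardinalities, dotted/reverse attributes, nested attribute groups and
member-field filters are out of the subset and raise
:class:`~termserve.errors.UnsupportedEclFeature`.

Evaluation is plain set algebra over the record's cached transitive
closure, restricted to active concepts.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional, Union

from .errors import CodeNotFound, EclSyntaxError, UnsupportedEclFeature
from .model import CodeSystemRecord, ancestor_map, descendant_map

# -- AST --------------------------------------------------------------------

OPERATORS = {
    "self": "",
    "descendantOf": "<",
    "descendantOrSelfOf": "<<",
    "ancestorOf": ">",
    "ancestorOrSelfOf": ">>",
    "memberOf": "^",
}
SYMBOL_TO_OPERATOR = {v: k for k, v in OPERATORS.items() if v}


@dataclass(frozen=True)
class FocusConcept:
    operator: str  # key of OPERATORS
    code: Optional[str]  # None means the * wildcard
    term: Optional[str] = field(default=None, compare=False)

    @property
    def wildcard(self) -> bool:
        return self.code is None


@dataclass(frozen=True)
class And:
    left: "EclExpression"
    right: "EclExpression"


@dataclass(frozen=True)
class Or:
    left: "EclExpression"
    right: "EclExpression"


@dataclass(frozen=True)
class Minus:
    left: "EclExpression"
    right: "EclExpression"


@dataclass(frozen=True)
class AttributeConstraint:
    attribute: "EclExpression"
    value: "EclExpression"
    grouped: bool = False


@dataclass(frozen=True)
class Refined:
    base: "EclExpression"
    refinements: tuple[AttributeConstraint, ...]


EclExpression = Union[FocusConcept, And, Or, Minus, Refined]


# -- lexer ------------------------------------------------------------------

_TOKEN_RE = re.compile(
    r"""
    (?P<ws>\s+)
  | (?P<term>\|[^|]*\|)
  | (?P<op><<|>>|<|>|\^)
  | (?P<kw>AND\b|OR\b|MINUS\b)
  | (?P<code>\w+)
  | (?P<punct>[():,{}=*])
  | (?P<unsupported>[\[\].!R])
    """,
    re.VERBOSE,
)


def _tokenize(text: str) -> list[tuple[str, str, int]]:
    tokens = []
    pos = 0
    while pos < len(text):
        m = _TOKEN_RE.match(text, pos)
        if not m:
            raise EclSyntaxError(f"unexpected character {text[pos]!r}", pos)
        kind = m.lastgroup
        value = m.group()
        if kind == "unsupported":
            feature = {
                "[": "cardinality", "]": "cardinality",
                ".": "dotted attribute", "!": "child/parent-of operator",
                "R": "reverse attribute",
            }[value]
            raise UnsupportedEclFeature(f"{feature} (at position {pos})")
        if kind not in ("ws", "term"):
            tokens.append((kind, value, pos))
        pos = m.end()
    tokens.append(("eof", "", len(text)))
    return tokens


# -- parser -----------------------------------------------------------------

class _Parser:
    def __init__(self, text: str):
        self.text = text
        self.tokens = _tokenize(text)
        self.i = 0

    def peek(self):
        return self.tokens[self.i]

    def next(self):
        tok = self.tokens[self.i]
        self.i += 1
        return tok

    def expect(self, value: str):
        kind, val, pos = self.next()
        if val != value:
            raise EclSyntaxError(f"expected {value!r}, found {val!r}", pos)

    # expression := conjunction ("MINUS" conjunction)*
    def expression(self) -> EclExpression:
        node = self.conjunction()
        while self.peek()[1] == "MINUS":
            self.next()
            node = Minus(node, self.conjunction())
        return node

    # conjunction := refined (("AND" | "OR") refined)*   (left-assoc, equal binding)
    def conjunction(self) -> EclExpression:
        node = self.refined()
        while self.peek()[1] in ("AND", "OR"):
            _, op, _ = self.next()
            rhs = self.refined()
            node = And(node, rhs) if op == "AND" else Or(node, rhs)
        return node

    # refined := subexpression (":" refinement)?
    def refined(self) -> EclExpression:
        base = self.subexpression()
        if self.peek()[1] == ":":
            self.next()
            constraints = self.refinement()
            return Refined(base, tuple(constraints))
        return base

    def refinement(self) -> list[AttributeConstraint]:
        constraints: list[AttributeConstraint] = []
        saw_group = False
        while True:
            if self.peek()[1] == "{":
                if saw_group:
                    raise UnsupportedEclFeature(
                        "multiple attribute groups in one refinement"
                    )
                saw_group = True
                self.next()
                constraints.append(self.attribute_constraint(grouped=True))
                while self.peek()[1] == ",":
                    self.next()
                    constraints.append(self.attribute_constraint(grouped=True))
                self.expect("}")
            else:
                constraints.append(self.attribute_constraint(grouped=False))
            if self.peek()[1] == ",":
                self.next()
                continue
            return constraints

    def attribute_constraint(self, grouped: bool) -> AttributeConstraint:
        kind, val, pos = self.peek()
        if val == "R":  # reserved reverse-attribute marker in ECL
            raise UnsupportedEclFeature(f"reverse attribute (at position {pos})")
        attribute = self.subexpression()
        self.expect("=")
        value = self.subexpression()
        return AttributeConstraint(attribute=attribute, value=value, grouped=grouped)

    # subexpression := focus | "(" expression ")"
    def subexpression(self) -> EclExpression:
        kind, val, pos = self.peek()
        if val == "(":
            self.next()
            node = self.expression()
            self.expect(")")
            return node
        return self.focus()

    def focus(self) -> FocusConcept:
        kind, val, pos = self.peek()
        operator = "self"
        if kind == "op":
            self.next()
            operator = SYMBOL_TO_OPERATOR[val]
            kind, val, pos = self.peek()
        if val == "*":
            self.next()
            if operator == "memberOf":
                raise EclSyntaxError("^ requires a refset code, not *", pos)
            return FocusConcept(operator=operator, code=None)
        if kind != "code":
            raise EclSyntaxError(f"expected a concept code, found {val!r}", pos)
        self.next()
        return FocusConcept(operator=operator, code=val)

    def parse(self) -> EclExpression:
        node = self.expression()
        kind, val, pos = self.peek()
        if kind != "eof":
            raise EclSyntaxError(f"trailing input {val!r}", pos)
        return node


def parse_ecl(text: str) -> EclExpression:
    """Parse ECL text (whitespace-insensitive) into an AST."""
    return _Parser(text).parse()


# -- rendering --------------------------------------------------------------

def render_ecl(expr: EclExpression) -> str:
    """Serialize an AST back to ECL text; ``parse(render(x)) == x``."""

    def atom(e: EclExpression) -> str:
        # parenthesize anything that is not a bare focus concept
        if isinstance(e, FocusConcept):
            return render_ecl(e)
        return "(" + render_ecl(e) + ")"

    if isinstance(expr, FocusConcept):
        sym = OPERATORS[expr.operator]
        body = "*" if expr.wildcard else expr.code
        return f"{sym} {body}".strip()
    if isinstance(expr, (And, Or, Minus)):
        kw = {And: "AND", Or: "OR", Minus: "MINUS"}[type(expr)]
        return f"{atom(expr.left)} {kw} {atom(expr.right)}"
    if isinstance(expr, Refined):
        # grouped constraints are contiguous (single-group subset); emit the
        # braces in place so render/parse round-trips preserve order
        parts = []
        i = 0
        refs = expr.refinements
        while i < len(refs):
            c = refs[i]
            if c.grouped:
                j = i
                while j < len(refs) and refs[j].grouped:
                    j += 1
                inner = ", ".join(
                    f"{atom(r.attribute)} = {atom(r.value)}" for r in refs[i:j]
                )
                parts.append("{ " + inner + " }")
                i = j
            else:
                parts.append(f"{atom(c.attribute)} = {atom(c.value)}")
                i += 1
        return f"{atom(expr.base)} : " + ", ".join(parts)
    raise TypeError(f"not an ECL node: {expr!r}")


# -- evaluation -------------------------------------------------------------

def evaluate_ecl(
    expr: Union[EclExpression, str], cs: CodeSystemRecord
) -> set[str]:
    """Evaluate an expression to the set of matching active concept codes."""
    if isinstance(expr, str):
        expr = parse_ecl(expr)
    active = cs.active_codes()
    ancestors = ancestor_map(cs)
    descendants = descendant_map(cs)

    def check(code: str) -> None:
        if code not in cs.concepts:
            raise CodeNotFound(f"{code} in {cs.url}|{cs.version}")

    def ev(node: EclExpression) -> set[str]:
        if isinstance(node, FocusConcept):
            if node.operator == "memberOf":
                if node.code not in cs.refsets:
                    raise CodeNotFound(
                        f"refset {node.code} in {cs.url}|{cs.version}"
                    )
                return cs.refsets[node.code] & active
            if node.wildcard:
                base = set(active)
                if node.operator == "self":
                    return base
                # hierarchy operators over * collapse to all active codes
                if node.operator in ("descendantOrSelfOf", "ancestorOrSelfOf"):
                    return base
                out: set[str] = set()
                m = descendants if node.operator == "descendantOf" else ancestors
                for c in base:
                    out |= m[c] & active
                return out
            check(node.code)
            c = node.code
            if node.operator == "self":
                return {c} & active if cs.concepts[c].active else set()
            if node.operator == "descendantOf":
                return descendants.get(c, set()) & active
            if node.operator == "descendantOrSelfOf":
                return (descendants.get(c, set()) | {c}) & active
            if node.operator == "ancestorOf":
                return ancestors.get(c, set()) & active
            if node.operator == "ancestorOrSelfOf":
                return (ancestors.get(c, set()) | {c}) & active
            raise TypeError(node.operator)
        if isinstance(node, And):
            return ev(node.left) & ev(node.right)
        if isinstance(node, Or):
            return ev(node.left) | ev(node.right)
        if isinstance(node, Minus):
            return ev(node.left) - ev(node.right)
        if isinstance(node, Refined):
            base = ev(node.base)
            if not node.refinements:
                return base
            resolved = [
                (c, ev(c.attribute), ev(c.value)) for c in node.refinements
            ]
            out = set()
            for code in base:
                if _satisfies(cs.concepts[code].defining_relationships, resolved):
                    out.add(code)
            return out
        raise TypeError(f"not an ECL node: {node!r}")

    return ev(expr)


def _satisfies(relationships, resolved) -> bool:
    """Check a concept's relationships against resolved attribute constraints.

    Ungrouped constraints may be met by any relationship; all grouped
    constraints must be met within one common relationship group (> 0).
    """
    def met_by(rel, types, targets):
        _, type_code, target = rel
        return type_code in types and target in targets

    for constraint, types, targets in resolved:
        if constraint.grouped:
            continue
        if not any(met_by(r, types, targets) for r in relationships):
            return False

    grouped = [(t, v) for c, t, v in resolved if c.grouped]
    if not grouped:
        return True
    groups = {r[0] for r in relationships if r[0] > 0}
    for g in groups:
        in_group = [r for r in relationships if r[0] == g]
        if all(any(met_by(r, t, v) for r in in_group) for t, v in grouped):
            return True
    return False
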