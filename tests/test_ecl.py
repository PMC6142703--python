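"""ECL parsing, rendering and evaluation against a set-algebra oracle."""
import random

import networkx as nx
import pytest

from conftest import random_dag_record
from termserve.ecl import (
    And,
    AttributeConstraint,
    FocusConcept,
    Minus,
    Or,
    Refined,
    evaluate_ecl,
    parse_ecl,
    render_ecl,
)
from termserve.errors import CodeNotFound, EclSyntaxError, UnsupportedEclFeature


class TestParse:
    def test_descendant_or_self(self):
        assert parse_ecl("<< 404684003") == FocusConcept(
            operator="descendantOrSelfOf", code="404684003"
        )

    def test_member_of_refset(self):
        assert parse_ecl("^ 171881000036108") == FocusConcept(
            operator="memberOf", code="171881000036108"
        )

    def test_minus_binds_loosest(self):
        assert parse_ecl("<A MINUS <B") == Minus(
            FocusConcept(operator="descendantOf", code="A"),
            FocusConcept(operator="descendantOf", code="B"),
        )
        # AND groups before MINUS
        expr = parse_ecl("<A AND <B MINUS <C")
        assert isinstance(expr, Minus)
        assert isinstance(expr.left, And)

    def test_term_annotations_ignored(self):
        a = parse_ecl("<< 404684003 |Clinical finding|")
        b = parse_ecl("<<404684003")
        assert a == b

    def test_refinement_with_group(self):
        expr = parse_ecl("<< A : B = C, { D = E, F = G }")
        assert isinstance(expr, Refined)
        assert [c.grouped for c in expr.refinements] == [False, True, True]

    def test_syntax_error_position(self):
        with pytest.raises(EclSyntaxError) as exc:
            parse_ecl("<< A MINUS")
        assert exc.value.position is not None

    @pytest.mark.parametrize("text", ["[1..2] A", "A . B", "<< A : R B = C"])
    def test_unsupported_constructs_named(self, text):
        with pytest.raises(UnsupportedEclFeature):
            parse_ecl(text)

    def test_nested_groups_rejected(self):
        with pytest.raises(UnsupportedEclFeature):
            parse_ecl("<< A : { B = C }, { D = E }")


class TestRenderRoundTrip:
    @pytest.mark.parametrize("text", [
        "<< 404684003",
        "^ 171881000036108",
        "<A MINUS <B",
        "* MINUS (<< A OR >> B)",
        "<< A : B = C, { D = << E, F = G }",
        "(<A AND <B) MINUS (^ R : X = (Y OR Z))",
    ])
    def test_render_reparses_to_equal_ast(self, text):
        ast = parse_ecl(text)
        assert parse_ecl(render_ecl(ast)) == ast


def _ecl_oracle(expr, record):
    """Naive bottom-up evaluation with explicit reachability matrices."""
    active = record.active_codes()
    g = nx.DiGraph()
    g.add_nodes_from(active)
    for code in active:
        for p in record.concepts[code].parents:
            if p in active:
                g.add_edge(code, p)  # child -> parent
    anc = {c: set(nx.descendants(g, c)) for c in active}
    desc = {c: {d for d in active if c in anc[d]} for c in active}

    def ev(node):
        if isinstance(node, FocusConcept):
            if node.operator == "memberOf":
                return record.refsets[node.code] & active
            if node.code is None:
                base = set(active)
                if node.operator in ("self", "descendantOrSelfOf",
                                     "ancestorOrSelfOf"):
                    return base
                out = set()
                src = desc if node.operator == "descendantOf" else anc
                for c in base:
                    out |= src[c]
                return out
            c = node.code
            if node.operator == "self":
                return {c} & active
            if node.operator == "descendantOf":
                return desc.get(c, set())
            if node.operator == "descendantOrSelfOf":
                return desc.get(c, set()) | ({c} & active)
            if node.operator == "ancestorOf":
                return anc.get(c, set())
            return anc.get(c, set()) | ({c} & active)
        if isinstance(node, And):
            return ev(node.left) & ev(node.right)
        if isinstance(node, Or):
            return ev(node.left) | ev(node.right)
        if isinstance(node, Minus):
            return ev(node.left) - ev(node.right)
        if isinstance(node, Refined):
            base = ev(node.base)
            resolved = [(c.grouped, ev(c.attribute), ev(c.value))
                        for c in node.refinements]
            out = set()
            for code in base:
                rels = record.concepts[code].defining_relationships
                ok = True
                for grouped, types, targets in resolved:
                    if grouped:
                        continue
                    if not any(t in types and v in targets
                               for _, t, v in rels):
                        ok = False
                grouped_cs = [(t, v) for g2, t, v in resolved if g2]
                if ok and grouped_cs:
                    ok = any(
                        all(any(r[1] in t and r[2] in v
                                for r in rels if r[0] == g3)
                            for t, v in grouped_cs)
                        for g3 in {r[0] for r in rels if r[0] > 0}
                    )
                if ok:
                    out.add(code)
            return out
        raise TypeError(node)

    return ev(expr)


def random_expression(rng, codes, refsets, attrs, depth=0):
    """Sample a random expression from the supported grammar."""
    ops = ["self", "descendantOf", "descendantOrSelfOf",
           "ancestorOf", "ancestorOrSelfOf"]
    if depth >= 3 or rng.random() < 0.4:
        if refsets and rng.random() < 0.2:
            return FocusConcept(operator="memberOf", code=rng.choice(refsets))
        if rng.random() < 0.1:
            return FocusConcept(operator=rng.choice(ops[:3]), code=None)
        return FocusConcept(operator=rng.choice(ops), code=rng.choice(codes))
    kind = rng.random()
    if kind < 0.3:
        return And(random_expression(rng, codes, refsets, attrs, depth + 1),
                   random_expression(rng, codes, refsets, attrs, depth + 1))
    if kind < 0.6:
        return Or(random_expression(rng, codes, refsets, attrs, depth + 1),
                  random_expression(rng, codes, refsets, attrs, depth + 1))
    if kind < 0.85:
        return Minus(random_expression(rng, codes, refsets, attrs, depth + 1),
                     random_expression(rng, codes, refsets, attrs, depth + 1))
    constraints = []
    n_plain = rng.randint(0, 2)
    for _ in range(n_plain):
        constraints.append(AttributeConstraint(
            attribute=FocusConcept(
                operator=rng.choice(["self", "descendantOrSelfOf"]),
                code=rng.choice(attrs)),
            value=random_expression(rng, codes, refsets, attrs, depth + 2),
            grouped=False,
        ))
    if rng.random() < 0.4 or not constraints:
        for _ in range(rng.randint(1, 2)):
            constraints.append(AttributeConstraint(
                attribute=FocusConcept(operator="self", code=rng.choice(attrs)),
                value=random_expression(rng, codes, refsets, attrs, depth + 2),
                grouped=True,
            ))
    return Refined(
        base=random_expression(rng, codes, refsets, attrs, depth + 1),
        refinements=tuple(constraints),
    )


def attributed_record(rng, n=150):
    record = random_dag_record(rng, n, url="http://example.org/ecl",
                               inactive_fraction=0.05)
    codes = list(record.concepts)
    attrs = codes[:4]  # attribute types are ordinary concepts
    for code in codes:
        if rng.random() < 0.5:
            record.concepts[code].defining_relationships.append(
                (rng.choice([0, 1, 2]), rng.choice(attrs), rng.choice(codes))
            )
    return record, codes, attrs


class TestEvaluate:
    def test_leaf_descendant_or_self_is_singleton(self, demo_record):
        assert evaluate_ecl("<< 47693006", demo_record) == {"47693006"}

    def test_wildcard_self_cancellation(self, demo_record):
        assert evaluate_ecl("* MINUS *", demo_record) == set()

    def test_unknown_code_raises(self, demo_record):
        with pytest.raises(CodeNotFound):
            evaluate_ecl("<< 999999999", demo_record)
        with pytest.raises(CodeNotFound):
            evaluate_ecl("^ 999999999", demo_record)

    def test_matches_set_algebra_oracle_on_random_expressions(self):
        rng = random.Random(31)
        record, codes, attrs = attributed_record(rng)
        refsets = list(record.refsets)
        for _ in range(100):
            expr = random_expression(rng, codes, refsets, attrs)
            assert evaluate_ecl(expr, record) == _ecl_oracle(expr, record), \
                render_ecl(expr)

    def test_descendant_or_self_union_identity(self):
        rng = random.Random(37)
        record, codes, _ = attributed_record(rng, n=60)
        for c in codes:
            left = evaluate_ecl(f"<< {c}", record)
            right = evaluate_ecl(f"< {c}", record) | (
                {c} if record.concepts[c].active else set()
            )
            assert left == right

    def test_minus_and_partition(self):
        rng = random.Random(41)
        record, codes, attrs = attributed_record(rng, n=60)
        refsets = list(record.refsets)
        for _ in range(20):
            a = random_expression(rng, codes, refsets, attrs, depth=2)
            b = random_expression(rng, codes, refsets, attrs, depth=2)
            ea = evaluate_ecl(a, record)
            assert (evaluate_ecl(Minus(a, b), record)
                    | evaluate_ecl(And(a, b), record)) == ea
            assert evaluate_ecl(Minus(a, b), record).isdisjoint(
                evaluate_ecl(And(a, b), record))

    def test_empty_refinement_is_base(self):
        rng = random.Random(43)
        record, codes, _ = attributed_record(rng, n=40)
        base = FocusConcept(operator="descendantOrSelfOf", code=codes[0])
        assert evaluate_ecl(Refined(base, ()), record) == \
            evaluate_ecl(base, record)
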