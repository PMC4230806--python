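"""Boolean -> AND-NOT transform and steady-state projection."""

import itertools

import pytest

from bnsteady.core import (
    And,
    Const,
    Not,
    Or,
    SteadyStateSet,
    Var,
    eval_expr,
    expr_variables,
)
from bnsteady.errors import InternalConsistencyError
from bnsteady.io import parse_expression, parse_rules
from bnsteady.oracles import enumerate_exhaustive
from bnsteady.transform import (
    VariableMap,
    balance_fanin,
    boolean_to_andnot,
    expand_xor,
    fold_constants,
    project_steady_states,
    to_nnf,
)

from conftest import random_boolean_network, random_expression


def assert_equivalent(a, b, variables):
    for bits in itertools.product((0, 1), repeat=len(variables)):
        env = dict(zip(variables, bits))
        assert eval_expr(a, env) == eval_expr(b, env)


class TestNNF:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("!(x & y)", "!x | !y"),
            ("!!x", "x"),
            ("!(x2 | !x3)", "!x2 & x3"),
        ],
    )
    def test_de_morgan_cases(self, text, expected):
        got = to_nnf(parse_expression(text))
        want = parse_expression(expected)
        assert_equivalent(got, want, ("x", "y", "x2", "x3"))
        # structural check: no negation above a non-variable
        def no_inner_not(e):
            if isinstance(e, Not):
                return isinstance(e.child, Var)
            if isinstance(e, (And, Or)):
                return all(no_inner_not(c) for c in e.children)
            return True

        assert no_inner_not(got)

    def test_nested_same_operator_flattened(self):
        e = to_nnf(And((And((Var("a"), Var("b"))), Var("c"))))
        assert isinstance(e, And)
        assert all(not isinstance(c, And) for c in e.children)

    def test_nnf_preserves_truth_tables_randomized(self, rng):
        names = ("a", "b", "c", "d")
        for _ in range(300):
            e = expand_xor(random_expression(rng, names, depth=3))
            assert_equivalent(e, to_nnf(e), names)

    def test_xor_expansion(self):
        e = expand_xor(parse_expression("a ^ b"))
        want = parse_expression("(a & !b) | (!a & b)")
        assert_equivalent(e, want, ("a", "b"))

    def test_constant_folding_prevents_spurious_structure(self):
        e = fold_constants(parse_expression("(x & 0) | y | (z & 1)"))
        assert expr_variables(e) == {"y", "z"}

    def test_balance_fanin_bounds_width_and_preserves_meaning(self, rng):
        names = tuple(f"v{i}" for i in range(12))
        wide = Or(tuple(Var(v) for v in names))
        bal = balance_fanin(wide, limit=4)

        def max_fanin(e):
            if isinstance(e, (And, Or)):
                return max(
                    [len(e.children)] + [max_fanin(c) for c in e.children]
                )
            if isinstance(e, Not):
                return max_fanin(e.child)
            return 0

        assert max_fanin(bal) <= 4
        assert_equivalent(wide, bal, names)


class TestBooleanToAndNot:
    def test_worked_example_single_auxiliary(self, gated_or_network):
        """!x2 & (x3 | x4) becomes !x2 & !a with a = !x3 & !x4."""
        g, vmap = boolean_to_andnot(gated_or_network)
        assert vmap.n_original == 4
        assert len(vmap.aux_names) == 1
        aux = vmap.aux_names[0]
        assert g.functions[aux] == {"x3": -1, "x4": -1}
        assert g.functions["x1"] == {"x2": -1, aux: -1}

    def test_pure_or_becomes_negated_auxiliary(self):
        f = parse_rules("x1 = x2 | x3\nx2 = x2\nx3 = x3")
        g, vmap = boolean_to_andnot(f)
        aux = vmap.aux_names[0]
        assert g.functions["x1"] == {aux: -1}
        assert g.functions[aux] == {"x2": -1, "x3": -1}

    def test_already_andnot_introduces_no_auxiliaries(self):
        f = parse_rules("a = !b & c\nb = b\nc = c")
        g, vmap = boolean_to_andnot(f)
        assert vmap.aux_names == ()
        assert g.n == f.n

    def test_steady_state_bijection_randomized(self, rng):
        """|SS(g)| == |SS(f)| and projection recovers SS(f) exactly."""
        for _ in range(300):
            f = random_boolean_network(rng, rng.randint(1, 6), depth=2)
            g, vmap = boolean_to_andnot(f)
            if g.n > 18:  # rare deep nest: exhaustive scan too wide
                continue
            ss_f = {
                s
                for s in itertools.product((0, 1), repeat=f.n)
                if all(
                    eval_expr(f.functions[v], dict(zip(f.variables, s)))
                    == s[i]
                    for i, v in enumerate(f.variables)
                )
            }
            ss_g = enumerate_exhaustive(g)
            assert len(ss_g) == len(ss_f)
            projected = project_steady_states(ss_g, vmap)
            assert projected.states == frozenset(ss_f)


class TestProjection:
    def test_projection_example(self):
        f = parse_rules("x1 = x2 | x3\nx2 = x1\nx3 = x1")
        g, vmap = boolean_to_andnot(f)
        ss_g = enumerate_exhaustive(g)
        assert len(ss_g) == 2
        got = project_steady_states(ss_g, vmap)
        assert got.states == frozenset({(0, 0, 0), (1, 1, 1)})

    def test_empty_input_empty_output(self):
        vmap = VariableMap(2, ("a",), {"a": {}})
        empty = SteadyStateSet(("x", "y", "a"), set())
        assert len(project_steady_states(empty, vmap)) == 0

    def test_identity_when_no_auxiliaries(self):
        vmap = VariableMap(2)
        s = SteadyStateSet(("x", "y"), {(0, 1)})
        assert project_steady_states(s, vmap).states == s.states

    def test_non_injective_projection_is_a_loud_bug(self):
        vmap = VariableMap(1, ("a",), {"a": {}})
        s = SteadyStateSet(("x", "a"), {(0, 0), (0, 1)})
        with pytest.raises(InternalConsistencyError):
            project_steady_states(s, vmap)
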