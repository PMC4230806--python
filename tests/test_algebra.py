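"""GF(2) polynomial encoding, Groebner bases, and solution enumeration."""

import itertools

import pytest

from bnsteady.algebra import (
    Polynomial,
    PolynomialSystem,
    default_variable_order,
    enumerate_solutions,
    expr_to_polynomial,
    groebner_basis,
    steady_state_system,
)
from bnsteady.core import AndNotNetwork, eval_expr
from bnsteady.errors import CapExceededError
from bnsteady.io import parse_expression
from bnsteady.oracles import enumerate_exhaustive

from conftest import random_andnot_network, random_expression

x = Polynomial.variable
one = Polynomial.one()


def brute_solutions(sys: PolynomialSystem) -> set:
    return {
        bits
        for bits in itertools.product((0, 1), repeat=len(sys.variables))
        if all(
            p.evaluate(dict(zip(sys.variables, bits))) == 0
            for p in sys.equations
        )
    }


class TestDictionary:
    @pytest.mark.parametrize(
        "text, expected",
        [
            ("!x", "x + 1"),
            ("x | y", "x*y + x + y"),
            ("x & !y", "x*y + x"),
        ],
    )
    def test_translation_cases(self, text, expected):
        assert str(expr_to_polynomial(parse_expression(text))) == expected

    def test_polynomial_matches_boolean_on_random_expressions(self, rng):
        names = tuple(f"a{i}" for i in range(6))
        for _ in range(400):
            e = random_expression(rng, names, depth=3)
            p = expr_to_polynomial(e)
            for bits in itertools.product((0, 1), repeat=len(names)):
                env = dict(zip(names, bits))
                assert p.evaluate(env) == eval_expr(e, env)

    def test_square_free_and_mod_two_cancellation(self):
        # x & x -> x (exponent truncation); x ^ x -> 0 (mod-2 cancellation)
        assert str(expr_to_polynomial(parse_expression("x & x"))) == "x"
        assert expr_to_polynomial(parse_expression("x ^ x")).is_zero()


class TestSteadyStateSystem:
    def test_negation_self_loop_gives_inconsistent_constant(self):
        h = AndNotNetwork(("x1",), {"x1": {"x1": -1}})
        sys = steady_state_system(h)
        assert [str(p) for p in sys.equations] == ["1"]
        assert len(enumerate_solutions(sys)) == 0

    def test_identity_node_gives_zero_polynomial(self):
        h = AndNotNetwork(("x1",), {"x1": {"x1": 1}})
        sys = steady_state_system(h)
        assert sys.equations[0].is_zero()

    def test_mutual_inhibition_system_and_solutions(self):
        h = AndNotNetwork(
            ("x1", "x2"), {"x1": {"x2": -1}, "x2": {"x1": -1}}
        )
        sys = steady_state_system(h)
        assert [str(p) for p in sys.equations] == [
            "x1 + x2 + 1",
            "x1 + x2 + 1",
        ]
        assert enumerate_solutions(sys).states == frozenset(
            {(0, 1), (1, 0)}
        )


class TestGroebner:
    def test_linear_elimination(self):
        sys = PolynomialSystem(
            ("x1", "x2"), (x("x1") + x("x2"), x("x2") + one)
        )
        basis = groebner_basis(sys, order=("x1", "x2"))
        assert [str(p) for p in basis] == ["x1 + 1", "x2 + 1"]

    def test_inconsistent_system_reduces_to_one(self):
        sys = PolynomialSystem(("x1",), (one,))
        basis = groebner_basis(sys)
        assert len(basis) == 1 and basis[0].is_one()

    def test_single_equation_already_a_basis(self):
        p = x("x1") + x("x2") + one
        sys = PolynomialSystem(("x1", "x2"), (p, p))
        basis = groebner_basis(sys, order=("x1", "x2"))
        assert basis == [p]

    def test_basis_has_same_variety_randomized(self, rng):
        names = tuple(f"v{i}" for i in range(5))
        for _ in range(100):
            eqs = []
            for _ in range(rng.randint(1, 4)):
                monos = set()
                for _ in range(rng.randint(0, 4)):
                    m = frozenset(
                        rng.sample(names, rng.randint(0, len(names)))
                    )
                    monos ^= {m}
                eqs.append(Polynomial(frozenset(monos)))
            sys = PolynomialSystem(names, tuple(eqs))
            basis = groebner_basis(sys)
            basis_sys = PolynomialSystem(names, tuple(basis))
            want = brute_solutions(sys)
            assert brute_solutions(basis_sys) == want
            # reduced basis is {1} exactly when the variety is empty
            trivial = len(basis) == 1 and basis[0].is_one()
            assert trivial == (not want)


class TestEnumerateSolutions:
    def test_empty_equation_set_yields_full_cube(self):
        sys = PolynomialSystem(
            ("a", "b", "c"),
            (Polynomial.zero(),) * 3,
        )
        assert len(enumerate_solutions(sys)) == 8

    def test_solution_cap_raises_instead_of_truncating(self):
        sys = PolynomialSystem(
            tuple(f"v{i}" for i in range(10)),
            (Polynomial.zero(),),
        )
        with pytest.raises(CapExceededError):
            enumerate_solutions(sys, max_solutions=100)

    def test_solver_equals_exhaustive_scan_on_random_networks(self, rng):
        for _ in range(400):
            h = random_andnot_network(rng, rng.randint(1, 12))
            sys = steady_state_system(h)
            got = enumerate_solutions(sys)
            assert got.states == enumerate_exhaustive(h).states

    def test_solution_set_invariant_under_variable_order(self, rng):
        for _ in range(100):
            h = random_andnot_network(rng, rng.randint(2, 10))
            sys = steady_state_system(h)
            a = enumerate_solutions(sys)
            reversed_order = tuple(reversed(default_variable_order(sys)))
            b = enumerate_solutions(sys, order=reversed_order)
            assert a.states == b.states


class TestAgainstIndependentBackend:
    def test_variety_matches_sympy_over_gf2(self, rng):
        """Cross-check the Boolean-ring Groebner engine against sympy.

        sympy computes a lex basis over GF(2) with the field polynomials
        x_i^2 + x_i appended explicitly; both bases must cut out the same
        variety, and triviality (basis == {1}) must agree.
        """
        sympy = pytest.importorskip("sympy")
        names = ("a", "b", "c", "d")
        syms = sympy.symbols(names)
        by_name = dict(zip(names, syms))
        for _ in range(40):
            eqs = []
            for _ in range(rng.randint(1, 3)):
                monos = set()
                for _ in range(rng.randint(1, 4)):
                    m = frozenset(
                        rng.sample(names, rng.randint(0, len(names)))
                    )
                    monos ^= {m}
                eqs.append(Polynomial(frozenset(monos)))
            sys = PolynomialSystem(names, tuple(eqs))
            mine = groebner_basis(sys, order=names)
            mine_trivial = len(mine) == 1 and mine[0].is_one()

            sy_polys = []
            for p in eqs:
                expr = sympy.Integer(0)
                for m in p.monomials:
                    term = sympy.Integer(1)
                    for v in m:
                        term *= by_name[v]
                    expr += term
                sy_polys.append(expr)
            sy_polys += [s**2 + s for s in syms]
            gb = sympy.groebner(
                sy_polys, *syms, order="lex", modulus=2
            )
            sympy_trivial = list(gb.exprs) == [sympy.Integer(1)]
            assert mine_trivial == sympy_trivial
            if mine_trivial:
                continue
            # same GF(2) variety
            for bits in itertools.product((0, 1), repeat=len(names)):
                env = dict(zip(names, bits))
                mine_zero = all(p.evaluate(env) == 0 for p in mine)
                subs = dict(zip(syms, bits))
                sympy_zero = all(
                    int(g.subs(subs)) % 2 == 0 for g in gb.exprs
                )
                assert mine_zero == sympy_zero


class TestRingAxioms:
    """Property checks of the GF(2) polynomial arithmetic itself."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    names = ("p", "q", "r")
    monomial = st.frozensets(st.sampled_from(names), max_size=3)
    poly = st.builds(
        lambda ms: Polynomial(frozenset(ms)),
        st.frozensets(monomial, max_size=6),
    )

    @given(poly, poly)
    @settings(deadline=None, derandomize=True)
    def test_evaluation_is_a_ring_homomorphism(self, a, b):
        """(a+b)(x) = a(x) xor b(x) and (a*b)(x) = a(x) and b(x)."""
        for bits in itertools.product((0, 1), repeat=3):
            env = dict(zip(self.names, bits))
            assert (a + b).evaluate(env) == a.evaluate(env) ^ b.evaluate(env)
            assert (a * b).evaluate(env) == a.evaluate(env) & b.evaluate(env)

    @given(poly)
    @settings(deadline=None, derandomize=True)
    def test_characteristic_two_and_idempotence(self, a):
        assert (a + a).is_zero()
        for bits in itertools.product((0, 1), repeat=3):
            env = dict(zip(self.names, bits))
            assert (a * a).evaluate(env) == a.evaluate(env)
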