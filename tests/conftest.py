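"""Shared fixtures and corpus helpers for the test suite."""

from __future__ import annotations

import itertools
import random

import pytest

from bnsteady.core import (
    And,
    AndNotNetwork,
    BooleanNetwork,
    Const,
    Expr,
    Not,
    Or,
    Var,
    Xor,
)


def random_expression(
    rng: random.Random, variables: tuple[str, ...], depth: int = 3
) -> Expr:
    """A random Boolean expression over *variables* (may use any operator)."""
    if depth == 0 or rng.random() < 0.3:
        roll = rng.random()
        if roll < 0.1:
            return Const(rng.randint(0, 1))
        v = Var(rng.choice(variables))
        return Not(v) if roll < 0.4 else v
    op = rng.choice((And, Or, Xor, Not))
    if op is Not:
        return Not(random_expression(rng, variables, depth - 1))
    arity = rng.randint(2, 3)
    return op(
        tuple(random_expression(rng, variables, depth - 1) for _ in range(arity))
    )


def random_boolean_network(
    rng: random.Random, n: int, depth: int = 3
) -> BooleanNetwork:
    names = tuple(f"v{i}" for i in range(n))
    return BooleanNetwork(
        names, {v: random_expression(rng, names, depth) for v in names}
    )


def random_andnot_network(rng: random.Random, m: int) -> AndNotNetwork:
    """Random AND-NOT network: occasional constants, small conjunctions."""
    names = tuple(f"n{i}" for i in range(m))
    fns = {}
    for v in names:
        if rng.random() < 0.1:
            fns[v] = rng.randint(0, 1)
        else:
            regs = rng.sample(names, rng.randint(1, min(3, m)))
            fns[v] = {r: rng.choice((1, -1)) for r in regs}
    return AndNotNetwork(names, fns)


def truth_table(fn, n: int) -> tuple:
    """Truth table of a callable state->state over all 2^n inputs."""
    return tuple(
        fn(bits) for bits in itertools.product((0, 1), repeat=n)
    )


@pytest.fixture
def rng() -> random.Random:
    return random.Random(20140626)


@pytest.fixture
def gated_or_network():
    """The 4-node running example: f1 = !x2 & (x3 | x4), inputs self-looped."""
    from bnsteady.io import parse_rules

    return parse_rules(
        "x1 = !x2 & (x3 | x4)\nx2 = x1\nx3 = x3\nx4 = x4"
    )
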