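"""Core data model for Boolean and AND-NOT networks.

A Boolean network on variables ``x1..xn`` over ``K = {0, 1}`` assigns each
variable an update expression; synchronous application of all updates defines
a map ``f : K^n -> K^n``.  A *steady state* (fixed point) is a state with
``f(x) = x``.

An AND-NOT network is the special case in which every update function is a
conjunction of literals (a variable or its negation) or a constant.  Such a
network is fully determined by its *signed wiring diagram*: one activating
(``+``) or inhibiting (``-``) edge per signed regulator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from functools import reduce
from typing import Iterable, Iterator, Mapping, Union

from .errors import InputError, StructuralError

NAME_RE = re.compile(r"[A-Za-z_][A-Za-z0-9_]*\Z")

# ---------------------------------------------------------------------------
# Boolean expressions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Expr:
    """Base class of Boolean expression tree nodes."""

    __slots__ = ()


@dataclass(frozen=True)
class Var(Expr):
    __slots__ = ("name",)
    name: str


@dataclass(frozen=True)
class Const(Expr):
    __slots__ = ("value",)
    value: int

    def __post_init__(self) -> None:
        if self.value not in (0, 1):
            raise InputError(f"constant must be 0 or 1, got {self.value!r}")


@dataclass(frozen=True)
class Not(Expr):
    __slots__ = ("child",)
    child: Expr


@dataclass(frozen=True)
class _Nary(Expr):
    __slots__ = ("children",)
    children: tuple[Expr, ...]

    def __post_init__(self) -> None:
        if len(self.children) < 2:
            raise InputError(
                f"{type(self).__name__} requires at least 2 operands"
            )


@dataclass(frozen=True)
class And(_Nary):
    __slots__ = ()


@dataclass(frozen=True)
class Or(_Nary):
    __slots__ = ()


@dataclass(frozen=True)
class Xor(_Nary):
    __slots__ = ()


TRUE = Const(1)
FALSE = Const(0)


def expr_variables(e: Expr) -> set[str]:
    """Set of variable names syntactically referenced by *e*."""
    out: set[str] = set()
    stack = [e]
    while stack:
        node = stack.pop()
        if isinstance(node, Var):
            out.add(node.name)
        elif isinstance(node, Not):
            stack.append(node.child)
        elif isinstance(node, _Nary):
            stack.extend(node.children)
    return out


def eval_expr(e: Expr, env: Mapping[str, object]):
    """Evaluate *e* under an assignment of variables to 0/1 values.

    Values may be Python ints or numpy integer arrays; logic is expressed
    with ``&``, ``|``, ``^`` so a single code path covers the scalar case and
    the vectorized whole-state-space scans used by the oracles.
    """
    if isinstance(e, Var):
        try:
            return env[e.name]
        except KeyError:
            raise StructuralError(f"undeclared variable {e.name!r}") from None
    if isinstance(e, Const):
        return e.value
    if isinstance(e, Not):
        return eval_expr(e.child, env) ^ 1
    vals = (eval_expr(c, env) for c in e.children)
    if isinstance(e, And):
        return reduce(lambda a, b: a & b, vals)
    if isinstance(e, Or):
        return reduce(lambda a, b: a | b, vals)
    if isinstance(e, Xor):
        return reduce(lambda a, b: a ^ b, vals)
    raise TypeError(f"not an expression: {e!r}")


# ---------------------------------------------------------------------------
# Networks
# ---------------------------------------------------------------------------

State = tuple[int, ...]

#: sign of a regulator: +1 activating, -1 inhibiting
Sign = int

#: AND-NOT update function: either a constant bit or a mapping
#: ``source variable -> sign`` (the conjunction of the signed literals).
AndNotFunction = Union[int, dict[str, Sign]]


def _check_names(variables: Iterable[str]) -> tuple[str, ...]:
    names = tuple(variables)
    if not names:
        raise InputError("a network needs at least one variable")
    seen: set[str] = set()
    for v in names:
        if not NAME_RE.match(v):
            raise InputError(f"invalid variable name {v!r}")
        if v in seen:
            raise InputError(f"duplicate variable {v!r}")
        seen.add(v)
    return names


@dataclass(frozen=True)
class BooleanNetwork:
    """Ordered variables plus one Boolean update expression per variable."""

    variables: tuple[str, ...]
    functions: dict[str, Expr]

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", _check_names(self.variables))
        declared = set(self.variables)
        if set(self.functions) != declared:
            missing = declared - set(self.functions)
            extra = set(self.functions) - declared
            raise StructuralError(
                f"functions do not match variables (missing={sorted(missing)},"
                f" extra={sorted(extra)})"
            )
        for v in self.variables:
            undeclared = expr_variables(self.functions[v]) - declared
            if undeclared:
                raise StructuralError(
                    f"function of {v!r} references undeclared "
                    f"{sorted(undeclared)}"
                )

    @property
    def n(self) -> int:
        return len(self.variables)


def conjunction(literals: Iterable[tuple[str, Sign]]) -> AndNotFunction:
    """Normalize signed literals into an AND-NOT function.

    An empty conjunction is the constant 1; a source appearing with both
    signs makes the whole conjunction identically 0.
    """
    out: dict[str, Sign] = {}
    for src, sign in literals:
        if sign not in (1, -1):
            raise InputError(f"sign must be +1/-1, got {sign!r}")
        if out.get(src, sign) != sign:
            return 0
        out[src] = sign
    return out if out else 1


@dataclass(frozen=True)
class AndNotNetwork:
    """Network whose every update is a conjunction of literals or a constant.

    ``functions[v]`` is either ``0``/``1`` or a dict ``source -> sign``; the
    node's value is the AND over regulators of (source value if sign ``+1``,
    its complement if ``-1``).
    """

    variables: tuple[str, ...]
    functions: dict[str, AndNotFunction]

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", _check_names(self.variables))
        declared = set(self.variables)
        if set(self.functions) != declared:
            raise StructuralError("functions do not match variables")
        for v, fn in self.functions.items():
            if isinstance(fn, int):
                if fn not in (0, 1):
                    raise StructuralError(f"bad constant for {v!r}: {fn!r}")
                continue
            if not fn:
                raise StructuralError(
                    f"empty conjunction for {v!r}; use the constant 1"
                )
            for src, sign in fn.items():
                if src not in declared:
                    raise StructuralError(
                        f"function of {v!r} references undeclared {src!r}"
                    )
                if sign not in (1, -1):
                    raise StructuralError(f"bad sign for {src!r}->{v!r}")

    @property
    def n(self) -> int:
        return len(self.variables)

    def regulators(self, v: str) -> dict[str, Sign]:
        fn = self.functions[v]
        return dict(fn) if isinstance(fn, dict) else {}


Network = Union[BooleanNetwork, AndNotNetwork]


def eval_andnot_function(fn: AndNotFunction, env: Mapping[str, object]):
    if isinstance(fn, int):
        return fn
    return reduce(
        lambda a, b: a & b,
        (env[s] if sign > 0 else env[s] ^ 1 for s, sign in fn.items()),
    )


def _env_of(network: Network, state: State) -> dict[str, object]:
    if len(state) != network.n:
        raise InputError(
            f"state length {len(state)} != network size {network.n}"
        )
    if any(b not in (0, 1) for b in state):
        raise InputError("state entries must be 0 or 1")
    return dict(zip(network.variables, state))


def evaluate(network: Network, state: State) -> State:
    """Synchronously apply every update function: returns f(x)."""
    env = _env_of(network, state)
    if isinstance(network, BooleanNetwork):
        return tuple(
            eval_expr(network.functions[v], env) for v in network.variables
        )
    return tuple(
        eval_andnot_function(network.functions[v], env)
        for v in network.variables
    )


def is_steady_state(network: Network, state: State) -> bool:
    """True iff *state* is a fixed point: f(x) == x."""
    return evaluate(network, state) == tuple(state)


# ---------------------------------------------------------------------------
# Steady-state sets and wiring diagrams
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SteadyStateSet:
    """A set of states together with the variable order they refer to."""

    variables: tuple[str, ...]
    states: frozenset[State]

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "states", frozenset(self.states))
        n = len(self.variables)
        for s in self.states:
            if len(s) != n:
                raise InputError(
                    f"state {s} has wrong length for {n} variables"
                )

    def __len__(self) -> int:
        return len(self.states)

    def __iter__(self) -> Iterator[State]:
        return iter(self.sorted_states())

    def __contains__(self, state: State) -> bool:
        return tuple(state) in self.states

    def sorted_states(self) -> list[State]:
        """States sorted as binary integers (leftmost variable = high bit)."""
        return sorted(self.states, key=lambda s: s)

    def bitstrings(self) -> list[str]:
        return ["".join(str(b) for b in s) for s in self.sorted_states()]


@dataclass(frozen=True)
class SignedDigraph:
    """Signed directed graph: the wiring diagram of an AND-NOT network."""

    nodes: tuple[str, ...]
    edges: frozenset[tuple[str, str, Sign]] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        object.__setattr__(self, "edges", frozenset(self.edges))
        declared = set(self.nodes)
        for src, tgt, sign in self.edges:
            if src not in declared or tgt not in declared:
                raise StructuralError(f"edge {src}->{tgt} uses unknown node")
            if sign not in (1, -1):
                raise StructuralError(f"bad sign on edge {src}->{tgt}")

    def sorted_edges(self) -> list[tuple[str, str, Sign]]:
        return sorted(self.edges)


def wiring_diagram(network: AndNotNetwork) -> SignedDigraph:
    """One signed edge per signed regulator; constant nodes have in-degree 0."""
    edges = {
        (src, tgt, sign)
        for tgt in network.variables
        for src, sign in network.regulators(tgt).items()
    }
    return SignedDigraph(network.variables, frozenset(edges))
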