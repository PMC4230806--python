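"""Conversion of arbitrary Boolean networks to AND-NOT form, and back.

Any Boolean network ``f`` on ``n`` variables can be rewritten, by introducing
auxiliary variables, as an AND-NOT network ``g`` on ``m >= n`` variables whose
steady states project bijectively onto the steady states of ``f`` via
truncation to the first ``n`` coordinates.  The rewrite is structural:

* a literal stays a literal;
* an AND becomes the conjunction of the literals of its operands, each
  non-literal operand first receiving an auxiliary node;
* an OR of operands ``e1..ek`` becomes ``!a`` where the auxiliary ``a`` is
  defined by De Morgan as the conjunction of the negated operand literals.

XOR is expanded to AND/OR/NOT and constants are folded before conversion, so
no spurious auxiliaries are introduced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .core import (
    And,
    AndNotNetwork,
    BooleanNetwork,
    Const,
    Expr,
    Not,
    Or,
    SteadyStateSet,
    Var,
    Xor,
    conjunction,
)
from .errors import InputError, InternalConsistencyError

# ---------------------------------------------------------------------------
# Expression rewrites
# ---------------------------------------------------------------------------


def expand_xor(e: Expr) -> Expr:
    """Rewrite every XOR as AND/OR/NOT: a ^ b -> (a & !b) | (!a & b)."""
    if isinstance(e, Not):
        return Not(expand_xor(e.child))
    if isinstance(e, (And, Or)):
        return type(e)(tuple(expand_xor(c) for c in e.children))
    if isinstance(e, Xor):
        out = expand_xor(e.children[0])
        for raw in e.children[1:]:
            nxt = expand_xor(raw)
            out = Or((And((out, Not(nxt))), And((Not(out), nxt))))
        return out
    return e


def fold_constants(e: Expr) -> Expr:
    """Propagate 0/1 subexpressions (x & 0 -> 0, x | 0 -> x, !1 -> 0, ...)."""
    if isinstance(e, Not):
        c = fold_constants(e.child)
        if isinstance(c, Const):
            return Const(c.value ^ 1)
        if isinstance(c, Not):
            return c.child
        return Not(c)
    if isinstance(e, (And, Or)):
        absorbing = 0 if isinstance(e, And) else 1
        kept: list[Expr] = []
        for raw in e.children:
            c = fold_constants(raw)
            if isinstance(c, Const):
                if c.value == absorbing:
                    return Const(absorbing)
                continue  # neutral element: drop
            kept.append(c)
        if not kept:
            return Const(absorbing ^ 1)
        if len(kept) == 1:
            return kept[0]
        return type(e)(tuple(kept))
    if isinstance(e, Xor):
        parity = 0
        kept = []
        for raw in e.children:
            c = fold_constants(raw)
            if isinstance(c, Const):
                parity ^= c.value
            else:
                kept.append(c)
        if not kept:
            return Const(parity)
        if len(kept) == 1:
            return Not(kept[0]) if parity else kept[0]
        expr: Expr = Xor(tuple(kept))
        return Not(expr) if parity else expr
    return e


def to_nnf(e: Expr) -> Expr:
    """Negation normal form: negations pushed onto variables, AND/OR flattened.

    XOR must already be expanded (see :func:`expand_xor`); constants should
    be folded first to keep the result clean, although ``!0``/``!1`` are
    handled.
    """
    def push(node: Expr, negate: bool) -> Expr:
        if isinstance(node, Xor):
            return push(expand_xor(node), negate)
        if isinstance(node, Const):
            return Const(node.value ^ 1) if negate else node
        if isinstance(node, Var):
            return Not(node) if negate else node
        if isinstance(node, Not):
            return push(node.child, not negate)
        # And/Or: De Morgan under negation, then flatten
        cls = type(node)
        if negate:
            cls = Or if cls is And else And
        parts: list[Expr] = []
        for child in node.children:
            sub = push(child, negate)
            if isinstance(sub, cls):
                parts.extend(sub.children)
            else:
                parts.append(sub)
        return parts[0] if len(parts) == 1 else cls(tuple(parts))

    return push(e, False)


FANIN_MAX = 8  # wide AND/OR gates are split into layers of this fan-in so
# the downstream polynomial encoding of any single conjunction stays small


def balance_fanin(e: Expr, limit: int = FANIN_MAX) -> Expr:
    """Rewrite wide AND/OR gates as layered gates of bounded fan-in."""
    if isinstance(e, Not):
        return Not(balance_fanin(e.child, limit))
    if isinstance(e, (And, Or)):
        children = tuple(balance_fanin(c, limit) for c in e.children)
        cls = type(e)
        while len(children) > limit:
            children = tuple(
                chunk[0] if len(chunk) == 1 else cls(chunk)
                for chunk in (
                    children[i : i + limit]
                    for i in range(0, len(children), limit)
                )
            )
        return children[0] if len(children) == 1 else cls(children)
    return e


# ---------------------------------------------------------------------------
# Boolean -> AND-NOT
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class VariableMap:
    """Bookkeeping for the transform: original count and auxiliary nodes."""

    n_original: int
    aux_names: tuple[str, ...] = ()
    aux_definitions: dict[str, object] = field(default_factory=dict)

    @property
    def m(self) -> int:
        return self.n_original + len(self.aux_names)


class _Converter:
    def __init__(self, variables: tuple[str, ...]):
        self.taken = set(variables)
        self.aux_names: list[str] = []
        self.aux_defs: dict[str, object] = {}
        self._memo: dict[frozenset, str] = {}
        self._counter = 0

    def _new_aux(self, conj: dict) -> str:
        key = frozenset(conj.items())
        hit = self._memo.get(key)
        if hit is not None:
            return hit
        while True:
            self._counter += 1
            name = f"_aux{self._counter}"
            if name not in self.taken:
                break
        self.taken.add(name)
        self.aux_names.append(name)
        self.aux_defs[name] = dict(conj)
        self._memo[key] = name
        return name

    def literal_of(self, e: Expr):
        """Literal ``(name, sign)`` for an NNF expression, or an int constant."""
        if isinstance(e, Const):
            return e.value
        if isinstance(e, Var):
            return (e.name, 1)
        if isinstance(e, Not):
            assert isinstance(e.child, Var), "not in NNF"
            return (e.child.name, -1)
        if isinstance(e, And):
            fn = self.convert(e)
            if isinstance(fn, int):
                return fn
            return (self._new_aux(fn), 1)
        if isinstance(e, Or):
            # e = !(AND of negated operands); reuse the AND machinery
            lits = []
            for part in e.children:
                lit = self.literal_of(part)
                if isinstance(lit, int):
                    if lit == 1:
                        return 1  # OR with a true operand
                    continue  # false operand: drop
                lits.append((lit[0], -lit[1]))
            fn = conjunction(lits)
            if isinstance(fn, int):
                return fn ^ 1
            return (self._new_aux(fn), -1)
        raise InternalConsistencyError(f"unexpected node in NNF: {e!r}")

    def convert(self, e: Expr):
        """AND-NOT function (constant or conjunction dict) for NNF expr *e*."""
        if isinstance(e, And):
            lits = []
            for part in e.children:
                lit = self.literal_of(part)
                if isinstance(lit, int):
                    if lit == 0:
                        return 0
                    continue
                lits.append(lit)
            return conjunction(lits)
        lit = self.literal_of(e)
        if isinstance(lit, int):
            return lit
        return conjunction([lit])


def boolean_to_andnot(f: BooleanNetwork) -> tuple[AndNotNetwork, VariableMap]:
    """Transform *f* into an AND-NOT network ``g`` with the same steady states.

    The original variables occupy the first ``n`` coordinates of ``g``;
    auxiliary nodes (``_aux1``, ``_aux2``, ... in a deterministic
    left-to-right, node-order traversal) follow.  The steady states of *f*
    are exactly the projections of those of ``g`` to the first ``n``
    coordinates, bijectively.
    """
    conv = _Converter(f.variables)
    functions: dict[str, object] = {}
    for v in f.variables:
        nnf = balance_fanin(to_nnf(fold_constants(expand_xor(f.functions[v]))))
        functions[v] = conv.convert(nnf)
    for aux in conv.aux_names:
        functions[aux] = conv.aux_defs[aux]
    g = AndNotNetwork(tuple(f.variables) + tuple(conv.aux_names), functions)
    vmap = VariableMap(f.n, tuple(conv.aux_names), dict(conv.aux_defs))
    return g, vmap


def project_steady_states(
    states_g: SteadyStateSet, map: VariableMap
) -> SteadyStateSet:
    """Truncate each steady state of ``g`` to the first ``n`` coordinates.

    On genuine steady states the projection is injective; a collision
    therefore signals a transform bug and raises
    :class:`InternalConsistencyError`.
    """
    n = map.n_original
    if len(states_g.variables) != map.m:
        raise InputError(
            f"states over {len(states_g.variables)} variables, expected {map.m}"
        )
    projected = {s[:n] for s in states_g.states}
    if len(projected) != len(states_g.states):
        raise InternalConsistencyError(
            "projection of steady states is not injective"
        )
    return SteadyStateSet(states_g.variables[:n], frozenset(projected))
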