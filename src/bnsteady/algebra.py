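"""Square-free polynomial algebra over GF(2) and the fixed-point solver.

Every Boolean function has a unique square-free polynomial form over the
two-element field via the dictionary ``x AND y <-> x*y``,
``x OR y <-> x + y + x*y``, ``NOT x <-> x + 1``.  Fixed points of an AND-NOT
network ``h`` are exactly the GF(2) solutions of the system
``p_i := h_i + x_i = 0``.

The solver computes a reduced lexicographic Groebner basis with Buchberger's
algorithm directly in the Boolean quotient ring (exponents truncated to 1,
so the field relations ``x^2 = x`` are implicit; the pair queue includes the
S-polynomials against those relations, one per variable dividing a leading
term) and then enumerates the GF(2) roots by back-substitution: variables
are assigned from the lowest to the highest in the elimination order,
branching where the triangular basis leaves a value unconstrained.  The
ideal contains 1 (reduced basis ``{1}``) exactly when there is no solution.

Internally monomials are integer bitmasks with the lex-greatest variable in
the most significant bit, so integer comparison *is* the lexicographic term
order; a polynomial is a set of masks and addition is symmetric difference.
"""

from __future__ import annotations

import heapq
import time
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .core import (
    And,
    AndNotNetwork,
    Const,
    Expr,
    Not,
    Or,
    SteadyStateSet,
    Var,
    Xor,
)
from .errors import (
    CapExceededError,
    InputError,
    InternalConsistencyError,
    SolveTimeoutError,
)

DEFAULT_MAX_SOLUTIONS = 65536
_EXPANSION_CAP = 1 << 20  # monomials per polynomial during products

# ---------------------------------------------------------------------------
# Public polynomial containers
# ---------------------------------------------------------------------------

Monomial = frozenset  # of variable names; frozenset() is the constant 1


@dataclass(frozen=True)
class Polynomial:
    """Sum (mod 2) of square-free monomials; the zero polynomial is empty."""

    monomials: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "monomials", frozenset(frozenset(m) for m in self.monomials)
        )

    # -- constructors -------------------------------------------------
    @classmethod
    def zero(cls) -> "Polynomial":
        return cls(frozenset())

    @classmethod
    def one(cls) -> "Polynomial":
        return cls(frozenset({frozenset()}))

    @classmethod
    def constant(cls, value: int) -> "Polynomial":
        return cls.one() if value & 1 else cls.zero()

    @classmethod
    def variable(cls, name: str) -> "Polynomial":
        return cls(frozenset({frozenset({name})}))

    # -- ring operations ----------------------------------------------
    def __add__(self, other: "Polynomial") -> "Polynomial":
        return Polynomial(self.monomials ^ other.monomials)

    def __mul__(self, other: "Polynomial") -> "Polynomial":
        acc: set = set()
        for a in self.monomials:
            for b in other.monomials:
                m = a | b  # square-free: x*x = x
                if m in acc:
                    acc.discard(m)
                else:
                    acc.add(m)
            if len(acc) > _EXPANSION_CAP:
                raise CapExceededError("polynomial expansion too large")
        return Polynomial(frozenset(acc))

    # -- queries -------------------------------------------------------
    def is_zero(self) -> bool:
        return not self.monomials

    def is_one(self) -> bool:
        return self.monomials == frozenset({frozenset()})

    def variables(self) -> set[str]:
        out: set[str] = set()
        for m in self.monomials:
            out |= m
        return out

    def evaluate(self, env: Mapping[str, int]) -> int:
        total = 0
        for m in self.monomials:
            total ^= 1 if all(env[v] for v in m) else 0
        return total

    def __str__(self) -> str:
        if not self.monomials:
            return "0"
        keys = sorted(
            self.monomials, key=lambda m: (-len(m), sorted(m))
        )
        return " + ".join("*".join(sorted(m)) if m else "1" for m in keys)


@dataclass(frozen=True)
class PolynomialSystem:
    """Equations ``p = 0`` over an ordered variable sequence."""

    variables: tuple[str, ...]
    equations: tuple[Polynomial, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "variables", tuple(self.variables))
        object.__setattr__(self, "equations", tuple(self.equations))
        declared = set(self.variables)
        for p in self.equations:
            stray = p.variables() - declared
            if stray:
                raise InputError(f"undeclared variables in system: {stray}")


# ---------------------------------------------------------------------------
# Boolean expression / network -> polynomial
# ---------------------------------------------------------------------------


def expr_to_polynomial(e: Expr) -> Polynomial:
    """Apply the Boolean/polynomial dictionary recursively."""
    if isinstance(e, Var):
        return Polynomial.variable(e.name)
    if isinstance(e, Const):
        return Polynomial.constant(e.value)
    if isinstance(e, Not):
        return expr_to_polynomial(e.child) + Polynomial.one()
    parts = [expr_to_polynomial(c) for c in e.children]
    if isinstance(e, And):
        out = parts[0]
        for p in parts[1:]:
            out = out * p
        return out
    if isinstance(e, Or):
        out = parts[0]
        for p in parts[1:]:
            out = out + p + out * p
        return out
    if isinstance(e, Xor):
        out = parts[0]
        for p in parts[1:]:
            out = out + p
        return out
    raise TypeError(f"not an expression: {e!r}")


def _conjunction_poly(fn) -> Polynomial:
    if isinstance(fn, int):
        return Polynomial.constant(fn)
    out = Polynomial.one()
    for src, sign in fn.items():
        lit = Polynomial.variable(src)
        if sign < 0:
            lit = lit + Polynomial.one()
        out = out * lit
    return out


def steady_state_system(h: AndNotNetwork) -> PolynomialSystem:
    """One equation ``h_i + x_i = 0`` per node (addition is mod 2)."""
    eqs = tuple(
        _conjunction_poly(h.functions[v]) + Polynomial.variable(v)
        for v in h.variables
    )
    return PolynomialSystem(h.variables, eqs)


# ---------------------------------------------------------------------------
# Mask-level arithmetic (lex order == integer order on masks)
# ---------------------------------------------------------------------------


def _to_masks(p: Polynomial, bit: Mapping[str, int]) -> frozenset:
    out: set[int] = set()
    for m in p.monomials:
        mask = 0
        for v in m:
            mask |= bit[v]
        out ^= {mask}
    return frozenset(out)


def _from_masks(masks: Iterable[int], names: Sequence[str], L: int):
    monos = []
    for mask in masks:
        monos.append(
            frozenset(names[r] for r in range(L) if mask & (1 << (L - 1 - r)))
        )
    return Polynomial(frozenset(monos))


def _normal_form(p: set, basis: list, lms: list, deadline=None) -> set:
    """Full multivariate division remainder of *p* by *basis* (mask level)."""
    work = set(p)
    remainder: set[int] = set()
    while work:
        if deadline is not None and time.monotonic() > deadline:
            raise SolveTimeoutError("Groebner reduction timed out")
        m = max(work)
        for lm, g in zip(lms, basis):
            if lm | m == m:  # lm divides m
                c = m & ~lm
                for mono in g:
                    work ^= {mono | c}
                break
        else:
            work.discard(m)
            remainder.add(m)
    return remainder


def _groebner_masks(
    polys: list, deadline=None
) -> list:
    """Reduced Groebner basis in the Boolean quotient ring, masks in, masks out."""
    G: list[frozenset] = []
    lms: list[int] = []
    pairs: list[tuple[int, tuple]] = []  # (lcm, spec)

    def add_poly(p: frozenset) -> None:
        lm = max(p)
        i = len(G)
        G.append(p)
        lms.append(lm)
        for j in range(i):
            if lms[j] & lm == 0:
                continue  # product criterion: coprime leads
            heapq.heappush(pairs, (lms[j] | lm, ("pp", j, i)))
        b = 1
        while b <= lm:
            if lm & b:
                heapq.heappush(pairs, (lm, ("fp", i, b)))
            b <<= 1

    seen = set()
    for p in sorted((frozenset(q) for q in polys if q), key=sorted):
        if p not in seen:
            seen.add(p)
            add_poly(p)
    if not G:
        return []

    while pairs:
        if deadline is not None and time.monotonic() > deadline:
            raise SolveTimeoutError("Groebner basis computation timed out")
        _, spec = heapq.heappop(pairs)  # normal selection: smallest lcm first
        s: set[int] = set()
        if spec[0] == "pp":
            _, i, j = spec
            L = lms[i] | lms[j]
            ci, cj = L & ~lms[i], L & ~lms[j]
            for mono in G[i]:
                s ^= {mono | ci}
            for mono in G[j]:
                s ^= {mono | cj}
        else:
            # S-polynomial against the field relation v^2 + v:
            # for f = lm + tail, it is v*tail + lm (computed square-free).
            _, i, vbit = spec
            lm = lms[i]
            for mono in G[i]:
                if mono != lm:
                    s ^= {mono | vbit}
            s ^= {lm}
        r = _normal_form(s, G, lms, deadline)
        if r:
            if r == {0}:
                return [frozenset({0})]  # ideal contains 1
            add_poly(frozenset(r))

    # inter-reduce to the unique reduced basis
    changed = True
    basis = [set(g) for g in G]
    while changed:
        changed = False
        for i in range(len(basis)):
            if not basis[i]:
                continue
            others = [frozenset(b) for k, b in enumerate(basis) if k != i and b]
            olms = [max(b) for b in others]
            r = _normal_form(set(basis[i]), others, olms, deadline)
            if r != basis[i]:
                basis[i] = r
                changed = True
    out = [frozenset(b) for b in basis if b]
    if frozenset({0}) in out:
        return [frozenset({0})]
    out.sort(key=max, reverse=True)
    return out


# ---------------------------------------------------------------------------
# Public Groebner / solver API
# ---------------------------------------------------------------------------


def default_variable_order(sys: PolynomialSystem) -> tuple[str, ...]:
    """Elimination order: rarest variables first, ties by declaration index.

    A variable's weight is the number of monomials of the system containing
    it; putting rare variables first (lex-greatest) empirically keeps
    intermediate bases small.
    """
    count = {v: 0 for v in sys.variables}
    for p in sys.equations:
        for m in p.monomials:
            for v in m:
                count[v] += 1
    index = {v: i for i, v in enumerate(sys.variables)}
    return tuple(sorted(sys.variables, key=lambda v: (count[v], index[v])))


def groebner_basis(
    sys: PolynomialSystem,
    order: Sequence[str] | None = None,
    deadline: float | None = None,
) -> list[Polynomial]:
    """Reduced lex Groebner basis of the system in the Boolean quotient ring.

    *order* lists the variables from lex-greatest to lex-least; by default
    :func:`default_variable_order` is used.  The basis is ``[1]`` iff the
    system has no GF(2) solutions.
    """
    names = tuple(order) if order is not None else default_variable_order(sys)
    if set(names) != set(sys.variables):
        raise InputError("order must be a permutation of the system variables")
    L = len(names)
    bit = {v: 1 << (L - 1 - r) for r, v in enumerate(names)}
    masks = [_to_masks(p, bit) for p in sys.equations]
    basis = _groebner_masks([m for m in masks if m], deadline)
    return [_from_masks(g, names, L) for g in basis]


def _substitute(p: frozenset, vbit: int, value: int) -> frozenset:
    if value == 0:
        return frozenset(m for m in p if not m & vbit)
    out: set[int] = set()
    for m in p:
        out ^= {m & ~vbit}
    return frozenset(out)


def _solve_component(
    basis: list,
    ranks: Sequence[int],
    L: int,
    cap: int,
    deadline,
) -> list[dict[int, int]]:
    """All GF(2) roots of a (mask-level) Groebner basis; maps rank -> bit.

    Back-substitution over the triangular lex basis: variables are handled
    from the lex-least upward; polynomials reduced to a unit clause force a
    value, otherwise the variable is branched.  Every polynomial produced
    lies in the ideal of the original equations, so pruning on a nonzero
    constant never discards a true solution and the enumeration is exact.
    """
    bits = [1 << (L - 1 - r) for r in range(L)]
    rank_of_bit = {bits[r]: r for r in range(L)}
    ranks_set = set(ranks)
    sols: list[dict[int, int]] = []

    def propagate(polys, assign):
        """Apply forced unit clauses (p == x or p == x + 1) to a fixpoint."""
        polys = [p for p in polys if p]
        while True:
            forced = None
            for p in polys:
                if p == frozenset({0}):
                    return None  # contradiction: 1 = 0
                nonconst = [m for m in p if m]
                if len(p) <= 2 and len(nonconst) == 1:
                    m = nonconst[0]
                    if m & (m - 1) == 0:  # single-variable monomial
                        forced = (m, 1 if 0 in p else 0)
                        break
            if forced is None:
                return polys
            m, val = forced
            assign[rank_of_bit[m]] = val
            polys = [q for q in (_substitute(p, m, val) for p in polys) if q]

    def rec(polys, assign):
        if deadline is not None and time.monotonic() > deadline:
            raise SolveTimeoutError("solution enumeration timed out")
        polys = propagate(polys, assign)
        if polys is None:
            return
        # next unassigned variable, lex-least (highest rank) first
        rank = None
        for r in sorted(ranks_set, reverse=True):
            if r not in assign:
                rank = r
                break
        if rank is None:
            if len(sols) >= cap:
                raise CapExceededError(
                    f"more than {cap} solutions; raise max_solutions"
                )
            sols.append(dict(assign))
            return
        for value in (0, 1):
            sub = [_substitute(p, bits[rank], value) for p in polys]
            rec(sub, {**assign, rank: value})

    rec(list(basis), {})
    return sols


def _eval_mask_poly(p: frozenset, ones: int) -> int:
    total = 0
    for m in p:
        if m & ones == m:
            total ^= 1
    return total


def _bits_of(mask: int) -> list[int]:
    out = []
    while mask:
        b = mask & -mask
        out.append(b)
        mask ^= b
    return out


GB_COMPONENT_LIMIT = 26  # components up to this many variables go straight
# to the Groebner engine; larger ones are first split by branching
_ELIM_Q_MAX = 1024  # max monomials in a definition used for elimination
_ELIM_GROWTH_MAX = 8192  # max predicted monomials in a substituted equation
GB_DENSITY_LIMIT = 600  # max total monomials for the direct Groebner path


class _MaskSolver:
    """Exact divide-and-conquer enumeration over mask-level equations.

    Unit clauses are propagated, the constraint graph is split into
    connected components, small components are solved exactly by a reduced
    lex Groebner basis with back-substitution, and oversized components are
    split further by branching on the variable occurring in the most
    monomials (both branches are explored, so the enumeration stays exact).
    Variables not constrained by any equation are free and double the
    solution count.
    """

    def __init__(self, L: int, cap: int, deadline):
        self.L = L
        self.cap = cap
        self.deadline = deadline
        self.bits = [1 << (L - 1 - r) for r in range(L)]
        self.rank_of_bit = {self.bits[r]: r for r in range(L)}

    def solve(self, eqs: list, var_bits: int) -> list[dict[int, int]]:
        """All assignments of the variables in *var_bits* satisfying *eqs*."""
        if self.deadline is not None and time.monotonic() > self.deadline:
            raise SolveTimeoutError("solution enumeration timed out")

        # unit propagation
        assign: dict[int, int] = {}
        polys = [p for p in eqs if p]
        while True:
            forced = None
            for p in polys:
                if p == frozenset({0}):
                    return []
                nonconst = [m for m in p if m]
                if len(p) <= 2 and len(nonconst) == 1 and (
                    nonconst[0] & (nonconst[0] - 1)
                ) == 0:
                    forced = (nonconst[0], 1 if 0 in p else 0)
                    break
            if forced is None:
                break
            m, val = forced
            assign[self.rank_of_bit[m]] = val
            polys = [
                q for q in (_substitute(p, m, val) for p in polys) if q
            ]

        # linear elimination (generalized Gaussian elimination): an equation
        # x + q = 0 whose variable x divides no other monomial determines
        # x = q exactly; substitute q for x everywhere, drop the equation,
        # and record the definition for back-substitution.  Definitions and
        # substituted equations are size-guarded so chains cannot blow up.
        eliminated: list[tuple[int, frozenset]] = []
        while True:
            if any(p == frozenset({0}) for p in polys):
                return []
            candidates = []
            for i, p in enumerate(polys):
                for m in p:
                    if m and (m & (m - 1)) == 0 and not any(
                        o != m and o & m for o in p
                    ):
                        if len(p) - 1 <= _ELIM_Q_MAX:
                            candidates.append((len(p) - 1, i, m))
            candidates.sort()
            chosen = None
            for qsize, i, vbit in candidates:
                q = frozenset(m for m in polys[i] if m != vbit)
                growth_ok = all(
                    j == i
                    or len(t) + sum(1 for m in t if m & vbit) * max(qsize, 1)
                    <= _ELIM_GROWTH_MAX
                    for j, t in enumerate(polys)
                )
                if growth_ok:
                    chosen = (i, vbit, q)
                    break
            if chosen is None:
                break
            i, vbit, q = chosen
            new_polys = []
            for j, t in enumerate(polys):
                if j == i:
                    continue
                if not any(m & vbit for m in t):
                    new_polys.append(t)
                    continue
                acc: set[int] = set()
                for m in t:
                    if m & vbit:
                        mm = m & ~vbit
                        for qm in q:
                            acc ^= {mm | qm}
                    else:
                        acc ^= {m}
                if acc:
                    new_polys.append(frozenset(acc))
            polys = new_polys
            eliminated.append((vbit, q))

        assigned_bits = 0
        for r in assign:
            assigned_bits |= self.bits[r]
        elim_bits = 0
        for b, _ in eliminated:
            elim_bits |= b
        remaining = var_bits & ~assigned_bits & ~elim_bits
        eq_vars = [0] * len(polys)
        constrained = 0
        for i, p in enumerate(polys):
            mask = 0
            for m in p:
                mask |= m
            eq_vars[i] = mask
            constrained |= mask
        free_bits = remaining & ~constrained
        total = 1 << free_bits.bit_count()
        if total > self.cap:
            raise CapExceededError(
                f"more than {self.cap} solutions; raise max_solutions"
            )

        # connected components of the constraint graph
        parent = list(range(len(polys)))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        owner: dict[int, int] = {}  # variable bit -> first equation seen
        for i in range(len(polys)):
            for b in _bits_of(eq_vars[i]):
                j = owner.setdefault(b, i)
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[ri] = rj

        groups: dict[int, list[int]] = {}
        for i in range(len(polys)):
            groups.setdefault(find(i), []).append(i)

        component_sols: list[list[dict[int, int]]] = []
        for root in sorted(groups):
            idxs = groups[root]
            comp = [polys[i] for i in idxs]
            comp_bits = 0
            for i in idxs:
                comp_bits |= eq_vars[i]
            sols = self._solve_component_eqs(comp, comp_bits)
            if not sols:
                return []
            component_sols.append(sols)
            total *= len(sols)
            if total > self.cap:
                raise CapExceededError(
                    f"more than {self.cap} solutions; raise max_solutions"
                )

        # Cartesian recombination: propagated + components + free variables
        out = [dict(assign)]
        for sols in component_sols:
            out = [{**b, **s} for b in out for s in sols]
        for b in _bits_of(free_bits):
            r = self.rank_of_bit[b]
            out = [{**base, r: v} for base in out for v in (0, 1)]
        # restore eliminated variables from their definitions (reverse order:
        # later definitions may appear inside earlier ones)
        if eliminated:
            for base in out:
                ones = 0
                for r, v in base.items():
                    if v:
                        ones |= self.bits[r]
                for vbit, q in reversed(eliminated):
                    val = _eval_mask_poly(q, ones)
                    base[self.rank_of_bit[vbit]] = val
                    if val:
                        ones |= vbit
        return out

    def _solve_component_eqs(
        self, comp: list, comp_bits: int
    ) -> list[dict[int, int]]:
        comp_bit_list = _bits_of(comp_bits)
        density = sum(len(p) for p in comp)
        if len(comp_bit_list) <= GB_COMPONENT_LIMIT and (
            density <= GB_DENSITY_LIMIT
        ):
            basis = _groebner_masks(list(comp), self.deadline)
            if basis == [frozenset({0})]:
                return []
            comp_ranks = sorted(self.rank_of_bit[b] for b in comp_bit_list)
            sols = _solve_component(
                basis, comp_ranks, self.L, self.cap, self.deadline
            )
            # leaf verification against the component's own equations
            for a in sols:
                ones = 0
                for r, v in a.items():
                    if v:
                        ones |= self.bits[r]
                for p in comp:
                    if _eval_mask_poly(p, ones) != 0:
                        raise InternalConsistencyError(
                            "enumerated assignment violates an input equation"
                        )
            return sols
        # branch on the variable occurring in the most monomials
        counts: dict[int, int] = {}
        for p in comp:
            for m in p:
                for b in _bits_of(m):
                    counts[b] = counts.get(b, 0) + 1
        vbit = max(sorted(counts), key=lambda b: counts[b])
        vrank = self.rank_of_bit[vbit]
        sols = []
        for value in (0, 1):
            sub = [_substitute(p, vbit, value) for p in comp]
            for s in self.solve(sub, comp_bits & ~vbit):
                s[vrank] = value
                sols.append(s)
            if len(sols) > self.cap:
                raise CapExceededError(
                    f"more than {self.cap} solutions; raise max_solutions"
                )
        return sols


def enumerate_solutions(
    sys: PolynomialSystem,
    max_solutions: int = DEFAULT_MAX_SOLUTIONS,
    order: Sequence[str] | None = None,
    deadline: float | None = None,
) -> SteadyStateSet:
    """All GF(2) solutions of the system as a steady-state set.

    The solver is exact: the system is decomposed (unit propagation,
    independent components, branching for oversized components) down to
    pieces that a reduced lexicographic Groebner basis plus
    back-substitution enumerates completely.  Variables constrained by no
    equation are free and contribute a factor of 2 each.  If the total
    number of solutions would exceed *max_solutions* a
    :class:`CapExceededError` is raised instead of silently truncating.
    """
    names = tuple(order) if order is not None else default_variable_order(sys)
    if set(names) != set(sys.variables):
        raise InputError("order must be a permutation of the system variables")
    L = len(names)
    bit = {v: 1 << (L - 1 - r) for r, v in enumerate(names)}
    rank = {v: r for r, v in enumerate(names)}

    eq_masks = [_to_masks(p, bit) for p in sys.equations if not p.is_zero()]
    import sys as _sys

    limit = _sys.getrecursionlimit()
    if limit < 4 * L + 1000:
        _sys.setrecursionlimit(4 * L + 1000)
    try:
        solver = _MaskSolver(L, max_solutions, deadline)
        sols = solver.solve(eq_masks, (1 << L) - 1)
    finally:
        _sys.setrecursionlimit(limit)
    states = frozenset(
        tuple(s[rank[v]] for v in sys.variables) for s in sols
    )
    return SteadyStateSet(sys.variables, states)
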