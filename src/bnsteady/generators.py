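"""Seeded random Boolean network generators for benchmarking.

Two wiring classes are provided:

* Kauffman N-K networks: every node draws exactly ``K`` distinct regulators
  uniformly (a node may draw itself unless ``allow_self=False``) and an
  update rule from a random truth table whose ``2^K`` entries are i.i.d.
  fair bits.
* Power-law in-degree networks: node in-degrees are sampled from a
  truncated discrete power law ``P(k) ~ k^-gamma`` on ``1..n-1``; the
  exponent is first calibrated so the distribution's mean matches the
  requested average connectivity ``<k>``, and degree samples are redrawn
  until the realized mean is within 5% of the target.

Update rules default to uniform random truth tables.  A nested canalyzing
family (``functions="ncf"``) is available as a biologically-motivated
alternative: inputs in a random order each get a canalyzing value and
output, the last input non-degenerate.  Nodes of in-degree above
``table_arity_cap`` always use nested canalyzing rules, since an explicit
``2^k`` truth table is no longer representable.

Equal specs (including the seed) produce byte-identical rule files.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import And, BooleanNetwork, Const, Expr, Not, Or, Var
from .errors import InputError

DEFAULT_GAMMA = 2.5
TABLE_ARITY_CAP = 12
_MEAN_TOL = 0.05


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of a random-network draw."""

    family: str  # "kauffman" | "powerlaw"
    n: int
    k: float  # exact in-degree (kauffman) or target mean <k> (powerlaw)
    gamma: float = DEFAULT_GAMMA
    functions: str = "uniform"  # "uniform" | "ncf"
    seed: int = 0
    allow_self: bool = True


def _var_names(n: int) -> tuple[str, ...]:
    return tuple(f"x{i + 1}" for i in range(n))


def _minterm(regs: list[str], pattern: int, k: int) -> Expr:
    lits: list[Expr] = []
    for j, r in enumerate(regs):
        bit = (pattern >> (k - 1 - j)) & 1
        lits.append(Var(r) if bit else Not(Var(r)))
    return lits[0] if len(lits) == 1 else And(tuple(lits))


def _table_to_expr(regs: list[str], table: np.ndarray) -> Expr:
    """Full disjunctive normal form of a truth table over its inputs.

    Minterms are written out without simplification so the drawn wiring is
    explicit in the rule text.  The all-false table is rendered as the
    contradictory conjunction ``r1 & !r1 & r2 & ...`` for the same reason
    (it still evaluates to the constant 0).
    """
    k = len(regs)
    ones = [p for p in range(1 << k) if table[p]]
    if not ones:
        lits: list[Expr] = [Var(regs[0]), Not(Var(regs[0]))]
        lits += [Var(r) for r in regs[1:]]
        return And(tuple(lits))
    terms = [_minterm(regs, p, k) for p in ones]
    return terms[0] if len(terms) == 1 else Or(tuple(terms))


def _ncf_expr_full(
    regs: list[str], canal: np.ndarray, outputs: np.ndarray
) -> Expr:
    """Nested canalyzing rule keeping every input syntactically present."""
    k = len(regs)

    def lit(r: str, value: int) -> Expr:
        return Var(r) if value else Not(Var(r))

    def build(i: int) -> Expr:
        if i == k - 1:
            inner: Expr = lit(regs[i], int(canal[i]) ^ 1)
            return Not(inner) if outputs[i] else inner
        trigger = lit(regs[i], int(canal[i]))
        rest = build(i + 1)
        if outputs[i]:
            return Or((trigger, rest))
        return And((lit(regs[i], int(canal[i]) ^ 1), rest))

    return build(0)


def _draw_function(
    regs: list[str], rng: np.random.Generator, functions: str
) -> Expr:
    k = len(regs)
    if functions == "uniform" and k <= TABLE_ARITY_CAP:
        table = rng.integers(0, 2, size=1 << k)
        return _table_to_expr(regs, table)
    if functions not in ("uniform", "ncf"):
        raise InputError(f"unknown function family {functions!r}")
    canal = rng.integers(0, 2, size=k)
    outputs = rng.integers(0, 2, size=k)
    return _ncf_expr_full(regs, canal, outputs)


def _draw_regulators(
    n: int, k: int, node: int, rng: np.random.Generator, allow_self: bool
) -> list[str]:
    pool = np.arange(n)
    if not allow_self:
        pool = np.delete(pool, node)
    if k > len(pool):
        raise InputError(f"in-degree {k} infeasible for n={n}")
    picks = np.sort(rng.choice(pool, size=k, replace=False))
    names = _var_names(n)
    return [names[i] for i in picks]


def generate_kauffman(
    n: int,
    k: int,
    seed: int = 0,
    functions: str = "uniform",
    allow_self: bool = True,
) -> BooleanNetwork:
    """Random N-K network: K regulators and a random rule per node."""
    if n < 1:
        raise InputError("n must be >= 1")
    if not 1 <= k <= (n if allow_self else n - 1):
        raise InputError(f"K={k} infeasible for n={n}")
    rng = np.random.default_rng(seed)
    names = _var_names(n)
    fns: dict[str, Expr] = {}
    for i, v in enumerate(names):
        regs = _draw_regulators(n, k, i, rng, allow_self)
        fns[v] = _draw_function(regs, rng, functions)
    return BooleanNetwork(names, fns)


def _truncated_powerlaw_mean(gamma: float, kmax: int) -> float:
    ks = np.arange(1, kmax + 1, dtype=float)
    w = ks ** (-gamma)
    return float((ks * w).sum() / w.sum())


def _calibrate_gamma(target: float, kmax: int, gamma: float) -> float:
    """Smallest adjustment of the exponent that matches the target mean."""
    if abs(_truncated_powerlaw_mean(gamma, kmax) - target) <= 1e-9:
        return gamma
    lo, hi = -8.0, 20.0  # mean is decreasing in gamma on this bracket
    if target <= _truncated_powerlaw_mean(hi, kmax):
        return hi  # boundary target (e.g. mean 1): essentially all degree 1
    if target >= _truncated_powerlaw_mean(lo, kmax):
        return lo
    for _ in range(200):
        mid = (lo + hi) / 2
        if _truncated_powerlaw_mean(mid, kmax) > target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def generate_powerlaw(
    n: int,
    avg_k: float,
    gamma: float = DEFAULT_GAMMA,
    seed: int = 0,
    functions: str = "uniform",
    allow_self: bool = True,
    max_attempts: int = 1000,
) -> BooleanNetwork:
    """Random network with power-law in-degrees of mean ``avg_k``.

    In-degrees follow ``P(k) ~ k^-gamma`` truncated to ``1..n-1`` with the
    exponent calibrated to the requested mean; whole degree sequences are
    redrawn until the sample mean lies within 5% of ``avg_k``.
    """
    if n < 2:
        raise InputError("powerlaw networks need n >= 2")
    kmax = n - 1
    if not 1 <= avg_k <= kmax:
        raise InputError(f"mean in-degree {avg_k} infeasible for n={n}")
    g_eff = _calibrate_gamma(float(avg_k), kmax, gamma)
    ks = np.arange(1, kmax + 1, dtype=float)
    w = ks ** (-g_eff)
    prob = w / w.sum()
    rng = np.random.default_rng(seed)
    for _ in range(max_attempts):
        degrees = rng.choice(np.arange(1, kmax + 1), size=n, p=prob)
        if abs(degrees.mean() - avg_k) <= _MEAN_TOL * avg_k:
            break
    else:
        raise InputError(
            f"could not realize mean in-degree {avg_k} in {max_attempts} draws"
        )
    names = _var_names(n)
    fns: dict[str, Expr] = {}
    for i, v in enumerate(names):
        regs = _draw_regulators(n, int(degrees[i]), i, rng, allow_self)
        fns[v] = _draw_function(regs, rng, functions)
    return BooleanNetwork(names, fns)


def generate(spec: GeneratorSpec) -> BooleanNetwork:
    """Dispatch on a :class:`GeneratorSpec`."""
    if spec.family == "kauffman":
        return generate_kauffman(
            spec.n, int(spec.k), spec.seed, spec.functions, spec.allow_self
        )
    if spec.family == "powerlaw":
        return generate_powerlaw(
            spec.n,
            spec.k,
            spec.gamma,
            spec.seed,
            spec.functions,
            spec.allow_self,
        )
    raise InputError(f"unknown generator family {spec.family!r}")
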