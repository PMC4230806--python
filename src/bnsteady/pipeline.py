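"""End-to-end steady-state computation: f -> g -> h -> polynomials -> states.

The pipeline composes the stages

1. AND-NOT transform (``f`` on n variables -> ``g`` on m >= n),
2. steady-state-preserving reduction (``g`` -> ``h`` on l <= m variables),
3. polynomial encoding ``h_i + x_i = 0`` over GF(2),
4. Groebner-basis solution enumeration (``L''``),
5. backtracking to steady states of ``g`` (``L'``),
6. projection to the first n coordinates (steady states of ``f``),

and always re-verifies every returned state with ``f(x) = x`` before
returning, so a bug in any stage surfaces as a loud
:class:`InternalConsistencyError` rather than a wrong answer.  Small
networks can instead be solved by the exhaustive oracle (``method="brute"``)
or the feedback-vertex-set oracle (``method="fvs"``).
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

from .algebra import (
    DEFAULT_MAX_SOLUTIONS,
    enumerate_solutions,
    steady_state_system,
)
from .core import (
    AndNotNetwork,
    BooleanNetwork,
    Network,
    SteadyStateSet,
    is_steady_state,
)
from .errors import InputError, InternalConsistencyError
from .oracles import (
    DEFAULT_EXHAUSTIVE_CAP,
    DEFAULT_FVS_CAP,
    dependency_digraph,
    enumerate_exhaustive,
    enumerate_via_fvs,
    find_fvs,
)
from .reduction import backtrack_states, reduce_andnot
from .transform import boolean_to_andnot, project_steady_states

AUTO_BRUTE_LIMIT = 18  # brute force is unbeatable below this size


@dataclass
class SolveReport:
    """Result of a solve plus per-stage diagnostics."""

    states: SteadyStateSet
    method: str
    n: int
    m: int | None = None
    l: int | None = None
    rule_counts: dict = field(default_factory=dict)
    stage_seconds: dict = field(default_factory=dict)

    @property
    def count(self) -> int:
        return len(self.states)


def _verify(f: Network, states: SteadyStateSet) -> None:
    for s in states.states:
        if not is_steady_state(f, s):
            raise InternalConsistencyError(
                f"emitted state {s} fails f(x) = x"
            )


def solve(
    f: Network,
    method: str = "auto",
    max_solutions: int = DEFAULT_MAX_SOLUTIONS,
    timeout: float | None = None,
    exhaustive_cap: int = DEFAULT_EXHAUSTIVE_CAP,
    fvs_cap: int = DEFAULT_FVS_CAP,
) -> SolveReport:
    """Compute all steady states of *f*.

    ``method`` is ``"pipeline"``, ``"brute"``, ``"fvs"`` or ``"auto"``
    (brute below 19 variables, pipeline above).  ``timeout`` is a
    wall-clock budget in seconds for the algebra stage; exceeding it raises
    :class:`SolveTimeoutError`.
    """
    if method == "auto":
        method = "brute" if f.n <= AUTO_BRUTE_LIMIT else "pipeline"
    deadline = None if timeout is None else time.monotonic() + timeout
    t0 = time.monotonic()

    if method == "brute":
        states = enumerate_exhaustive(f, cap=exhaustive_cap)
        if len(states) > max_solutions:
            raise InputError(
                f"{len(states)} steady states exceed max_solutions"
            )
        report = SolveReport(states, "brute", f.n)
    elif method == "fvs":
        S = find_fvs(dependency_digraph(f))
        states = enumerate_via_fvs(f, S, cap=fvs_cap)
        report = SolveReport(states, "fvs", f.n)
    elif method == "pipeline":
        stages: dict[str, float] = {}
        if isinstance(f, AndNotNetwork):
            # already AND-NOT: the transform stage is the identity
            g, vmap = f, None
        else:
            g, vmap = boolean_to_andnot(f)
        stages["transform"] = time.monotonic() - t0

        t = time.monotonic()
        h, trace = reduce_andnot(g)
        stages["reduce"] = time.monotonic() - t

        t = time.monotonic()
        system = steady_state_system(h)
        sols = enumerate_solutions(
            system, max_solutions=max_solutions, deadline=deadline
        )
        stages["solve"] = time.monotonic() - t

        t = time.monotonic()
        lifted = backtrack_states(trace, sols, g)
        states = (
            lifted if vmap is None else project_steady_states(lifted, vmap)
        )
        stages["backtrack"] = time.monotonic() - t
        report = SolveReport(
            states,
            "pipeline",
            f.n,
            m=g.n,
            l=h.n,
            rule_counts=dict(trace.rule_counts),
            stage_seconds=stages,
        )
    else:
        raise InputError(f"unknown method {method!r}")

    _verify(f, report.states)
    report.stage_seconds["total"] = time.monotonic() - t0
    return report


@dataclass(frozen=True)
class VerifyReport:
    """Agreement between two solve methods on one network."""

    methods: tuple[str, str]
    agree: bool
    only_first: frozenset
    only_second: frozenset
    count: int


def verify(
    f: Network, methods: tuple[str, str] = ("pipeline", "brute"), **kwargs
) -> VerifyReport:
    """Run two methods and report set equality and the symmetric difference."""
    a = solve(f, method=methods[0], **kwargs).states
    b = solve(f, method=methods[1], **kwargs).states
    return VerifyReport(
        methods=tuple(methods),
        agree=a.states == b.states,
        only_first=frozenset(a.states - b.states),
        only_second=frozenset(b.states - a.states),
        count=len(a.states & b.states),
    )
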