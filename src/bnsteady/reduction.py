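"""Steady-state-preserving reduction of AND-NOT networks.

Four rules are applied to the signed wiring diagram until none fires; each
keeps the steady-state sets of the network before and after in an explicit
bijection that :func:`backtrack_states` replays in reverse:

R1 (constant propagation)
    A node with a constant function is removed; its literal is absorbed into
    each target (dropped if satisfied, otherwise the target becomes the
    constant 0).  At a fixed point the node must hold its constant.
R2 (unit-input elimination)
    A node ``y`` with a single regulator ``x != y`` is removed; occurrences
    of ``y`` elsewhere are replaced by the sign-composed literal of ``x``.
    At a fixed point ``y`` equals that literal exactly.
R3 (sink elimination)
    A node with no outgoing edges and no self-loop constrains nothing; it is
    removed and its value is reconstructed from its recorded conjunction.
R4 (feed-forward redundancy)
    With edges ``x -s-> y``, ``y -+-> z`` and ``x -s-> z`` present, the direct
    ``x`` literal in ``z`` is redundant at every fixed point (``y <= x^s``
    there), so the edge ``x -> z`` is deleted.  No variable is removed.

R1/R2/R3 delete a node and R4 deletes an edge, so the fixpoint loop
terminates after at most ``m + |edges|`` applications.  Nodes with
self-loops are never reduced (except via R1 once constant): positive
self-inputs carry environmental degrees of freedom and negative self-loops
are handled exactly by the polynomial stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

from .core import (
    AndNotNetwork,
    SteadyStateSet,
    eval_andnot_function,
    is_steady_state,
)
from .errors import InternalConsistencyError

RecordKind = Literal["constant", "alias", "sink"]


@dataclass(frozen=True)
class ReductionRecord:
    """One removed variable: how to reconstruct its steady-state value."""

    variable: str
    kind: RecordKind
    #: constant -> bit; alias -> (source, sign); sink -> conjunction dict
    payload: object


@dataclass
class ReductionTrace:
    """Ordered removal records plus per-rule application counts."""

    records: list[ReductionRecord] = field(default_factory=list)
    rule_counts: dict[str, int] = field(
        default_factory=lambda: {"R1": 0, "R2": 0, "R3": 0, "R4": 0}
    )

    def __len__(self) -> int:
        return len(self.records)


class _Working:
    """Mutable network view with a reverse-adjacency (targets) index."""

    def __init__(self, g: AndNotNetwork):
        self.order = list(g.variables)
        self.functions: dict[str, object] = {
            v: (fn if isinstance(fn, int) else dict(fn))
            for v, fn in g.functions.items()
        }
        self.targets: dict[str, set[str]] = {v: set() for v in self.order}
        for tgt, fn in self.functions.items():
            if isinstance(fn, dict):
                for src in fn:
                    self.targets[src].add(tgt)

    def live(self) -> list[str]:
        return [v for v in self.order if v in self.functions]

    def drop_literal(self, tgt: str, src: str) -> None:
        fn = self.functions[tgt]
        del fn[src]
        self.targets[src].discard(tgt)
        if not fn:
            self.functions[tgt] = 1

    def set_constant(self, tgt: str, value: int) -> None:
        fn = self.functions[tgt]
        if isinstance(fn, dict):
            for src in fn:
                self.targets[src].discard(tgt)
        self.functions[tgt] = value

    def add_literal(self, tgt: str, src: str, sign: int) -> None:
        """Merge a literal into tgt's conjunction; conflicts give constant 0."""
        fn = self.functions[tgt]
        have = fn.get(src)
        if have is None:
            fn[src] = sign
            self.targets[src].add(tgt)
        elif have != sign:
            self.set_constant(tgt, 0)

    def remove_node(self, v: str) -> None:
        fn = self.functions.pop(v)
        if isinstance(fn, dict):
            for src in fn:
                self.targets[src].discard(v)
        if self.targets[v]:
            raise InternalConsistencyError(
                f"removing {v!r} while it still has targets"
            )
        del self.targets[v]


def _apply_r1(w: _Working, trace: ReductionTrace) -> bool:
    for y in w.live():
        fn = w.functions[y]
        if not isinstance(fn, int):
            continue
        for z in sorted(w.targets[y]):
            sign = w.functions[z][y]
            satisfied = (fn == 1) == (sign > 0)
            if satisfied:
                w.drop_literal(z, y)
            else:
                w.set_constant(z, 0)
        w.remove_node(y)
        trace.records.append(ReductionRecord(y, "constant", fn))
        trace.rule_counts["R1"] += 1
        return True
    return False


def _apply_r2(w: _Working, trace: ReductionTrace) -> bool:
    for y in w.live():
        fn = w.functions[y]
        if not (isinstance(fn, dict) and len(fn) == 1):
            continue
        (x, s0), = fn.items()
        if x == y:
            continue  # self-input or negative self-loop: never reduced
        for z in sorted(w.targets[y]):
            t = w.functions[z][y]
            w.drop_literal(z, y)
            if isinstance(w.functions[z], int):
                # conjunction emptied -> constant 1; re-add composed literal
                w.functions[z] = {}
            w.add_literal(z, x, s0 * t)
            if w.functions[z] == {}:
                w.functions[z] = 1
        w.remove_node(y)
        trace.records.append(ReductionRecord(y, "alias", (x, s0)))
        trace.rule_counts["R2"] += 1
        return True
    return False


def _apply_r4(w: _Working, trace: ReductionTrace) -> bool:
    for y in w.live():
        fy = w.functions[y]
        if not isinstance(fy, dict):
            continue
        for z in sorted(w.targets[y]):
            if z == y or w.functions[z][y] != 1:
                continue  # need a positive edge y -> z
            fz = w.functions[z]
            for x, s in fy.items():
                if x != y and x != z and fz.get(x) == s:
                    w.drop_literal(z, x)
                    trace.rule_counts["R4"] += 1
                    return True
    return False


def _apply_r3(w: _Working, trace: ReductionTrace) -> bool:
    for y in w.live():
        fn = w.functions[y]
        if isinstance(fn, int):
            continue  # R1 territory
        if w.targets[y] or y in fn:
            continue
        conj = dict(fn)
        for src in conj:
            w.targets[src].discard(y)
        w.functions[y] = 1  # clear regs so remove_node's audit passes
        w.remove_node(y)
        trace.records.append(ReductionRecord(y, "sink", conj))
        trace.rule_counts["R3"] += 1
        return True
    return False


def reduce_andnot(g: AndNotNetwork) -> tuple[AndNotNetwork, ReductionTrace]:
    """Apply R1-R4 to a fixpoint; returns the reduced network and the trace.

    Scan order is declaration order, and after any rule fires the cycle
    restarts at R1 (constants unlock the most follow-up reductions), so
    traces are reproducible.  An already-irreducible network comes back
    unchanged with an empty trace.
    """
    w = _Working(g)
    trace = ReductionTrace()
    while True:
        if _apply_r1(w, trace):
            continue
        if _apply_r2(w, trace):
            continue
        if _apply_r4(w, trace):
            continue
        if _apply_r3(w, trace):
            continue
        break
    live = [v for v in w.order if v in w.functions]
    if not live:
        # Everything was determined; keep one recorded node as an anchor so
        # the result is still a valid (single-constant) network.
        last = trace.records.pop()
        trace.rule_counts[
            {"constant": "R1", "alias": "R2", "sink": "R3"}[last.kind]
        ] -= 1
        value = last.payload if last.kind == "constant" else None
        if value is None:
            raise InternalConsistencyError(
                "last removed node of a fully-reduced network must be constant"
            )
        h = AndNotNetwork((last.variable,), {last.variable: value})
        return h, trace
    h = AndNotNetwork(
        tuple(live),
        {
            v: (w.functions[v] if isinstance(w.functions[v], int)
                else dict(w.functions[v]))
            for v in live
        },
    )
    return h, trace


def backtrack_states(
    trace: ReductionTrace, states_h: SteadyStateSet, g: AndNotNetwork
) -> SteadyStateSet:
    """Replay the trace in reverse to lift steady states of ``h`` to ``g``.

    Each record assigns its removed variable from values already known at
    that point of the reverse replay (later removals are restored earlier,
    so every payload reference is resolved).  Every reconstructed state is
    verified with :func:`is_steady_state` against ``g``; failure indicates a
    reduction bug and raises :class:`InternalConsistencyError`.
    """
    out = set()
    for hs in states_h.states:
        env: dict[str, int] = dict(zip(states_h.variables, hs))
        for rec in reversed(trace.records):
            if rec.variable in env:
                continue  # anchor node already present in h
            if rec.kind == "constant":
                env[rec.variable] = rec.payload
            elif rec.kind == "alias":
                x, sign = rec.payload
                env[rec.variable] = env[x] if sign > 0 else env[x] ^ 1
            else:  # sink
                env[rec.variable] = eval_andnot_function(rec.payload, env)
        state = tuple(env[v] for v in g.variables)
        if not is_steady_state(g, state):
            raise InternalConsistencyError(
                f"backtracked state {state} is not steady in g"
            )
        out.add(state)
    if len(out) != len(states_h.states):
        raise InternalConsistencyError("backtracking lost states")
    return SteadyStateSet(g.variables, frozenset(out))
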