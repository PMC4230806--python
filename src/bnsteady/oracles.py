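"""Independent verification oracles: exhaustive scan and FVS enumeration.

Both oracles compute the steady states of a network without the
transform/reduce/solve pipeline, so agreement between a pipeline result and
an oracle is a genuine cross-check.

* :func:`enumerate_exhaustive` scans all ``2^n`` states (vectorized with
  numpy over the whole state space).
* :func:`enumerate_via_fvs` exploits a feedback vertex set ``S`` of the
  dependency graph: fixing the coordinates in ``S`` determines every other
  coordinate (the remainder is acyclic, so values propagate in topological
  order), giving ``2^|S|`` candidate states that are then checked with
  ``f(x) = x``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .core import (
    AndNotNetwork,
    BooleanNetwork,
    Network,
    SignedDigraph,
    SteadyStateSet,
    eval_andnot_function,
    eval_expr,
    expr_variables,
)
from .errors import CapExceededError, InputError, InternalConsistencyError
from .transform import fold_constants

DEFAULT_EXHAUSTIVE_CAP = 22
DEFAULT_FVS_CAP = 24
_CHUNK_BITS = 16  # candidate blocks of 2^16 states keep memory flat


@dataclass(frozen=True)
class FeedbackVertexSet:
    """Node set whose removal leaves the digraph acyclic."""

    nodes: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", frozenset(self.nodes))

    def __len__(self) -> int:
        return len(self.nodes)

    def __iter__(self):
        return iter(sorted(self.nodes))


# ---------------------------------------------------------------------------
# Dependency graphs
# ---------------------------------------------------------------------------


def dependency_digraph(network: Network) -> SignedDigraph:
    """Syntactic dependency graph: edge ``x -> y`` if x occurs in f_y.

    For general Boolean networks constants are folded first so a vacuous
    mention (e.g. ``x & 0``) creates no phantom edge; the sign is recorded
    as activating since general expressions carry no sign information.  For
    AND-NOT networks the true signed wiring diagram is returned.
    """
    if isinstance(network, AndNotNetwork):
        from .core import wiring_diagram

        return wiring_diagram(network)
    edges = set()
    for tgt in network.variables:
        for src in expr_variables(fold_constants(network.functions[tgt])):
            edges.add((src, tgt, 1))
    return SignedDigraph(network.variables, frozenset(edges))


def _nx_digraph(d: SignedDigraph) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(d.nodes)
    g.add_edges_from((s, t) for s, t, _ in d.edges)
    return g


# ---------------------------------------------------------------------------
# Vectorized evaluation helpers
# ---------------------------------------------------------------------------


def _eval_function_vec(
    network: Network, v: str, env: dict, size: int, folded: dict | None = None
) -> np.ndarray:
    if isinstance(network, BooleanNetwork):
        fn = folded[v] if folded is not None else network.functions[v]
        out = eval_expr(fn, env)
    else:
        out = eval_andnot_function(network.functions[v], env)
    if not isinstance(out, np.ndarray):  # constant function
        out = np.full(size, out, dtype=np.uint8)
    return out


def enumerate_exhaustive(
    f: Network, cap: int = DEFAULT_EXHAUSTIVE_CAP
) -> SteadyStateSet:
    """Scan all ``2^n`` states and keep the fixed points.

    Refuses networks with ``n`` above *cap* (default 22) so an accidental
    ``2^50`` scan fails loudly instead of hanging.
    """
    n = f.n
    if n > cap:
        raise CapExceededError(
            f"exhaustive enumeration refused: n={n} exceeds cap {cap}"
        )
    idx = np.arange(1 << n, dtype=np.uint32 if n <= 31 else np.uint64)
    env = {
        v: ((idx >> (n - 1 - j)) & 1).astype(np.uint8)
        for j, v in enumerate(f.variables)
    }
    steady = np.ones(1 << n, dtype=bool)
    for v in f.variables:
        steady &= _eval_function_vec(f, v, env, 1 << n) == env[v]
    hits = np.nonzero(steady)[0]
    states = frozenset(
        tuple(int((h >> (n - 1 - j)) & 1) for j in range(n)) for h in hits
    )
    return SteadyStateSet(f.variables, states)


# ---------------------------------------------------------------------------
# Feedback vertex sets
# ---------------------------------------------------------------------------


def _shortest_cycle(g: nx.DiGraph) -> list | None:
    """A shortest directed cycle as a node list, or None if acyclic."""
    for v in g.nodes:
        if g.has_edge(v, v):
            return [v]
    best: list | None = None
    for source in g.nodes:
        # BFS from source; first return to source closes a shortest cycle
        # through it.
        parent = {source: None}
        queue = [source]
        found = None
        while queue and found is None:
            nxt = []
            for u in queue:
                for w in g.successors(u):
                    if w == source:
                        found = u
                        break
                    if w not in parent:
                        parent[w] = u
                        nxt.append(w)
                if found is not None:
                    break
            queue = nxt
        if found is not None:
            cycle = [found]
            while parent[cycle[-1]] is not None:
                cycle.append(parent[cycle[-1]])
            cycle.reverse()
            if best is None or len(cycle) < len(best):
                best = cycle
                if len(best) == 2:
                    break
    return best


def _fvs_exact(g: nx.DiGraph, budget: int) -> frozenset | None:
    """Minimum FVS of *g* if its size is <= *budget*, else None.

    Branch and bound: self-loop nodes are forced; otherwise branch on the
    members of one shortest cycle (some member must be removed).
    """
    forced = frozenset(v for v in g.nodes if g.has_edge(v, v))
    if forced:
        if len(forced) > budget:
            return None
        sub = g.copy()
        sub.remove_nodes_from(forced)
        rest = _fvs_exact(sub, budget - len(forced))
        return None if rest is None else forced | rest
    cycle = _shortest_cycle(g)
    if cycle is None:
        return frozenset()
    best: frozenset | None = None
    for v in cycle:
        sub_budget = (budget if best is None else len(best) - 1) - 1
        if sub_budget < 0:
            break
        sub = g.copy()
        sub.remove_node(v)
        rest = _fvs_exact(sub, sub_budget)
        if rest is not None:
            best = rest | {v}
    return best


def _cycle_through(g: nx.DiGraph, source) -> list | None:
    """A shortest cycle through *source*, or None."""
    best = None
    for u in g.predecessors(source):
        if u == source:
            return [source]
        try:
            p = nx.shortest_path(g, source, u)
        except nx.NetworkXNoPath:
            continue
        if best is None or len(p) < len(best):
            best = p
    return best


def _fvs_greedy(g: nx.DiGraph, order: dict) -> set:
    """Remove the node lying on the most shortest cycles until acyclic."""
    g = g.copy()
    removed: set = set()
    while True:
        for v in list(g.nodes):
            if g.has_edge(v, v):
                removed.add(v)
                g.remove_node(v)
        shortest = _shortest_cycle(g)
        if shortest is None:
            return removed
        k = len(shortest)
        counts: dict = {}
        for source in g.nodes:
            cyc = _cycle_through(g, source)
            if cyc is not None and len(cyc) == k:
                for v in cyc:
                    counts[v] = counts.get(v, 0) + 1
        if not counts:
            counts = {v: 1 for v in shortest}
        top = min(counts, key=lambda v: (-counts[v], order[v]))
        removed.add(top)
        g.remove_node(top)


def find_fvs(d: SignedDigraph, exact_limit: int = 25) -> FeedbackVertexSet:
    """A feedback vertex set of *d*: minimum for small graphs, greedy above.

    Graphs with at most *exact_limit* nodes are solved exactly by branch
    and bound; larger graphs use the greedy shortest-cycle heuristic (ties
    broken by declaration order).  Validity is always re-verified by an
    acyclicity check.
    """
    order = {v: i for i, v in enumerate(d.nodes)}
    g = _nx_digraph(d)
    result: set = set()
    for comp in nx.strongly_connected_components(g):
        comp = set(comp)
        if len(comp) == 1:
            (v,) = comp
            if g.has_edge(v, v):
                result.add(v)
            continue
        sub = g.subgraph(comp).copy()
        if len(d.nodes) <= exact_limit:
            greedy = _fvs_greedy(sub.copy(), order)
            exact = _fvs_exact(sub, len(greedy))
            result |= set(exact) if exact is not None else greedy
        else:
            result |= _fvs_greedy(sub, order)
    check = g.copy()
    check.remove_nodes_from(result)
    if not nx.is_directed_acyclic_graph(check):
        raise InternalConsistencyError("FVS removal left a directed cycle")
    return FeedbackVertexSet(frozenset(result))


# ---------------------------------------------------------------------------
# FVS-based enumeration
# ---------------------------------------------------------------------------


def enumerate_via_fvs(
    f: Network,
    S: FeedbackVertexSet | None = None,
    cap: int = DEFAULT_FVS_CAP,
) -> SteadyStateSet:
    """Steady states via ``2^|S|`` candidates over a feedback vertex set.

    For each assignment of the FVS coordinates the remaining variables are
    evaluated in topological order of the acyclic remainder; the candidate
    is kept iff the full state is a fixed point.  Candidates are processed
    in vectorized blocks.
    """
    d = dependency_digraph(f)
    if S is None:
        S = find_fvs(d)
    g = _nx_digraph(d)
    rest_graph = g.copy()
    rest_graph.remove_nodes_from(S.nodes)
    if not nx.is_directed_acyclic_graph(rest_graph):
        raise InputError("S is not a valid feedback vertex set")
    unknown = S.nodes - set(f.variables)
    if unknown:
        raise InputError(f"FVS nodes not in network: {sorted(unknown)}")
    s_vars = sorted(S.nodes, key=list(f.variables).index)
    k = len(s_vars)
    if k > cap:
        raise CapExceededError(f"|S|={k} exceeds FVS enumeration cap {cap}")
    topo = list(nx.topological_sort(rest_graph))
    # fold constants so evaluation only touches true (graph) dependencies
    folded = (
        {v: fold_constants(f.functions[v]) for v in f.variables}
        if isinstance(f, BooleanNetwork)
        else None
    )

    accepted: set = set()
    total = 1 << k
    block = 1 << min(k, _CHUNK_BITS)
    for start in range(0, total, block):
        size = min(block, total - start)
        idx = np.arange(start, start + size, dtype=np.uint64)
        env = {
            v: ((idx >> np.uint64(k - 1 - j)) & np.uint64(1)).astype(np.uint8)
            for j, v in enumerate(s_vars)
        }
        for v in topo:
            env[v] = _eval_function_vec(f, v, env, size, folded)
        ok = np.ones(size, dtype=bool)
        for v in f.variables:
            ok &= _eval_function_vec(f, v, env, size, folded) == env[v]
        for pos in np.nonzero(ok)[0]:
            accepted.add(
                tuple(int(env[v][pos]) for v in f.variables)
            )
    return SteadyStateSet(f.variables, frozenset(accepted))
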