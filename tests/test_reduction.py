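"""Wiring-diagram reduction rules and backtracking."""

import pytest

from bnsteady.core import AndNotNetwork, wiring_diagram
from bnsteady.oracles import enumerate_exhaustive
from bnsteady.reduction import backtrack_states, reduce_andnot

from conftest import random_andnot_network


def exhaustive_matches_after_reduction(g: AndNotNetwork) -> bool:
    h, trace = reduce_andnot(g)
    lifted = backtrack_states(trace, enumerate_exhaustive(h), g)
    return lifted.states == enumerate_exhaustive(g).states


class TestRules:
    def test_chain_into_input_is_aliased_away(self):
        g = AndNotNetwork(
            ("x1", "x2", "x3"),
            {"x1": {"x2": -1}, "x2": {"x3": 1}, "x3": {"x3": 1}},
        )
        h, trace = reduce_andnot(g)
        # the unit node x2 is recorded as an alias of +x3
        assert ("x2", "alias", ("x3", 1)) in [
            (r.variable, r.kind, r.payload) for r in trace.records
        ]
        # the input loop survives; steady states are preserved (2 each)
        assert "x3" in h.variables
        assert h.functions["x3"] == {"x3": 1}
        assert exhaustive_matches_after_reduction(g)
        assert len(enumerate_exhaustive(g)) == 2

    def test_contradictory_conjunction_becomes_constant_and_propagates(self):
        g = AndNotNetwork(
            ("x1", "x2"),
            {"x1": 0, "x2": {"x1": 1}},
        )
        h, trace = reduce_andnot(g)
        assert trace.rule_counts["R1"] >= 1
        assert backtrack_states(
            trace, enumerate_exhaustive(h), g
        ).states == frozenset({(0, 0)})

    def test_mutual_inhibition_collapses_to_one_input_node(self):
        """A bare 2-cycle is a unit-input chain: R2 folds it to one node.

        The toggle switch x1 = !x2, x2 = !x1 leaves a single self-input
        node; backtracking restores both antipodal steady states.
        """
        g = AndNotNetwork(
            ("x1", "x2"), {"x1": {"x2": -1}, "x2": {"x1": -1}}
        )
        h, trace = reduce_andnot(g)
        assert h.n == 1
        assert backtrack_states(
            trace, enumerate_exhaustive(h), g
        ).states == frozenset({(0, 1), (1, 0)})

    def test_irreducible_core_untouched(self):
        # mutual inhibition gated by an input: every node keeps >= 2
        # regulators (or a self-loop), so no rule applies
        g = AndNotNetwork(
            ("x1", "x2", "x3"),
            {
                "x1": {"x2": -1, "x3": 1},
                "x2": {"x1": -1, "x3": 1},
                "x3": {"x3": 1},
            },
        )
        h, trace = reduce_andnot(g)
        assert h.functions == g.functions
        assert len(trace) == 0
        assert trace.rule_counts == {"R1": 0, "R2": 0, "R3": 0, "R4": 0}

    def test_feed_forward_redundant_edge_removed(self):
        # x -> y (+), y -> z (+), x -> z (+) with y not unit-input:
        # the direct x literal in z is absorbed and dropped
        g = AndNotNetwork(
            ("x", "w", "y", "z"),
            {
                "x": {"x": 1},
                "w": {"w": 1},
                "y": {"x": 1, "w": 1},
                "z": {"x": 1, "y": 1},
            },
        )
        h, trace = reduce_andnot(g)
        assert trace.rule_counts["R4"] >= 1
        assert exhaustive_matches_after_reduction(g)

    def test_self_loops_are_never_reduced(self):
        g = AndNotNetwork(
            ("inp", "neg"),
            {"inp": {"inp": 1}, "neg": {"neg": -1}},
        )
        h, trace = reduce_andnot(g)
        assert set(h.variables) == {"inp", "neg"}
        assert len(trace) == 0

    def test_fully_constant_network_keeps_an_anchor_node(self):
        g = AndNotNetwork(("a", "b"), {"a": 1, "b": {"a": 1}})
        h, trace = reduce_andnot(g)
        assert h.n == 1
        assert backtrack_states(
            trace, enumerate_exhaustive(h), g
        ).states == frozenset({(1, 1)})


class TestBacktracking:
    def test_alias_record_reconstructs_source_value(self):
        g = AndNotNetwork(
            ("x1", "x2", "x3"),
            {"x1": {"x2": -1}, "x2": {"x3": 1}, "x3": {"x3": 1}},
        )
        h, trace = reduce_andnot(g)
        lifted = backtrack_states(trace, enumerate_exhaustive(h), g)
        assert lifted.states == frozenset({(1, 0, 0), (0, 1, 1)})

    def test_empty_trace_is_identity(self):
        g = AndNotNetwork(
            ("x1", "x2"), {"x1": {"x2": -1}, "x2": {"x1": -1}}
        )
        h, trace = reduce_andnot(g)
        assert backtrack_states(
            trace, enumerate_exhaustive(h), g
        ).states == enumerate_exhaustive(g).states

    def test_constant_record_extends_every_state(self):
        g = AndNotNetwork(
            ("c", "inp"), {"c": 1, "inp": {"inp": 1}}
        )
        h, trace = reduce_andnot(g)
        lifted = backtrack_states(trace, enumerate_exhaustive(h), g)
        assert lifted.states == frozenset({(1, 0), (1, 1)})


class TestReductionProperties:
    def test_end_to_end_soundness_on_random_corpus(self, rng):
        for _ in range(400):
            g = random_andnot_network(rng, rng.randint(1, 12))
            assert exhaustive_matches_after_reduction(g)

    def test_monotone_and_bounded_rule_applications(self, rng):
        for _ in range(100):
            g = random_andnot_network(rng, rng.randint(1, 12))
            h, trace = reduce_andnot(g)
            assert h.n <= g.n
            m_edges = len(wiring_diagram(g).edges)
            assert sum(trace.rule_counts.values()) <= g.n + m_edges
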