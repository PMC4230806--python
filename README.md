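# bnsteady

Exact steady-state (fixed-point) computation for Boolean molecular network
models.

Boolean networks are a standard coarse-grained formalism for gene-regulatory
and signaling systems: each molecular species is a variable over
`K = {0, 1}` with an update rule in the others, and the synchronous update
defines a map `f : K^n -> K^n`. A *steady state* is a state with
`f(x) = x` — the discrete analogue of an equilibrium, typically interpreted
as a stable cellular phenotype. Enumerating all steady states by scanning
the `2^n` state space stops being feasible near `n ≈ 30`, while published
models now exceed 100 nodes; sampling-based approaches can miss attractors
entirely. `bnsteady` is for modelers who need *all* fixed points of such
models, exactly, at sizes where brute force fails.

## Method

The solver is algebraic, not heuristic, and proceeds in stages that each
preserve the steady-state set up to an explicit bijection:

1. **AND-NOT transform** — any network `f` on `n` variables is rewritten,
   by introducing auxiliary variables, as a network `g` on `m ≥ n`
   variables whose every update is a conjunction of literals
   (`y1 ∧ y2 ∧ …` with `y_i ∈ {x_i, ¬x_i}`). For example
   `f1 = ¬x2 ∧ (x3 ∨ x4)` becomes `f1 = ¬x2 ∧ ¬x5` with a new node
   `f5 = ¬x3 ∧ ¬x4`. Steady states of `f` are the projections of those of
   `g` to the first `n` coordinates.
2. **Wiring-diagram reduction** — `g` is determined by its signed digraph,
   which is shrunk by steady-state-preserving rules (constant propagation,
   unit-input aliasing, sink removal, feed-forward edge redundancy) to a
   reduced AND-NOT network `h` on `l ≤ m` variables, with a replayable
   trace.
3. **GF(2) polynomial solving** — via the dictionary `x∧y ⇔ xy`,
   `x∨y ⇔ x+y+xy`, `¬x ⇔ x+1`, the fixed-point conditions become the
   square-free polynomial system `h_i + x_i = 0` over the two-element
   field. Its solutions are enumerated exactly with a reduced
   lexicographic Gröbner basis (Buchberger in the Boolean quotient ring)
   plus back-substitution, preceded by generalized Gaussian elimination and
   component decomposition for large sparse systems.
4. **Backtracking and projection** — solutions are lifted through the
   reduction trace back to `g` and truncated to the original variables.
   Every emitted state is re-verified with `f(x) = x` before being
   returned.

Two independent oracles — exhaustive scan and feedback-vertex-set
enumeration (fix the coordinates of a vertex set `S` whose removal makes the
dependency graph acyclic; propagate the rest; check the `2^|S|`
candidates) — are built in for cross-validation, together with seeded
Kauffman N-K and power-law in-degree benchmark generators.

## Worked example

A toggle switch gated by two inputs, in the line-rule dialect
(`&`/`|`/`!`/`^` or `AND`/`OR`/`NOT`/`XOR`; inputs are self-looped so both
environments are explored):

```sh
$ cat toggle.txt
GeneA = !GeneB & Signal
GeneB = !GeneA & Signal
Signal = Signal

$ bnsteady solve toggle.txt --method pipeline
stages: n=3 -> m=3 -> l=3; rules {'R1': 0, 'R2': 0, 'R3': 0, 'R4': 0}
3 steady state(s) via pipeline
GeneA,GeneB,Signal
0,0,0
0,1,1
1,0,1
```

With the signal off everything is off (`000`); with it on, the mutual
inhibition locks into one of the two antipodal expression states (`011`,
`101`) — the classic bistable switch, with the environment bit carried
along as a free input. `bnsteady verify toggle.txt` re-derives the same
set with an independent oracle and reports agreement;
`bnsteady reduce` prints the reduced AND-NOT model;
`bnsteady generate kauffman -n 1000 -k 2 --seed 1` emits benchmark
networks. A BoolNet-style `targets, factors` table is accepted
interchangeably. Steady states can be written as CSV, JSON, or bitstrings,
and wiring diagrams exported as SIF or DOT.

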