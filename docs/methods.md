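# Methods

## Model and problem

A Boolean network on variables `x1..xn` over `K = {0,1}` assigns each
variable an update function `f_i : K^n -> K`; synchronous application
defines `f : K^n -> K^n`. The package computes the set
`S = {x : f(x) = x}` of steady states (fixed points) exactly — no
sampling, no heuristics. Asynchronous dynamics, trajectories, and limit
cycles of period greater than one are out of scope: only `f(x) = x` is
ever decided, and that condition is update-schedule-independent.

Environmental inputs are modeled as self-loops (`x = x`), which leaves
both environments in the solution set; writing `x = 0` or `x = 1` pins
one. The parser therefore rejects symbols that are referenced but never
defined, rather than guessing their role.

## Pipeline

### 1. AND-NOT transform (`transform.boolean_to_andnot`)

Expressions are preprocessed by XOR expansion (`a^b` →
`(a&!b)|(!a&b)`), constant folding, and negation normal form, then
converted structurally: a literal stays a literal; an AND becomes the
conjunction of its operands' literals, with an auxiliary node introduced
for any operand that is not a literal; an OR of operands `e1..ek`
becomes `!a` where the auxiliary `a = !l(e1) & ... & !l(ek)` (De
Morgan). The conversion is structural rather than DNF-based, so
`!x2 & (x3 | x4)` costs exactly one auxiliary, and it never blows up
exponentially. Auxiliaries are named `_aux<k>` in a deterministic
left-to-right, node-order traversal and share definitions (identical
conjunctions are reused).

Correctness argument: auxiliary definitions form an acyclic hierarchy
over the original variables, so at any fixed point of `g` the auxiliary
values are the unique consistent extension of the first `n` coordinates,
and the first `n` coordinates are fixed under `f` iff the extended state
is fixed under `g`. Projection to the first `n` coordinates is therefore
a bijection between the two steady-state sets; the code enforces
injectivity at run time and fails loudly if it is ever violated.

Wide gates are layered to fan-in 8 (`balance_fanin`) before conversion.
This bounds the GF(2) expansion of any one conjunction at `2^8` + 1
monomials — without it, a node with a dense 12-input rule would produce
a single conjunction of thousands of negative literals whose polynomial
has astronomically many terms. The extra auxiliaries are cheap: they are
linear in the expression size and most are eliminated again downstream.

### 2. Wiring-diagram reduction (`reduction.reduce_andnot`)

An AND-NOT network is fully described by its signed wiring diagram. Four
rules shrink it while keeping the steady-state sets in an explicit
bijection; each removal is recorded in a trace that is replayed in
reverse to reconstruct the removed coordinates:

* **R1 constant propagation** — a constant node's literal is absorbed
  into each target (dropped if satisfied, else the target becomes
  constant 0); at a fixed point the node must hold its constant.
* **R2 unit-input elimination** — a node `y` with a single regulator
  `x != y` satisfies `y = ±x` at every fixed point, so occurrences of
  `y` are replaced by the sign-composed literal of `x`; duplicate
  literals merge and opposite-sign collisions force constant 0.
* **R3 sink elimination** — a node with no targets and no self-loop
  constrains nothing; its value is recomputed from its recorded
  conjunction during backtracking.
* **R4 feed-forward redundancy** — with edges `x -s-> y`, `y -+-> z`,
  `x -s-> z`, any fixed point has `y <= x^s`, hence `y & x^s = y` and
  the direct `x` literal in `z` is redundant; the edge is deleted.

Rules are applied in the order R1 (to exhaustion), R2, R4, R3, with
declaration-order tie-breaks and a restart after every change, so traces
are reproducible. R1–R3 each remove a node and R4 removes an edge, so
the loop terminates after at most `m + |edges|` applications. Nodes with
self-loops are never reduced: a positive self-input is an environmental
degree of freedom, and a negative self-loop is handled exactly by the
algebra (its equation is `1 = 0` when isolated). Note that R2 applies to
bare feedback loops as well — the two-node toggle `x1 = !x2, x2 = !x1`
legitimately collapses to a single self-input node, with both antipodal
states restored by backtracking. If reduction consumes the entire
network, the last constant node is kept as an anchor so the result is
still a well-formed one-node network.

Every backtracked state is verified with `is_steady_state` against the
pre-reduction network; a failure raises an internal-consistency error
rather than returning a wrong answer.

### 3. GF(2) encoding and solving (`algebra`)

The dictionary `x∧y ⇔ xy`, `x∨y ⇔ x+y+xy`, `¬x ⇔ x+1` maps each Boolean
function to its unique square-free polynomial over the two-element
field; fixed points of the reduced network `h` are the solutions of
`p_i := h_i + x_i = 0`. Polynomials are stored as sets of square-free
monomials; internally a monomial is an integer bitmask whose most
significant bit is the lex-greatest variable, so native integer
comparison *is* the lexicographic term order, multiplication is bitwise
OR, and addition is symmetric difference.

The Gröbner engine is Buchberger's algorithm run directly in the Boolean
quotient ring (exponents truncated to 1, making the field relations
`x² = x` implicit). The pair queue holds the usual S-pairs — pruned by
the product criterion and selected smallest-lcm-first — plus, for each
basis element `f = m + t` and each variable `v` dividing `m`, the
S-polynomial against the field relation, which reduces to `v·t + m`
computed square-free. The final basis is inter-reduced; it equals `{1}`
exactly when the system has no GF(2) solutions. An independent
cross-check in the test suite compares varieties and triviality against
sympy's lex Gröbner bases over GF(2) with the field polynomials appended
explicitly.

Root enumeration is exact and layered:

* **Unit propagation** — equations reduced to `x` or `x + 1` force the
  variable.
* **Generalized Gaussian elimination** — an equation `x + q = 0` whose
  `x` divides no other monomial of the equation determines `x = q`
  exactly; `q` is substituted everywhere and the definition recorded for
  reverse replay. Definitions are capped at 1024 monomials and
  substitutions at a predicted 8192 monomials, so chains cannot blow up;
  capped candidates are simply skipped.
* **Component decomposition** — equations sharing no variables are
  solved independently and recombined as a Cartesian product; variables
  in no equation are free and double the count.
* **Base case** — components with at most 26 variables and at most 600
  total monomials go to the Gröbner engine followed by
  back-substitution (variables assigned from the lex-least upward,
  branching where the triangular basis leaves a value unconstrained).
  Larger or denser components are first split by branching on the
  variable occurring in the most monomials; both branches re-enter the
  full procedure.

Exactness does not depend on the branching heuristics: every polynomial
ever derived lies in the ideal of the input system together with the
field relations, so pruning on a nonzero constant never discards a true
solution, both branch values are always explored, and every complete
assignment is verified against the input equations before being
accepted. The solution set is also invariant under the elimination
order, which the suite checks by re-solving under a reversed order.

The default elimination order puts rare variables first (ascending count
of monomial occurrences, ties by declaration index); rare-first
empirically keeps intermediate bases small. A configurable solution cap
(default 65536) raises a loud error instead of silently truncating —
relevant mainly for networks with many free inputs, where the count is
exponential by nature. An optional wall-clock deadline threads through
the Gröbner loop and the search and raises a timeout error; dense
high-connectivity models can genuinely be out of reach, and the artifact
is designed to fail loudly there.

## Oracles (`oracles`)

Two independent methods validate the pipeline:

* **Exhaustive scan** — all `2^n` states evaluated in one vectorized
  numpy pass; refused above `n = 22` by default so an accidental `2^50`
  scan cannot hang.
* **Feedback-vertex-set enumeration** — a vertex set `S` whose removal
  leaves the dependency graph acyclic determines all other coordinates
  of any fixed point: the remainder is evaluated in topological order
  for each of the `2^|S|` assignments (vectorized in blocks of `2^16`),
  and candidates are kept iff `f(x) = x`. Dependency edges come from
  syntactic occurrence after constant folding, so vacuous mentions
  create no phantom edges. `find_fvs` is exact (branch and bound over
  shortest cycles, self-loops forced) for graphs up to 25 nodes and
  greedy (remove the node on the most shortest cycles, ties by
  declaration order) above; only validity — rechecked by an acyclicity
  test — is load-bearing, minimality is an optimization.

## Benchmark generators (`generators`)

The generators define the study conditions for validation:

* **Kauffman N-K** — each node draws exactly K distinct regulators
  uniformly (self allowed unless `allow_self=False`) and an update rule
  from a truth table of `2^K` i.i.d. fair bits. Tables are rendered as
  full DNF so the drawn wiring is explicit in the rule text; the
  all-false table becomes the contradictory conjunction
  `r1 & !r1 & r2 & ...` for the same reason.
* **Power-law in-degree** — in-degrees follow `P(k) ∝ k^-γ` truncated to
  `1..n-1`. The exponent defaults to γ = 2.5, in the 2–3 range reported
  for biological in-degree distributions, and is calibrated by bisection
  so the distribution mean hits the requested average connectivity
  `<k>`; whole degree sequences are redrawn until the sample mean is
  within 5% of the target. Nodes of in-degree above 12 receive nested
  canalyzing rules instead of explicit tables (a `2^k` table is no
  longer representable); the nested canalyzing family — random input
  order, canalyzing value and output per input, last input
  non-degenerate — is also available for all nodes via
  `functions="ncf"`.

Equal seeds give byte-identical rule files (numpy `default_rng`
throughout).

What the synthetic corpora do and do not show: random tables are
unbiased in a way biological rules are not (real rules are heavily
canalyzing and far sparser in their truth tables), and random wiring
lacks the modularity and long-tailed out-degrees of curated models.
Passing the validation therefore demonstrates correctness of the
machinery on the standard benchmark classes, and scalability on sparse
random topologies; it does not by itself bound running time on dense
curated models, where the algebra stage can still be expensive.

## Validation design and problem sizes

The suite's end-to-end checks mirror the method's own validation logic:
pipeline output must equal the exhaustive scan set-for-set on 10,000
mixed seeded networks (Kauffman K ∈ {1,2,3}, power-law `<k>` ∈ {2,3},
n = 3..14), and equal the FVS oracle on 200 Kauffman K=2 networks at
n = 50, where exhaustive scanning is impossible. Steady-state counts are
conserved across every stage boundary on 2,000 networks small enough to
scan at each stage; the algebra solver is checked against scans on 2,000
AND-NOT networks up to 14 nodes and under two elimination orders on a
200-network subset. Closed forms (identity cube `2^n`, negation loop 0,
toggle `{01,10}`, acyclic networks exactly 1) and one n = 1000 Kauffman
K=2 solve complete the set. These sizes keep the whole suite around
four minutes on one CPU while exercising every stage at scales where
each cross-check is independently computable; `scripts/acceptance.py`
re-runs the same design with moderately smaller corpora and reports the
measured agreement rates.

## Numerical and degenerate-input choices

* State vectors are ordered by declaration; bitstrings print
  left-to-right in that order.
* Steady-state sets serialize sorted as ascending binary integers, so
  output is deterministic across runs.
* A conjunction containing both `x` and `!x` normalizes to constant 0 at
  construction; an empty conjunction is constant 1.
* `solve` auto-selects brute force at `n <= 18` (unbeatable at that
  size) and the pipeline above.
* Every `solve` result, whatever the method, is re-verified
  state-by-state against `f` before being returned; internal errors are
  never downgraded to wrong answers.

## Known limitations

* Dense networks (mean in-degree well above 3) can exhaust the algebra
  stage; the timeout and cap errors are the intended failure mode.
* The reduction rule set is the fixed catalog R1–R4; further sound
  motifs (e.g. two-node subsumption) could shrink `h` further and can be
  added behind the same property suite.
* The FVS heuristic makes no minimality guarantee above 25 nodes, so
  `enumerate_via_fvs` on large graphs may face more candidates than the
  optimum would give.
* Only synchronous fixed points are computed; limit cycles and basin
  structure are explicitly out of scope.
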