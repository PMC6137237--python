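# Methods

## Model class and dynamics

A logical regulatory graph is a list of components `g_i` with finite
domains `D_i = {0, …, M_i}` and logical functions `K_i : S → D_i`, stored
as explicit truth tables over each component's declared regulators. Truth
tables keep evaluation unambiguous and make exhaustive validation cheap
(at the typical 2–4 regulators a table has at most a few dozen rows);
validating the table also proves `K_i(v) ∈ D_i` for *every* state, since
`K_i` depends only on the regulator levels.

Asynchronous updating: state `w` is a successor of `v` iff exactly one
component `i` has `K_i(v) ≠ v_i` and `w` moves that component one unit
toward the target (`w_i = v_i + sign(K_i(v) − v_i)`). Multi-valued
components therefore never jump levels; no jump mode is offered. Input
components carry the identity function on their own level, so the dynamics
freeze them automatically and their value is set by the initial condition
or sampled in whole-state-space mode. Concurrent transitions are uniformly
probable (`1/|Succ(v)|`); the machinery accepts any per-state distribution
(the rewiring analysis relies on this), but no other scheme is exposed.

States are identified by a reversible mixed-radix key, little-endian in
component order: `key(v) = Σ_i v_i · Π_{j<i}(M_j + 1)`. The key is the
canonical identity in all sets and maps; algorithms see only a successor
function over keys, so hand-built explicit graphs can drive them in place
of a model.

## Exact route

For a reachable state space that fits in memory, the STG is built by
breadth-first closure (with a hard node budget that fails cleanly),
decomposed into SCCs by an *iterative* Tarjan — recursion depth would
otherwise reach the number of states on long chains — and reduced to an
absorbing chain: each terminal SCC is collapsed to a single absorbing
class before assembling the transient block `Q` and the exit block `L`,
so the linear system has one column per attractor. Row sums of `[Q | L]`
are checked to 1e-9 at assembly.

The solve is dense (`numpy.linalg.solve`) below 2 000 transient states and
sparse LU (`scipy.sparse.linalg.splu`) above; `Q` has out-degree at most
the number of components, so the system is very sparse. An independent
check, `power_iteration`, propagates the initial law through the chain,
accumulating the mass crossing into each class until the transient mass
falls below a tolerance (default 1e-12); reaching the step cap returns a
flagged partial result rather than raising. The two routes agree to 1e-9
across the test batches, which is the package's internal consistency
guarantee for everything that uses the exact solver as ground truth.

## Firefront

One expansion is a synchronized whole-frontier step: every state in `F`
sends `p/|Succ|` to each successor, all contributions to a target are
summed *before* the neglect test, so the processing order of `F` is
irrelevant; a target below `α` is parked in `N` (its mass accumulating
across visits and promoted back to `F` once it crosses `α`); a state with
no successors, or one recognized by an oracle or a previously certified
complex attractor, banks its mass in `A`. Total mass is conserved to
floating-point accuracy at every step.

Termination: `F` empty, `mass(F) ≤ β`, the expansion budget, or a
periodicity detection that empties `F`. Reported bounds per attractor:
`lower = mass banked in A`, `upper = lower + mass(N) + mass(F at halt)`.
The upper bound uses the actual frontier mass rather than `β` because
`mass(F) ≤ β` at a β-halt, so it is never looser and equals the β-form at
the boundary. Attractors never discovered are implicitly bounded by
`[0, mass(N) + mass(F)]`. Mass left in `N` is reported as residual only —
it is never re-expanded.

**Periodicity detection.** A ring buffer (default 64 entries, configurable)
keeps recent frontier snapshots; a snapshot is the set of
*(state, probability)* pairs, screened by hash and confirmed by exact set
comparison, so hash collisions cannot trigger a detection. When the same
snapshot occurs a third time, the union of supports between the second and
third occurrences is the candidate attractor. Two deliberate design
choices make the heuristic sound rather than merely plausible:

1. Probabilities are part of the snapshot. The *support* of a transient
   cycle recurs while its mass decays; including the probabilities means a
   repeat can only happen where the rotating mass is conserved, i.e.
   inside a terminal structure.
2. The candidate is verified: it is SCC-decomposed, and only subsets that
   are strongly connected *and closed under the successor function* are
   certified (such a set is provably a terminal SCC). Mass split over two
   disjoint deterministic cycles repeats the frontier, and verification
   then certifies the two terminal SCCs separately instead of merging
   them.

The cost of soundness is sensitivity: a complex attractor whose internal
branching keeps mixing mass never repeats exactly and is not detected; the
run then ends at the expansion budget with the attractor's mass still in
`F`, and the bounds remain valid. Oracles (known attractor descriptions,
as level patterns or explicit keys) short-circuit this entirely.

Defaults: `α = 1e-5`, `β = 1e-4`, 1000 expansions. The expansion budget is
a conventional default for this class of tool; `α` and `β` were chosen so
that ten-component random models distribute essentially all of their mass
(≥ 99.9 % in the test batches) while keeping frontiers small. All three
are exposed on the CLI.

## Avatar

A walk samples successors uniformly (or per the current overrides) until
it reaches a successorless state (a stable state), a state recognized by
an oracle, or a state already on its visited set — a cycle. The cycle is
the walk segment between the two visits; because the segment is a closed
walk of the current incarnation, it is always strongly connected there.

*Extension*: breadth-first exploration up to `τ` transitions from the
cycle states; the SCC (within that ball) containing the revisited state is
the extended cycle. `τ` starts at 3, doubles on each successive extension
within a run, and resets between runs — a cheap first attempt with rapid
escalation for large transients. With a horizon covering the SCC the
extension is exactly the SCC containing the cycle.

*Rewiring*: with `q` and `r` the within-set and exit blocks of the current
incarnation, each set state's transitions are replaced by its row of
`r¹ = (I − q)^{-1} r` over the exits (dense solve below 400 states, sparse
LU above; rows are clipped at zero and renormalized against rounding).
Replacing `q` by 0 and `r` by `r¹` preserves the absorption distribution
of the chain exactly — the geometric series `Σ q^k r` is precisely the
asymptotic exit law — which the test suite verifies to 1e-9 on planted
transient SCCs up to 200 states. The *approximate* strategy assigns
uniform exit probabilities instead: no solve, guaranteed escape, but
biased whenever the true exit law is not uniform (the bias is measured,
not hidden). An extended set with *no* exits is a terminal SCC: the walk
reports it as a complex attractor.

*Ceiling* (default 10 000 states): an extended set above the ceiling is
truncated by breadth-first growth from the current state, reduced to the
strongly connected subset containing it (falling back to a segment of the
detected cycle if no cyclic subset fits). Rewiring a subset of a transient
SCC is always sound — every subset state still reaches an exit, so
`I − q` stays nonsingular — just less effective per incarnation; the walk
re-triggers with a doubled horizon.

After a rewiring, the dismantled states are removed from the walk's
revisit-trigger set: their overrides jump straight to exits, and stale
path segments through removed edges are no longer cycles of the current
incarnation. Overrides are cached across runs by default (`keep_cache`),
never mixing strategies; `generation` counts incarnations.

*Attractor identity across incarnations.* Partial rewirings inside a
terminal SCC can disconnect it in the incarnation, so the final exit-less
extension may be a strict subset of the attractor. Every rewired or
terminal set is therefore recorded in a union-find over its member states;
sets sharing a state merge, and a complex attractor is reported as the
union of its equivalence class. Transient and terminal classes can never
merge: no incarnation contains a path from a terminal state out of its
SCC.

Estimates are `hits/runs` with 95 % Wilson intervals (well-behaved near 0
and 1); runs that exhaust the per-walk step cap (default 10⁶) count as
inconclusive, so reported probabilities sum to at most 1 with equality when
every run concludes. Mean depth is the mean number of walk steps until
absorption, counting each post-rewiring jump as one step — a package
convention, since a jump summarizes arbitrarily many original transitions.
Per-run random streams are derived from the root seed and the run index,
so results are reproducible and independent of scheduling; identical seed
and parameters give identical results, which is asserted in the suite.

Whole-state-space mode draws each run's start uniformly over the
unconstrained components; named components (typically inputs) can be
pinned. The plain Monte-Carlo baseline shares the aggregation but does no
cycle handling; its `support` (conclusive fraction) collapses on dynamics
with complex attractors or hard-to-leave transient cycles, which is the
motivating failure mode.

## Synthetic inputs

Random models follow the standard random Boolean network recipe: each of
`n` components gets `k` distinct regulators drawn uniformly and a truth
table with uniformly drawn entries; generation is bit-reproducible from
the seed. Degenerate (constant) rules are kept; callers needing a given
attractor structure screen seeds with the exact solver. Test batches use
`n = 8–10`, `k = 2`, matching the scale at which the full state space
(≤ 1024 states) can be solved exactly and the estimators meaningfully
compared; planted fixtures (pure cycles, transient SCCs of 4–200 states
with 1–5 exits and random chords for asymmetric exit laws) supply the
cyclic structure that random two-regulator models rarely produce at that
size.

What the generator does *not* emulate: the regulator-count heterogeneity,
canalizing structure and input components of curated biological models,
or state spaces beyond exhaustive reach. Passing tests therefore certify
the algorithms' correctness contracts (conservation, bracketing,
rewiring-invariance, binomial-level accuracy against ground truth) on
dynamics whose ground truth is computable — not performance claims on
models whose state spaces cannot be enumerated.

## Numerical choices and limitations

* Row-sum checks at 1e-9; solver cross-validation and rewiring invariance
  asserted at 1e-9; conservation at 1e-9 per expansion.
* Dense/sparse thresholds: 2 000 transient states (absorption solve), 400
  cycle states (rewiring solve).
* State strings are one character per component, so models with
  `M_i > 9` are rejected at CLI load (library use is unaffected).
* CLI seeds default to a fresh random value that is always echoed in the
  result document, making every run reproducible after the fact.
* Firefront offers no guarantee of detecting a complex attractor without
  an oracle when the frontier never exactly repeats; the bounds degrade
  gracefully instead.
* The `largestTransientSCC` diagnostic reports the largest extended cycle
  with exits encountered by the walks, which can undershoot the true SCC
  size when the horizon never needed to cover it.
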