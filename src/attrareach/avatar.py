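"""Monte-Carlo random walks with exact cycle rewiring (Avatar).

A plain random walk over an asynchronous state transition graph estimates
attractor reachability but fails on cyclic structure: it re-visits
transient cycles an unbounded number of times and never leaves a terminal
cycle at all.  Avatar detects a cycle the moment the walk returns to a
state it has already visited, enlarges the detected cycle toward the full
strongly connected component by a depth-bounded search (depth ``tau``,
doubled on every successive attempt within a run), and then *rewires* the
dynamics: all transitions internal to the cycle set ``C`` are removed and
replaced by direct transitions to the exit states ``B``, weighted by the
asymptotic exit distribution

    r1 = (I - q)^{-1} r

where ``q`` and ``r`` are the within-cycle and cycle-to-exit blocks of the
current transition matrix.  This preserves the absorption probabilities of
the chain exactly, so the rewired walk reaches each attractor with the
same probability as the original dynamics while taking finitely many
steps.  A cycle set with no exits is a terminal SCC, i.e. a complex
attractor.  Each rewiring produces a new *incarnation* of the dynamics;
incarnations may be cached across simulations.

An approximate rewiring strategy (uniform probability over the exits) is
also provided; it avoids the linear solve but biases the estimates
whenever the exact exit distribution is not uniform.
"""

from __future__ import annotations

import math
import random
from collections import deque
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .io import Oracle
from .model import DynamicsProvider, StateKey

_DENSE_REWIRE_LIMIT = 400  # dense solve below this many cycle states

Override = tuple[tuple[StateKey, ...], tuple[float, ...]]


@dataclass(frozen=True)
class AvatarParams:
    """Simulation parameters.

    runs:
        Number of independent random walks aggregated into the estimate.
    tau_init:
        Initial extension depth when enlarging a detected cycle toward
        its SCC; doubled on every successive extension within a run and
        reset between runs.
    ceiling:
        Largest cycle set rewired exactly; larger extended cycles are
        truncated to a connected cyclic subset of at most this size.
    strategy:
        'exact' solves the linear system for the asymptotic exit
        distribution; 'approx' assigns uniform probabilities to the exits.
    max_steps:
        Per-simulation step cap; a walk that exhausts it is counted as
        inconclusive, not raised.
    keep_cache:
        Reuse rewiring overrides computed in earlier runs of the same
        invocation.
    """

    runs: int = 10_000
    tau_init: int = 3
    ceiling: int = 10_000
    strategy: str = "exact"
    max_steps: int = 1_000_000
    keep_cache: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.runs < 1:
            raise ValueError("runs must be >= 1")
        if self.tau_init < 1:
            raise ValueError("tau_init must be >= 1")
        if self.ceiling < 2:
            raise ValueError("ceiling must be >= 2")
        if self.strategy not in ("exact", "approx"):
            raise ValueError("strategy must be 'exact' or 'approx'")
        if self.max_steps < 1:
            raise ValueError("max_steps must be >= 1")


@dataclass
class Incarnation:
    """Per-invocation transition overrides produced by cycle rewiring."""

    overrides: dict[StateKey, Override] = field(default_factory=dict)
    generation: int = 0


class AttractorRegistry:
    """Union-find over cycle memberships across incarnations.

    Cycles discovered in different incarnations that share a state belong
    to the same structure; the equivalence class accumulated here is what
    identifies a complex attractor across simulations.
    """

    def __init__(self) -> None:
        self._parent: dict[StateKey, StateKey] = {}
        self._members: dict[StateKey, set[StateKey]] = {}
        self._terminal: set[StateKey] = set()

    def find(self, state: StateKey) -> StateKey:
        root = state
        while self._parent[root] != root:
            root = self._parent[root]
        while self._parent[state] != root:  # path compression
            self._parent[state], state = root, self._parent[state]
        return root

    def _union(self, a: StateKey, b: StateKey) -> StateKey:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return ra
        if len(self._members[ra]) < len(self._members[rb]):
            ra, rb = rb, ra
        self._parent[rb] = ra
        self._members[ra] |= self._members.pop(rb)
        if rb in self._terminal:
            self._terminal.discard(rb)
            self._terminal.add(ra)
        return ra

    def register_cycle(self, states) -> StateKey:
        states = list(states)
        root = None
        for s in states:
            if s not in self._parent:
                self._parent[s] = s
                self._members[s] = {s}
            root = s if root is None else self._union(root, s)
        return self.find(root)

    def register_terminal(self, states) -> StateKey:
        root = self.register_cycle(states)
        self._terminal.add(root)
        return root

    def in_cycle(self, state: StateKey) -> bool:
        return state in self._parent

    def members(self, state: StateKey) -> frozenset[StateKey]:
        return frozenset(self._members[self.find(state)])


@dataclass
class CycleRecord:
    """The blocks of the transition matrix around a detected cycle.

    ``states`` lists the cycle set C in a fixed order, ``exits`` the set B
    of states directly reachable from C, ``q`` the within-cycle and ``r``
    the cycle-to-exit probability blocks of the *current* incarnation.
    """

    states: tuple[StateKey, ...]
    exits: tuple[StateKey, ...]
    q: np.ndarray
    r: np.ndarray


def _distribution(
    provider: DynamicsProvider,
    overrides: Mapping[StateKey, Override],
    state: StateKey,
) -> Override:
    ov = overrides.get(state)
    if ov is not None:
        return ov
    succ = tuple(provider.successors(state))
    if not succ:
        return ((), ())
    p = 1.0 / len(succ)
    return (succ, (p,) * len(succ))


def make_cycle_record(
    provider: DynamicsProvider,
    states: Sequence[StateKey],
    overrides: Mapping[StateKey, Override] | None = None,
) -> CycleRecord:
    overrides = overrides or {}
    states = tuple(dict.fromkeys(states))
    index = {s: i for i, s in enumerate(states)}
    exit_index: dict[StateKey, int] = {}
    rows: list[list[tuple[int, float, bool]]] = []
    for s in states:
        targets, probs = _distribution(provider, overrides, s)
        row = []
        for t, p in zip(targets, probs):
            if t in index:
                row.append((index[t], p, True))
            else:
                j = exit_index.setdefault(t, len(exit_index))
                row.append((j, p, False))
        rows.append(row)
    k, nb = len(states), len(exit_index)
    q = np.zeros((k, k))
    r = np.zeros((k, nb))
    for i, row in enumerate(rows):
        for j, p, internal in row:
            if internal:
                q[i, j] += p
            else:
                r[i, j] += p
    exits = tuple(sorted(exit_index, key=exit_index.get))
    return CycleRecord(states, exits, q, r)


def rewire_exact(rec: CycleRecord) -> dict[StateKey, Override]:
    """Asymptotic exit distribution per cycle state: ``(I - q)^{-1} r``.

    Each returned row is stochastic; the caller installs it as the
    override of the corresponding cycle state, which removes every
    within-cycle transition.
    """
    if not rec.exits:
        raise ValueError(
            "cycle has no exit; it is a terminal SCC, not rewireable"
        )
    k = len(rec.states)
    if k < _DENSE_REWIRE_LIMIT:
        r1 = np.linalg.solve(np.eye(k) - rec.q, rec.r)
    else:
        A = sp.csc_array(np.eye(k) - rec.q)
        r1 = spla.splu(A).solve(rec.r)
    r1 = np.clip(r1, 0.0, None)
    row_sums = r1.sum(axis=1, keepdims=True)
    if np.any(row_sums <= 0):
        raise ValueError("rewiring produced an empty exit row")
    r1 /= row_sums
    return _rows_to_overrides(rec, r1)


def rewire_approx(rec: CycleRecord) -> dict[StateKey, Override]:
    """Uniform probability from every cycle state to every exit.

    No linear solve, but the estimate is biased whenever the exact exit
    distribution is not uniform.
    """
    if not rec.exits:
        raise ValueError(
            "cycle has no exit; it is a terminal SCC, not rewireable"
        )
    nb = len(rec.exits)
    r1 = np.full((len(rec.states), nb), 1.0 / nb)
    return _rows_to_overrides(rec, r1)


def _rows_to_overrides(rec: CycleRecord, r1: np.ndarray) -> dict[StateKey, Override]:
    out: dict[StateKey, Override] = {}
    for i, s in enumerate(rec.states):
        targets = []
        probs = []
        for j, b in enumerate(rec.exits):
            p = float(r1[i, j])
            if p > 0.0:
                targets.append(b)
                probs.append(p)
        out[s] = (tuple(targets), tuple(probs))
    return out


def extend_cycle(
    provider: DynamicsProvider,
    cycle: Sequence[StateKey],
    tau: int,
    overrides: Mapping[StateKey, Override] | None = None,
    anchor: StateKey | None = None,
) -> frozenset[StateKey]:
    """Enlarge a detected cycle toward its SCC within a depth horizon.

    Explores up to ``tau`` transitions away from the cycle states and
    returns the strongly connected component, within that horizon, that
    contains the anchor (the revisited state).  With a horizon covering
    the whole SCC this is exactly the SCC containing the cycle; smaller
    horizons return a subset that still contains the original cycle.
    """
    overrides = overrides or {}
    cycle = list(dict.fromkeys(cycle))
    if anchor is None:
        anchor = cycle[0]
    depth = {s: 0 for s in cycle}
    queue = deque(cycle)
    local_edges: dict[StateKey, tuple[StateKey, ...]] = {}
    while queue:
        v = queue.popleft()
        targets, _ = _distribution(provider, overrides, v)
        local_edges[v] = targets
        d = depth[v] + 1
        if d > tau:
            continue
        for w in targets:
            if w not in depth:
                depth[w] = d
                queue.append(w)

    # SCCs of the subgraph induced on the explored ball
    from .stg import tarjan_scc

    induced = {
        v: tuple(w for w in targets if w in local_edges)
        for v, targets in local_edges.items()
    }
    for comp in tarjan_scc(induced):
        if anchor in comp:
            return frozenset(comp)
    return frozenset(cycle)  # unreachable; defensive


def has_exit(
    provider: DynamicsProvider,
    states: frozenset[StateKey],
    overrides: Mapping[StateKey, Override] | None = None,
) -> bool:
    overrides = overrides or {}
    for s in states:
        targets, _ = _distribution(provider, overrides, s)
        for t in targets:
            if t not in states:
                return True
    return False


def apply_ceiling(
    provider: DynamicsProvider,
    extended: frozenset[StateKey],
    ceiling: int,
    anchor: StateKey,
    cycle: Sequence[StateKey],
    overrides: Mapping[StateKey, Override] | None = None,
) -> frozenset[StateKey]:
    """Select the subset of an extended cycle to rewire.

    If the extended set fits under the ceiling it is rewired whole.
    Otherwise a breadth-first truncation grown from the anchor is reduced
    to the strongly connected subset containing the anchor; rewiring a
    subset is always sound (the rewiring is repeatable), merely less
    effective per incarnation.
    """
    if len(extended) <= ceiling:
        return extended
    overrides = overrides or {}
    picked: list[StateKey] = []
    seen = set()
    queue = deque([anchor])
    seen.add(anchor)
    while queue and len(picked) < ceiling:
        v = queue.popleft()
        picked.append(v)
        targets, _ = _distribution(provider, overrides, v)
        for w in targets:
            if w in extended and w not in seen:
                seen.add(w)
                queue.append(w)
    picked_set = set(picked)
    from .stg import tarjan_scc

    induced = {}
    for v in picked:
        targets, _ = _distribution(provider, overrides, v)
        induced[v] = tuple(w for w in targets if w in picked_set)
    for comp in tarjan_scc(induced):
        if anchor in comp and len(comp) > 1:
            return frozenset(comp)
    # no cyclic subset under the ceiling: fall back to a segment of the
    # detected cycle (a path; rewiring it still removes internal edges)
    segment = list(dict.fromkeys(cycle))[:ceiling]
    return frozenset(segment)


# ---------------------------------------------------------------------------
# Single simulation


@dataclass
class RunOutcome:
    """Result of one walk: the attractor handle (or None) and the depth."""

    kind: str  # 'stable' | 'complex' | 'oracle' | 'inconclusive'
    handle: object = None  # state key | registry representative | name
    depth: int = 0


def simulate_once(
    provider: DynamicsProvider,
    v0: StateKey,
    params: AvatarParams,
    incarnation: Incarnation,
    registry: AttractorRegistry,
    rng: random.Random,
    oracle: Oracle | None = None,
    stats: dict | None = None,
) -> RunOutcome:
    """One Avatar walk from ``v0`` (Algorithm: walk, detect, extend,
    rewire, continue), using and updating the shared incarnation."""
    overrides = incarnation.overrides
    tau = params.tau_init
    state = v0
    steps = 0
    visited: dict[StateKey, int] = {state: 0}
    path: list[StateKey] = [state]

    while steps < params.max_steps:
        if oracle is not None:
            name = oracle.identify(state)
            if name is not None:
                return RunOutcome("oracle", name, steps)
        ov = overrides.get(state)
        if ov is None:
            succ = provider.successors(state)
            if not succ:
                if registry.in_cycle(state):
                    # dismantled cycle state left with no outgoing edges:
                    # part of a complex attractor recorded earlier
                    rep = registry.find(state)
                    return RunOutcome("complex", rep, steps)
                return RunOutcome("stable", state, steps)
            nxt = succ[rng.randrange(len(succ))] if len(succ) > 1 else succ[0]
        else:
            targets, probs = ov
            if len(targets) == 1:
                nxt = targets[0]
            else:
                x = rng.random()
                acc = 0.0
                nxt = targets[-1]
                for t, p in zip(targets, probs):
                    acc += p
                    if x < acc:
                        nxt = t
                        break
        steps += 1

        if nxt in visited:
            cycle = path[visited[nxt]:]
            extended = extend_cycle(provider, cycle, tau, overrides, anchor=nxt)
            tau *= 2
            if not has_exit(provider, extended, overrides):
                rep = registry.register_terminal(extended)
                if stats is not None:
                    stats["terminal_scc"] = max(
                        stats.get("terminal_scc", 0), len(extended)
                    )
                return RunOutcome("complex", rep, steps)
            rewire_set = apply_ceiling(
                provider, extended, params.ceiling, nxt, cycle, overrides
            )
            rec = make_cycle_record(provider, tuple(rewire_set), overrides)
            if rec.exits:
                new_overrides = (
                    rewire_exact(rec)
                    if params.strategy == "exact"
                    else rewire_approx(rec)
                )
                overrides.update(new_overrides)
                incarnation.generation += 1
                registry.register_cycle(rewire_set)
                if stats is not None:
                    stats["transient_scc"] = max(
                        stats.get("transient_scc", 0), len(extended)
                    )
                    stats["rewired"] = stats.get("rewired", 0) + 1
                # dismantled states now jump straight to exits; stop
                # treating them as revisit triggers
                for s in rewire_set:
                    visited.pop(s, None)
            state = nxt
            continue

        visited[nxt] = len(path)
        path.append(nxt)
        state = nxt

    return RunOutcome("inconclusive", None, steps)


# ---------------------------------------------------------------------------
# Aggregation


def wilson_interval(hits: int, n: int, z: float = 1.959964) -> tuple[float, float]:
    """95% Wilson score interval for a binomial proportion."""
    if n == 0:
        return (0.0, 1.0)
    phat = hits / n
    denom = 1.0 + z * z / n
    center = (phat + z * z / (2 * n)) / denom
    half = (
        z * math.sqrt(phat * (1 - phat) / n + z * z / (4 * n * n)) / denom
    )
    return (max(0.0, center - half), min(1.0, center + half))


@dataclass
class AttractorEstimate:
    kind: str  # 'stable' | 'complex' | 'oracle'
    probability: float
    ci: tuple[float, float]
    mean_depth: float
    hits: int
    states: frozenset[StateKey] | None = None
    name: str | None = None

    @property
    def label(self) -> str:
        if self.name is not None:
            return self.name
        if self.kind == "stable":
            return f"stable:{min(self.states)}"
        return f"complex:{min(self.states)}x{len(self.states)}"


@dataclass
class AvatarResult:
    attractors: list[AttractorEstimate]
    runs: int
    inconclusive: int
    largest_transient_scc: int
    seed: int
    outcomes: list[tuple[str, object]] = field(default_factory=list, repr=False)

    @property
    def support(self) -> float:
        """Fraction of simulations that concluded in an attractor."""
        return 1.0 - self.inconclusive / self.runs

    def probabilities(self) -> dict[str, float]:
        return {a.label: a.probability for a in self.attractors}


def _run_seed(seed: int, run_index: int) -> int:
    child = np.random.SeedSequence([seed, run_index]).generate_state(1)[0]
    return int(child) & 0x7FFFFFFF


def _resolve_initial(provider, init, sampling, fixed_inputs, rng):
    if sampling:
        return provider.sample_state(rng, fixed_inputs)
    if init is None:
        raise ValueError("an initial state is required unless sampling")
    return init


def _aggregate(
    outcomes: list[RunOutcome],
    registry: AttractorRegistry,
    runs: int,
    largest: int,
    seed: int,
) -> AvatarResult:
    groups: dict[tuple, list[RunOutcome]] = {}
    for out in outcomes:
        if out.kind == "inconclusive":
            continue
        if out.kind == "complex":
            key = ("complex", registry.find(out.handle))
        else:
            key = (out.kind, out.handle)
        groups.setdefault(key, []).append(out)

    estimates = []
    for (kind, handle), outs in groups.items():
        hits = len(outs)
        est = AttractorEstimate(
            kind=kind,
            probability=hits / runs,
            ci=wilson_interval(hits, runs),
            mean_depth=sum(o.depth for o in outs) / hits,
            hits=hits,
            states=(
                frozenset({handle})
                if kind == "stable"
                else registry.members(handle) if kind == "complex" else None
            ),
            name=handle if kind == "oracle" else None,
        )
        estimates.append(est)
    estimates.sort(key=lambda e: (-e.hits, e.label))
    inconclusive = sum(1 for o in outcomes if o.kind == "inconclusive")
    resolved = [
        (
            o.kind,
            registry.find(o.handle) if o.kind == "complex" else o.handle,
        )
        for o in outcomes
    ]
    return AvatarResult(
        attractors=estimates,
        runs=runs,
        inconclusive=inconclusive,
        largest_transient_scc=largest,
        seed=seed,
        outcomes=resolved,
    )


def run_avatar(
    provider: DynamicsProvider,
    init: StateKey | None = None,
    params: AvatarParams | None = None,
    oracle: Oracle | None = None,
    sampling: bool = False,
    fixed_inputs: Mapping[str, int] | None = None,
) -> AvatarResult:
    """Aggregate ``params.runs`` Avatar walks into reachability estimates.

    With ``sampling=True`` each walk starts from a state drawn uniformly
    over the unconstrained components (``fixed_inputs`` pins named
    components), estimating the attractor distribution over the whole
    state space rather than from one initial state.  Per-run random
    streams are derived from the root seed and the run index, so results
    are reproducible and independent of scheduling.
    """
    params = params or AvatarParams()
    incarnation = Incarnation()
    registry = AttractorRegistry()
    stats: dict = {}
    outcomes: list[RunOutcome] = []
    for i in range(params.runs):
        rng = random.Random(_run_seed(params.seed, i))
        if not params.keep_cache:
            incarnation = Incarnation()
        v0 = _resolve_initial(provider, init, sampling, fixed_inputs, rng)
        outcomes.append(
            simulate_once(
                provider, v0, params, incarnation, registry, rng, oracle, stats
            )
        )
    largest = max(stats.get("transient_scc", 0), 0)
    return _aggregate(outcomes, registry, params.runs, largest, params.seed)


def run_monte_carlo(
    provider: DynamicsProvider,
    init: StateKey | None = None,
    runs: int = 10_000,
    max_depth: int = 1_000_000,
    seed: int = 0,
    sampling: bool = False,
    fixed_inputs: Mapping[str, int] | None = None,
) -> AvatarResult:
    """Plain Monte-Carlo baseline: random walks with no cycle handling.

    A walk halts only at a stable state (no successor) or at the depth
    cap; walks trapped in complex attractors or long transient cycles end
    inconclusive, so the reported ``support`` (conclusive fraction) drops
    below 1 exactly where cycle-aware exploration is needed.
    """
    if max_depth < 1:
        raise ValueError("max_depth must be >= 1")
    registry = AttractorRegistry()
    outcomes: list[RunOutcome] = []
    for i in range(runs):
        rng = random.Random(_run_seed(seed, i))
        state = _resolve_initial(provider, init, sampling, fixed_inputs, rng)
        outcome = RunOutcome("inconclusive", None, max_depth)
        for step in range(max_depth):
            succ = provider.successors(state)
            if not succ:
                outcome = RunOutcome("stable", state, step)
                break
            state = succ[rng.randrange(len(succ))] if len(succ) > 1 else succ[0]
        outcomes.append(outcome)
    return _aggregate(outcomes, registry, runs, 0, seed)
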