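"""Explicit state transition graphs and exact absorption probabilities.

For models whose reachable state space fits in memory, the asynchronous
dynamics define a finite absorbing Markov chain: attractors are the terminal
strongly connected components (SCCs) of the state transition graph, and the
probability of reaching each attractor from an initial state is obtained by
solving a sparse linear system on the transient part of the chain.

Writing the transition matrix in canonical form

    pi = [[Q, L],
          [0, I]]

with ``Q`` the transient-to-transient block and ``L`` the transient-to-
absorbing block (each attractor collapsed to a single absorbing class), the
absorption probabilities from transient state ``u`` are the rows of
``(I - Q)^{-1} L``.  :func:`solve_absorption` computes them by a direct
solve; :func:`power_iteration` propagates the initial law through the chain
step by step until the transient mass vanishes, providing an independent
numerical route to the same quantities.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .model import DynamicsProvider, StateKey, transition_probabilities

_DENSE_LIMIT = 2000  # direct dense solve below this many transient states


class LimitExceeded(RuntimeError):
    """Raised when an exploration would exceed its node budget."""

    def __init__(self, limit: int, count: int) -> None:
        super().__init__(
            f"state-space exploration exceeded limit {limit} "
            f"(reached {count} states)"
        )
        self.limit = limit
        self.count = count


@dataclass
class ExplicitSTG:
    """A reachability-closed transition graph over state keys."""

    edges: dict[StateKey, tuple[StateKey, ...]]
    roots: tuple[StateKey, ...] = ()

    @property
    def nodes(self) -> list[StateKey]:
        return sorted(self.edges)

    @property
    def n_edges(self) -> int:
        return sum(len(t) for t in self.edges.values())

    def successors(self, state: StateKey) -> tuple[StateKey, ...]:
        return self.edges[state]


def explore_reachable(
    provider: DynamicsProvider,
    roots: Iterable[StateKey],
    limit: int = 1_000_000,
) -> ExplicitSTG:
    """Breadth-first closure of ``roots`` under the successor function."""
    if limit <= 0:
        raise ValueError("limit must be positive")
    roots = tuple(dict.fromkeys(roots))
    edges: dict[StateKey, tuple[StateKey, ...]] = {}
    queue = deque(roots)
    seen = set(roots)
    if len(seen) > limit:
        raise LimitExceeded(limit, len(seen))
    while queue:
        v = queue.popleft()
        succ = tuple(provider.successors(v))
        edges[v] = succ
        for w in succ:
            if w not in seen:
                seen.add(w)
                if len(seen) > limit:
                    raise LimitExceeded(limit, len(seen))
                queue.append(w)
    return ExplicitSTG(edges, roots)


# ---------------------------------------------------------------------------
# Strongly connected components


@dataclass
class SCCDecomposition:
    sccs: list[tuple[StateKey, ...]]
    terminal: list[bool]
    component_of: dict[StateKey, int]


def tarjan_scc(edges: Mapping[StateKey, Sequence[StateKey]]) -> list[tuple[StateKey, ...]]:
    """Tarjan's algorithm with an explicit stack.

    Iterative on purpose: recursion depth would otherwise reach the number
    of states on long chains or large cycles.
    """
    index: dict[StateKey, int] = {}
    low: dict[StateKey, int] = {}
    on_stack: set[StateKey] = set()
    stack: list[StateKey] = []
    sccs: list[tuple[StateKey, ...]] = []
    counter = 0

    for root in edges:
        if root in index:
            continue
        work: list[tuple[StateKey, int]] = [(root, 0)]
        while work:
            v, pi = work[-1]
            if pi == 0:
                index[v] = low[v] = counter
                counter += 1
                stack.append(v)
                on_stack.add(v)
            recurse = False
            succ = edges.get(v, ())
            for i in range(pi, len(succ)):
                w = succ[i]
                if w not in index:
                    work[-1] = (v, i + 1)
                    work.append((w, 0))
                    recurse = True
                    break
                if w in on_stack:
                    low[v] = min(low[v], index[w])
            if recurse:
                continue
            work.pop()
            if low[v] == index[v]:
                comp = []
                while True:
                    w = stack.pop()
                    on_stack.discard(w)
                    comp.append(w)
                    if w == v:
                        break
                sccs.append(tuple(comp))
            if work:
                u, _ = work[-1]
                low[u] = min(low[u], low[v])
    return sccs


def decompose_scc(stg: ExplicitSTG) -> SCCDecomposition:
    """SCC partition plus terminal flags from the condensation."""
    sccs = tarjan_scc(stg.edges)
    component_of = {}
    for idx, comp in enumerate(sccs):
        for v in comp:
            component_of[v] = idx
    terminal = [True] * len(sccs)
    for v, succ in stg.edges.items():
        cv = component_of[v]
        for w in succ:
            if component_of[w] != cv:
                terminal[cv] = False
    return SCCDecomposition(sccs, terminal, component_of)


@dataclass(frozen=True)
class Attractor:
    """A terminal SCC: a stable state if singleton, else a complex attractor."""

    states: frozenset[StateKey]

    @property
    def is_stable(self) -> bool:
        return len(self.states) == 1

    @property
    def kind(self) -> str:
        return "stable" if self.is_stable else "complex"

    def __repr__(self) -> str:
        inner = sorted(self.states)
        if len(inner) > 6:
            shown = ", ".join(map(str, inner[:6])) + ", ..."
        else:
            shown = ", ".join(map(str, inner))
        return f"Attractor({self.kind}, {{{shown}}})"


def attractors_of(stg: ExplicitSTG) -> list[Attractor]:
    decomp = decompose_scc(stg)
    atts = [
        Attractor(frozenset(comp))
        for comp, term in zip(decomp.sccs, decomp.terminal)
        if term
    ]
    return sorted(atts, key=lambda a: min(a.states))


# ---------------------------------------------------------------------------
# Absorption


@dataclass
class AbsorptionProblem:
    """Canonical-form blocks of the chain stopped at its attractors."""

    transient: list[StateKey]
    classes: list[Attractor]
    Q: sp.csr_array
    L: sp.csr_array
    initial_law: dict[StateKey, float]
    index: dict[StateKey, int] = field(repr=False, default_factory=dict)
    class_of: dict[StateKey, int] = field(repr=False, default_factory=dict)


@dataclass
class AbsorptionResult:
    probabilities: dict[Attractor, float]
    residual: float = 0.0
    converged: bool = True
    steps: int = 0


ProbabilityFn = Callable[[StateKey], Mapping[StateKey, float]]


def build_absorption(
    stg: ExplicitSTG,
    initial_law: Mapping[StateKey, float] | None = None,
    probabilities: ProbabilityFn | None = None,
) -> AbsorptionProblem:
    """Assemble the Q and L blocks of the stopped chain.

    ``probabilities`` maps a state to its outgoing distribution; by default
    concurrent transitions are uniform.  Passing a custom function lets the
    caller analyse a modified chain (e.g. one with rewired cycles) over the
    same node set.  Each absorbing class is collapsed to a single sink, so
    ``L`` has one column per attractor.
    """
    decomp = decompose_scc(stg)
    classes = []
    class_of: dict[StateKey, int] = {}
    for comp, term in zip(decomp.sccs, decomp.terminal):
        if term:
            for v in comp:
                class_of[v] = len(classes)
            classes.append(Attractor(frozenset(comp)))
    if not classes:
        raise ValueError("graph has no terminal SCC; not a closed dynamics")

    transient = sorted(v for v in stg.edges if v not in class_of)
    index = {v: i for i, v in enumerate(transient)}

    if probabilities is None:
        def probabilities(v: StateKey) -> Mapping[StateKey, float]:
            return transition_probabilities(stg, v)

    q_rows, q_cols, q_data = [], [], []
    l_rows, l_cols, l_data = [], [], []
    for v in transient:
        i = index[v]
        dist = probabilities(v)
        total = 0.0
        for w, p in dist.items():
            total += p
            if w in index:
                q_rows.append(i)
                q_cols.append(index[w])
                q_data.append(p)
            else:
                l_rows.append(i)
                l_cols.append(class_of[w])
                l_data.append(p)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(
                f"transition probabilities out of state {v} sum to {total}"
            )
    n_t, n_a = len(transient), len(classes)
    Q = sp.csr_array(
        (q_data, (q_rows, q_cols)), shape=(n_t, n_t), dtype=float
    )
    L = sp.csr_array(
        (l_data, (l_rows, l_cols)), shape=(n_t, n_a), dtype=float
    )

    if initial_law is None:
        roots = stg.roots or tuple(stg.edges)
        initial_law = {v: 1.0 / len(roots) for v in roots}
    else:
        initial_law = dict(initial_law)
        mass = sum(initial_law.values())
        if abs(mass - 1.0) > 1e-9:
            raise ValueError(f"initial law sums to {mass}, expected 1")
        for v in initial_law:
            if v not in stg.edges:
                raise ValueError(f"initial-law state {v} not in the graph")

    return AbsorptionProblem(
        transient, classes, Q, L, dict(initial_law), index, class_of
    )


def absorption_matrix(problem: AbsorptionProblem) -> np.ndarray:
    """Per-transient-state absorption probabilities ``(I - Q)^{-1} L``."""
    n_t = len(problem.transient)
    if n_t == 0:
        return np.zeros((0, len(problem.classes)))
    L = problem.L.toarray()
    if n_t < _DENSE_LIMIT:
        A = np.eye(n_t) - problem.Q.toarray()
        return np.linalg.solve(A, L)
    A = (sp.eye_array(n_t, format="csc") - problem.Q).tocsc()
    try:
        lu = spla.splu(A)
        return lu.solve(L)
    except RuntimeError as exc:  # singular: malformed graph
        raise ValueError(
            "absorbing chain is singular; the graph is malformed"
        ) from exc


def _weight_by_initial_law(
    problem: AbsorptionProblem, Z: np.ndarray
) -> np.ndarray:
    probs = np.zeros(len(problem.classes))
    for v, p in problem.initial_law.items():
        if v in problem.index:
            probs += p * Z[problem.index[v]]
        else:
            probs[problem.class_of[v]] += p
    return probs


def solve_absorption(problem: AbsorptionProblem) -> AbsorptionResult:
    """Exact absorption probabilities, weighted by the initial law."""
    Z = absorption_matrix(problem)
    probs = _weight_by_initial_law(problem, Z)
    return AbsorptionResult(
        probabilities=dict(zip(problem.classes, probs.tolist()))
    )


def power_iteration(
    problem: AbsorptionProblem,
    epsilon: float = 1e-12,
    max_steps: int = 1_000_000,
) -> AbsorptionResult:
    """Propagate the initial law through the chain until the transient
    mass drops below ``epsilon``.

    Independent of the direct solve: repeatedly applies the canonical-form
    transition matrix, accumulating the mass that crosses into each
    absorbing class.  Non-convergence within ``max_steps`` is reported, not
    raised.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    n_t = len(problem.transient)
    absorbed = np.zeros(len(problem.classes))
    m = np.zeros(n_t)
    for v, p in problem.initial_law.items():
        if v in problem.index:
            m[problem.index[v]] += p
        else:
            absorbed[problem.class_of[v]] += p
    steps = 0
    while m.sum() >= epsilon and steps < max_steps:
        absorbed += m @ problem.L
        m = m @ problem.Q
        steps += 1
    residual = float(m.sum())
    return AbsorptionResult(
        probabilities=dict(zip(problem.classes, absorbed.tolist())),
        residual=residual,
        converged=residual < epsilon,
        steps=steps,
    )


def exact_attractor_probabilities(
    provider: DynamicsProvider,
    roots: Iterable[StateKey] | None = None,
    initial_law: Mapping[StateKey, float] | None = None,
    limit: int = 1_000_000,
) -> AbsorptionResult:
    """Convenience: explore, build the stopped chain, and solve it.

    ``roots`` defaults to the support of ``initial_law``.
    """
    if roots is None:
        if initial_law is None:
            raise ValueError("either roots or initial_law is required")
        roots = list(initial_law)
    stg = explore_reachable(provider, roots, limit)
    problem = build_absorption(stg, initial_law)
    return solve_absorption(problem)
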