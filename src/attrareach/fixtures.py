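"""Hand-built dynamics with known structure, for tests and benchmarks.

The exploration algorithms only see a successor function, so alongside full
logical models the package provides explicit transition graphs with planted
features — linear chains, pure cycles, transient strongly connected
components with a controlled number of exits — whose attractors and
absorption probabilities are known by construction.  These play the role of
the synthetic challenge models used to stress attractor search: a large
cyclic structure that is either terminal (a complex attractor) or transient
(a trap the walk must escape).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .model import Component, LogicalModel, StateKey


@dataclass
class ExplicitGraph:
    """A dynamics provider backed by an explicit adjacency map.

    States are plain integer keys.  Self-loops are rejected: asynchronous
    transitions always change a component, so no state is its own
    successor; stability is encoded as an empty successor list.
    """

    adjacency: dict[int, tuple[int, ...]]
    name: str = "explicit"

    def __post_init__(self) -> None:
        adj = {}
        for v, targets in self.adjacency.items():
            targets = tuple(targets)
            if v in targets:
                raise ValueError(f"state {v}: self-loop not allowed")
            adj[v] = targets
        # close over targets that never appear as sources (stable states)
        for targets in list(adj.values()):
            for w in targets:
                adj.setdefault(w, ())
        self.adjacency = adj

    @property
    def nodes(self) -> list[int]:
        return sorted(self.adjacency)

    def successors(self, state: StateKey) -> tuple[StateKey, ...]:
        return self.adjacency[state]

    def sample_state(self, rng, fixed=None) -> StateKey:
        nodes = self.nodes
        return nodes[rng.randrange(len(nodes))]


def toggle_switch() -> LogicalModel:
    """Two mutually inhibiting Boolean components.

    Stable states (0,1) and (1,0); from (0,0) or (1,1) each is reached
    with probability 1/2.
    """
    return LogicalModel(
        components=[Component("g0"), Component("g1")],
        regulators=[(1,), (0,)],
        tables=[[1, 0], [1, 0]],
    )


def chain_to_stable(length: int) -> ExplicitGraph:
    """A linear path 0 -> 1 -> ... -> length-1; the last state is stable."""
    if length < 1:
        raise ValueError("length must be >= 1")
    adj = {i: (i + 1,) for i in range(length - 1)}
    adj[length - 1] = ()
    return ExplicitGraph(adj, name=f"chain_to_stable({length})")


def pure_cycle(size: int) -> ExplicitGraph:
    """A single deterministic cycle with no exits: one complex attractor."""
    if size < 2:
        raise ValueError("cycle size must be >= 2")
    adj = {i: ((i + 1) % size,) for i in range(size)}
    return ExplicitGraph(adj, name=f"pure_cycle({size})")


def planted_transient(
    cycle_size: int,
    n_exits: int,
    n_shortcuts: int = 0,
    seed: int | None = None,
) -> ExplicitGraph:
    """A transient SCC of ``cycle_size`` states with ``n_exits`` exits.

    States ``0..cycle_size-1`` form a directed cycle; ``n_exits`` distinct
    cycle states gain an extra transition to a fresh stable state each
    (stable states are numbered from ``cycle_size`` up).  Optional random
    chords (``n_shortcuts``) keep the set strongly connected while making
    the within-cycle transition probabilities asymmetric, so the exit
    distribution is not uniform.
    """
    k = cycle_size
    if k < 2:
        raise ValueError("cycle_size must be >= 2")
    if not 1 <= n_exits <= k:
        raise ValueError("n_exits must be between 1 and cycle_size")
    rng = random.Random(seed if seed is not None else 0)
    adj: dict[int, list[int]] = {i: [(i + 1) % k] for i in range(k)}
    # evenly spaced exit states, deterministic for a given (k, n_exits)
    exit_sources = [round(j * k / n_exits) % k for j in range(n_exits)]
    exit_sources = sorted(set(exit_sources))
    while len(exit_sources) < n_exits:  # collisions at tiny k
        for i in range(k):
            if i not in exit_sources:
                exit_sources.append(i)
                break
        exit_sources.sort()
    for j, src in enumerate(exit_sources[:n_exits]):
        adj[src].append(k + j)
    for _ in range(n_shortcuts):
        a = rng.randrange(k)
        b = rng.randrange(k)
        if b != a and b not in adj[a] and b != (a + 1) % k:
            adj[a].append(b)
    for j in range(n_exits):
        adj[k + j] = []
    return ExplicitGraph(
        {v: tuple(t) for v, t in adj.items()},
        name=f"planted_transient({k},{n_exits})",
    )


def delayed_merge() -> ExplicitGraph:
    """A branch whose arms reach a shared state at different depths.

    With a neglect threshold between 1/4 and 3/4, state ``x`` (key 5) first
    arrives with mass 1/4 and is set aside as unlikely, then accumulates a
    further 1/2 one step later and must be promoted back into the frontier.
    States: 0=root, 1-2 short arm, 3-4 long arm, 5=merge, 6-7 stable.
    """
    return ExplicitGraph(
        {
            0: (1, 3),      # root splits 1/2 : 1/2
            1: (5, 2),      # short arm: x receives 1/4
            2: (6,),
            3: (4,),
            4: (5,),        # long arm: x receives another 1/2
            5: (7,),
            6: (),
            7: (),
        },
        name="delayed_merge",
    )


def shortcut_cycle() -> ExplicitGraph:
    """A 4-cycle with a chord and two asymmetric exits.

    Cycle 0 -> 1 -> 2 -> 3 -> 0 with shortcut 1 -> 3; exits 0 -> 4 and
    2 -> 5 (both stable).  The chord makes the two exits unequally likely,
    which distinguishes exact from uniform rewiring.
    """
    return ExplicitGraph(
        {
            0: (1, 4),
            1: (2, 3),
            2: (3, 5),
            3: (0,),
            4: (),
            5: (),
        },
        name="shortcut_cycle",
    )


def two_cycle(symmetric_exits: bool = True) -> ExplicitGraph:
    """A 2-cycle 0 <-> 1 with one exit per state (or a single exit).

    With symmetric exits, each cycle state leaves toward its own stable
    state with probability 1/2 per step; the asymptotic exit distribution
    from state 0 is (2/3, 1/3).  With ``symmetric_exits=False`` only state
    0 has an exit, which must then receive all the mass.
    """
    if symmetric_exits:
        adj = {0: (1, 2), 1: (0, 3), 2: (), 3: ()}
    else:
        adj = {0: (1, 2), 1: (0,), 2: ()}
    return ExplicitGraph(adj, name=f"two_cycle(symmetric={symmetric_exits})")


_FIXTURES = {
    "toggle_switch": toggle_switch,
    "chain_to_stable": chain_to_stable,
    "pure_cycle": pure_cycle,
    "planted_transient": planted_transient,
    "delayed_merge": delayed_merge,
    "shortcut_cycle": shortcut_cycle,
    "two_cycle": two_cycle,
}


def build_fixture(name: str, *args, **kwargs):
    """Instantiate a named fixture dynamics (see module docstring)."""
    try:
        factory = _FIXTURES[name]
    except KeyError:
        raise ValueError(
            f"unknown fixture {name!r}; known: {sorted(_FIXTURES)}"
        ) from None
    return factory(*args, **kwargs)
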