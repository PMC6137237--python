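"""Quasi-exact breadth-first probability propagation (Firefront).

Starting from an initial state carrying probability 1, the frontier set
``F`` is expanded one synchronized breadth step at a time: every state in
``F`` distributes its probability uniformly over its successors.  States
whose accumulated probability falls below a neglect threshold ``alpha`` are
parked in a set ``N`` of neglected states (and promoted back into ``F``
should later visits push them over the threshold again); stable states and
states recognized as attractor members accumulate into a set ``A``.  The
three sets partition the unit of probability at every step.

On halt, the probability accumulated for each attractor is a certified
lower bound of its exact reachability probability; adding the mass left in
``N`` and ``F`` gives an upper bound.  Complex attractors are detected
heuristically: three occurrences of exactly the same frontier (same states
carrying the same probabilities, which requires the rotating mass to be
conserved) are taken as evidence that the propagation is locked in a
terminal cycle, and
the union of the supports seen between the second and third occurrences is
the candidate attractor.  Each candidate is verified to be a closed,
strongly connected set before it is certified, so the reported bounds stay
valid even when the repetition is coincidental.
"""

from __future__ import annotations

from collections import defaultdict, deque
from dataclasses import dataclass, field
from typing import Mapping

from .io import Oracle
from .model import DynamicsProvider, StateKey

AttractorId = tuple  # ('stable', key) | ('oracle', name) | ('cycle', frozenset)


@dataclass(frozen=True)
class FirefrontParams:
    """Tuning knobs of the propagation.

    alpha:
        Neglect threshold: a state whose accumulated frontier probability
        is below ``alpha`` is parked in ``N`` instead of being expanded.
    beta:
        Termination residual: the run halts once the total frontier
        probability drops to or below ``beta``.
    max_expansions:
        Hard cap on the number of breadth steps.
    history_window:
        Number of recent frontier supports retained for the periodicity
        test; unbounded history would defeat the memory advantage.
    """

    alpha: float = 1e-5
    beta: float = 1e-4
    max_expansions: int = 1000
    history_window: int = 64

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.beta < 1:
            raise ValueError("beta must be in (0, 1)")
        if self.max_expansions < 1:
            raise ValueError("max_expansions must be >= 1")
        if self.history_window < 3:
            raise ValueError("history_window must be >= 3")


@dataclass
class AttractorEstimate:
    """Reachability bounds for one attractor found by the propagation."""

    kind: str  # 'stable' | 'complex' | 'oracle'
    lower: float
    upper: float
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
class TraceRow:
    iteration: int
    size_f: int
    size_n: int
    size_a: int
    mass_f: float
    mass_n: float
    mass_a: float


@dataclass
class FirefrontResult:
    attractors: list[AttractorEstimate]
    residual_f: float
    residual_n: float
    termination: str  # 'F-empty' | 'beta-reached' | 'max-expansions' | 'periodicity'
    iterations: int
    trace: list[TraceRow] = field(default_factory=list)

    def bounds(self) -> dict[str, tuple[float, float]]:
        return {a.label: (a.lower, a.upper) for a in self.attractors}


class _FrontierHistory:
    """Ring buffer of recent frontiers with an order-independent digest.

    A frontier snapshot is the set of (state, probability) pairs: inside a
    terminal cycle the rotating mass is conserved, so the snapshot repeats
    exactly, whereas in a transient cycle the same support recurs with
    strictly smaller probabilities and never matches.  Candidate repeats
    are screened by hash before the exact set comparison, so collisions
    cannot cause a false detection.
    """

    def __init__(self, window: int) -> None:
        self._window = window
        self._items: deque[tuple[int, frozenset]] = deque(maxlen=window)

    def push(self, frontier: Mapping[StateKey, float]) -> None:
        snapshot = frozenset(frontier.items())
        self._items.append((hash(snapshot), snapshot))

    def detect(self) -> frozenset[StateKey] | None:
        """Union of frontier supports between the 2nd and 3rd occurrence
        of the current snapshot, if that third occurrence just happened."""
        if len(self._items) < 3:
            return None
        h, current = self._items[-1]
        occurrences = [
            i
            for i, (hi, si) in enumerate(self._items)
            if hi == h and si == current
        ]
        if len(occurrences) < 3:
            return None
        second = occurrences[-2]
        members: set[StateKey] = set()
        for i in range(second, len(self._items)):
            members.update(state for state, _ in self._items[i][1])
        return frozenset(members)


def expand(
    F: Mapping[StateKey, float],
    N: dict[StateKey, float],
    A: dict[AttractorId, float],
    provider: DynamicsProvider,
    alpha: float,
    member_of: dict[StateKey, AttractorId],
    oracle: Oracle | None = None,
) -> dict[StateKey, float]:
    """One synchronized breadth step; returns the next frontier.

    All contributions reaching a target within the step are summed before
    the threshold test, so the processing order of ``F`` is irrelevant.
    ``N`` and ``A`` are updated in place; total mass is conserved.
    """
    contrib: dict[StateKey, float] = defaultdict(float)
    for v, p in F.items():
        att = member_of.get(v)
        if att is None and oracle is not None:
            name = oracle.identify(v)
            if name is not None:
                att = ("oracle", name)
                member_of[v] = att
        if att is not None:
            A[att] = A.get(att, 0.0) + p
            continue
        succ = provider.successors(v)
        if not succ:
            att = ("stable", v)
            A[att] = A.get(att, 0.0) + p
            continue
        share = p / len(succ)
        for w in succ:
            contrib[w] += share

    new_f: dict[StateKey, float] = {}
    for w, p in contrib.items():
        att = member_of.get(w)
        if att is None and oracle is not None:
            name = oracle.identify(w)
            if name is not None:
                att = ("oracle", name)
                member_of[w] = att
        if att is not None:
            A[att] = A.get(att, 0.0) + p
            continue
        if w in N:
            total = N[w] + p
            if total >= alpha:
                del N[w]
                new_f[w] = total
            else:
                N[w] = total
        elif p >= alpha:
            new_f[w] = p
        else:
            N[w] = p
    return new_f


def _closed_sccs(
    provider: DynamicsProvider, candidate: frozenset[StateKey]
) -> list[frozenset[StateKey]]:
    """Verified complex attractors inside a periodicity candidate.

    A subset that is strongly connected and closed under the successor
    function is a terminal SCC of the full dynamics, so each returned set
    is a genuine complex attractor; anything else in the candidate (e.g.
    mass split over several structures whose rotation happens to repeat)
    is left on the frontier.  This keeps the periodicity heuristic from
    ever certifying a false attractor.
    """
    from .stg import tarjan_scc

    induced = {
        m: tuple(w for w in provider.successors(m) if w in candidate)
        for m in candidate
    }
    out = []
    for comp in tarjan_scc(induced):
        if len(comp) < 2:
            continue
        comp_set = frozenset(comp)
        if all(
            w in comp_set for m in comp_set for w in provider.successors(m)
        ):
            out.append(comp_set)
    return out


def run_firefront(
    provider: DynamicsProvider,
    v0: StateKey,
    params: FirefrontParams | None = None,
    oracle: Oracle | None = None,
) -> FirefrontResult:
    """Propagate probability from ``v0`` until the frontier dies out.

    Termination: the frontier mass reaches zero ('F-empty') or drops to
    ``beta`` ('beta-reached'); the expansion budget runs out
    ('max-expansions'); or a detected terminal cycle absorbs the whole
    frontier ('periodicity').  Non-convergence is reported in
    ``termination``, never raised.
    """
    params = params or FirefrontParams()
    F: dict[StateKey, float] = {v0: 1.0}
    N: dict[StateKey, float] = {}
    A: dict[AttractorId, float] = {}
    member_of: dict[StateKey, AttractorId] = {}
    history = _FrontierHistory(params.history_window)
    trace: list[TraceRow] = []
    termination = "max-expansions"
    iteration = 0

    for iteration in range(1, params.max_expansions + 1):
        F = expand(F, N, A, provider, params.alpha, member_of, oracle)

        detected_now = False
        if F:
            history.push(F)
            candidate = history.detect()
            if candidate is not None:
                for comp in _closed_sccs(provider, candidate):
                    if any(m in member_of for m in comp):
                        continue
                    att: AttractorId = ("cycle", comp)
                    for m in comp:
                        member_of[m] = att
                    gained = 0.0
                    for m in comp:
                        if m in F:
                            gained += F.pop(m)
                    if gained:
                        A[att] = A.get(att, 0.0) + gained
                    detected_now = True

        mass_f = sum(F.values())
        trace.append(
            TraceRow(
                iteration,
                len(F),
                len(N),
                len(A),
                mass_f,
                sum(N.values()),
                sum(A.values()),
            )
        )

        if not F:
            termination = "periodicity" if detected_now else "F-empty"
            break
        if mass_f <= params.beta:
            termination = "beta-reached"
            break

    residual_f = sum(F.values())
    residual_n = sum(N.values())
    slack = residual_f + residual_n
    attractors = []
    for att_id, mass in sorted(A.items(), key=lambda kv: -kv[1]):
        kind = att_id[0]
        if kind == "stable":
            est = AttractorEstimate(
                "stable", mass, mass + slack, states=frozenset({att_id[1]})
            )
        elif kind == "cycle":
            est = AttractorEstimate(
                "complex", mass, mass + slack, states=att_id[1]
            )
        else:
            est = AttractorEstimate(
                "oracle", mass, mass + slack, name=att_id[1]
            )
        attractors.append(est)

    return FirefrontResult(
        attractors=attractors,
        residual_f=residual_f,
        residual_n=residual_n,
        termination=termination,
        iterations=iteration,
        trace=trace,
    )
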