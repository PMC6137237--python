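"""Logical regulatory graphs and their asynchronous dynamics.

A logical model consists of regulatory components, each holding a discrete
level in ``{0, ..., M_i}``, together with logical functions ``K_i`` that give
the level each component is called to adopt as a function of its regulators.
Under the asynchronous updating scheme a state has one outgoing transition
per component whose target level differs from its current level, and each
transition moves that single component one unit toward its target.

States are identified throughout the package by a reversible mixed-radix
integer key (little-endian in declared component order), which serves as the
canonical hashable identity in every set and map the exploration algorithms
maintain.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Protocol, Sequence, runtime_checkable

import numpy as np

StateKey = int
Levels = tuple[int, ...]


@runtime_checkable
class DynamicsProvider(Protocol):
    """Anything that can enumerate asynchronous successors of a state.

    Implemented by :class:`LogicalModel` (successors derived from the logical
    functions) and by :class:`attrareach.fixtures.ExplicitGraph` (hand-built
    transition graphs used to exercise the algorithms on planted structures).
    A successor list never contains the state itself: asynchronous
    transitions change exactly one component.
    """

    def successors(self, state: StateKey) -> Sequence[StateKey]:
        ...


@dataclass(frozen=True)
class Component:
    """A regulatory component with domain ``{0, ..., max_level}``.

    Input components keep a constant level: their logical function is the
    identity on their own level, so the asynchronous dynamics never move
    them.  Their value is fixed by the initial condition (or sampled, in
    whole-state-space mode).
    """

    name: str
    max_level: int = 1
    is_input: bool = False

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("component name must be non-empty")
        if self.max_level < 1:
            raise ValueError(
                f"component {self.name!r}: max_level must be >= 1, "
                f"got {self.max_level}"
            )


def identity_table(max_level: int) -> np.ndarray:
    """Truth table of the identity function on a single regulator."""
    return np.arange(max_level + 1, dtype=np.int64)


class LogicalModel:
    """A logical regulatory graph with explicit truth tables.

    Parameters
    ----------
    components:
        Ordered list of :class:`Component`.  The order fixes the state
        encoding and the character order of state strings.
    regulators:
        Per-component tuple of regulator indices (indices into
        ``components``).  An input component must list exactly itself.
    tables:
        Per-component truth table: a flat integer array of length
        ``prod(M_r + 1 for r in regulators[i])`` indexed by the mixed-radix
        (little-endian, in regulator order) encoding of the regulator
        levels.  Entry values are the target levels ``K_i`` and must lie in
        the component's domain.

    Tables are validated exhaustively on construction, which also proves
    ``K_i(v)`` lies in the domain for *every* state ``v`` since ``K_i``
    depends only on the declared regulators.
    """

    def __init__(
        self,
        components: Sequence[Component],
        regulators: Sequence[Sequence[int]],
        tables: Sequence[Iterable[int]],
    ) -> None:
        self.components: tuple[Component, ...] = tuple(components)
        n = len(self.components)
        if len(regulators) != n or len(tables) != n:
            raise ValueError("components, regulators and tables must align")
        self.regulators: tuple[tuple[int, ...], ...] = tuple(
            tuple(int(r) for r in regs) for regs in regulators
        )
        self.tables: list[np.ndarray] = [
            np.asarray(list(t), dtype=np.int64) for t in tables
        ]

        self._radices = np.array(
            [c.max_level + 1 for c in self.components], dtype=np.int64
        )
        # place value of component i in the mixed-radix state key
        self._places = np.concatenate(([1], np.cumprod(self._radices[:-1])))
        self.n_states = int(np.prod(self._radices, dtype=object))

        self._reg_places: list[np.ndarray] = []
        for i, regs in enumerate(self.regulators):
            comp = self.components[i]
            for r in regs:
                if not 0 <= r < n:
                    raise ValueError(
                        f"component {comp.name!r}: regulator index {r} "
                        "out of range"
                    )
            if len(set(regs)) != len(regs):
                raise ValueError(
                    f"component {comp.name!r}: duplicate regulator"
                )
            sizes = [self.components[r].max_level + 1 for r in regs]
            places = np.concatenate(
                ([1], np.cumprod(np.array(sizes[:-1], dtype=np.int64)))
            ) if regs else np.array([], dtype=np.int64)
            self._reg_places.append(places.astype(np.int64))
            expected = int(np.prod(sizes)) if regs else 1
            table = self.tables[i]
            if table.shape != (expected,):
                raise ValueError(
                    f"component {comp.name!r}: truth table has "
                    f"{table.size} rows, expected {expected}"
                )
            if table.min(initial=0) < 0 or table.max(initial=0) > comp.max_level:
                raise ValueError(
                    f"component {comp.name!r}: truth-table entry outside "
                    f"domain 0..{comp.max_level}"
                )
            if comp.is_input:
                if regs != (i,) or not np.array_equal(
                    table, identity_table(comp.max_level)
                ):
                    raise ValueError(
                        f"input component {comp.name!r} must have the "
                        "identity function on its own level"
                    )

        self._succ: dict[StateKey, tuple[StateKey, ...]] = {}

    # -- basic accessors ---------------------------------------------------

    @property
    def n(self) -> int:
        return len(self.components)

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.components)

    def component_index(self, name: str) -> int:
        for i, c in enumerate(self.components):
            if c.name == name:
                return i
        raise KeyError(f"unknown component {name!r}")

    # -- state encoding ----------------------------------------------------

    def encode(self, levels: Sequence[int]) -> StateKey:
        """Mixed-radix key of a level vector (reversible; little-endian)."""
        if len(levels) != self.n:
            raise ValueError(f"state has {len(levels)} levels, expected {self.n}")
        key = 0
        for v, m, p in zip(levels, self._radices, self._places):
            if not 0 <= v < m:
                raise ValueError(f"level {v} outside domain 0..{m - 1}")
            key += int(v) * int(p)
        return key

    def decode(self, key: StateKey) -> Levels:
        if not 0 <= key < self.n_states:
            raise ValueError(f"state key {key} out of range")
        levels = []
        for m in self._radices:
            key, v = divmod(key, int(m))
            levels.append(v)
        return tuple(levels)

    def parse_state(self, text: str) -> StateKey:
        """Parse a state string: one character (a digit) per component."""
        if len(text) != self.n:
            raise ValueError(
                f"state string {text!r} has {len(text)} characters, "
                f"expected {self.n}"
            )
        return self.encode(tuple(int(ch) for ch in text))

    def format_state(self, key: StateKey) -> str:
        return "".join(str(v) for v in self.decode(key))

    # -- dynamics ----------------------------------------------------------

    def target_value(self, i: int, levels: Sequence[int]) -> int:
        """Level ``K_i(v)`` the logical function calls component ``i`` to."""
        regs = self.regulators[i]
        places = self._reg_places[i]
        idx = 0
        for r, p in zip(regs, places):
            idx += levels[r] * int(p)
        return int(self.tables[i][idx])

    def targets(self, levels: Sequence[int]) -> list[int]:
        return [self.target_value(i, levels) for i in range(self.n)]

    def successor_levels(self, levels: Sequence[int]) -> list[Levels]:
        """Asynchronous successors: one per component called to change,
        moving a single unit toward its target level."""
        out: list[Levels] = []
        for i in range(self.n):
            t = self.target_value(i, levels)
            vi = levels[i]
            if t != vi:
                w = list(levels)
                w[i] = vi + (1 if t > vi else -1)
                out.append(tuple(w))
        return out

    def successors(self, state: StateKey) -> tuple[StateKey, ...]:
        cached = self._succ.get(state)
        if cached is None:
            levels = self.decode(state)
            cached = tuple(self.encode(w) for w in self.successor_levels(levels))
            self._succ[state] = cached
        return cached

    def is_stable(self, state: StateKey) -> bool:
        return not self.successors(state)

    def sample_state(
        self,
        rng,
        fixed: Mapping[str, int] | None = None,
    ) -> StateKey:
        """Draw a state uniformly over the unconstrained components.

        ``fixed`` pins named components (typically inputs) to a level; all
        other components, inputs included, are sampled uniformly over their
        domain.  ``rng`` is a :class:`random.Random`.
        """
        fixed = fixed or {}
        for name in fixed:
            self.component_index(name)  # raises on unknown name
        levels = []
        for c in self.components:
            if c.name in fixed:
                lvl = int(fixed[c.name])
                if not 0 <= lvl <= c.max_level:
                    raise ValueError(
                        f"component {c.name!r}: level {lvl} outside domain"
                    )
                levels.append(lvl)
            else:
                levels.append(rng.randrange(c.max_level + 1))
        return self.encode(levels)

    # -- misc ----------------------------------------------------------------

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LogicalModel):
            return NotImplemented
        return (
            self.components == other.components
            and self.regulators == other.regulators
            and all(
                np.array_equal(a, b) for a, b in zip(self.tables, other.tables)
            )
        )

    def __repr__(self) -> str:
        return (
            f"<LogicalModel n={self.n} states={self.n_states} "
            f"components={[c.name for c in self.components]}>"
        )


def transition_probabilities(
    provider: DynamicsProvider, state: StateKey
) -> dict[StateKey, float]:
    """Uniform distribution over the concurrent asynchronous transitions.

    A state with no successor returns an empty map; the absorbing
    self-loop of the stopped chain is handled downstream.
    """
    succ = provider.successors(state)
    if not succ:
        return {}
    p = 1.0 / len(succ)
    return {w: p for w in succ}


def perturb(model: LogicalModel, clamps: Mapping[str, int]) -> LogicalModel:
    """Clamp components to fixed levels (ectopic expression / knockout).

    Each perturbed component's function becomes the constant clamped level,
    so from any state it moves stepwise to that level and never leaves it.
    A knockout clamps to 0; an activating mutation clamps to the maximum.
    """
    indices: dict[int, int] = {}
    for name, level in clamps.items():
        i = model.component_index(name)
        comp = model.components[i]
        if not 0 <= int(level) <= comp.max_level:
            raise ValueError(
                f"component {name!r}: clamp level {level} outside domain "
                f"0..{comp.max_level}"
            )
        indices[i] = int(level)

    components = []
    regulators = []
    tables = []
    for i, comp in enumerate(model.components):
        if i in indices:
            components.append(
                Component(comp.name, comp.max_level, is_input=False)
            )
            regulators.append(())
            tables.append(np.array([indices[i]], dtype=np.int64))
        else:
            components.append(comp)
            regulators.append(model.regulators[i])
            tables.append(model.tables[i])
    return LogicalModel(components, regulators, tables)
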