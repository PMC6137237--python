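"""Random logical models with uniformly sampled rules.

Mirrors the standard random Boolean network construction: every component
receives a fixed number of distinct regulators drawn uniformly, and every
truth-table entry is drawn uniformly over the component's domain.
Generation is bit-reproducible from the seed.  Constant (degenerate) rules
can occur and are kept; callers that need a particular attractor structure
screen seeds with the exact solver (see :func:`multistable_seeds`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import Component, LogicalModel


@dataclass(frozen=True)
class RandomModelSpec:
    """Parameters of the random-model distribution.

    ``max_level=1`` gives Boolean components; larger values give
    multi-valued components with the same uniform table sampling.
    """

    n_components: int
    n_regulators: int = 2
    seed: int = 0
    max_level: int = 1

    def __post_init__(self) -> None:
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")
        if not 1 <= self.n_regulators <= self.n_components:
            raise ValueError(
                "n_regulators must be between 1 and n_components"
            )
        if self.max_level < 1:
            raise ValueError("max_level must be >= 1")


def generate_random_model(spec: RandomModelSpec) -> LogicalModel:
    """Draw a model from the distribution described by ``spec``."""
    rng = np.random.default_rng(spec.seed)
    n, k, m = spec.n_components, spec.n_regulators, spec.max_level
    components = [Component(f"g{i}", max_level=m) for i in range(n)]
    regulators = []
    tables = []
    for _ in range(n):
        regs = tuple(sorted(int(r) for r in rng.choice(n, size=k, replace=False)))
        regulators.append(regs)
        table_size = (m + 1) ** k
        tables.append(rng.integers(0, m + 1, size=table_size, dtype=np.int64))
    return LogicalModel(components, regulators, tables)


def multistable_seeds(
    n_components: int,
    n_regulators: int,
    seeds,
    min_attractors: int = 2,
    max_level: int = 1,
) -> list[int]:
    """Screen seeds whose model has at least ``min_attractors`` attractors.

    Uses the explicit state-transition-graph decomposition, so it is only
    meant for small models (the full state space is enumerated).
    """
    from .stg import attractors_of, explore_reachable

    hits = []
    for seed in seeds:
        model = generate_random_model(
            RandomModelSpec(n_components, n_regulators, seed, max_level)
        )
        stg = explore_reachable(
            model, range(model.n_states), limit=model.n_states
        )
        if len(attractors_of(stg)) >= min_attractors:
            hits.append(seed)
    return hits
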