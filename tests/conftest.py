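"""Shared fixtures and oracles for the test suite.

All inputs are generated programmatically: random logical models from the
seeded generator, and explicit graphs with planted structure from
:mod:`attrareach.fixtures`.
"""

from __future__ import annotations

import pytest

from attrareach.fixtures import toggle_switch
from attrareach.generate import RandomModelSpec, generate_random_model
from attrareach.stg import (
    build_absorption,
    explore_reachable,
    solve_absorption,
)


@pytest.fixture
def toggle():
    return toggle_switch()


def random_model(seed: int, n: int = 10, k: int = 2, max_level: int = 1):
    return generate_random_model(RandomModelSpec(n, k, seed, max_level))


def exact_probabilities(provider, v0, limit: int = 1 << 16):
    """Ground truth: absorption probabilities keyed by attractor state set."""
    stg = explore_reachable(provider, [v0], limit)
    result = solve_absorption(build_absorption(stg, {v0: 1.0}))
    return {att.states: p for att, p in result.probabilities.items()}
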