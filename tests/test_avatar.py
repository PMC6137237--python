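"""Avatar: rewiring correctness, extension horizons, estimates, baseline."""

import math

import numpy as np
import pytest

from attrareach.avatar import (
    AvatarParams,
    apply_ceiling,
    extend_cycle,
    make_cycle_record,
    rewire_approx,
    rewire_exact,
    run_avatar,
    run_monte_carlo,
    wilson_interval,
)
from attrareach.fixtures import (
    ExplicitGraph,
    chain_to_stable,
    planted_transient,
    pure_cycle,
    shortcut_cycle,
    two_cycle,
)
from attrareach.model import transition_probabilities
from attrareach.stg import (
    build_absorption,
    decompose_scc,
    explore_reachable,
    solve_absorption,
)

from conftest import exact_probabilities, random_model


def overrides_as_probability_fn(provider, overrides):
    def probs(v):
        ov = overrides.get(v)
        if ov is not None:
            return dict(zip(*ov))
        return transition_probabilities(provider, v)

    return probs


def rewired_absorption(provider, v0, cycle_states, strategy="exact"):
    """Exact absorption of the chain after rewiring ``cycle_states``."""
    stg = explore_reachable(provider, [v0])
    rec = make_cycle_record(provider, tuple(sorted(cycle_states)))
    overrides = (
        rewire_exact(rec) if strategy == "exact" else rewire_approx(rec)
    )
    problem = build_absorption(
        stg, {v0: 1.0}, overrides_as_probability_fn(provider, overrides)
    )
    return {
        att.states: p for att, p in solve_absorption(problem).probabilities.items()
    }


class TestRewire:
    def test_single_exit_receives_all_mass(self):
        g = two_cycle(symmetric_exits=False)
        rec = make_cycle_record(g, (0, 1))
        overrides = rewire_exact(rec)
        assert overrides[0] == ((2,), (1.0,))
        assert overrides[1] == ((2,), (1.0,))

    def test_symmetric_two_cycle_geometric_series(self):
        # from c_i the chain leaves via its own exit with probability
        # sum_k (1/4)^k / 2 = 2/3, via the other with 1/3
        g = two_cycle(symmetric_exits=True)
        overrides = rewire_exact(make_cycle_record(g, (0, 1)))
        targets, probs = overrides[0]
        assert targets == (2, 3)
        assert probs == pytest.approx((2 / 3, 1 / 3))
        targets, probs = overrides[1]
        assert probs == pytest.approx((1 / 3, 2 / 3))

    def test_override_rows_are_stochastic(self):
        g = planted_transient(40, 3, n_shortcuts=10, seed=2)
        scc = next(
            c
            for c in decompose_scc(explore_reachable(g, [0])).sccs
            if len(c) > 1
        )
        for strategy in (rewire_exact, rewire_approx):
            for targets, probs in strategy(
                make_cycle_record(g, scc)
            ).values():
                assert sum(probs) == pytest.approx(1.0, abs=1e-9)
                assert all(p >= 0 for p in probs)
                assert not set(targets) & set(scc)

    def test_terminal_cycle_cannot_be_rewired(self):
        rec = make_cycle_record(pure_cycle(3), (0, 1, 2))
        with pytest.raises(ValueError):
            rewire_exact(rec)
        with pytest.raises(ValueError):
            rewire_approx(rec)

    def test_approx_equals_exact_with_single_exit(self):
        g = two_cycle(symmetric_exits=False)
        rec = make_cycle_record(g, (0, 1))
        assert rewire_approx(rec) == rewire_exact(rec)

    @pytest.mark.parametrize(
        "cycle_size,n_exits,n_shortcuts,seed",
        [(4, 1, 0, 0), (10, 2, 3, 1), (50, 5, 10, 2), (120, 3, 25, 3)],
    )
    def test_rewiring_preserves_absorption(
        self, cycle_size, n_exits, n_shortcuts, seed
    ):
        # the rewired chain must reach every attractor with exactly the
        # probability of the original chain
        g = planted_transient(cycle_size, n_exits, n_shortcuts, seed)
        base = exact_probabilities(g, 0)
        rewired = rewired_absorption(g, 0, range(cycle_size))
        for states, p in base.items():
            assert rewired[states] == pytest.approx(p, abs=1e-9)

    def test_uniform_strategy_biased_on_asymmetric_exits(self):
        g = shortcut_cycle()
        base = exact_probabilities(g, 0)
        approx = rewired_absorption(g, 0, range(4), strategy="approx")
        deviation = max(
            abs(approx[states] - p) for states, p in base.items()
        )
        assert deviation > 0.01


class TestExtension:
    def test_fixed_point_on_full_scc(self):
        g = pure_cycle(5)
        assert extend_cycle(g, [0, 1, 2, 3, 4], tau=3) == frozenset(range(5))

    @staticmethod
    def _scc_with_inner_two_cycle(size=100, n_exits=2):
        # a big transient loop containing a genuine 2-cycle 0 <-> 1
        g = planted_transient(size, n_exits)
        adj = dict(g.adjacency)
        adj[1] = tuple(adj[1]) + (0,)
        return ExplicitGraph(adj)

    def test_large_tau_recovers_whole_transient_scc(self):
        g = self._scc_with_inner_two_cycle()
        ext = extend_cycle(g, [0, 1], tau=100)
        scc = next(
            c
            for c in decompose_scc(explore_reachable(g, [0])).sccs
            if len(c) == 100
        )
        assert ext == frozenset(scc)

    def test_small_tau_returns_strict_subset_containing_cycle(self):
        g = self._scc_with_inner_two_cycle()
        ext = extend_cycle(g, [0, 1], tau=1)
        assert {0, 1} <= ext
        assert len(ext) < 100

    def test_ceiling_truncates_to_cyclic_subset_with_anchor(self):
        g = planted_transient(60, 2)
        extended = extend_cycle(g, list(range(60)), tau=60)
        cut = apply_ceiling(g, extended, ceiling=20, anchor=5,
                            cycle=list(range(60)))
        assert 5 in cut
        assert len(cut) <= 20

    def test_ceiling_noop_when_under_limit(self):
        g = planted_transient(10, 1)
        extended = frozenset(range(10))
        assert apply_ceiling(g, extended, 10, 0, list(range(10))) == extended


class TestRuns:
    def test_chain_reaches_stable_with_certainty(self):
        result = run_avatar(
            chain_to_stable(5), 0, AvatarParams(runs=50, seed=0)
        )
        (est,) = result.attractors
        assert est.kind == "stable"
        assert est.probability == 1.0
        assert est.mean_depth == 4
        assert result.inconclusive == 0

    def test_pure_cycle_identified_as_complex_attractor(self):
        result = run_avatar(pure_cycle(4), 0, AvatarParams(runs=50, seed=0))
        (est,) = result.attractors
        assert est.kind == "complex"
        assert est.states == frozenset(range(4))
        assert est.probability == 1.0

    def test_balanced_branch_binomial(self):
        g = ExplicitGraph({0: (1, 2), 1: (), 2: ()})
        result = run_avatar(g, 0, AvatarParams(runs=10_000, seed=3))
        sigma = math.sqrt(0.25 / 10_000)
        for est in result.attractors:
            assert abs(est.probability - 0.5) < 3 * sigma + 1e-9

    def test_deterministic_for_identical_seed(self):
        model = random_model(5)
        params = AvatarParams(runs=300, seed=11)
        a = run_avatar(model, 0, params)
        b = run_avatar(model, 0, params)
        assert a.outcomes == b.outcomes
        assert [
            (e.label, e.probability, e.ci, e.mean_depth)
            for e in a.attractors
        ] == [
            (e.label, e.probability, e.ci, e.mean_depth)
            for e in b.attractors
        ]

    @pytest.mark.parametrize("strategy", ["exact", "approx"])
    def test_terminates_on_planted_transients_with_small_ceiling(
        self, strategy
    ):
        g = planted_transient(200, 2, n_shortcuts=20, seed=4)
        result = run_avatar(
            g,
            0,
            AvatarParams(
                runs=200, seed=5, ceiling=30, strategy=strategy,
                max_steps=200_000,
            ),
        )
        assert result.inconclusive == 0
        assert sum(e.probability for e in result.attractors) == 1.0

    @pytest.mark.parametrize("seed", [0, 7, 13, 21])
    def test_estimates_match_exact_solver(self, seed):
        model = random_model(seed)
        runs = 3000
        result = run_avatar(model, 0, AvatarParams(runs=runs, seed=seed))
        exact = exact_probabilities(model, 0)
        found = {est.states: est.probability for est in result.attractors}
        for states, p in exact.items():
            estimate = found.pop(states, 0.0)
            sigma = math.sqrt(max(p * (1 - p), 1e-12) / runs)
            assert abs(estimate - p) <= 3 * sigma + 0.01
        assert not found  # no spurious attractors

    def test_sampling_mode_matches_uniform_initial_law(self):
        model = random_model(7, n=8)
        stg = explore_reachable(model, range(model.n_states))
        law = {v: 1.0 / model.n_states for v in range(model.n_states)}
        exact = {
            att.states: p
            for att, p in solve_absorption(
                build_absorption(stg, law)
            ).probabilities.items()
        }
        runs = 4000
        result = run_avatar(
            model, params=AvatarParams(runs=runs, seed=2), sampling=True
        )
        for est in result.attractors:
            p = exact[est.states]
            sigma = math.sqrt(max(p * (1 - p), 1e-12) / runs)
            assert abs(est.probability - p) <= 3 * sigma + 0.01

    def test_sampling_respects_fixed_inputs(self):
        from attrareach.model import Component, LogicalModel, identity_table
        import random as pyrandom

        model = LogicalModel(
            [Component("u", is_input=True), Component("g")],
            [(0,), (0,)],
            [identity_table(1), [1, 0]],
        )
        rng = pyrandom.Random(0)
        for _ in range(20):
            key = model.sample_state(rng, {"u": 1})
            assert model.decode(key)[0] == 1

    def test_no_state_revisited_after_its_cycle_was_rewired(self):
        # the override of a dismantled state sends the walk straight to
        # an exit, so walk lengths stay bounded
        g = planted_transient(50, 2, n_shortcuts=5, seed=6)
        result = run_avatar(
            g, 0, AvatarParams(runs=100, seed=7, max_steps=5000)
        )
        assert result.inconclusive == 0


class TestMonteCarlo:
    def test_chain_support_full(self):
        result = run_monte_carlo(chain_to_stable(5), 0, runs=50, seed=0)
        assert result.support == 1.0
        assert result.attractors[0].probability == 1.0

    def test_cannot_retrieve_complex_attractor(self):
        result = run_monte_carlo(
            pure_cycle(4), 0, runs=50, max_depth=2000, seed=0
        )
        assert result.support == 0.0
        assert result.attractors == []

    def test_stable_only_model_matches_exact(self):
        g = ExplicitGraph({0: (1, 2), 1: (3,), 2: (4,), 3: (), 4: ()})
        runs = 5000
        result = run_monte_carlo(g, 0, runs=runs, seed=1)
        exact = exact_probabilities(g, 0)
        for est in result.attractors:
            p = exact[est.states]
            sigma = math.sqrt(p * (1 - p) / runs)
            assert abs(est.probability - p) <= 3 * sigma + 1e-9


class TestWilson:
    def test_interval_contains_point_estimate(self):
        lo, hi = wilson_interval(37, 100)
        assert lo < 0.37 < hi

    def test_extremes_behave(self):
        lo, hi = wilson_interval(0, 100)
        assert lo == 0.0 and hi < 0.05
        lo, hi = wilson_interval(100, 100)
        assert lo > 0.95 and hi == 1.0
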