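"""Firefront: conservation, bracketing, neglect/promotion, periodicity."""

import pytest

from attrareach.firefront import (
    FirefrontParams,
    expand,
    run_firefront,
)
from attrareach.fixtures import (
    ExplicitGraph,
    chain_to_stable,
    delayed_merge,
    pure_cycle,
)
from attrareach.io import Oracle, OracleAttractor

from conftest import exact_probabilities, random_model


def assert_conserved(result):
    for row in result.trace:
        assert row.mass_f + row.mass_n + row.mass_a == pytest.approx(
            1.0, abs=1e-9
        )


class TestExpansion:
    def test_stable_state_moves_to_A(self):
        g = chain_to_stable(1)
        F, N, A = {0: 1.0}, {}, {}
        new_f = expand(F, N, A, g, alpha=1e-6, member_of={})
        assert new_f == {}
        assert A == {("stable", 0): 1.0}

    def test_two_successors_split_mass(self):
        g = ExplicitGraph({0: (1, 2), 1: (), 2: ()})
        new_f = expand({0: 1.0}, {}, {}, g, alpha=1e-6, member_of={})
        assert new_f == {1: 0.5, 2: 0.5}

    def test_neglected_state_promoted_after_accumulation(self):
        # the short arm delivers 1/4 (below alpha=0.3, parked in N); the
        # long arm delivers another 1/2 one step later, promoting it back
        g = delayed_merge()
        F, N, A, member_of = {0: 1.0}, {}, {}, {}
        alpha = 0.3
        F = expand(F, N, A, g, alpha, member_of)  # {1: .5, 3: .5}
        F = expand(F, N, A, g, alpha, member_of)
        assert N[5] == pytest.approx(0.25)
        assert 5 not in F
        F = expand(F, N, A, g, alpha, member_of)
        assert 5 in F
        assert F[5] == pytest.approx(0.75)
        assert 5 not in N

    def test_contributions_accumulate_before_threshold(self):
        # two quarter-contributions arriving in the same step must be
        # summed before the alpha test
        g = ExplicitGraph(
            {0: (1, 2), 1: (3, 4), 2: (3, 5), 3: (), 4: (), 5: ()}
        )
        F = expand({0: 1.0}, {}, {}, g, alpha=0.3, member_of={})
        N = {}
        F = expand(F, N, {}, g, alpha=0.3, member_of={})
        # state 3 receives 0.25 from each arm: individually below alpha,
        # summed above it, so it must stay on the frontier
        assert F == {3: pytest.approx(0.5)}
        assert N == {4: pytest.approx(0.25), 5: pytest.approx(0.25)}

    def test_order_independence_under_shuffled_frontier(self):
        g = delayed_merge()
        member_of = {}
        F, N, A = {0: 1.0}, {}, {}
        F = expand(F, N, A, g, 0.3, member_of)
        forward = expand(dict(F), dict(N), dict(A), g, 0.3, dict(member_of))
        reversed_f = dict(reversed(list(F.items())))
        backward = expand(reversed_f, dict(N), dict(A), g, 0.3, dict(member_of))
        assert forward == backward


class TestRun:
    def test_chain_terminates_exactly(self):
        result = run_firefront(chain_to_stable(5), 0)
        assert result.termination == "F-empty"
        assert result.residual_f == 0
        assert result.residual_n == 0
        assert result.bounds() == {"stable:4": (1.0, 1.0)}
        assert_conserved(result)

    def test_balanced_branch_bounds_are_half(self, toggle):
        result = run_firefront(toggle, toggle.parse_state("00"))
        bounds = result.bounds()
        assert bounds["stable:1"] == pytest.approx((0.5, 0.5))
        assert bounds["stable:2"] == pytest.approx((0.5, 0.5))

    def test_initial_state_already_stable(self, toggle):
        v0 = toggle.parse_state("01")
        result = run_firefront(toggle, v0)
        assert result.bounds() == {f"stable:{v0}": (1.0, 1.0)}

    def test_mass_in_A_is_monotone(self):
        result = run_firefront(random_model(12), 0)
        masses = [row.mass_a for row in result.trace]
        assert all(b >= a - 1e-12 for a, b in zip(masses, masses[1:]))

    @pytest.mark.parametrize("seed", range(12))
    def test_bracketing_against_exact_solver(self, seed):
        model = random_model(seed)
        v0 = 0
        exact = exact_probabilities(model, v0)
        result = run_firefront(
            model, v0, FirefrontParams(alpha=1e-5)
        )
        assert_conserved(result)
        slack = result.residual_f + result.residual_n
        found = {
            est.states: (est.lower, est.upper)
            for est in result.attractors
        }
        for states, p in exact.items():
            lower, upper = found.get(states, (0.0, slack))
            assert lower - 1e-9 <= p <= upper + 1e-9

    def test_alpha_beta_limit_recovers_exact_on_acyclic_fixture(self):
        # binary tree into 4 stable states with distinct probabilities
        g = ExplicitGraph(
            {0: (1, 2), 1: (3, 4), 2: (5,), 3: (), 4: (), 5: ()}
        )
        result = run_firefront(
            g, 0, FirefrontParams(alpha=1e-12, beta=1e-12)
        )
        bounds = result.bounds()
        assert bounds["stable:5"] == pytest.approx((0.5, 0.5), abs=1e-9)
        assert bounds["stable:3"] == pytest.approx((0.25, 0.25), abs=1e-9)


class TestPeriodicity:
    @pytest.mark.parametrize("k", range(3, 11))
    def test_pure_cycle_detected_exactly(self, k):
        result = run_firefront(pure_cycle(k), 0)
        assert result.termination == "periodicity"
        (est,) = result.attractors
        assert est.kind == "complex"
        assert est.states == frozenset(range(k))
        assert (est.lower, est.upper) == (1.0, 1.0)

    def test_chain_never_triggers(self):
        result = run_firefront(chain_to_stable(5), 0)
        assert all(est.kind == "stable" for est in result.attractors)

    def test_two_disjoint_cycles_reported_separately(self):
        # split mass over two deterministic 3-cycles: the repeating
        # frontier covers both, but each terminal SCC must be certified
        # on its own
        g = ExplicitGraph(
            {
                0: (1, 4),
                1: (2,), 2: (3,), 3: (1,),
                4: (5,), 5: (6,), 6: (4,),
            }
        )
        result = run_firefront(g, 0)
        exact = exact_probabilities(g, 0)
        found = {est.states: est for est in result.attractors}
        assert set(found) == set(exact)
        for states, p in exact.items():
            assert found[states].lower == pytest.approx(p, abs=1e-9)

    def test_transient_cycle_not_certified_as_attractor(self):
        # the decaying mass rotating in a transient cycle repeats its
        # support but never its probabilities: no false attractor
        from attrareach.fixtures import planted_transient

        g = planted_transient(6, 1)
        result = run_firefront(g, 0, FirefrontParams(alpha=1e-9))
        assert all(est.kind == "stable" for est in result.attractors)


class TestOracle:
    def test_oracle_halts_exploration_at_known_attractor(self):
        g = pure_cycle(4)
        oracle = Oracle([OracleAttractor("spin", keys=frozenset(range(4)))])
        result = run_firefront(g, 0, oracle=oracle)
        assert result.termination == "F-empty"
        assert result.iterations == 1
        assert result.bounds() == {"spin": (1.0, 1.0)}

    def test_oracle_guarantees_termination_on_covered_model(self):
        # terminal SCC with loops of different lengths: the rotating mass
        # keeps splitting and the frontier does not repeat exactly within
        # the budget, so without the oracle the run times out
        g = ExplicitGraph(
            {0: (1,), 1: (0, 2), 2: (3,), 3: (0,)}
        )
        blind = run_firefront(g, 0, FirefrontParams(max_expansions=50))
        assert blind.termination == "max-expansions"
        oracle = Oracle([OracleAttractor("osc", keys=frozenset(range(4)))])
        seeing = run_firefront(
            g, 0, FirefrontParams(max_expansions=50), oracle=oracle
        )
        assert seeing.termination == "F-empty"
        assert seeing.bounds() == {"osc": (1.0, 1.0)}
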