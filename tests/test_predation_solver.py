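"""Predatory MDP solvers: Bellman operator, value iteration, asymptotics."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stingmdp import (
    CostSpec,
    PredationMDP,
    RewardSpec,
    asymptotic_policy,
    bellman_update,
    policy_monotonicity_report,
    solve_with_increasing_cost,
    value_iteration,
)
from stingmdp.synthetic_data import generate_toy_mdp_fixtures

from .oracles import enumerate_optimal_values, evaluate_stationary_policy

STEP_TABLE = ((0.0, 0.0), (0.95, 0.0), (1.0, -1.0))


class TestBellmanUpdate:
    def test_myopic_at_zero_value(self, mdp_cos):
        """With V = 0 the update is the one-step expected net-reward argmax."""
        V0 = np.zeros(mdp_cos.n_states)
        V1, a1 = bellman_update(V0, mdp_cos)
        # independent recomputation, straight from the model definition
        r = mdp_cos.reward_array()
        a = mdp_cos.action_values
        p = mdp_cos.success.pM * a * (2 - a)
        for i in range(mdp_cos.n_states - 1):
            up, dn = max(i - 1, 0), i + 1
            q = p * r[up] + (1 - p) * r[dn] - mdp_cos.cost.c0(mdp_cos.state_grid[i]) * a
            assert V1[i] == pytest.approx(q.max())
            assert a1[i] == pytest.approx(a[q.argmax()])

    def test_absorbing_state_stays_zero(self, mdp_cos):
        V = np.arange(mdp_cos.n_states, dtype=float)
        V1, a1 = bellman_update(V, mdp_cos)
        assert V1[-1] == 0.0
        assert a1[-1] == 0.0

    def test_length_mismatch_rejected(self, mdp_cos):
        with pytest.raises(ValueError):
            bellman_update(np.zeros(5), mdp_cos)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_contraction(self, seed):
        """Sup-norm distance between updates contracts by at least gamma."""
        mdp = PredationMDP(n_states=9, gamma=0.9, action_grid=51)
        rng = np.random.default_rng(seed)
        U = rng.normal(size=9) * 10
        V = rng.normal(size=9) * 10
        U[-1] = V[-1] = 0.0
        TU, _ = bellman_update(U, mdp)
        TV, _ = bellman_update(V, mdp)
        assert np.max(np.abs(TU - TV)) <= mdp.gamma * np.max(np.abs(U - V)) + 1e-12


class TestValueIteration:
    def test_converges_to_fixed_point(self, mdp_cos, vi_cos):
        assert vi_cos.converged
        assert vi_cos.final_residual <= 1e-9
        assert vi_cos.V[-1] == 0.0
        # returned policy is greedy with respect to the returned values
        V1, a1 = bellman_update(vi_cos.V, mdp_cos)
        assert np.allclose(a1, vi_cos.a_star)
        assert np.max(np.abs(V1 - vi_cos.V)) <= 1e-9

    def test_successive_updates_shrink(self, mdp_cos):
        V = np.zeros(mdp_cos.n_states)
        V1, _ = bellman_update(V, mdp_cos)
        V2, _ = bellman_update(V1, mdp_cos)
        V3, _ = bellman_update(V2, mdp_cos)
        d12 = np.max(np.abs(V2 - V1))
        d23 = np.max(np.abs(V3 - V2))
        assert d23 <= mdp_cos.gamma * d12 + 1e-12

    @pytest.mark.parametrize("fixture", ["vi_cos", "vi_atan"])
    def test_policy_increases_with_starvation(self, fixture, request):
        """Headline prediction: predatory stinging intensifies with starvation."""
        sol = request.getfixturevalue(fixture)
        assert np.all(np.diff(sol.a_star[:-1]) >= -1e-12)

    def test_costly_stinging_without_benefit_is_avoided(self):
        """A flat reward and a steep cost should shut stinging off."""
        mdp = PredationMDP(
            reward=RewardSpec(form="custom_tabulated", table=STEP_TABLE),
            cost=CostSpec(c0_base=5.0),
        )
        sol = value_iteration(mdp)
        assert np.all(sol.a_star[: mdp.n_states // 2] == 0.0)

    def test_nonconvergence_flagged(self, mdp_cos):
        sol = value_iteration(mdp_cos, tol=1e-9, max_iter=3)
        assert not sol.converged
        assert sol.iterations == 3

    @pytest.mark.parametrize("form", ["cos_example", "atan_example"])
    def test_grid_refinement_self_consistency(self, form):
        """Policies at 11 and 21 states agree on shared interior states."""
        a21 = value_iteration(PredationMDP(n_states=21, reward=RewardSpec(form=form))).a_star
        a11 = value_iteration(PredationMDP(n_states=11, reward=RewardSpec(form=form))).a_star
        shared = a21[::2]
        # the satiation-boundary state feels the clamp differently per grid;
        # compare away from both boundary states
        assert np.max(np.abs(shared[1:-1] - a11[1:-1])) <= 0.06

    def test_matches_exhaustive_policy_enumeration(self):
        """On 4-state/3-action instances value iteration equals brute force."""
        for mdp in generate_toy_mdp_fixtures():
            sol = value_iteration(mdp, tol=1e-12)
            V_star = enumerate_optimal_values(mdp)
            assert np.max(np.abs(sol.V - V_star)) <= 1e-8
            # and the greedy policy attains the optimal values
            V_pol = evaluate_stationary_policy(mdp, sol.a_star)
            assert np.max(np.abs(V_pol - V_star)) <= 1e-8


class TestAsymptoticPolicy:
    def test_flat_interior_reward_gives_lower_boundary(self):
        """Zero reward differential leaves no interior benefit to stinging."""
        mdp = PredationMDP(reward=RewardSpec(form="custom_tabulated", table=STEP_TABLE))
        sol = asymptotic_policy(mdp)
        assert np.all(sol.a_star[: mdp.n_states - 3] == 0.0)

    @pytest.mark.parametrize("form", ["cos_example", "atan_example"])
    def test_tracks_value_iteration_in_moderate_regime(self, form):
        """Away from the two boundary layers the relation tracks the exact policy.

        At a moderate discount the optimal actions are interior and
        p'(a) is well-conditioned; the slow-policy approximation then
        reproduces value iteration over the bulk of the grid.
        """
        mdp = PredationMDP(gamma=0.65, reward=RewardSpec(form=form))
        vi = value_iteration(mdp)
        asym = asymptotic_policy(mdp)
        bulk = slice(5, mdp.n_states - 2)
        assert np.max(np.abs(vi.a_star[bulk] - asym.a_star[bulk])) <= 0.05
        assert np.all(np.diff(asym.a_star[1:-1]) >= -1e-9)

    def test_requires_non_increasing_reward(self):
        # a negative scale flips the built-in example into an increasing curve
        mdp = PredationMDP(reward=RewardSpec(form="cos_example", scale=-5.0))
        with pytest.raises(ValueError):
            asymptotic_policy(mdp)


class TestIncreasingCost:
    def test_zero_slope_reduces_to_base_case(self, mdp_cos, vi_cos):
        mdp = PredationMDP(cost=CostSpec(c0_base=1.0, slope=0.0, form="linear_increasing"))
        sol = solve_with_increasing_cost(mdp)
        assert np.allclose(sol.a_star, vi_cos.a_star)

    def test_moderate_slope_still_increasing(self):
        mdp = PredationMDP(cost=CostSpec(c0_base=1.0, slope=1.0, form="linear_increasing"))
        sol = solve_with_increasing_cost(mdp)
        assert sol.extras["monotonicity"]["direction"] == "increasing"

    def test_steep_slope_eventually_decreasing(self):
        mdp = PredationMDP(cost=CostSpec(c0_base=1.0, slope=40.0, form="linear_increasing"))
        sol = solve_with_increasing_cost(mdp)
        report = sol.extras["monotonicity"]
        assert report["direction"] in ("mixed", "decreasing")
        assert report["n_decreasing_steps"] > 0


class TestMonotonicityReport:
    @pytest.mark.parametrize(
        "policy,direction,violations",
        [
            (np.array([0.1, 0.2, 0.3, 0.4, 0.0]), "increasing", 0),
            (np.array([0.5, 0.5, 0.5, 0.5, 0.0]), "constant", 0),
            (np.array([0.1, 0.4, 0.3, 0.5, 0.0]), "mixed", 1),
        ],
    )
    def test_directions(self, policy, direction, violations):
        report = policy_monotonicity_report(policy)
        assert report["direction"] == direction
        assert report["violations"] == violations
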