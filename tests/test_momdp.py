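"""Occupancy-measure LP of finite-horizon multi-objective MDPs.

The brute-force oracle is enumeration of all deterministic Markov policies,
each evaluated exactly by forward dynamic programming; the LP's feasible
criteria region must be the convex hull of those points.
"""

import numpy as np
import pytest

from refpoint import (
    FiniteHorizonMDP,
    MarkovPolicy,
    ScalarizationConfig,
    build_momdp_problem,
    compute_bounds,
    enumerate_policy_points,
    evaluate_policy_dp,
    extract_policy,
    generate_predator_prey_mdp,
    generate_random_mdp,
    occupancy_from_solution,
    solve_reference_point,
    solve_weighted_sum,
)


def split_chain_mdp():
    """One state, two actions, horizon 1: action a1 pays (2, 0), a2 pays (0, 1)."""
    return FiniteHorizonMDP(
        transitions=np.ones((1, 2, 1)),
        rewards=[np.array([[2.0, 0.0]]), np.array([[0.0, 1.0]])],
        horizon=1,
        mu0=np.array([1.0]),
    )


class TestFiniteHorizonMDPValidation:
    def test_bad_row_sum_rejected(self):
        tr = np.ones((1, 2, 1)) * 0.5
        with pytest.raises(ValueError, match="sum to 1"):
            FiniteHorizonMDP(tr, [np.zeros((1, 2))], 2, np.array([1.0]))

    def test_bad_mu0_rejected(self):
        with pytest.raises(ValueError, match="mu0"):
            FiniteHorizonMDP(np.ones((1, 1, 1)), [np.zeros((1, 1))] * 2, 2, np.array([0.5]))

    def test_horizon_must_be_positive(self):
        with pytest.raises(ValueError, match="horizon"):
            FiniteHorizonMDP(np.ones((1, 1, 1)), [np.zeros((1, 1))] * 2, 0, np.array([1.0]))


class TestBuildProblem:
    def test_variable_and_constraint_counts(self, tiny_mdp):
        prob = build_momdp_problem(tiny_mdp)
        # 2 states x 2 actions x 3 steps occupancy variables
        assert prob.n_variables == 12
        # one flow equation per (state, time)
        assert prob.A_eq.shape[0] == 6

    def test_one_step_split_reference_point(self):
        """Hand-derived randomized optimum: maximize min(2a - 2, (1-a) - 1)."""
        from refpoint import CriteriaBounds

        mdp = split_chain_mdp()
        prob = build_momdp_problem(mdp)
        bounds = compute_bounds(prob)
        np.testing.assert_allclose(bounds.z_max, [2, 1], atol=1e-9)
        np.testing.assert_allclose(bounds.z_min, [0, 0], atol=1e-9)
        # unit normalization (lam = (1, 1)) to match the hand derivation
        unit = CriteriaBounds(z_max=np.array([1.0, 1.0]), z_min=np.array([0.0, 0.0]))
        sol = solve_reference_point(
            prob, unit, np.array([2.0, 1.0]), ScalarizationConfig(rho=1e-4)
        )
        np.testing.assert_allclose(sol.criteria, [4 / 3, 1 / 3], atol=1e-6)
        occ = occupancy_from_solution(mdp, sol)
        np.testing.assert_allclose(occ[0, 0], [2 / 3, 1 / 3], atol=1e-6)

    def test_zero_rewards_zero_criteria(self):
        mdp = generate_random_mdp(2, 2, 3, seed=1)
        mdp = FiniteHorizonMDP(
            mdp.transitions, [np.zeros((2, 2)), np.zeros((2, 2))], 3, mdp.mu0
        )
        prob = build_momdp_problem(mdp)
        with pytest.warns(UserWarning, match="degenerate"):
            bounds = compute_bounds(prob)
        np.testing.assert_allclose(bounds.z_max, 0, atol=1e-9)
        np.testing.assert_allclose(bounds.z_min, 0, atol=1e-9)


class TestPolicyExtraction:
    def test_normalization(self):
        mdp = split_chain_mdp()
        occ = np.array([[[2 / 3, 1 / 3]]])
        pol = extract_policy(mdp, occ)
        np.testing.assert_allclose(pol.pi[0, 0], [2 / 3, 1 / 3])

    def test_unreachable_state_uniform(self):
        mdp = generate_random_mdp(2, 2, 1, seed=0)
        occ = np.array([[[1.0, 0.0], [0.0, 0.0]]])  # state 1 never visited
        pol = extract_policy(mdp, occ)
        np.testing.assert_allclose(pol.pi[0, 1], [0.5, 0.5])

    def test_negative_occupancy_rejected(self):
        mdp = split_chain_mdp()
        with pytest.raises(ValueError, match="nonnegative"):
            extract_policy(mdp, np.array([[[-0.5, 1.5]]]))


class TestEvaluatePolicyDP:
    def test_one_step_randomized_policy(self):
        mdp = split_chain_mdp()
        pol = MarkovPolicy(np.array([[[2 / 3, 1 / 3]]]))
        np.testing.assert_allclose(evaluate_policy_dp(mdp, pol), [4 / 3, 1 / 3], atol=1e-12)

    def test_constant_reward_chain(self):
        mdp = FiniteHorizonMDP(
            np.ones((1, 1, 1)), [np.ones((1, 1)), np.zeros((1, 1))], 5, np.array([1.0])
        )
        pol = MarkovPolicy(np.ones((5, 1, 1)))
        np.testing.assert_allclose(evaluate_policy_dp(mdp, pol), [5, 0], atol=1e-12)


class TestPredatorPreyGenerator:
    def test_shapes_and_stochasticity(self):
        mdp = generate_predator_prey_mdp(5, 5, 20, seed=1)
        assert mdp.n_states == 25 and mdp.n_actions == 4 and mdp.horizon == 20
        np.testing.assert_allclose(mdp.transitions.sum(axis=2), 1.0, atol=1e-12)
        assert all(R.max() == pytest.approx(1.0) for R in mdp.rewards)

    def test_seed_determinism(self):
        a = generate_predator_prey_mdp(4, 4, 10, seed=7)
        b = generate_predator_prey_mdp(4, 4, 10, seed=7)
        np.testing.assert_array_equal(a.transitions, b.transitions)
        np.testing.assert_array_equal(a.rewards[0], b.rewards[0])

    def test_criteria_genuinely_conflict(self):
        """Optimizing prey alone and predators alone land at different points."""
        mdp = generate_predator_prey_mdp(3, 3, 8, seed=2)
        bounds = compute_bounds(build_momdp_problem(mdp))
        prob = build_momdp_problem(mdp)
        best_prey = solve_weighted_sum(prob, np.array([1.0, 0.0]))
        best_pred = solve_weighted_sum(prob, np.array([0.0, 1.0]))
        assert best_prey.criteria[1] < bounds.z_max[1] - 0.1
        assert best_pred.criteria[0] < bounds.z_max[0] - 0.1

    def test_invalid_sizes(self):
        with pytest.raises(ValueError):
            generate_predator_prey_mdp(1, 5, 10, seed=0)


class TestEnumeratePolicies:
    def test_counts(self):
        assert len(enumerate_policy_points(split_chain_mdp())) == 2
        mdp = generate_random_mdp(2, 2, 2, seed=3)
        assert len(enumerate_policy_points(mdp)) == 16

    def test_cap(self):
        mdp = generate_random_mdp(3, 3, 5, seed=0)
        with pytest.raises(ValueError, match="cap"):
            enumerate_policy_points(mdp, cap=100)


class TestLPAgainstOracles:
    @pytest.mark.parametrize("seed", range(6))
    def test_lp_dp_round_trip(self, seed):
        """Solve LP, extract policy, re-evaluate by DP: criteria agree to 1e-6."""
        mdp = generate_random_mdp(3, 2, 4, seed=seed)
        prob = build_momdp_problem(mdp)
        bounds = compute_bounds(prob)
        z_bar = bounds.z_max  # utopian corner
        sol = solve_reference_point(prob, bounds, z_bar)
        occ = occupancy_from_solution(mdp, sol)
        got = evaluate_policy_dp(mdp, extract_policy(mdp, occ))
        np.testing.assert_allclose(got, sol.criteria, atol=1e-6)

    @pytest.mark.parametrize("seed", range(4))
    def test_occupancy_sums_to_one_each_step(self, seed):
        mdp = generate_random_mdp(3, 2, 4, seed=100 + seed)
        prob = build_momdp_problem(mdp)
        bounds = compute_bounds(prob)
        sol = solve_reference_point(prob, bounds, (bounds.z_max + bounds.z_min) / 2)
        occ = occupancy_from_solution(mdp, sol)
        np.testing.assert_allclose(occ.sum(axis=(1, 2)), 1.0, atol=1e-9)

    def test_weighted_sum_matches_best_deterministic_policy(self):
        """LP weighted optimum equals the max over enumerated deterministic policies."""
        mdp = generate_random_mdp(2, 2, 3, seed=9)
        prob = build_momdp_problem(mdp)
        pts = enumerate_policy_points(mdp).criteria
        for w in ([1.0, 0.0], [0.3, 0.7], [0.5, 0.5]):
            w = np.asarray(w)
            sol = solve_weighted_sum(prob, w)
            assert float(w @ sol.criteria) == pytest.approx(float((pts @ w).max()), abs=1e-6)

    def test_rp_solution_in_hull_and_undominated(self):
        """LP criteria lie in the deterministic-policy hull and are non-dominated."""
        from scipy.optimize import linprog

        mdp = generate_random_mdp(2, 2, 2, seed=21)
        prob = build_momdp_problem(mdp)
        bounds = compute_bounds(prob)
        pts = enumerate_policy_points(mdp).criteria
        sol = solve_reference_point(prob, bounds, bounds.z_max)
        # hull membership: exists convex combination of pts equal to sol.criteria
        m = pts.shape[0]
        res = linprog(
            c=np.zeros(m),
            A_eq=np.vstack([pts.T, np.ones(m)]),
            b_eq=np.concatenate([sol.criteria, [1.0]]),
            bounds=[(0, 1)] * m,
            method="highs",
        )
        assert res.status == 0, "LP optimum outside deterministic-policy hull"
        for z in pts:
            assert not (np.all(z >= sol.criteria + 1e-9) and np.any(z > sol.criteria + 1e-6))
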