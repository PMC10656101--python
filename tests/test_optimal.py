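"""Belief-state MDP: posteriors, beliefs, transitions, Bellman solution,
reward-rate calibration."""

import numpy as np
import pytest

from difficulty_ddm.optimal import (
    CHOOSE_S1,
    CHOOSE_S2,
    SAMPLE,
    OptimalConfig,
    backward_induction,
    belief_correct,
    coherence_posterior,
    known_color_config,
    sample_transition_matrix,
    simulate_optimal,
    solve_reward_rate,
    _increment_kernels,
    _omega_matrix,
    _slice_times,
)

#: Small, fast MDP used for solver tests.
SMALL = OptimalConfig(
    kappa=8.0, dt=0.1, ddv=0.25, dv_range=3.0, horizon=2.0
)


class TestPosterior:
    def test_prior_at_t_zero(self):
        p = coherence_posterior(np.array([0.4]), 0.0, SMALL)
        assert np.allclose(p, 1.0 / 12)

    def test_normalized_everywhere(self):
        p = coherence_posterior(SMALL.dv_grid, 0.7, SMALL)
        assert np.allclose(p.sum(axis=1), 1.0, atol=1e-10)

    def test_mode_at_generating_coherence(self):
        cfg = OptimalConfig(kappa=13.0, dt=0.05, ddv=0.1, dv_range=30.0, horizon=5.0)
        t = 2.0
        dv = 13.0 * 0.64 * t
        p = coherence_posterior(np.array([dv]), t, cfg)[0]
        assert cfg.coherences[int(np.argmax(p))] == pytest.approx(0.64)

    def test_brute_force_agreement(self):
        # direct unnormalized Gaussian x prior evaluation
        dv, t = 0.8, 0.6
        coh = np.asarray(SMALL.coherences)
        w = np.exp(-((dv - SMALL.kappa * coh * t) ** 2) / (2 * t)) / 12
        assert np.allclose(
            coherence_posterior(np.array([dv]), t, SMALL)[0], w / w.sum()
        )


class TestBelief:
    @pytest.mark.parametrize(
        "a,b,expected", [(0.512, 0.256, 1.0), (0.256, 0.512, 0.0), (0.384, -0.384, 0.5)]
    )
    def test_omega_truth_table(self, a, b, expected):
        om = _omega_matrix([a, b])
        assert om[0, 1] == expected

    def test_initial_state_is_even(self):
        b = belief_correct(np.array([0.0]), 0.0, np.array([0.0]), 0.0, SMALL)
        assert b[0, 0] == pytest.approx(0.5, abs=1e-12)

    def test_brute_force_double_sum(self):
        dv1, t1, dv2, t2 = 0.9, 0.5, -0.3, 0.4
        p1 = coherence_posterior(np.array([dv1]), t1, SMALL)[0]
        p2 = coherence_posterior(np.array([dv2]), t2, SMALL)[0]
        coh = SMALL.coherences
        total = 0.0
        for i, c1 in enumerate(coh):
            for j, c2 in enumerate(coh):
                w = 1.0 if abs(c1) > abs(c2) else (0.0 if abs(c1) < abs(c2) else 0.5)
                total += p1[i] * p2[j] * w
        b = belief_correct(np.array([dv1]), t1, np.array([dv2]), t2, SMALL)
        assert b[0, 0] == pytest.approx(total, abs=1e-12)

    def test_complement(self):
        g = SMALL.dv_grid
        b1 = belief_correct(g, 0.5, g, 0.4, SMALL)
        b2 = 1.0 - b1
        assert np.all((b1 >= 0) & (b1 <= 1)) and np.all((b2 >= 0) & (b2 <= 1))


class TestTransitions:
    def test_rows_sum_to_one(self):
        T = sample_transition_matrix(0.5, SMALL)
        assert np.allclose(T.sum(axis=1), 1.0, atol=1e-8)

    def test_symmetric_at_prior(self):
        # before any evidence the posterior is sign-symmetric, so the
        # transition from dv = 0 is symmetric about 0
        T = sample_transition_matrix(0.0, SMALL)
        center = SMALL.dv_grid.size // 2
        row = T[center]
        assert np.allclose(row, row[::-1], atol=1e-12)

    def test_concentrated_posterior_single_gaussian(self):
        cfg = OptimalConfig(
            kappa=8.0, coherences=(0.64,), prior=(1.0,),
            dt=0.1, ddv=0.25, dv_range=3.0, horizon=2.0,
        )
        kern = _increment_kernels(cfg)
        T = sample_transition_matrix(1.0, cfg, kern)
        assert np.allclose(T, kern[0], atol=1e-12)
        mean_inc = (T * (cfg.dv_grid[None, :] - cfg.dv_grid[:, None])).sum(axis=1)
        center = cfg.dv_grid.size // 2
        assert mean_inc[center] == pytest.approx(8.0 * 0.64 * 0.1, abs=0.01)


class TestBackwardInduction:
    def test_degenerate_rewards_stop_immediately(self):
        cfg = OptimalConfig(
            kappa=8.0, rc=1.0, rn=1.0, tp=0.0,
            dt=0.1, ddv=0.25, dv_range=3.0, horizon=2.0,
        )
        sol = backward_induction(cfg, rho=0.5)
        center = cfg.dv_grid.size // 2
        assert sol.policy[0, center, center] in (CHOOSE_S1, CHOOSE_S2)

    def test_value_dominates_stopping_values(self):
        sol = backward_induction(SMALL, rho=0.4)
        for n in (0, 5, 10):
            t1, t2 = _slice_times(n, SMALL.dt)
            b1 = belief_correct(SMALL.dv_grid, t1, SMALL.dv_grid, t2, SMALL)
            stop_cost = (SMALL.tnd + SMALL.tw) * 0.4
            err = SMALL.rn - SMALL.tp * 0.4
            v1 = b1 * SMALL.rc + (1 - b1) * err - stop_cost
            v2 = (1 - b1) * SMALL.rc + b1 * err - stop_cost
            assert np.all(sol.value[n] >= np.maximum(v1, v2) - 1e-12)

    def test_terminal_slice_is_terminal(self):
        sol = backward_induction(SMALL, rho=0.4)
        assert np.all(sol.policy[-1] != SAMPLE)

    def test_bellman_slice_consistency(self):
        # recompute slice n from slice n+1 with independently composed
        # pieces and compare against the stored value function
        rho = 0.35
        sol = backward_induction(SMALL, rho)
        n = 4  # even: S1 is sampled next
        t1, t2 = _slice_times(n, SMALL.dt)
        T = sample_transition_matrix(t1, SMALL)
        cont = T @ sol.value[n + 1] - rho * SMALL.dt
        b1 = belief_correct(SMALL.dv_grid, t1, SMALL.dv_grid, t2, SMALL)
        stop_cost = (SMALL.tnd + SMALL.tw) * rho
        err = SMALL.rn - SMALL.tp * rho
        v_stop = np.maximum(
            b1 * SMALL.rc + (1 - b1) * err - stop_cost,
            (1 - b1) * SMALL.rc + b1 * err - stop_cost,
        )
        assert np.allclose(sol.value[n], np.maximum(cont, v_stop), atol=1e-12)

    @staticmethod
    def _mirror(pol):
        swapped = pol.T.copy()
        s1 = swapped == CHOOSE_S1
        s2 = swapped == CHOOSE_S2
        swapped[s1] = CHOOSE_S2
        swapped[s2] = CHOOSE_S1
        return swapped

    def test_policy_mirror_symmetry(self):
        # exchanging the DVs swaps the choose regions.  At the terminal
        # slice (no continuation) the mirror is exact away from exact
        # stopping-value ties; at interior slices the fixed alternation
        # order (S1 is always the next sample on even slices) perturbs the
        # symmetry by at most one dt of sampling, so it holds approximately
        sol = backward_induction(SMALL, rho=0.4)
        n_term = sol.policy.shape[0] - 1
        t1, t2 = _slice_times(n_term, SMALL.dt)
        b1 = belief_correct(SMALL.dv_grid, t1, SMALL.dv_grid, t2, SMALL)
        untied = ~np.isclose(b1, b1.T, atol=1e-12)
        pol = sol.policy[n_term]
        assert np.array_equal(pol[untied], self._mirror(pol)[untied])
        for n in (2, 8):
            assert np.allclose(sol.value[n], sol.value[n].T, atol=0.02)
            pol = sol.policy[n]
            mismatch = (pol != self._mirror(pol)).mean()
            assert mismatch < 0.05


class TestRewardRate:
    def test_root_found(self):
        sol = solve_reward_rate(SMALL)
        assert abs(sol.v0) < 1e-3

    def test_rho_decreases_with_longer_intertrial(self):
        slow = OptimalConfig(
            kappa=8.0, tw=2.0, dt=0.1, ddv=0.25, dv_range=3.0, horizon=2.0
        )
        assert solve_reward_rate(slow).rho < solve_reward_rate(SMALL).rho

    def test_rho_increases_with_sensitivity(self):
        sharp = OptimalConfig(
            kappa=16.0, dt=0.1, ddv=0.25, dv_range=3.0, horizon=2.0
        )
        assert solve_reward_rate(sharp).rho > solve_reward_rate(SMALL).rho

    def test_bad_bracket_reported(self):
        with pytest.raises(ValueError, match="bracket"):
            solve_reward_rate(SMALL, bracket=(5.0, 6.0))


class TestSimulateAndKnownColor:
    def test_simulation_outputs(self, rng):
        sol = solve_reward_rate(SMALL)
        sim = simulate_optimal(sol, 2000, rng)
        assert set(np.unique(sim["choice"])) <= {1, 2}
        assert np.all(sim["rt"] == sim["decision_time"] + SMALL.tnd)
        # harder-vs-easier discrimination beats chance
        clear = np.abs(np.abs(sim["c1"]) - np.abs(sim["c2"])) >= 0.384
        assert sim["correct"][clear].mean() > 0.6

    def test_known_color_restricts_support(self):
        cfg = known_color_config(SMALL)
        assert len(cfg.coherences) == 6
        assert all(c >= 0 for c in cfg.coherences)
        b = belief_correct(np.array([0.0]), 0.0, np.array([0.0]), 0.0, cfg)
        assert b[0, 0] == pytest.approx(0.5)

    def test_negative_evidence_means_lowest_coherence(self):
        cfg = known_color_config(SMALL)
        p = coherence_posterior(np.array([-2.5]), 0.5, cfg)[0]
        assert int(np.argmax(p)) == int(np.argmin(np.abs(cfg.coherences)))
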