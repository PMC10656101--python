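"""Smoothed simulation likelihood, fitting machinery, model selection."""

import math

import numpy as np
import pandas as pd
import pytest

from difficulty_ddm.core import CollapsingBound, ColorDDMParams
from difficulty_ddm.data import design_exp1_color, design_grid, generate_dataset
from difficulty_ddm.fitting import (
    DENSITY_FLOOR,
    bic,
    exceedance_probabilities,
    fit_color_ddm,
    fit_controlled_duration,
    fit_difficulty_model,
    group_bic,
    negative_log_likelihood,
    simulate_likelihood_table,
)
from difficulty_ddm.models import DifficultyParams


PAIRS = [(a, b) for a in (-0.384, 0.0, 0.384) for b in (-0.384, 0.0, 0.384)]


class TestBIC:
    def test_zero(self):
        assert bic(0.0, 0, 10) == 0.0

    def test_parameter_penalty(self):
        assert bic(-5.0, 3, 100) - bic(-5.0, 2, 100) == pytest.approx(math.log(100))

    def test_group_sum(self):
        m = np.array([[10.0, 12.0]] * 5)
        assert np.allclose(group_bic(m), [50.0, 60.0])

    def test_invalid_n(self):
        with pytest.raises(ValueError):
            bic(0.0, 1, 0)


class TestSmoothedLikelihood:
    def test_normalizes_per_condition(self, ref_params):
        tab = simulate_likelihood_table(
            "difference", ref_params, PAIRS, n_sim_per_condition=400, dt=0.01, seed=3
        )
        t = np.arange(0.0, 7.0, 0.005)
        for key in list(tab.cells)[:3]:
            total = sum(
                np.trapezoid(tab.density(key[0], key[1], ch, t), t) for ch in (1, 2)
            )
            # floor adds ~7 * 2 * 1e-5; kernel mass is preserved otherwise
            assert total == pytest.approx(1.0, abs=2e-3)

    def test_far_rt_hits_floor(self, ref_params):
        tab = simulate_likelihood_table(
            "difference", ref_params, PAIRS, n_sim_per_condition=100, dt=0.01, seed=3
        )
        d = tab.density(0.0, 0.0, 1, 60.0)
        assert d[0] == DENSITY_FLOOR

    def test_common_random_numbers_bitwise(self, ref_params):
        a = simulate_likelihood_table(
            "difference", ref_params, PAIRS, n_sim_per_condition=200, dt=0.01, seed=9
        )
        b = simulate_likelihood_table(
            "difference", ref_params, PAIRS, n_sim_per_condition=200, dt=0.01, seed=9
        )
        for key in a.cells:
            assert np.array_equal(a.cells[key].dts[0], b.cells[key].dts[0])
            assert a.cells[key].p_s1 == b.cells[key].p_s1

    def test_monte_carlo_error_scaling(self, ref_params):
        # choice-mass standard error should shrink ~1/sqrt(n_sim)
        def sds(n):
            ps = []
            for s in range(40):
                tab = simulate_likelihood_table(
                    "difference", ref_params, [(0.128, 0.0)],
                    n_sim_per_condition=n, dt=0.01, seed=100 + s,
                )
                ps.append(tab.cells[(0.128, 0.0)].p_s1)
            return np.std(ps)

        ratio = sds(100) / sds(400)  # expect ~2 for a 4x simulation count
        assert 1.4 < ratio < 2.9


class TestNegativeLogLikelihood:
    def test_empty_data(self, ref_params):
        tab = simulate_likelihood_table(
            "difference", ref_params, PAIRS, n_sim_per_condition=50, dt=0.01, seed=1
        )
        empty = pd.DataFrame(columns=["c1_signed", "c2_signed", "choice", "rt"])
        assert negative_log_likelihood(empty, tab) == 0.0

    def test_floor_contribution(self, ref_params):
        tab = simulate_likelihood_table(
            "difference", ref_params, PAIRS, n_sim_per_condition=50, dt=0.01, seed=1
        )
        one = pd.DataFrame(
            {"c1_signed": [0.0], "c2_signed": [0.0], "choice": [1], "rt": [55.0]}
        )
        assert negative_log_likelihood(one, tab) == pytest.approx(
            -math.log(DENSITY_FLOOR)
        )

    def test_unseen_condition_rejected(self, ref_params):
        tab = simulate_likelihood_table(
            "difference", ref_params, PAIRS, n_sim_per_condition=50, dt=0.01, seed=1
        )
        odd = pd.DataFrame(
            {"c1_signed": [0.512], "c2_signed": [0.0], "choice": [1], "rt": [1.0]}
        )
        with pytest.raises(KeyError):
            negative_log_likelihood(odd, tab)

    def test_true_params_beat_mismatched(self, ref_params):
        design = design_grid(strengths=(0.0, 0.384), trials_per_pair=30, seed=2)
        data = generate_dataset("difference", ref_params, design, seed=5, dt=0.01)
        pairs = list(zip(data["c1_signed"], data["c2_signed"]))
        tab_true = simulate_likelihood_table(
            "difference", ref_params, pairs, n_sim_per_condition=600, dt=0.01, seed=6
        )
        wrong = DifficultyParams(
            kappa=2 * ref_params.kappa, bound=ref_params.bound, tnd_mean=0.35
        )
        tab_wrong = simulate_likelihood_table(
            "difference", wrong, pairs, n_sim_per_condition=600, dt=0.01, seed=6
        )
        assert negative_log_likelihood(data, tab_true) < negative_log_likelihood(
            data, tab_wrong
        )


class TestFitDifficulty:
    def test_recovers_kappa_and_tnd(self, ref_params):
        design = design_grid(strengths=(0.0, 0.128, 0.384, 0.64),
                             trials_per_pair=10, seed=3)
        data = generate_dataset("difference", ref_params, design, seed=31, dt=0.01)
        rng = np.random.default_rng(32)
        fr = fit_difficulty_model(
            "difference", data, n_starts=3, n_sim_per_condition=120, dt=0.01,
            rng=rng, maxfev=50, n_sim_refine=600, maxfev_refine=50,
        )
        assert fr.params["kappa"] == pytest.approx(ref_params.kappa, rel=0.2)
        assert fr.params["tnd"] == pytest.approx(ref_params.tnd_mean, abs=0.08)
        assert fr.bic == pytest.approx(
            -2 * fr.log_lik + fr.n_params * math.log(fr.n_trials)
        )

    def test_deterministic_given_rng_state(self, ref_params):
        design = design_grid(strengths=(0.0, 0.384), trials_per_pair=8, seed=4)
        data = generate_dataset("difference", ref_params, design, seed=41, dt=0.01)
        fits = [
            fit_difficulty_model(
                "difference", data, n_starts=1, n_sim_per_condition=60, dt=0.01,
                rng=np.random.default_rng(42), maxfev=15, n_sim_refine=0,
            )
            for _ in range(2)
        ]
        assert fits[0].log_lik == fits[1].log_lik
        assert fits[0].params == fits[1].params


class TestFitColorDDM:
    def test_recovery_and_bias_sign(self):
        truth = ColorDDMParams(
            kappa=12.0, c0=0.05, bound=CollapsingBound(1.6, 1.5, 1.0), tnd_mean=0.32
        )
        design = design_exp1_color(seed=0)  # 432 trials, 12 signed levels
        data = generate_dataset("color", truth, design, seed=100, dt=0.002)
        rng = np.random.default_rng(10)
        fr = fit_color_ddm(
            data, n_starts=2, dt=0.01, rng=rng, maxfev=110, n_dv_cells=100
        )
        assert fr.params["kappa"] == pytest.approx(12.0, rel=0.15)
        assert fr.params["c0"] > 0
        # fitted psychometric curve must be monotone in signed coherence
        from difficulty_ddm.core import fp_choice_rt_density

        fitted = ColorDDMParams(
            kappa=fr.params["kappa"], c0=fr.params["c0"],
            bound=CollapsingBound(fr.params["u"], fr.params["a"], fr.params["d"]),
            tnd_mean=fr.params["tnd"],
        )
        p_up = [
            fp_choice_rt_density(fitted, c, dt=0.01, horizon=6.0).prob_upper
            for c in (-0.64, -0.256, 0.0, 0.256, 0.64)
        ]
        assert np.all(np.diff(p_up) > 0)


def _controlled_table(strengths, sign, durations, reps, knowledge):
    rows = []
    for s1 in strengths:
        for s2 in strengths:
            for dur in durations:
                for _ in range(reps):
                    rows.append((sign * s1, sign, sign * s2, sign, dur))
    df = pd.DataFrame(
        rows, columns=["c1_signed", "c1_tag", "c2_signed", "c2_tag", "duration"]
    )
    df["participant"] = "sim01"
    df["session"] = 1
    df["block"] = 1
    df["task"] = "difficulty"
    df["paradigm"] = "controlled_duration"
    df["color_knowledge"] = knowledge
    return df


class TestControlledDurationFit:
    def test_single_kappa_and_buffer_preferred(self, ref_params):
        strengths = (0.0, 0.256, 0.64)
        durations = (0.1, 0.25, 0.85)
        du = _controlled_table(strengths, 1, durations, 14, "unknown")
        dk = _controlled_table(strengths, 1, durations, 14, "known_blue")
        data_u = generate_dataset("difference", ref_params, du, seed=7, dt=0.005)
        data_k = generate_dataset("difference", ref_params, dk, seed=8, dt=0.005)
        common = dict(
            n_starts=2, n_sim_per_condition=400, dt=0.005, maxfev=60
        )
        fr1 = fit_controlled_duration(
            data_u, data_k, single_kappa=True, use_buffer=True,
            rng=np.random.default_rng(1), **common,
        )
        fr2 = fit_controlled_duration(
            data_u, data_k, single_kappa=False, use_buffer=True,
            rng=np.random.default_rng(2), **common,
        )
        fr0 = fit_controlled_duration(
            data_u, data_k, single_kappa=True, use_buffer=False,
            rng=np.random.default_rng(3), **common,
        )
        # generator used one kappa and the 80 ms buffer
        assert fr1.bic < fr2.bic
        assert fr1.bic < fr0.bic
        assert fr1.params["kappa"] == pytest.approx(ref_params.kappa, rel=0.35)


class TestExceedance:
    def test_uniform_under_identical_evidence(self, rng):
        lme = np.zeros((12, 3))
        xp, _, _ = exceedance_probabilities(lme, rng=rng)
        assert np.allclose(xp, 1 / 3, atol=0.02)

    def test_dominant_model_wins(self, rng):
        bics = np.zeros((20, 4))
        bics[:, 1] = -10.0  # better by dBIC = 10 for every participant
        xp, _, _ = exceedance_probabilities(-bics / 2.0, rng=rng)
        assert xp[1] > 0.95

    def test_sums_to_one(self, rng):
        lme = rng.normal(size=(6, 5))
        xp, alpha, freq = exceedance_probabilities(lme, rng=rng)
        assert xp.sum() == pytest.approx(1.0, abs=1e-6)
        assert freq.sum() == pytest.approx(1.0, abs=1e-9)

    def test_rejects_non_finite(self, rng):
        lme = np.array([[0.0, np.inf]])
        with pytest.raises(ValueError):
            exceedance_probabilities(lme, rng=rng)
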