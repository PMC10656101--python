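"""Reward-rate-optimal policy for difficulty judgments.

The task is a POMDP whose belief state is fully summarized by the tuple
⟨tS1, tS2, DVS1, DVS2⟩ — how long each stimulus has been sampled and the
evidence accumulated for each.  Sampling alternates between stimuli in
steps of dt.  The decision maker can stop and name either stimulus as the
easier one, earning Rc if its coherence strength is strictly larger (ties
pay half the time), Rn plus a time penalty tp otherwise, or pay the
opportunity cost rho*dt to take one more sample.  Discretizing time and
evidence turns the problem into a finite MDP solved exactly by one
backward pass; the reward rate rho is not known a priori (it depends on
the policy) and is pinned down by bisecting on V(s0) = 0, the defining
property of the optimal average-reward policy.

Posterior beliefs over the discrete coherence set follow from the Gaussian
evidence model: P(C | dv, t) ∝ N(dv | kappa*C*t, t) P(C).  The known-color
task replaces the signed coherence set by the unsigned one.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.special import ndtr

from ._kernels import optimal_policy_batch
from .core import COHERENCE_STRENGTHS, SIGNED_COHERENCES

__all__ = [
    "OptimalConfig",
    "PolicySolution",
    "coherence_posterior",
    "belief_correct",
    "sample_transition_matrix",
    "backward_induction",
    "solve_reward_rate",
    "simulate_optimal",
    "known_color_config",
]

#: Action codes in the policy table.
SAMPLE, CHOOSE_S1, CHOOSE_S2 = 0, 1, 2


@dataclass(frozen=True)
class OptimalConfig:
    """Parameters of the belief-state MDP.

    Defaults follow the reference simulation: kappa = 13, Rc = 1, Rn = 0,
    tp = 1 s, tnd = 0.4 s, tw = 0.5 s, dt = 0.05 s, ddv = 0.1.  ``dv_range``
    bounds the evidence grid; probability mass drifting beyond it is
    accumulated in the edge bins (kappa = 13 runs clip substantial drift,
    so +/-6 is the working default).  ``horizon`` is total sampling time;
    at the final slice a terminal action is forced.
    """

    kappa: float = 13.0
    coherences: tuple = SIGNED_COHERENCES
    rc: float = 1.0
    rn: float = 0.0
    tp: float = 1.0
    tnd: float = 0.4
    tw: float = 0.5
    dt: float = 0.05
    ddv: float = 0.1
    dv_range: float = 6.0
    horizon: float = 5.0
    prior: tuple = field(default=None)

    def __post_init__(self):
        if self.dt <= 0 or self.ddv <= 0:
            raise ValueError("dt and ddv must be positive")
        if self.prior is None:
            n = len(self.coherences)
            object.__setattr__(self, "prior", tuple([1.0 / n] * n))
        if abs(sum(self.prior) - 1.0) > 1e-9:
            raise ValueError("prior must sum to 1")

    @property
    def dv_grid(self) -> np.ndarray:
        half = int(round(self.dv_range / self.ddv))
        return np.arange(-half, half + 1) * self.ddv

    @property
    def n_slices(self) -> int:
        return int(round(self.horizon / self.dt))


def known_color_config(config: OptimalConfig) -> OptimalConfig:
    """Restrict the coherence set to the unsigned values (known dominance)."""
    return replace(
        config, coherences=tuple(COHERENCE_STRENGTHS), prior=None
    )


def coherence_posterior(dv, t, config: OptimalConfig) -> np.ndarray:
    """P(C | dv, t) over the coherence set; the prior at t = 0.

    Vectorized over ``dv``: returns shape (len(dv), n_coherences).
    """
    dv = np.atleast_1d(np.asarray(dv, dtype=float))
    coh = np.asarray(config.coherences)
    prior = np.asarray(config.prior)
    if t <= 0:
        return np.tile(prior, (dv.size, 1))
    z = -((dv[:, None] - config.kappa * coh[None, :] * t) ** 2) / (2.0 * t)
    z -= z.max(axis=1, keepdims=True)
    w = np.exp(z) * prior[None, :]
    return w / w.sum(axis=1, keepdims=True)


def _omega_matrix(coherences) -> np.ndarray:
    """Pairwise win matrix: 1 if |C1| > |C2|, 0 if smaller, 0.5 on ties."""
    a = np.abs(np.asarray(coherences))
    return np.where(
        a[:, None] > a[None, :], 1.0, np.where(a[:, None] < a[None, :], 0.0, 0.5)
    )


def belief_correct(dv1, t1, dv2, t2, config: OptimalConfig) -> np.ndarray:
    """b(s, S1): probability that choosing S1 is correct.

    Double sum over coherence pairs of the posterior product weighted by
    the win matrix; returns shape (len(dv1), len(dv2)).
    """
    p1 = coherence_posterior(dv1, t1, config)
    p2 = coherence_posterior(dv2, t2, config)
    om = _omega_matrix(config.coherences)
    return p1 @ om @ p2.T


def _increment_kernels(config: OptimalConfig) -> np.ndarray:
    """Per-coherence transition kernels K[c, i, j] = P(dv_j | dv_i, C_c).

    Gaussian CDF differences over the destination bins, with out-of-range
    mass accumulated at the edge bins (exact mass conservation).
    """
    grid = config.dv_grid
    m = grid.size
    coh = np.asarray(config.coherences)
    sd = math.sqrt(config.dt)
    edges = np.concatenate([[-np.inf], (grid[:-1] + grid[1:]) / 2.0, [np.inf]])
    kernels = np.empty((coh.size, m, m))
    for c, cval in enumerate(coh):
        mean = config.kappa * cval * config.dt
        # increment = dv_j - dv_i; rows are sources
        z = (edges[None, :] - (grid[:, None] + mean)) / sd
        cdf = np.empty_like(z)
        finite = np.isfinite(z)
        cdf[finite] = ndtr(z[finite])
        cdf[z == -np.inf] = 0.0
        cdf[z == np.inf] = 1.0
        kernels[c] = np.diff(cdf, axis=1)
    return kernels


def sample_transition_matrix(t, config: OptimalConfig, kernels=None) -> np.ndarray:
    """T[i, j] = P(dv' = grid[j] | dv = grid[i]) after one sample at time t.

    Mixture of the per-coherence kernels weighted by the current posterior
    at each source dv.
    """
    if kernels is None:
        kernels = _increment_kernels(config)
    w = coherence_posterior(config.dv_grid, t, config)  # (m, n_coh)
    return np.einsum("ic,cij->ij", w, kernels)


@dataclass
class PolicySolution:
    """Solved value function and policy over ⟨slice, dv1, dv2⟩ states."""

    config: OptimalConfig
    rho: float
    policy: np.ndarray  # int8 (n_slices+1, m, m)
    value: np.ndarray  # float64 (n_slices+1, m, m)
    v0: float

    def continue_region(self, n: int) -> np.ndarray:
        return self.policy[n] == SAMPLE


def _slice_times(n: int, dt: float) -> tuple[float, float]:
    """Sampling times (tS1, tS2) after n total samples (S1 on even steps)."""
    return (math.ceil(n / 2) * dt, math.floor(n / 2) * dt)


def backward_induction(config: OptimalConfig, rho: float) -> PolicySolution:
    """Solve the Bellman equations for a given reward rate rho.

    One backward pass over sampling slices; at the terminal slice only the
    two stopping actions are available.  Ties between stopping actions and
    sampling resolve to stopping (degenerate reward structures then stop
    immediately, as they should under an opportunity cost of time).
    """
    grid = config.dv_grid
    m = grid.size
    n_slices = config.n_slices
    kernels = _increment_kernels(config)
    om = _omega_matrix(config.coherences)
    stop_cost = (config.tnd + config.tw) * rho
    err_val = config.rn - config.tp * rho

    policy = np.zeros((n_slices + 1, m, m), dtype=np.int8)
    value = np.empty((n_slices + 1, m, m))

    v_next = None
    for n in range(n_slices, -1, -1):
        t1, t2 = _slice_times(n, config.dt)
        b1 = belief_correct(grid, t1, grid, t2, config)
        val1 = b1 * config.rc + (1.0 - b1) * err_val - stop_cost
        val2 = (1.0 - b1) * config.rc + b1 * err_val - stop_cost
        v_stop = np.maximum(val1, val2)
        a_stop = np.where(val1 >= val2, CHOOSE_S1, CHOOSE_S2).astype(np.int8)
        if n == n_slices:
            value[n] = v_stop
            policy[n] = a_stop
        else:
            if n % 2 == 0:  # next sample is S1: its time advances to t1 + dt
                trans = sample_transition_matrix(t1, config, kernels)
                cont = np.einsum("ik,kj->ij", trans, v_next)
            else:
                trans = sample_transition_matrix(t2, config, kernels)
                cont = np.einsum("jk,ik->ij", trans, v_next)
            cont -= rho * config.dt
            take_sample = cont > v_stop
            value[n] = np.where(take_sample, cont, v_stop)
            policy[n] = np.where(take_sample, SAMPLE, a_stop)
        v_next = value[n]

    center = m // 2
    return PolicySolution(
        config=config,
        rho=rho,
        policy=policy,
        value=value,
        v0=float(value[0, center, center]),
    )


def solve_reward_rate(
    config: OptimalConfig,
    bracket: tuple[float, float] | None = None,
    tol: float = 1e-3,
    max_iter: int = 40,
) -> PolicySolution:
    """Find rho* with V(s0) = 0 by bisection; returns the converged policy.

    The default bracket is [0, Rc/(tnd+tw)] — zero reward rate versus the
    rate of being paid Rc every trial with no sampling time.
    """
    if bracket is None:
        bracket = (0.0, config.rc / (config.tnd + config.tw))
    lo, hi = bracket
    sol_lo = backward_induction(config, lo)
    sol_hi = backward_induction(config, hi)
    if not (sol_lo.v0 >= 0 >= sol_hi.v0):
        raise ValueError(
            f"rho bracket [{lo}, {hi}] does not straddle V(s0)=0 "
            f"(V={sol_lo.v0:.4g}, {sol_hi.v0:.4g}); widen the bracket"
        )
    sol = sol_lo
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        sol = backward_induction(config, mid)
        if abs(sol.v0) < tol:
            return sol
        if sol.v0 > 0:
            lo = mid
        else:
            hi = mid
    return sol


def simulate_optimal(
    solution: PolicySolution,
    n_trials: int,
    rng: np.random.Generator,
    pairs=None,
) -> dict:
    """Simulate trials under a solved policy.

    Coherence pairs default to independent draws from the config's prior
    (the experimental design).  Evidence evolves continuously with the
    true drifts; states are looked up at the nearest grid cell.  RT adds
    the constant non-decision time.  Returns arrays: c1, c2, choice,
    decision_time, rt, correct.
    """
    cfg = solution.config
    coh = np.asarray(cfg.coherences)
    if pairs is None:
        c1 = rng.choice(coh, p=cfg.prior, size=n_trials)
        c2 = rng.choice(coh, p=cfg.prior, size=n_trials)
    else:
        c1 = np.asarray([p[0] for p in pairs], dtype=float)
        c2 = np.asarray([p[1] for p in pairs], dtype=float)
        n_trials = c1.size
    seed = int(rng.integers(0, 2**31 - 1))
    choice, dtime = optimal_policy_batch(
        solution.policy,
        cfg.kappa * c1,
        cfg.kappa * c2,
        cfg.dt,
        float(cfg.dv_grid[0]),
        cfg.ddv,
        seed,
    )
    s1 = np.abs(c1)
    s2 = np.abs(c2)
    easier = np.where(s1 > s2, 1, 2)
    tie = s1 == s2
    easier = np.where(tie, rng.integers(1, 3, size=n_trials), easier)
    return {
        "c1": c1,
        "c2": c2,
        "choice": choice,
        "decision_time": dtime,
        "rt": dtime + cfg.tnd,
        "correct": choice == easier,
    }
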