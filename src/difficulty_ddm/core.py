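"""Single-accumulator drift diffusion with logistic collapsing bounds.

The momentary evidence for the dominant color of a dynamic random-dot
patch is modeled as Gaussian increments with drift ``mu = kappa * (C + c0)``
where ``C`` is the signed color coherence, and unit diffusion variance per
second of sampling (the conventional scaling: the decision variable has
variance 1 after 1 s of accumulation).  Accumulation terminates at the
first crossing of a time-varying symmetric bound ``+/-B(t)`` parameterized
as a three-parameter logistic that collapses toward zero.

This module provides the two complementary routes to the joint
(choice, decision-time) distribution — Monte Carlo simulation of the
discrete Euler update, and forward propagation of the probability density
(a Fokker-Planck / Kolmogorov-forward solve on a uniform evidence grid) —
plus Gaussian non-decision-time convolution to map decision times to
reaction times.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.linalg import solve_banded
from scipy.special import expit, ndtr

from ._kernels import ddm_first_passage_batch

__all__ = [
    "COHERENCE_STRENGTHS",
    "SIGNED_COHERENCES",
    "SignedCoherence",
    "CollapsingBound",
    "ColorDDMParams",
    "ChoiceRTDistribution",
    "color_coherence",
    "bound_height",
    "drift",
    "simulate_first_passage",
    "simulate_first_passage_batch",
    "fp_choice_rt_density",
    "add_nondecision",
]

#: Unsigned color strengths used across the experiments.
COHERENCE_STRENGTHS: tuple[float, ...] = (0.0, 0.128, 0.256, 0.384, 0.512, 0.64)

#: The 12 signed coherence levels (+/- each strength; zero appears with both tags).
SIGNED_COHERENCES: tuple[float, ...] = tuple(
    s * c for c in COHERENCE_STRENGTHS for s in (+1, -1)
)


@dataclass(frozen=True)
class SignedCoherence:
    """Signed color coherence ``C = 2*(p_blue - 0.5)``.

    Positive values are blue-dominant.  ``sign`` disambiguates the two
    zero-coherence stimuli (the experiment tags 0 with an explicit +/- that
    decides which response is rewarded); for nonzero values it must match
    ``sign(value)``.
    """

    value: float
    sign: int = field(default=0)

    def __post_init__(self):
        if not -1.0 <= self.value <= 1.0:
            raise ValueError(f"coherence must lie in [-1, 1], got {self.value}")
        if self.value != 0.0:
            object.__setattr__(self, "sign", 1 if self.value > 0 else -1)
        elif self.sign not in (-1, 1):
            object.__setattr__(self, "sign", 1)

    @property
    def strength(self) -> float:
        """Unsigned coherence (the difficulty variable)."""
        return abs(self.value)


def color_coherence(p_blue: float) -> SignedCoherence:
    """Map a blue-dot probability to a signed coherence, ``2*(p_blue - 0.5)``."""
    if not 0.0 <= p_blue <= 1.0:
        raise ValueError(f"p_blue must be a probability, got {p_blue}")
    return SignedCoherence(2.0 * (p_blue - 0.5))


@dataclass(frozen=True)
class CollapsingBound:
    """Logistic collapsing bound ``B(t) = u / (1 + exp(a*(t - d)))``.

    Parameters
    ----------
    u : float
        Bound scale (evidence units); ``B(t) < u`` for all ``t >= 0``.
    a : float
        Collapse rate (1/s).  ``a = 0`` gives a flat bound at ``u/2``.
    d : float
        Half-height time (s): ``B(d) = u/2``.
    """

    u: float
    a: float
    d: float

    def __post_init__(self):
        if self.u <= 0:
            raise ValueError("bound scale u must be positive")

    def height(self, t):
        """Evaluate ``B(t)``; overflow-safe for large ``a*(t - d)``."""
        return self.u * expit(-self.a * (np.asarray(t, dtype=float) - self.d))

    def __call__(self, t):
        return self.height(t)


def bound_height(bound: CollapsingBound, t):
    """Bound height ``B(t)``; the lower bound is its negation."""
    return bound.height(t)


@dataclass(frozen=True)
class ColorDDMParams:
    """Parameters of the 1D color-judgment DDM.

    ``kappa`` converts coherence to drift rate, ``c0`` is a color bias
    expressed as a coherence offset (not a starting-point shift), and the
    non-decision time is Gaussian with mean ``tnd_mean`` and standard
    deviation ``tnd_sd`` (fixed to 0.05 s in the experiments).
    """

    kappa: float
    c0: float
    bound: CollapsingBound
    tnd_mean: float
    tnd_sd: float = 0.05

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.tnd_mean <= 0:
            raise ValueError("tnd_mean must be positive")
        if self.tnd_sd < 0:
            raise ValueError("tnd_sd must be non-negative")


def drift(params: ColorDDMParams, c: SignedCoherence | float) -> float:
    """Drift rate ``mu = kappa * (C + c0)``."""
    value = c.value if isinstance(c, SignedCoherence) else float(c)
    return params.kappa * (value + params.c0)


# ---------------------------------------------------------------------------
# Monte Carlo first passage
# ---------------------------------------------------------------------------


def _bound_array(bound: CollapsingBound, dt: float, horizon: float) -> np.ndarray:
    """B evaluated at the end of each Euler step, t = (k+1)*dt."""
    n_steps = int(round(horizon / dt))
    return bound.height((np.arange(n_steps) + 1) * dt)


def simulate_first_passage(
    params: ColorDDMParams,
    c: SignedCoherence | float,
    dt: float,
    horizon: float,
    rng: np.random.Generator,
):
    """Simulate one Euler path to first bound crossing.

    Returns ``(hit, decision_time)`` with ``hit`` in {"upper", "lower",
    "none"}; ``decision_time = horizon`` when no bound is crossed.  The
    update is ``dDV = mu*dt + Normal(0, dt)`` and crossing is checked on the
    step grid (no sub-step interpolation).
    """
    choices, times = simulate_first_passage_batch(params, c, dt, horizon, rng, 1)
    hit = {1: "upper", -1: "lower", 0: "none"}[int(choices[0])]
    return hit, float(times[0])


def simulate_first_passage_batch(
    params: ColorDDMParams,
    c: SignedCoherence | float,
    dt: float,
    horizon: float,
    rng: np.random.Generator,
    n_trials: int,
):
    """Simulate ``n_trials`` first-passage trials; returns (choices, times).

    ``choices`` is +1 (upper), -1 (lower) or 0 (no crossing by the horizon).
    """
    if dt <= 0 or horizon <= 0:
        raise ValueError("dt and horizon must be positive")
    mu = drift(params, c)
    bound_arr = _bound_array(params.bound, dt, horizon)
    seed = int(rng.integers(0, 2**31 - 1))
    return ddm_first_passage_batch(mu, bound_arr, dt, int(n_trials), seed)


# ---------------------------------------------------------------------------
# Fokker-Planck (Kolmogorov forward) density propagation
# ---------------------------------------------------------------------------


@dataclass
class ChoiceRTDistribution:
    """Defect densities over (choice, time) for a two-boundary diffusion.

    ``t`` is a uniform grid (step ``dt``); ``p_upper``/``p_lower`` are the
    sub-distribution densities (units 1/s) of absorption at the upper/lower
    boundary; ``survivor`` is the unabsorbed probability mass at the last
    grid time.  The two defect integrals plus ``survivor`` sum to 1.
    """

    t: np.ndarray
    p_upper: np.ndarray
    p_lower: np.ndarray
    survivor: float

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if self.t.size > 1 else float(self.t[0])

    @property
    def prob_upper(self) -> float:
        return float(np.sum(self.p_upper) * self.dt)

    @property
    def prob_lower(self) -> float:
        return float(np.sum(self.p_lower) * self.dt)

    @property
    def prob_absorbed(self) -> float:
        return self.prob_upper + self.prob_lower

    def mean_decision_time(self) -> float:
        """Mean absorption time, conditional on absorption at either bound."""
        w = (self.p_upper + self.p_lower) * self.dt
        total = w.sum()
        if total <= 0:
            return math.nan
        return float(np.sum(self.t * w) / total)

    def density_at(self, choice: int, rt) -> np.ndarray:
        """Linear interpolation of the defect density for ``choice`` (+1/-1)."""
        p = self.p_upper if choice > 0 else self.p_lower
        return np.interp(np.asarray(rt, dtype=float), self.t, p, left=0.0, right=0.0)

    def to_frame(self):
        """Export as a tidy table (columns t, density_upper, density_lower)."""
        import pandas as pd

        return pd.DataFrame(
            {"t": self.t, "density_upper": self.p_upper, "density_lower": self.p_lower}
        )


def fp_choice_rt_density(
    params: ColorDDMParams,
    c: SignedCoherence | float,
    dt: float = 0.0005,
    dv_step: float | None = None,
    horizon: float = 6.0,
) -> ChoiceRTDistribution:
    """Choice/decision-time density by forward density propagation.

    The density of the unabsorbed decision variable is propagated on a
    uniform evidence grid with a Crank-Nicolson step for the
    advection-diffusion operator; at the end of every time step the mass at
    or beyond the (grid-snapped) collapsing bound is removed and credited
    to that boundary's defect density.  This discrete-monitoring convention
    matches the Euler simulator's crossing check on the step grid.

    ``dv_step`` defaults to ``u/200`` so that at least 400 cells span the
    full evidence range ``[-u, u]``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    bound = params.bound
    if dv_step is None:
        dv_step = bound.u / 200.0
    if dv_step <= 0:
        raise ValueError("dv_step must be positive")

    mu = drift(params, c)
    n_steps = int(round(horizon / dt))
    t_grid = (np.arange(n_steps) + 1) * dt
    b_arr = np.asarray(bound.height(t_grid))

    # Bound must not move by more than one cell per time step, otherwise the
    # snapped absorbing boundary skips cells and the defect timing degrades.
    max_move = float(np.max(np.abs(np.diff(b_arr)), initial=0.0))
    if max_move > dv_step:
        raise ValueError(
            "evidence grid too coarse for this bound: the bound moves "
            f"{max_move:.4g} evidence units in one time step but dv_step is "
            f"{dv_step:.4g}; decrease dv_step or dt"
        )

    half = int(math.ceil(bound.u / dv_step)) + 2
    x = np.arange(-half, half + 1) * dv_step  # symmetric, includes 0
    m = x.size
    dx = dv_step
    diffusion = 0.5

    # Tridiagonal generator A of dp/dt = -mu dp/dx + (1/2) d2p/dx2 (central).
    lo = diffusion / dx**2 + mu / (2 * dx)
    di = -2 * diffusion / dx**2
    up = diffusion / dx**2 - mu / (2 * dx)

    # Crank-Nicolson: (I - dt/2 A) p' = (I + dt/2 A) p, banded LHS.
    ab = np.zeros((3, m))
    ab[0, 1:] = -0.5 * dt * up
    ab[1, :] = 1.0 - 0.5 * dt * di
    ab[2, :-1] = -0.5 * dt * lo

    p = np.zeros(m)
    p[half] = 1.0 / dx  # delta at DV = 0

    upper_def = np.zeros(n_steps)
    lower_def = np.zeros(n_steps)
    idx_up = np.minimum(np.round((b_arr + half * dx) / dx).astype(int), m - 1)
    idx_lo = np.maximum(np.round((-b_arr + half * dx) / dx).astype(int), 0)

    for k in range(n_steps):
        rhs = p.copy()
        rhs[1:-1] += 0.5 * dt * (lo * p[:-2] + di * p[1:-1] + up * p[2:])
        rhs[0] += 0.5 * dt * (di * p[0] + up * p[1])
        rhs[-1] += 0.5 * dt * (lo * p[-2] + di * p[-1])
        p = solve_banded((1, 1), ab, rhs)
        iu, il = idx_up[k], idx_lo[k]
        if iu <= il:
            # bound fully collapsed onto the grid origin: split remaining mass
            mass = p.sum() * dx
            upper_def[k] += 0.5 * mass / dt
            lower_def[k] += 0.5 * mass / dt
            p[:] = 0.0
            continue
        up_mass = p[iu:].sum() * dx
        lo_mass = p[:il + 1].sum() * dx
        if up_mass > 0:
            upper_def[k] = up_mass / dt
            p[iu:] = 0.0
        if lo_mass > 0:
            lower_def[k] = lo_mass / dt
            p[: il + 1] = 0.0

    # Crank-Nicolson can leave O(1e-30) negative ripples; clip to zero so
    # the defects are proper sub-densities.
    np.maximum(upper_def, 0.0, out=upper_def)
    np.maximum(lower_def, 0.0, out=lower_def)
    survivor = max(float(p.sum() * dx), 0.0)
    return ChoiceRTDistribution(t_grid, upper_def, lower_def, survivor)


def add_nondecision(
    dist: ChoiceRTDistribution, tnd_mean: float, tnd_sd: float
) -> ChoiceRTDistribution:
    """Convolve the defect densities with a Gaussian non-decision time.

    The Gaussian kernel is discretized by CDF differences on the time grid
    and truncated to non-negative offsets with renormalization, so the
    output is a proper density over RT > 0 (the truncated mass is
    negligible for the experimental regime, tnd_mean >= 0.2 s with
    sd = 0.05 s).  Total mass is preserved to machine precision.
    """
    if tnd_mean <= 0:
        raise ValueError("tnd_mean must be positive")
    dt = dist.dt
    if tnd_sd == 0:
        shift = int(round(tnd_mean / dt))
        kernel = np.zeros(shift + 1)
        kernel[shift] = 1.0
    else:
        n_k = int(math.ceil((tnd_mean + 6 * tnd_sd) / dt))
        offsets = np.arange(n_k + 1) * dt
        edges_hi = (offsets + 0.5 * dt - tnd_mean) / tnd_sd
        edges_lo = (offsets - 0.5 * dt - tnd_mean) / tnd_sd
        kernel = ndtr(edges_hi) - ndtr(edges_lo)
        total = kernel.sum()
        if total <= 0:
            raise ValueError("non-decision kernel has no mass on the grid")
        kernel /= total

    p_upper = np.convolve(dist.p_upper, kernel)
    p_lower = np.convolve(dist.p_lower, kernel)
    n_out = p_upper.size
    t_out = (np.arange(n_out) + 1) * dt
    return ChoiceRTDistribution(t_out, p_upper, p_lower, dist.survivor)


def with_params(params: ColorDDMParams, **kwargs) -> ColorDDMParams:
    """Return a copy of ``params`` with the given fields replaced."""
    return replace(params, **kwargs)
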