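"""Two-dimensional accumulator models of difficulty judgments.

All four models (race, difference, two-step, absolute momentary evidence)
integrate momentary color evidence for the two stimuli in a serial,
time-multiplexed manner: updates alternate between S1 and S2 every ``dt``
of real time, so each stimulus is sampled for half of the elapsed time
and decision times are twice those of parallel integration.  The models
differ in the decision statistic the collapsing bound is applied to:

* race — each DV races to its own ``+/-B(t)``; first crossing wins.
* difference — bound on ``|DV1| - |DV2|``.
* two-step — a low-threshold mini-decision fixes both color signs, then
  the bound applies to the appropriately signed DV difference.
* absolute — accumulate ``|mu*dt + noise|`` (color-agnostic), bound on
  ``DV1 - DV2``.

Known-color and difference-in-confidence variants, and the
controlled-duration paradigm with an 80 ms sensory buffer, are provided
alongside.  No color-bias term is used for difficulty judgments.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from . import _kernels as K
from .confidence import ConfidenceMap
from .core import CollapsingBound, SignedCoherence

__all__ = [
    "MODEL_NAMES",
    "StimulusPair",
    "DifficultyParams",
    "DifficultyTrial",
    "REFERENCE_PARAMS",
    "serial_dv_paths",
    "parallel_equivalent_params",
    "simulate_difficulty_batch",
    "race_trial",
    "difference_trial",
    "two_step_trial",
    "absolute_trial",
    "known_color_trial",
    "confidence_difference_trial",
    "effective_sampling_time",
    "controlled_duration_batch",
    "controlled_duration_trial",
]

MODEL_NAMES = ("race", "difference", "two_step", "absolute")

#: Default step for the two-step model's mini-bound sharp collapse (s).
T_MINI_COLLAPSE = 2.0


@dataclass(frozen=True)
class StimulusPair:
    """The two signed coherences shown left (S1) and right (S2)."""

    c1: SignedCoherence
    c2: SignedCoherence

    @property
    def equal_strength(self) -> bool:
        return self.c1.strength == self.c2.strength

    @property
    def same_sign(self) -> bool:
        return self.c1.sign == self.c2.sign


@dataclass(frozen=True)
class DifficultyParams:
    """Parameter bundle shared by the difficulty models.

    ``b_mini`` is only consumed by the two-step model.  Difficulty models
    carry no color-bias term.
    """

    kappa: float
    bound: CollapsingBound
    tnd_mean: float
    tnd_sd: float = 0.05
    b_mini: float | None = None

    def __post_init__(self):
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")
        if self.b_mini is not None and self.b_mini <= 0:
            raise ValueError("b_mini must be positive when present")


#: Reference parameters for the package's synthetic studies.  kappa = 13
#: matches the drift coefficient used for the reward-rate-optimal policy
#: simulations; the bound produces reaction times in the empirically
#: observed range (hard-hard pairs near 2 s, easy-easy shorter) with a
#: well-identified non-decision time.
REFERENCE_PARAMS = DifficultyParams(
    kappa=13.0,
    bound=CollapsingBound(u=2.0, a=2.0, d=1.2),
    tnd_mean=0.35,
    tnd_sd=0.05,
    b_mini=0.8,
)


@dataclass(frozen=True)
class DifficultyTrial:
    """Outcome of one simulated difficulty trial."""

    choice: int  # 1 = S1, 2 = S2
    decision_time: float
    rt: float
    terminated_by: str  # "bound" | "horizon" | "stimulus_offset"
    t_mini: float = math.nan


def serial_dv_paths(
    params: DifficultyParams,
    pair: StimulusPair,
    dt: float,
    horizon: float,
    rng: np.random.Generator,
):
    """Simulate the two alternating DV trajectories on the shared time grid.

    Returns ``(t, dv1, dv2)`` where ``t[k] = (k+1)*dt``; S1 is updated on
    even steps, S2 on odd steps, each accruing drift and unit-rate variance
    only during its own steps (half of real time per stimulus).
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n = int(round(horizon / dt))
    t = (np.arange(n) + 1) * dt
    inc = rng.normal(0.0, math.sqrt(dt), size=n)
    d1 = np.zeros(n)
    d2 = np.zeros(n)
    even = np.arange(n) % 2 == 0
    d1[even] = params.kappa * pair.c1.value * dt + inc[even]
    d2[~even] = params.kappa * pair.c2.value * dt + inc[~even]
    return t, np.cumsum(d1), np.cumsum(d2)


def parallel_equivalent_params(
    params: DifficultyParams, time_dilation: float = 1.0
) -> DifficultyParams:
    """Parameters of the parallel-integration model equivalent to ``params``.

    A serial model with parameters ``(kappa, u, a, d)`` is, in distribution,
    identical to a parallel model observed on a time axis dilated by
    ``gamma = time_dilation`` with ``kappa_p = kappa / sqrt(2*gamma)``,
    ``u_p = u * sqrt(2*gamma)``, ``a_p = a / gamma`` and ``d_p = d * gamma``
    (the DV and bound are jointly rescaled to restore unit diffusion
    variance).  ``gamma = 1`` gives the parallel model whose choice/RT
    predictions coincide with the serial model's at the same real times —
    the form in which the bound scales by sqrt(2).
    """
    g = float(time_dilation)
    if g <= 0:
        raise ValueError("time_dilation must be positive")
    s = math.sqrt(2.0 * g)
    b = params.bound
    return replace(
        params,
        kappa=params.kappa / s,
        bound=CollapsingBound(u=b.u * s, a=b.a / g, d=b.d * g),
    )


# ---------------------------------------------------------------------------
# Batch simulation
# ---------------------------------------------------------------------------


def _as_value_array(c) -> np.ndarray:
    arr = np.asarray(
        [x.value if isinstance(x, SignedCoherence) else float(x) for x in np.atleast_1d(c)],
        dtype=float,
    )
    return arr


def _sign_array(c) -> np.ndarray:
    out = []
    for x in np.atleast_1d(c):
        if isinstance(x, SignedCoherence):
            out.append(x.sign)
        else:
            v = float(x)
            out.append(1 if v > 0 else (-1 if v < 0 else 1))
    return np.asarray(out, dtype=np.int8)


def _bound_array(bound: CollapsingBound, dt: float, horizon: float) -> np.ndarray:
    n = int(round(horizon / dt))
    return np.asarray(bound.height((np.arange(n) + 1) * dt), dtype=float)


def simulate_difficulty_batch(
    model: str,
    params: DifficultyParams,
    c1,
    c2,
    dt: float = 0.005,
    horizon: float = 5.0,
    rng: np.random.Generator | None = None,
    known_signs=None,
    conf_map: ConfidenceMap | None = None,
    add_nondecision_time: bool = True,
    parallel: bool = False,
) -> dict:
    """Simulate many difficulty trials of one model.

    Parameters
    ----------
    model : {"race", "difference", "two_step", "absolute", "known_color",
             "confidence", "confidence_known"}
    c1, c2 : array-like of signed coherences (floats or SignedCoherence).
    known_signs : (s1, s2) arrays of +/-1, required for the known-color and
        signed-confidence variants; for zero coherence the sign must come
        from the design's +/- tag.
    parallel : run the difference model with both DVs updated every step
        (used for the serial/parallel equivalence analysis).

    Returns a dict of arrays: choice (1/2), decision_time, rt,
    terminated_by (0 bound, 1 horizon), and t_mini for the two-step model.
    """
    if rng is None:
        rng = np.random.default_rng()
    mu1 = params.kappa * _as_value_array(c1)
    mu2 = params.kappa * _as_value_array(c2)
    if mu1.size != mu2.size:
        raise ValueError("c1 and c2 must have equal length")
    b_arr = _bound_array(params.bound, dt, horizon)
    seed = int(rng.integers(0, 2**31 - 1))
    t_mini = None

    if parallel:
        if model != "difference":
            raise ValueError("parallel mode is implemented for the difference model")
        n = int(round(horizon / dt))
        n_eff = np.full(mu1.size, n, dtype=np.int64)
        s = np.ones(mu1.size, dtype=np.int8)
        choice, dtime, term = K.controlled_duration_batch(
            mu1, mu2, s, s, 0, n_eff, b_arr, dt, seed
        )
    elif model == "race":
        choice, dtime, term = K.race_batch(mu1, mu2, b_arr, dt, seed)
    elif model == "difference":
        choice, dtime, term = K.difference_batch(mu1, mu2, b_arr, dt, seed)
    elif model == "absolute":
        choice, dtime, term = K.absolute_batch(mu1, mu2, b_arr, dt, seed)
    elif model == "two_step":
        if params.b_mini is None:
            raise ValueError("two_step model requires b_mini")
        k_collapse = int(round(T_MINI_COLLAPSE / dt))
        choice, dtime, term, t_mini = K.two_step_batch(
            mu1, mu2, b_arr, params.b_mini, k_collapse, dt, seed
        )
    elif model == "known_color":
        s1, s2 = _resolve_known_signs(known_signs, c1, c2)
        choice, dtime, term = K.known_color_batch(mu1, mu2, s1, s2, b_arr, dt, seed)
    elif model in ("confidence", "confidence_known"):
        if conf_map is None:
            raise ValueError("confidence models require a ConfidenceMap")
        signed = 1 if model == "confidence_known" else 0
        if signed:
            s1, s2 = _resolve_known_signs(known_signs, c1, c2)
        else:
            s1 = np.ones(mu1.size, dtype=np.int8)
            s2 = s1
        choice, dtime, term = K.confidence_batch(
            mu1, mu2, s1, s2, signed, conf_map.lo, conf_map.dv_min,
            conf_map.ddv, b_arr, dt, seed,
        )
    else:
        raise ValueError(f"unknown model {model!r}")

    if add_nondecision_time:
        tnd = rng.normal(params.tnd_mean, params.tnd_sd, size=dtime.size)
        rt = dtime + np.maximum(tnd, 0.0)
    else:
        rt = dtime.copy()
    out = {
        "choice": choice,
        "decision_time": dtime,
        "rt": rt,
        "terminated_by": term,
    }
    if t_mini is not None:
        out["t_mini"] = t_mini
    return out


def _resolve_known_signs(known_signs, c1, c2):
    if known_signs is not None:
        s1 = np.asarray(np.atleast_1d(known_signs[0]), dtype=np.int8)
        s2 = np.asarray(np.atleast_1d(known_signs[1]), dtype=np.int8)
    else:
        s1, s2 = _sign_array(c1), _sign_array(c2)
    v1, v2 = _as_value_array(c1), _as_value_array(c2)
    if np.any((v1 != 0) & (np.sign(v1) != s1)) or np.any((v2 != 0) & (np.sign(v2) != s2)):
        raise ValueError("known_signs must match the coherence signs")
    return s1, s2


# ---------------------------------------------------------------------------
# Single-trial convenience wrappers
# ---------------------------------------------------------------------------


def _one(model, params, pair, dt, horizon, rng, **kw) -> DifficultyTrial:
    res = simulate_difficulty_batch(
        model, params, [pair.c1], [pair.c2], dt=dt, horizon=horizon, rng=rng, **kw
    )
    term = {0: "bound", 1: "horizon"}[int(res["terminated_by"][0])]
    return DifficultyTrial(
        choice=int(res["choice"][0]),
        decision_time=float(res["decision_time"][0]),
        rt=float(res["rt"][0]),
        terminated_by=term,
        t_mini=float(res["t_mini"][0]) if "t_mini" in res else math.nan,
    )


def race_trial(params, pair, dt=0.005, horizon=5.0, rng=None) -> DifficultyTrial:
    """One race-model trial: first DV to reach +/-B(t) designates the choice."""
    return _one("race", params, pair, dt, horizon, rng)


def difference_trial(params, pair, dt=0.005, horizon=5.0, rng=None) -> DifficultyTrial:
    """One difference-model trial: bound applied to |DV1| - |DV2|."""
    return _one("difference", params, pair, dt, horizon, rng)


def two_step_trial(params, pair, dt=0.005, horizon=5.0, rng=None) -> DifficultyTrial:
    """One two-step trial; requires ``params.b_mini``."""
    return _one("two_step", params, pair, dt, horizon, rng)


def absolute_trial(params, pair, dt=0.005, horizon=5.0, rng=None) -> DifficultyTrial:
    """One absolute-momentary-evidence trial."""
    return _one("absolute", params, pair, dt, horizon, rng)


def known_color_trial(
    params, pair, known_signs=None, dt=0.005, horizon=5.0, rng=None
) -> DifficultyTrial:
    """One known-color trial: bound on the appropriately signed DV difference."""
    kw = {}
    if known_signs is not None:
        kw["known_signs"] = ([known_signs[0]], [known_signs[1]])
    return _one("known_color", params, pair, dt, horizon, rng, **kw)


def confidence_difference_trial(
    params, conf_map, pair, known_signs=None, dt=0.005, horizon=5.0, rng=None
) -> DifficultyTrial:
    """One difference-in-confidence trial (signed variant if signs given)."""
    model = "confidence_known" if known_signs is not None else "confidence"
    kw = {"conf_map": conf_map}
    if known_signs is not None:
        kw["known_signs"] = ([known_signs[0]], [known_signs[1]])
    return _one(model, params, pair, dt, horizon, rng, **kw)


# ---------------------------------------------------------------------------
# Controlled-duration paradigm
# ---------------------------------------------------------------------------

#: Stimulus durations used in the controlled-duration experiment (s).
CONTROLLED_DURATIONS = (0.1, 0.15, 0.25, 0.45, 0.85, 1.65)

#: Sensory buffer: duration of both streams storable before serial sharing.
T_BUFFER = 0.08


def effective_sampling_time(t_stim: float, t_buf: float = T_BUFFER) -> float:
    """Per-stimulus sampling time under the sensory-buffer rule.

    Within the buffer both streams are acquired in parallel; beyond it the
    remaining stimulus time is shared equally between the two stimuli::

        Tdur = t_stim                          if t_stim <= t_buf
               t_buf + (t_stim - t_buf) / 2    otherwise
    """
    if t_stim <= 0:
        raise ValueError("stimulus duration must be positive")
    if t_stim <= t_buf:
        return t_stim
    return t_buf + 0.5 * (t_stim - t_buf)


def _real_time_of_evidence_step(j_times_dt: np.ndarray, t_buf: float) -> np.ndarray:
    """Invert the buffer rule: real time at which evidence time tau accrues."""
    tau = j_times_dt
    return np.where(tau <= t_buf, tau, t_buf + 2.0 * (tau - t_buf))


def controlled_duration_batch(
    model: str,
    params: DifficultyParams,
    c1,
    c2,
    t_stim,
    t_buf: float = T_BUFFER,
    dt: float = 0.005,
    rng: np.random.Generator | None = None,
    known_signs=None,
) -> dict:
    """Controlled-duration difficulty choices for many trials.

    ``model`` is "difference" (unknown color, bound on |DV1| - |DV2|) or
    "known_color" (bound on the signed difference).  The collapsing bound
    is evaluated at real time; if no bound is crossed by stimulus offset
    the choice is the sign of the decision statistic (ties random).
    """
    if rng is None:
        rng = np.random.default_rng()
    t_stim = np.asarray(np.atleast_1d(t_stim), dtype=float)
    if np.any(t_stim <= 0):
        raise ValueError("stimulus durations must be positive")
    mu1 = params.kappa * _as_value_array(c1)
    mu2 = params.kappa * _as_value_array(c2)
    n_eff = np.array(
        [int(round(effective_sampling_time(ts, t_buf) / dt)) for ts in t_stim],
        dtype=np.int64,
    )
    tau = (np.arange(int(n_eff.max())) + 1) * dt
    b_eff = np.asarray(
        params.bound.height(_real_time_of_evidence_step(tau, t_buf)), dtype=float
    )
    if model == "known_color":
        s1, s2 = _resolve_known_signs(known_signs, c1, c2)
        mode = 1
    elif model == "difference":
        s1 = np.ones(mu1.size, dtype=np.int8)
        s2 = s1
        mode = 0
    else:
        raise ValueError("controlled-duration paradigm supports 'difference' and 'known_color'")
    seed = int(rng.integers(0, 2**31 - 1))
    choice, dtime, term = K.controlled_duration_batch(
        mu1, mu2, s1, s2, mode, n_eff, b_eff, dt, seed
    )
    return {"choice": choice, "decision_time": dtime, "terminated_by": term}


def controlled_duration_trial(
    model, params, pair, t_stim, t_buf=T_BUFFER, dt=0.005, rng=None
) -> DifficultyTrial:
    """One controlled-duration trial (choice only; no RT is produced)."""
    res = controlled_duration_batch(
        model, params, [pair.c1], [pair.c2], [t_stim], t_buf=t_buf, dt=dt, rng=rng
    )
    term = {0: "bound", 1: "stimulus_offset"}[int(res["terminated_by"][0])]
    return DifficultyTrial(
        choice=int(res["choice"][0]),
        decision_time=float(res["decision_time"][0]),
        rt=math.nan,
        terminated_by=term,
    )
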