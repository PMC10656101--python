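"""Mapping from (decision variable, time) to the log-odds of a correct
color choice.

Confidence that a sign(DV)-based color choice would be correct is the
posterior probability, under a uniform prior over the discrete signed
coherence set, that the true coherence sign matches sign(DV) given the
Gaussian evidence model DV | C, t ~ Normal(kappa*C*t, t).  The map is
stored as *signed* log-odds of blue dominance L(dv, t), antisymmetric in
dv; the unsigned confidence used by the unknown-color model is |L|.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

__all__ = ["ConfidenceMap", "build_confidence_map"]


@dataclass
class ConfidenceMap:
    """Gridded signed log-odds of blue dominance.

    ``lo[j, i]`` is the log-odds after ``j`` evidence updates (sampling
    time ``j * dt``) at decision-variable value ``dv_min + i * ddv``,
    clipped at ``+/-clip``.  Row 0 (t = 0) is identically zero.
    """

    lo: np.ndarray
    dv_min: float
    ddv: float
    dt: float
    kappa: float
    coherences: np.ndarray
    clip: float

    def log_odds(self, dv, t):
        """Bilinear interpolation of the signed log-odds at (dv, t)."""
        dv = np.asarray(dv, dtype=float)
        t = np.asarray(t, dtype=float)
        tj = np.clip(t / self.dt, 0, self.lo.shape[0] - 1)
        j0 = np.floor(tj).astype(int)
        j1 = np.minimum(j0 + 1, self.lo.shape[0] - 1)
        ft = tj - j0
        xi = np.clip((dv - self.dv_min) / self.ddv, 0, self.lo.shape[1] - 1)
        i0 = np.floor(xi).astype(int)
        i1 = np.minimum(i0 + 1, self.lo.shape[1] - 1)
        fx = xi - i0
        row0 = self.lo[j0, i0] * (1 - fx) + self.lo[j0, i1] * fx
        row1 = self.lo[j1, i0] * (1 - fx) + self.lo[j1, i1] * fx
        return row0 * (1 - ft) + row1 * ft

    def prob_correct(self, dv, t):
        """P(sign(dv)-based color choice is correct) = sigmoid(|L(dv, t)|)."""
        lo = np.abs(self.log_odds(dv, t))
        return 1.0 / (1.0 + np.exp(-lo))


def build_confidence_map(
    kappa: float,
    coherence_set,
    dt: float = 0.005,
    t_max: float = 2.5,
    dv_step: float = 0.025,
    clip: float = 10.0,
) -> ConfidenceMap:
    """Build the signed log-odds map for a coherence set with uniform prior.

    The set must contain matched positive and negative entries (zero may
    appear with both +/- tags); blue-dominant entries are those with a
    non-negative tag.  For zero coherence the two tags contribute equal
    likelihood, pulling the log-odds toward 0 as appropriate.
    """
    coh = np.asarray(sorted(coherence_set), dtype=float)
    if coh.size == 0:
        raise ValueError("coherence set must not be empty")
    # Sign tags: entries are signed values; split zeros evenly between signs
    # by treating each listed element as its own prior atom.
    n_zero = int(np.sum(coh == 0.0))
    signs = np.sign(coh)
    if n_zero:
        z = np.flatnonzero(coh == 0.0)
        half = n_zero // 2
        signs[z[:half]] = -1.0
        signs[z[half:]] = 1.0

    n_rows = int(round(t_max / dt)) + 1
    reach = kappa * np.max(np.abs(coh)) * t_max + 5.0 * np.sqrt(max(t_max, dt))
    half_cells = int(np.ceil(reach / dv_step))
    dv = np.arange(-half_cells, half_cells + 1) * dv_step

    lo = np.zeros((n_rows, dv.size))
    pos = signs > 0
    neg = ~pos
    for j in range(1, n_rows):
        t = j * dt
        # log N(dv | kappa*C*t, t) up to shared constants
        z = -((dv[:, None] - kappa * coh[None, :] * t) ** 2) / (2.0 * t)
        lp_pos = logsumexp(z[:, pos], axis=1) if pos.any() else np.full(dv.size, -np.inf)
        lp_neg = logsumexp(z[:, neg], axis=1) if neg.any() else np.full(dv.size, -np.inf)
        lo[j] = np.clip(lp_pos - lp_neg, -clip, clip)

    return ConfidenceMap(
        lo=lo,
        dv_min=float(dv[0]),
        ddv=dv_step,
        dt=dt,
        kappa=kappa,
        coherences=coh,
        clip=clip,
    )
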