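"""Numba-compiled Monte Carlo kernels.

Every kernel gives each trial its own counter-based random substream
(splitmix64-seeded xorshift128+ with Box-Muller normals), derived from the
caller's seed and the trial index.  Trial i therefore sees the *same*
noise sequence regardless of model parameters or of how many draws other
trials consumed — true common-random-numbers path coupling, which makes
simulation-based objectives smooth in the parameters.  Results are
bit-reproducible given (seed, arguments).

Trial loops exit at the first bound crossing; crossing is checked on the
discrete step grid with no sub-step interpolation.

Choice coding: 1 = S1, 2 = S2.  terminated_by coding: 0 = bound,
1 = horizon / stimulus offset.
"""

import math

import numpy as np
from numba import njit

__all__ = [
    "ddm_first_passage_batch",
    "race_batch",
    "difference_batch",
    "absolute_batch",
    "known_color_batch",
    "two_step_batch",
    "confidence_batch",
    "controlled_duration_batch",
    "optimal_policy_batch",
    "epan_nll_shift",
]

_U64 = np.uint64
_TWO_PI = 2.0 * math.pi
_INV53 = 1.0 / 9007199254740992.0  # 2**-53


@njit(inline="always")
def _mix64(x):
    """splitmix64 finalizer: high-quality 64-bit hash."""
    x = (x ^ (x >> _U64(30))) * _U64(0xBF58476D1CE4E5B9)
    x = (x ^ (x >> _U64(27))) * _U64(0x94D049BB133111EB)
    return x ^ (x >> _U64(31))


@njit(inline="always")
def _trial_state(seed, trial):
    """Independent xorshift128+ state for one (seed, trial) pair."""
    s0 = _mix64(_U64(seed) * _U64(0x9E3779B97F4A7C15) + _U64(trial) + _U64(1))
    s1 = _mix64(s0 ^ _U64(0xDEADBEEFCAFEBABE))
    if s0 == _U64(0) and s1 == _U64(0):
        s1 = _U64(1)
    return s0, s1


@njit(inline="always")
def _xs_step(s0, s1):
    x = s0
    y = s1
    s0 = y
    x ^= x << _U64(23)
    s1 = x ^ y ^ (x >> _U64(17)) ^ (y >> _U64(26))
    return s0, s1, s1 + y


@njit(inline="always")
def _uniform(s0, s1):
    s0, s1, r = _xs_step(s0, s1)
    return s0, s1, float(r >> _U64(11)) * _INV53


@njit(inline="always")
def _normal_pair(s0, s1):
    """Box-Muller pair from two uniforms."""
    s0, s1, u1 = _uniform(s0, s1)
    s0, s1, u2 = _uniform(s0, s1)
    if u1 < 1e-300:
        u1 = 1e-300
    r = math.sqrt(-2.0 * math.log(u1))
    return s0, s1, r * math.cos(_TWO_PI * u2), r * math.sin(_TWO_PI * u2)


@njit(cache=True)
def ddm_first_passage_batch(mu, bound_arr, dt, n_trials, seed):
    """1D DDM Euler first passage against a precomputed bound array.

    Returns (choices, times): choices +1 upper, -1 lower, 0 no crossing.
    """
    n_steps = bound_arr.size
    sdt = math.sqrt(dt)
    choices = np.zeros(n_trials, np.int8)
    times = np.empty(n_trials, np.float64)
    for i in range(n_trials):
        s0, s1 = _trial_state(seed, i)
        have = False
        spare = 0.0
        dv = 0.0
        ch = 0
        td = n_steps * dt
        for k in range(n_steps):
            if have:
                z = spare
                have = False
            else:
                s0, s1, z, spare = _normal_pair(s0, s1)
                have = True
            dv += mu * dt + z * sdt
            b = bound_arr[k]
            if dv >= b:
                ch = 1
                td = (k + 1) * dt
                break
            elif dv <= -b:
                ch = -1
                td = (k + 1) * dt
                break
        choices[i] = ch
        times[i] = td
    return choices, times


@njit(cache=True)
def race_batch(mu1, mu2, bound_arr, dt, seed):
    """Race model: the first DV to reach +/-B(t) designates the easier stimulus."""
    n = mu1.size
    n_steps = bound_arr.size
    sdt = math.sqrt(dt)
    choice = np.empty(n, np.int8)
    dtime = np.empty(n, np.float64)
    term = np.zeros(n, np.int8)
    for i in range(n):
        s0, s1 = _trial_state(seed, i)
        have = False
        spare = 0.0
        dv1 = 0.0
        dv2 = 0.0
        ch = 0
        td = n_steps * dt
        tm = 1
        for k in range(n_steps):
            if have:
                z = spare
                have = False
            else:
                s0, s1, z, spare = _normal_pair(s0, s1)
                have = True
            if k % 2 == 0:
                dv1 += mu1[i] * dt + z * sdt
            else:
                dv2 += mu2[i] * dt + z * sdt
            b = bound_arr[k]
            c1 = abs(dv1) >= b
            c2 = abs(dv2) >= b
            if c1 or c2:
                if c1 and c2:
                    s0, s1, u = _uniform(s0, s1)
                    ch = 1 if u < 0.5 else 2
                elif c1:
                    ch = 1
                else:
                    ch = 2
                td = (k + 1) * dt
                tm = 0
                break
        if ch == 0:
            st = abs(dv1) - abs(dv2)
            if st > 0:
                ch = 1
            elif st < 0:
                ch = 2
            else:
                s0, s1, u = _uniform(s0, s1)
                ch = 1 if u < 0.5 else 2
        choice[i] = ch
        dtime[i] = td
        term[i] = tm
    return choice, dtime, term


@njit(cache=True)
def difference_batch(mu1, mu2, bound_arr, dt, seed):
    """Difference model: bound applied to |DV1| - |DV2|."""
    n = mu1.size
    n_steps = bound_arr.size
    sdt = math.sqrt(dt)
    choice = np.empty(n, np.int8)
    dtime = np.empty(n, np.float64)
    term = np.zeros(n, np.int8)
    for i in range(n):
        s0, s1 = _trial_state(seed, i)
        have = False
        spare = 0.0
        dv1 = 0.0
        dv2 = 0.0
        ch = 0
        td = n_steps * dt
        tm = 1
        stat = 0.0
        for k in range(n_steps):
            if have:
                z = spare
                have = False
            else:
                s0, s1, z, spare = _normal_pair(s0, s1)
                have = True
            if k % 2 == 0:
                dv1 += mu1[i] * dt + z * sdt
            else:
                dv2 += mu2[i] * dt + z * sdt
            stat = abs(dv1) - abs(dv2)
            b = bound_arr[k]
            if stat >= b:
                ch = 1
                td = (k + 1) * dt
                tm = 0
                break
            elif stat <= -b:
                ch = 2
                td = (k + 1) * dt
                tm = 0
                break
        if ch == 0:
            if stat > 0:
                ch = 1
            elif stat < 0:
                ch = 2
            else:
                s0, s1, u = _uniform(s0, s1)
                ch = 1 if u < 0.5 else 2
        choice[i] = ch
        dtime[i] = td
        term[i] = tm
    return choice, dtime, term


@njit(cache=True)
def absolute_batch(mu1, mu2, bound_arr, dt, seed):
    """Absolute-momentary-evidence model: accumulate |dMCE|, bound on DV1 - DV2."""
    n = mu1.size
    n_steps = bound_arr.size
    sdt = math.sqrt(dt)
    choice = np.empty(n, np.int8)
    dtime = np.empty(n, np.float64)
    term = np.zeros(n, np.int8)
    for i in range(n):
        s0, s1 = _trial_state(seed, i)
        have = False
        spare = 0.0
        dv1 = 0.0
        dv2 = 0.0
        ch = 0
        td = n_steps * dt
        tm = 1
        stat = 0.0
        for k in range(n_steps):
            if have:
                z = spare
                have = False
            else:
                s0, s1, z, spare = _normal_pair(s0, s1)
                have = True
            if k % 2 == 0:
                dv1 += abs(mu1[i] * dt + z * sdt)
            else:
                dv2 += abs(mu2[i] * dt + z * sdt)
            stat = dv1 - dv2
            b = bound_arr[k]
            if stat >= b:
                ch = 1
                td = (k + 1) * dt
                tm = 0
                break
            elif stat <= -b:
                ch = 2
                td = (k + 1) * dt
                tm = 0
                break
        if ch == 0:
            if stat > 0:
                ch = 1
            elif stat < 0:
                ch = 2
            else:
                s0, s1, u = _uniform(s0, s1)
                ch = 1 if u < 0.5 else 2
        choice[i] = ch
        dtime[i] = td
        term[i] = tm
    return choice, dtime, term


@njit(cache=True)
def known_color_batch(mu1, mu2, sg1, sg2, bound_arr, dt, seed):
    """Known-color variant: bound on sign1*DV1 - sign2*DV2 with known signs."""
    n = mu1.size
    n_steps = bound_arr.size
    sdt = math.sqrt(dt)
    choice = np.empty(n, np.int8)
    dtime = np.empty(n, np.float64)
    term = np.zeros(n, np.int8)
    for i in range(n):
        s0, s1 = _trial_state(seed, i)
        have = False
        spare = 0.0
        dv1 = 0.0
        dv2 = 0.0
        ch = 0
        td = n_steps * dt
        tm = 1
        stat = 0.0
        for k in range(n_steps):
            if have:
                z = spare
                have = False
            else:
                s0, s1, z, spare = _normal_pair(s0, s1)
                have = True
            if k % 2 == 0:
                dv1 += mu1[i] * dt + z * sdt
            else:
                dv2 += mu2[i] * dt + z * sdt
            stat = sg1[i] * dv1 - sg2[i] * dv2
            b = bound_arr[k]
            if stat >= b:
                ch = 1
                td = (k + 1) * dt
                tm = 0
                break
            elif stat <= -b:
                ch = 2
                td = (k + 1) * dt
                tm = 0
                break
        if ch == 0:
            if stat > 0:
                ch = 1
            elif stat < 0:
                ch = 2
            else:
                s0, s1, u = _uniform(s0, s1)
                ch = 1 if u < 0.5 else 2
        choice[i] = ch
        dtime[i] = td
        term[i] = tm
    return choice, dtime, term


@njit(cache=True)
def two_step_batch(mu1, mu2, bound_arr, b_mini, k_collapse, dt, seed):
    """Two-step model: low-threshold mini-decision fixes both DV signs.

    The mini-bound is flat at ``b_mini`` until step ``k_collapse`` (2 s),
    then collapses sharply to 0, forcing a mini-decision by the current DV
    signs.  The difficulty bound (on sign1*DV1 - sign2*DV2) collapses from
    t = 0 but a difficulty choice can occur at t_mini at the earliest.
    """
    n = mu1.size
    n_steps = bound_arr.size
    sdt = math.sqrt(dt)
    choice = np.empty(n, np.int8)
    dtime = np.empty(n, np.float64)
    term = np.zeros(n, np.int8)
    tmini = np.empty(n, np.float64)
    for i in range(n):
        s0, s1 = _trial_state(seed, i)
        have = False
        spare = 0.0
        dv1 = 0.0
        dv2 = 0.0
        ch = 0
        td = n_steps * dt
        tm = 1
        g1 = 0
        g2 = 0
        t1 = math.nan
        stage = 0
        for k in range(n_steps):
            if have:
                z = spare
                have = False
            else:
                s0, s1, z, spare = _normal_pair(s0, s1)
                have = True
            if k % 2 == 0:
                dv1 += mu1[i] * dt + z * sdt
            else:
                dv2 += mu2[i] * dt + z * sdt
            if stage == 0:
                m1 = abs(dv1) >= b_mini
                m2 = abs(dv2) >= b_mini
                forced = (k + 1) >= k_collapse
                if m1 or m2 or forced:
                    if dv1 > 0:
                        g1 = 1
                    elif dv1 < 0:
                        g1 = -1
                    else:
                        s0, s1, u = _uniform(s0, s1)
                        g1 = 1 if u < 0.5 else -1
                    if dv2 > 0:
                        g2 = 1
                    elif dv2 < 0:
                        g2 = -1
                    else:
                        s0, s1, u = _uniform(s0, s1)
                        g2 = 1 if u < 0.5 else -1
                    stage = 1
                    t1 = (k + 1) * dt
            if stage == 1:
                stat = g1 * dv1 - g2 * dv2
                b = bound_arr[k]
                if stat >= b:
                    ch = 1
                    td = (k + 1) * dt
                    tm = 0
                    break
                elif stat <= -b:
                    ch = 2
                    td = (k + 1) * dt
                    tm = 0
                    break
        if ch == 0:
            if stage == 1:
                stat = g1 * dv1 - g2 * dv2
            else:
                stat = abs(dv1) - abs(dv2)
            if stat > 0:
                ch = 1
            elif stat < 0:
                ch = 2
            else:
                s0, s1, u = _uniform(s0, s1)
                ch = 1 if u < 0.5 else 2
        choice[i] = ch
        dtime[i] = td
        term[i] = tm
        tmini[i] = t1
    return choice, dtime, term, tmini


@njit(inline="always")
def _interp_row(row, x, xmin, dx):
    pos = (x - xmin) / dx
    if pos <= 0.0:
        return row[0]
    if pos >= row.size - 1:
        return row[row.size - 1]
    i = int(pos)
    f = pos - i
    return row[i] * (1.0 - f) + row[i + 1] * f


@njit(cache=True)
def confidence_batch(mu1, mu2, sg1, sg2, signed_mode, lo_map, dv_min, ddv,
                     bound_arr, dt, seed):
    """Difference-in-confidence model.

    ``lo_map[j, :]`` is the signed log-odds of blue dominance after j
    updates of one stimulus (its sampling time j*dt), on a uniform DV grid.
    Unknown color (signed_mode = 0): bound on |L1| - |L2|.  Known color
    (signed_mode = 1): bound on s1*L1 - s2*L2, the log-odds of the known
    color being correct.
    """
    n = mu1.size
    n_steps = bound_arr.size
    n_rows = lo_map.shape[0]
    sdt = math.sqrt(dt)
    choice = np.empty(n, np.int8)
    dtime = np.empty(n, np.float64)
    term = np.zeros(n, np.int8)
    for i in range(n):
        s0, s1 = _trial_state(seed, i)
        have = False
        spare = 0.0
        dv1 = 0.0
        dv2 = 0.0
        j1 = 0
        j2 = 0
        ch = 0
        td = n_steps * dt
        tm = 1
        stat = 0.0
        for k in range(n_steps):
            if have:
                z = spare
                have = False
            else:
                s0, s1, z, spare = _normal_pair(s0, s1)
                have = True
            if k % 2 == 0:
                dv1 += mu1[i] * dt + z * sdt
                j1 += 1
            else:
                dv2 += mu2[i] * dt + z * sdt
                j2 += 1
            r1 = j1 if j1 < n_rows else n_rows - 1
            r2 = j2 if j2 < n_rows else n_rows - 1
            lo1 = _interp_row(lo_map[r1], dv1, dv_min, ddv)
            lo2 = _interp_row(lo_map[r2], dv2, dv_min, ddv)
            if signed_mode == 1:
                stat = sg1[i] * lo1 - sg2[i] * lo2
            else:
                stat = abs(lo1) - abs(lo2)
            b = bound_arr[k]
            if stat >= b:
                ch = 1
                td = (k + 1) * dt
                tm = 0
                break
            elif stat <= -b:
                ch = 2
                td = (k + 1) * dt
                tm = 0
                break
        if ch == 0:
            if stat > 0:
                ch = 1
            elif stat < 0:
                ch = 2
            else:
                s0, s1, u = _uniform(s0, s1)
                ch = 1 if u < 0.5 else 2
        choice[i] = ch
        dtime[i] = td
        term[i] = tm
    return choice, dtime, term


@njit(cache=True)
def controlled_duration_batch(mu1, mu2, sg1, sg2, signed_mode, n_eff,
                              bound_eff, dt, seed):
    """Controlled-duration difficulty choice with a sensory buffer.

    Each stimulus is sampled for ``n_eff[i]`` evidence steps (the buffer
    rule applied outside); both DVs advance every evidence step.
    ``bound_eff[j]`` is the collapsing bound evaluated at the real time
    corresponding to evidence step j.  Choice is made at a bound crossing,
    or by the sign of the decision statistic at stimulus offset.
    """
    n = mu1.size
    sdt = math.sqrt(dt)
    choice = np.empty(n, np.int8)
    dtime = np.empty(n, np.float64)
    term = np.zeros(n, np.int8)
    for i in range(n):
        s0, s1 = _trial_state(seed, i)
        dv1 = 0.0
        dv2 = 0.0
        ch = 0
        tm = 1
        stat = 0.0
        m = n_eff[i]
        td = m * dt
        for k in range(m):
            s0, s1, z1, z2 = _normal_pair(s0, s1)
            dv1 += mu1[i] * dt + z1 * sdt
            dv2 += mu2[i] * dt + z2 * sdt
            if signed_mode == 1:
                stat = sg1[i] * dv1 - sg2[i] * dv2
            else:
                stat = abs(dv1) - abs(dv2)
            b = bound_eff[k]
            if stat >= b:
                ch = 1
                td = (k + 1) * dt
                tm = 0
                break
            elif stat <= -b:
                ch = 2
                td = (k + 1) * dt
                tm = 0
                break
        if ch == 0:
            if stat > 0:
                ch = 1
            elif stat < 0:
                ch = 2
            else:
                s0, s1, u = _uniform(s0, s1)
                ch = 1 if u < 0.5 else 2
        choice[i] = ch
        dtime[i] = td
        term[i] = tm
    return choice, dtime, term


@njit(cache=True)
def optimal_policy_batch(policy, mu1, mu2, dt, dv_min, ddv, seed):
    """Follow a solved policy table through alternately sampled evidence.

    ``policy[n, i1, i2]``: action before the n-th sample (0 = sample,
    1 = choose S1, 2 = choose S2); S1 is sampled on even n.  DV paths are
    continuous; states are looked up at the nearest grid cell.
    """
    n = mu1.size
    n_slices = policy.shape[0]
    n_dv = policy.shape[1]
    sdt = math.sqrt(dt)
    choice = np.empty(n, np.int8)
    dtime = np.empty(n, np.float64)
    for i in range(n):
        s0, s1 = _trial_state(seed, i)
        have = False
        spare = 0.0
        dv1 = 0.0
        dv2 = 0.0
        ch = 0
        td = (n_slices - 1) * dt
        for step in range(n_slices):
            i1 = int(round((dv1 - dv_min) / ddv))
            if i1 < 0:
                i1 = 0
            elif i1 >= n_dv:
                i1 = n_dv - 1
            i2 = int(round((dv2 - dv_min) / ddv))
            if i2 < 0:
                i2 = 0
            elif i2 >= n_dv:
                i2 = n_dv - 1
            act = policy[step, i1, i2]
            if act != 0:
                ch = act
                td = step * dt
                break
            if have:
                z = spare
                have = False
            else:
                s0, s1, z, spare = _normal_pair(s0, s1)
                have = True
            if step % 2 == 0:
                dv1 += mu1[i] * dt + z * sdt
            else:
                dv2 += mu2[i] * dt + z * sdt
        if ch == 0:
            # terminal slice policy is always terminal; defensive fallback
            s0, s1, u = _uniform(s0, s1)
            ch = 1 if u < 0.5 else 2
        choice[i] = ch
        dtime[i] = td
    return choice, dtime


@njit(cache=True)
def epan_nll_shift(sims, sim_off, rts, rt_off, p_choice, h, n_sim, shift, floor):
    """Total negative log likelihood over grouped (condition, choice) cells.

    ``sims``/``rts`` are concatenated sorted segments with offset arrays;
    the Epanechnikov kernel density of segment g is evaluated at
    ``rts - shift``, scaled by ``p_choice[g] / (n_sim[g] * h[g])``, and
    floored at ``floor``.
    """
    total = 0.0
    n_groups = p_choice.size
    for g in range(n_groups):
        a0, a1 = sim_off[g], sim_off[g + 1]
        r0, r1 = rt_off[g], rt_off[g + 1]
        if r1 == r0:
            continue
        hg = h[g]
        inv = p_choice[g] / (n_sim[g] * hg) if n_sim[g] > 0 else 0.0
        for j in range(r0, r1):
            x = rts[j] - shift
            dens = 0.0
            if a1 > a0 and inv > 0.0:
                lo = np.searchsorted(sims[a0:a1], x - hg) + a0
                hi = np.searchsorted(sims[a0:a1], x + hg) + a0
                acc = 0.0
                for k in range(lo, hi):
                    z = (x - sims[k]) / hg
                    acc += 1.0 - z * z
                dens = 0.75 * acc * inv
            if dens < floor:
                dens = floor
            total -= math.log(dens)
    return total
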