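"""Numba hot loops for the stochastic membrane simulation.

Everything in this module is a plain-float/ndarray kernel compiled with
``numba.njit``; the public API in :mod:`srneuron.channel_kinetics` and
:mod:`srneuron.membrane_sim` wraps these with typed containers and
validation.  Stochastic kernels seed numba's internal RNG via
``np.random.seed`` at entry, so a (kernel, seed) pair is reproducible.

Voltage is in mV, time in ms, rates in 1/ms throughout.
"""

import numpy as np
from numba import njit

# Tolerance around the removable singularities of the (V+c)/(1-exp) forms.
_SINGULAR_EPS = 1e-6


@njit(cache=True)
def rates_scalar(v):
    """Six HH gating rates (alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n)."""
    if abs(v + 40.0) < _SINGULAR_EPS:
        am = 1.0
    else:
        am = 0.1 * (v + 40.0) / (1.0 - np.exp(-(v + 40.0) / 10.0))
    bm = 4.0 * np.exp(-(v + 65.0) / 18.0)
    ah = 0.07 * np.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + np.exp(-(v + 35.0) / 10.0))
    if abs(v + 55.0) < _SINGULAR_EPS:
        an = 0.1
    else:
        an = 0.01 * (v + 55.0) / (1.0 - np.exp(-(v + 55.0) / 10.0))
    bn = 0.125 * np.exp(-(v + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


@njit(cache=True)
def seed_rng(seed):
    """Seed numba's internal RNG (the one the stochastic kernels draw from)."""
    np.random.seed(seed)


@njit(cache=True)
def step_ensembles(na, k, v, dt):
    """One channel-state-tracking step of both ensembles, in place.

    For every source state the numbers of channels taking each outgoing
    transition are drawn jointly from a multinomial over
    {p_1, ..., p_k, stay}, realised as a chain of conditional binomials.
    Counts are updated from a snapshot (delta accumulators), so
    conservation and non-negativity hold by construction.

    Returns 1 if any per-state total exit probability had to be clamped
    to 1 (never at dt = 0.01 ms and physiological voltages), else 0.
    """
    am, bm, ah, bh, an, bn = rates_scalar(v)
    clamped = 0
    dna = np.zeros((4, 2), np.int64)
    dk = np.zeros(5, np.int64)

    # Na: 4x2 grid, (i, j) = (# open m-particles, h-particle state).
    for i in range(4):
        for j in range(2):
            n0 = na[i, j]
            if n0 == 0:
                continue
            p_up = (3 - i) * am * dt
            p_dn = i * bm * dt
            p_h = (ah if j == 0 else bh) * dt
            ptot = p_up + p_dn + p_h
            if ptot > 1.0:
                s = 1.0 / ptot
                p_up *= s
                p_dn *= s
                p_h *= s
                clamped = 1
            rem = n0
            q = 1.0
            n_up = 0
            n_dn = 0
            n_h = 0
            if p_up > 0.0:
                n_up = np.random.binomial(rem, p_up / q)
                rem -= n_up
                q -= p_up
            if p_dn > 0.0 and rem > 0:
                n_dn = np.random.binomial(rem, p_dn / q)
                rem -= n_dn
                q -= p_dn
            if p_h > 0.0 and rem > 0:
                n_h = np.random.binomial(rem, p_h / q)
            dna[i, j] -= n_up + n_dn + n_h
            if i < 3:
                dna[i + 1, j] += n_up
            if i > 0:
                dna[i - 1, j] += n_dn
            dna[i, 1 - j] += n_h

    # K: 5 states, i = # open n-particles.
    for i in range(5):
        n0 = k[i]
        if n0 == 0:
            continue
        p_up = (4 - i) * an * dt
        p_dn = i * bn * dt
        ptot = p_up + p_dn
        if ptot > 1.0:
            s = 1.0 / ptot
            p_up *= s
            p_dn *= s
            clamped = 1
        rem = n0
        q = 1.0
        n_up = 0
        n_dn = 0
        if p_up > 0.0:
            n_up = np.random.binomial(rem, p_up / q)
            rem -= n_up
            q -= p_up
        if p_dn > 0.0 and rem > 0:
            n_dn = np.random.binomial(rem, p_dn / q)
        dk[i] -= n_up + n_dn
        if i < 4:
            dk[i + 1] += n_up
        if i > 0:
            dk[i - 1] += n_dn

    na += dna
    k += dk
    return clamped


@njit(cache=True)
def step_ensembles_expected(na, k, v, dt):
    """Expected-value variant of :func:`step_ensembles` (float occupancies).

    Replaces every multinomial draw by its mean, i.e. one forward-Euler
    step of the 13-state master equation.
    """
    am, bm, ah, bh, an, bn = rates_scalar(v)
    dna = np.zeros((4, 2), np.float64)
    dk = np.zeros(5, np.float64)
    for i in range(4):
        for j in range(2):
            n0 = na[i, j]
            if n0 == 0.0:
                continue
            f_up = n0 * (3 - i) * am * dt
            f_dn = n0 * i * bm * dt
            f_h = n0 * (ah if j == 0 else bh) * dt
            dna[i, j] -= f_up + f_dn + f_h
            if i < 3:
                dna[i + 1, j] += f_up
            if i > 0:
                dna[i - 1, j] += f_dn
            dna[i, 1 - j] += f_h
    for i in range(5):
        n0 = k[i]
        if n0 == 0.0:
            continue
        f_up = n0 * (4 - i) * an * dt
        f_dn = n0 * i * bn * dt
        dk[i] -= f_up + f_dn
        if i < 4:
            dk[i + 1] += f_up
        if i > 0:
            dk[i - 1] += f_dn
    na += dna
    k += dk
    return 0


@njit(cache=True)
def run_clamped(na, k, v, dt, n_steps, stride, seed):
    """Voltage-clamped ensemble relaxation; records counts every `stride` steps.

    Returns (na_traj, k_traj, n_clamped) with na_traj of shape
    (n_steps // stride, 4, 2) and k_traj of shape (n_steps // stride, 5).
    """
    np.random.seed(seed)
    n_rec = n_steps // stride
    na_traj = np.empty((n_rec, 4, 2), np.int64)
    k_traj = np.empty((n_rec, 5), np.int64)
    n_clamped = 0
    r = 0
    for t in range(n_steps):
        n_clamped += step_ensembles(na, k, v, dt)
        if (t + 1) % stride == 0 and r < n_rec:
            na_traj[r] = na
            k_traj[r] = k
            r += 1
    return na_traj, k_traj, n_clamped


@njit(cache=True)
def run_stochastic(v0, na, k, drive, dt, i0, f_na, f_k, cm, gl, v_na, v_k, v_l,
                   seed):
    """Forward-Euler integration of the stochastic membrane equation.

    `drive` holds the series voltage perturbation V_ES + V_noise at each
    step; the gating voltage and the ionic driving forces see
    V_tot = V + drive, while the capacitive update applies to the
    physiological voltage V only.  `f_na`/`f_k` convert open-channel
    counts to specific conductance (mS/cm^2 per open channel).

    Returns (V, V_tot, n_clamped, blowup_step); blowup_step is 0 for a
    healthy run, else the 1-based step at which |V| exceeded 200 mV.
    """
    np.random.seed(seed)
    n = drive.size
    V = np.empty(n)
    Vtot = np.empty(n)
    v = v0
    n_clamped = 0
    for t in range(n):
        V[t] = v
        vtot = v + drive[t]
        Vtot[t] = vtot
        g_na = f_na * na[3, 1]
        g_k = f_k * k[4]
        v = v + dt / cm * (-g_na * (vtot - v_na) - g_k * (vtot - v_k)
                           - gl * (vtot - v_l) + i0)
        n_clamped += step_ensembles(na, k, vtot, dt)
        if abs(v) > 200.0 or np.isnan(v):
            V[t + 1:] = v
            Vtot[t + 1:] = v
            return V, Vtot, n_clamped, t + 1
    return V, Vtot, n_clamped, 0


@njit(cache=True)
def run_expected(v0, na, k, drive, dt, i0, f_na, f_k, cm, gl, v_na, v_k, v_l):
    """As :func:`run_stochastic` but with expected-value channel updates.

    `na` and `k` are float occupancies; the trajectory is deterministic.
    """
    n = drive.size
    V = np.empty(n)
    Vtot = np.empty(n)
    v = v0
    for t in range(n):
        V[t] = v
        vtot = v + drive[t]
        Vtot[t] = vtot
        g_na = f_na * na[3, 1]
        g_k = f_k * k[4]
        v = v + dt / cm * (-g_na * (vtot - v_na) - g_k * (vtot - v_k)
                           - gl * (vtot - v_l) + i0)
        step_ensembles_expected(na, k, vtot, dt)
        if abs(v) > 200.0 or np.isnan(v):
            V[t + 1:] = v
            Vtot[t + 1:] = v
            return V, Vtot, 0, t + 1
    return V, Vtot, 0, 0


@njit(cache=True)
def run_deterministic(v0, m0, h0, n0, drive, dt, i0, gbar_na, gbar_k, cm, gl,
                      v_na, v_k, v_l):
    """Classic deterministic HH integration (m^3 h / n^4 conductances).

    Same series-perturbation coupling as the stochastic kernel.  Returns
    (V, V_tot, blowup_step).
    """
    n = drive.size
    V = np.empty(n)
    Vtot = np.empty(n)
    v = v0
    m = m0
    h = h0
    nn = n0
    for t in range(n):
        V[t] = v
        vtot = v + drive[t]
        Vtot[t] = vtot
        g_na = gbar_na * m * m * m * h
        g_k = gbar_k * nn * nn * nn * nn
        v = v + dt / cm * (-g_na * (vtot - v_na) - g_k * (vtot - v_k)
                           - gl * (vtot - v_l) + i0)
        am, bm, ah, bh, an, bn = rates_scalar(vtot)
        m = m + dt * (am * (1.0 - m) - bm * m)
        h = h + dt * (ah * (1.0 - h) - bh * h)
        nn = nn + dt * (an * (1.0 - nn) - bn * nn)
        if abs(v) > 200.0 or np.isnan(v):
            V[t + 1:] = v
            Vtot[t + 1:] = v
            return V, Vtot, t + 1
    return V, Vtot, 0
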