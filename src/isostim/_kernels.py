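"""Compiled inner loops for stochastic simulation with per-step control.

These kernels mirror, step for step, the pure-Python decision logic in
:mod:`isostim.controller` and :mod:`isostim.baselines`; a test asserts that
both paths produce identical event logs on shared noise.  All kernels take
a pre-generated array of standard-normal increments so that paired-seed
comparisons are exact.

Falls back to plain Python (slow but correct) if numba is unavailable.
"""

from __future__ import annotations

import math

import numpy as np

try:  # pragma: no cover - numba is expected to be present
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]
        return lambda f: f

__all__ = [
    "sde_plain",
    "sde_scheduled",
    "sde_closed_loop",
    "sde_phase_locked",
    "discount_alpha",
]


@njit(cache=True)
def _drift_E(E, I, nu, beta, etaE, etaI, wEE, wIE, wEI):
    u = etaE + wEE * E - wIE * I
    f = 0.5 * (1.0 + math.tanh(0.5 * beta * (u - 1.0)))
    return (-E + f) / nu


@njit(cache=True)
def _drift_I(E, I, nu, beta, etaE, etaI, wEE, wIE, wEI):
    u = etaI + wEI * E
    f = 0.5 * (1.0 + math.tanh(0.5 * beta * (u - 1.0)))
    return (-I + f) / nu


@njit(cache=True)
def discount_alpha(i, k, n0, n1, b, dt):
    """Temporal discount: 1 at k=1, 0 at the predicted period end."""
    if k == 1:
        return 1.0
    ti = (i - n0) * dt
    tik = (i + k - 1 - n0) * dt
    tn1 = (n1 - n0) * dt
    if tik >= tn1:
        return 0.0
    if abs(b) < 1e-9:
        # log limit of the power-law form (which cancels catastrophically
        # for tiny |b|)
        if ti <= 0.0:
            return 0.0
        return math.log(tn1 / tik) / math.log(tn1 / ti)
    if ti <= 0.0:
        if b > 0.0:
            return 0.0
        return (tik ** (-b) - tn1 ** (-b)) / (0.0 - tn1 ** (-b))
    num = tik ** (-b) - tn1 ** (-b)
    den = ti ** (-b) - tn1 ** (-b)
    return num / den


@njit(cache=True)
def sde_plain(x0, nu, beta, etaE, etaI, wEE, wIE, wEI, sq, dt, noise):
    n = noise.shape[0]
    out = np.empty((n + 1, 2))
    E = x0[0]
    I = x0[1]
    out[0, 0] = E
    out[0, 1] = I
    for k in range(n):
        dE = _drift_E(E, I, nu, beta, etaE, etaI, wEE, wIE, wEI)
        dI = _drift_I(E, I, nu, beta, etaE, etaI, wEE, wIE, wEI)
        E = E + dt * dE + sq * noise[k, 0]
        I = I + dt * dI + sq * noise[k, 1]
        out[k + 1, 0] = E
        out[k + 1, 1] = I
    return out


@njit(cache=True)
def sde_scheduled(x0, nu, beta, etaE, etaI, wEE, wIE, wEI, sq, dt, noise,
                  interval, magnitude):
    """Open-loop pulses every ``interval`` steps (high-frequency baseline)."""
    n = noise.shape[0]
    out = np.empty((n + 1, 2))
    stim = np.empty(n // max(interval, 1) + 1, dtype=np.int64)
    ns = 0
    E = x0[0]
    I = x0[1]
    out[0, 0] = E
    out[0, 1] = I
    for k in range(n):
        if magnitude != 0.0 and k % interval == 0:
            E = E + magnitude
            stim[ns] = k
            ns += 1
        dE = _drift_E(E, I, nu, beta, etaE, etaI, wEE, wIE, wEI)
        dI = _drift_I(E, I, nu, beta, etaE, etaI, wEE, wIE, wEI)
        E = E + dt * dE + sq * noise[k, 0]
        I = I + dt * dI + sq * noise[k, 1]
        out[k + 1, 0] = E
        out[k + 1, 1] = I
    return out, stim[:ns]


@njit(cache=True)
def sde_closed_loop(x0, nu, beta, etaE, etaI, wEE, wIE, wEI, sq, dt, noise,
                    gamma, e_min, de, n_E, i_min, di, n_I,
                    pulse_dE, b, n_lim, boot_steps, win, e_star):
    """Euler-Maruyama with the augmented-response-field decision at each step.

    Zero-crossing phase tracking uses a causal running mean over the
    previous ``win`` samples of E (fallback ``e_star`` until the window is
    filled).  At most one pulse per detected period, never more often than
    every ``n_lim`` steps.
    """
    n = noise.shape[0]
    u = gamma.shape[2]
    out = np.empty((n + 1, 2))
    stim = np.empty(n // max(n_lim, 1) + 1, dtype=np.int64)
    ns = 0
    E = x0[0]
    I = x0[1]
    out[0, 0] = E
    out[0, 1] = I

    buf = np.zeros(win)
    rsum = 0.0
    seen = 0
    n0 = 0
    prev_period = boot_steps
    n1 = boot_steps
    n_cross = 0
    stimulated = False
    last_stim = -n_lim
    prev_centered = 0.0

    for k in range(n):
        if seen >= win:
            centered = E - rsum / win
        else:
            centered = E - e_star
        if k > 0 and prev_centered < 0.0 and centered >= 0.0:
            if n_cross >= 1:
                prev_period = k - n0
            n0 = k
            n1 = k + prev_period
            stimulated = False
            n_cross += 1
        # decision on the pre-pulse state
        if (not stimulated) and (k - last_stim >= n_lim):
            pe = int(math.floor((E - e_min) / de))
            qi = int(math.floor((I - i_min) / di))
            if 0 <= pe < n_E and 0 <= qi < n_I:
                g1v = gamma[pe, qi, 0]
                if g1v < 0.0:
                    fire = False
                    if k >= n1:
                        fire = True
                    else:
                        kmax = n1 - k + 1
                        if kmax > u:
                            kmax = u
                        m = np.inf
                        for kk in range(2, kmax + 1):
                            a = discount_alpha(k, kk, n0, n1, b, dt)
                            v = a * gamma[pe, qi, kk - 1]
                            if v < m:
                                m = v
                        if kmax >= 2 and g1v < m:
                            fire = True
                    if fire:
                        # update the centering buffer with the observed
                        # (pre-pulse) sample, then apply the pulse
                        if win > 0:
                            j = seen % win
                            rsum += E - buf[j]
                            buf[j] = E
                            seen += 1
                        prev_centered = centered
                        E = E + pulse_dE
                        stim[ns] = k
                        ns += 1
                        last_stim = k
                        stimulated = True
                        dEd = _drift_E(E, I, nu, beta, etaE, etaI, wEE, wIE, wEI)
                        dId = _drift_I(E, I, nu, beta, etaE, etaI, wEE, wIE, wEI)
                        E = E + dt * dEd + sq * noise[k, 0]
                        I = I + dt * dId + sq * noise[k, 1]
                        out[k + 1, 0] = E
                        out[k + 1, 1] = I
                        continue
        if win > 0:
            j = seen % win
            rsum += E - buf[j]
            buf[j] = E
            seen += 1
        prev_centered = centered
        dEd = _drift_E(E, I, nu, beta, etaE, etaI, wEE, wIE, wEI)
        dId = _drift_I(E, I, nu, beta, etaE, etaI, wEE, wIE, wEI)
        E = E + dt * dEd + sq * noise[k, 0]
        I = I + dt * dId + sq * noise[k, 1]
        out[k + 1, 0] = E
        out[k + 1, 1] = I
    return out, stim[:ns]


@njit(cache=True)
def sde_phase_locked(x0, nu, beta, etaE, etaI, wEE, wIE, wEI, sq, dt, noise,
                     target_phase, pulse_dE, boot_steps, win, e_star):
    """One pulse per period at the first step where tracked phase reaches
    ``target_phase``; if a positive zero-crossing arrives first, the pulse
    is delivered at the crossing."""
    n = noise.shape[0]
    out = np.empty((n + 1, 2))
    stim = np.empty(n // 2 + 1, dtype=np.int64)
    ns = 0
    E = x0[0]
    I = x0[1]
    out[0, 0] = E
    out[0, 1] = I

    buf = np.zeros(win)
    rsum = 0.0
    seen = 0
    n0 = 0
    prev_period = boot_steps
    n_cross = 0
    phase = 0.0
    stimulated = False
    prev_centered = 0.0

    for k in range(n):
        if seen >= win:
            centered = E - rsum / win
        else:
            centered = E - e_star
        fire = False
        if k > 0 and prev_centered < 0.0 and centered >= 0.0:
            missed = (n_cross >= 1) and (not stimulated)
            if n_cross >= 1:
                prev_period = k - n0
            n0 = k
            n_cross += 1
            phase = 0.0
            stimulated = False
            if missed and target_phase > 0.0:
                fire = True  # phase was underestimated: stimulate right then
        elif k > 0:
            phase += 2.0 * math.pi / prev_period
        if (not fire) and (not stimulated) and phase >= target_phase:
            fire = True
        if win > 0:
            j = seen % win
            rsum += E - buf[j]
            buf[j] = E
            seen += 1
        prev_centered = centered
        if fire:
            E = E + pulse_dE
            stim[ns] = k
            ns += 1
            stimulated = True
        dEd = _drift_E(E, I, nu, beta, etaE, etaI, wEE, wIE, wEI)
        dId = _drift_I(E, I, nu, beta, etaE, etaI, wEE, wIE, wEI)
        E = E + dt * dEd + sq * noise[k, 0]
        I = I + dt * dId + sq * noise[k, 1]
        out[k + 1, 0] = E
        out[k + 1, 1] = I
    return out, stim[:ns]
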