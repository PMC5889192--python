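"""Numba-compiled numerical cores.

Two kernels power everything model-related:

* :func:`cn_propagate` — Crank-Nicolson integration of the 1-D
  Fokker-Planck equation dp/dt = -d(mu p)/dx + D d2p/dx2 on a fixed grid,
  with absorbing boundaries that may move over time (collapsing bounds,
  urgency reinterpreted as a 1/t bound on the raw accumulator).  Mass
  leaving the active region is booked as upper/lower first-passage flux;
  bookkeeping conserves total mass to machine precision by construction.

* :func:`sim_batch` / :func:`sim_path` — Euler-Maruyama trial simulation
  for the same drift/bound families, batch (own RNG) or single path
  (caller-supplied noise, so per-trial substreams stay reproducible).

Drift modes: 0 constant drift A; 1 leaky integrator tau dx = (A-x)dt+c dW
(noise scale c/tau); 2 attractor A - G'(x) + [U(t)+F(t)] x with
G(x) = b(x^2 - beta x^4 + gamma x^6).
Bound modes: 0 fixed B; 1 collapsing B exp(-t/lambda); 2 urgency B/(u t).
"""

from __future__ import annotations

import numpy as np
from numba import njit

DRIFT_CONST = 0
DRIFT_LEAK = 1
DRIFT_ATTRACTOR = 2

BOUND_FIXED = 0
BOUND_COLLAPSE = 1
BOUND_URGENCY = 2


@njit(cache=True)
def cn_propagate(p, mu0, x, s_t, D, lo_idx, hi_idx, dt, dx):
    """Advance the density ``p`` (probability mass per cell) over len(s_t)
    steps.  Drift at step n is mu0 + s_t[n] * x.  Active interior cells are
    lo_idx[n]..hi_idx[n] inclusive; everything outside is absorbed.

    Returns (flux_up, flux_lo, p_final); flux arrays hold the mass absorbed
    at the upper/lower boundary during each step.
    """
    n_t = s_t.shape[0]
    n_x = p.shape[0]
    flux_up = np.zeros(n_t)
    flux_lo = np.zeros(n_t)
    half = 0.5 * dt
    Ddx2 = D / (dx * dx)
    inv2dx = 1.0 / (2.0 * dx)

    sub = np.empty(n_x)
    dia = np.empty(n_x)
    sup = np.empty(n_x)
    rhs = np.empty(n_x)
    cp = np.empty(n_x)
    mu = np.empty(n_x)
    pnew = np.empty(n_x)

    for n in range(n_t):
        lo = lo_idx[n]
        hi = hi_idx[n]
        # absorb cells that the (possibly moved) bound now excludes
        for i in range(0, lo):
            flux_lo[n] += p[i]
            p[i] = 0.0
        for i in range(hi + 1, n_x):
            flux_up[n] += p[i]
            p[i] = 0.0
        if hi < lo:
            continue

        s = s_t[n]
        for i in range(lo - 1 if lo > 0 else 0, min(hi + 2, n_x)):
            mu[i] = mu0[i] + s * x[i]

        # L p |_i = a_i p_{i-1} + b_i p_i + g_i p_{i+1}
        # a_i = mu_{i-1}/(2dx) + D/dx^2, b_i = -2D/dx^2,
        # g_i = -mu_{i+1}/(2dx) + D/dx^2 ; Dirichlet 0 beyond [lo, hi]
        m_before = 0.0
        for i in range(lo, hi + 1):
            m_before += p[i]
            pl = p[i - 1] if i > lo else 0.0
            pr = p[i + 1] if i < hi else 0.0
            mul = mu[i - 1] if i > 0 else mu[i]
            mur = mu[i + 1] if i < n_x - 1 else mu[i]
            a_i = mul * inv2dx + Ddx2
            g_i = -mur * inv2dx + Ddx2
            b_i = -2.0 * Ddx2
            rhs[i] = p[i] + half * (a_i * pl + b_i * p[i] + g_i * pr)
            sub[i] = -half * a_i
            dia[i] = 1.0 - half * b_i
            sup[i] = -half * g_i

        # Thomas solve on [lo, hi]
        cp[lo] = sup[lo] / dia[lo]
        pnew[lo] = rhs[lo] / dia[lo]
        for i in range(lo + 1, hi + 1):
            m = dia[i] - sub[i] * cp[i - 1]
            cp[i] = sup[i] / m
            pnew[i] = (rhs[i] - sub[i] * pnew[i - 1]) / m
        for i in range(hi - 1, lo - 1, -1):
            pnew[i] -= cp[i] * pnew[i + 1]

        m_after = 0.0
        for i in range(lo, hi + 1):
            if pnew[i] < 0.0:
                pnew[i] = 0.0
            m_after += pnew[i]

        dm = m_before - m_after
        # split the step's absorbed mass by the discrete boundary currents
        pbar_hi = 0.5 * (p[hi] + pnew[hi])
        pbar_lo = 0.5 * (p[lo] + pnew[lo])
        w_up = Ddx2 * dx * pbar_hi + max(mu[hi], 0.0) * pbar_hi
        w_lo = Ddx2 * dx * pbar_lo + max(-mu[lo], 0.0) * pbar_lo
        tot = w_up + w_lo
        if tot > 0.0:
            flux_up[n] += dm * w_up / tot
            flux_lo[n] += dm * w_lo / tot
        else:
            flux_up[n] += 0.5 * dm
            flux_lo[n] += 0.5 * dm

        for i in range(lo, hi + 1):
            p[i] = pnew[i]

    return flux_up, flux_lo, p


@njit(cache=True, inline="always")
def _drift(mode, x, a, tau, att_b, att_beta, att_gamma, ut):
    if mode == DRIFT_CONST:
        return a
    elif mode == DRIFT_LEAK:
        return (a - x) / tau
    else:
        x2 = x * x
        gprime = att_b * (2.0 * x - 4.0 * att_beta * x2 * x
                          + 6.0 * att_gamma * x2 * x2 * x)
        return a - gprime + ut * x


@njit(cache=True, inline="always")
def _bound(mode, t, B, lam, u):
    if mode == BOUND_FIXED:
        return B
    elif mode == BOUND_COLLAPSE:
        return B * np.exp(-t / lam)
    else:
        denom = u * t
        if denom < 1e-12:
            return 1e12
        return B / denom


@njit(cache=True)
def sim_batch(seed, n_trials, n_t, dt, drift_mode, bound_mode, A_trial,
              tau, c, B, lam, u, att_b, att_beta, att_gamma,
              f_amp, f_onset, bound_shift):
    """Euler-Maruyama simulation of n_trials independent trials.

    A_trial: per-trial drift input (length n_trials; constant families pass
    a filled array, variant-drift passes per-trial Gaussian draws).
    bound_shift: Broadie-Glasserman-Kou continuity correction,
    0.5826 * sigma * sqrt(dt), subtracted from the bound to offset the
    systematic overshoot of discrete-time crossing detection.
    Returns (choice, rt): choice +1 upper / -1 lower / 0 no crossing.
    """
    np.random.seed(seed)
    choice = np.zeros(n_trials, dtype=np.int8)
    rt = np.full(n_trials, np.nan)
    if drift_mode == DRIFT_LEAK:
        noise_scale = (c / tau) * np.sqrt(dt)
    else:
        noise_scale = c * np.sqrt(dt)
    for i in range(n_trials):
        x = 0.0
        a = A_trial[i]
        for n in range(n_t):
            t_mid = (n + 0.5) * dt
            ut = 0.0
            if drift_mode == DRIFT_ATTRACTOR:
                ut = u * t_mid
                if t_mid >= f_onset:
                    ut += f_amp
            mu = _drift(drift_mode, x, a, tau, att_b, att_beta, att_gamma, ut)
            x += mu * dt + noise_scale * np.random.normal()
            t = (n + 1) * dt
            b = _bound(bound_mode, t, B, lam, u) - bound_shift
            if x >= b:
                choice[i] = 1
                rt[i] = t
                break
            elif x <= -b:
                choice[i] = -1
                rt[i] = t
                break
    return choice, rt


@njit(cache=True)
def sim_path(noise, drift_t, dt, drift_mode, bound_mode,
             tau, c, B, lam, u, att_b, att_beta, att_gamma,
             f_amp, f_onset, bound_shift, record_path):
    """Single-trial simulation with caller-supplied standard-normal noise
    and per-step drift input drift_t (stimulus-driven or constant).

    Returns (side, step, x, path): side +1/-1/0, step = index of the
    crossing step (rt = (step+1)*dt), x = decision variable at exit or at
    the deadline, path = trajectory if record_path else empty.
    """
    n_t = noise.shape[0]
    if drift_mode == DRIFT_LEAK:
        noise_scale = (c / tau) * np.sqrt(dt)
    else:
        noise_scale = c * np.sqrt(dt)
    path = np.zeros(n_t if record_path else 0)
    x = 0.0
    for n in range(n_t):
        t_mid = (n + 0.5) * dt
        ut = 0.0
        if drift_mode == DRIFT_ATTRACTOR:
            ut = u * t_mid
            if t_mid >= f_onset:
                ut += f_amp
        mu = _drift(drift_mode, x, drift_t[n], tau, att_b, att_beta,
                    att_gamma, ut)
        x += mu * dt + noise_scale * noise[n]
        if record_path:
            path[n] = x
        t = (n + 1) * dt
        b = _bound(bound_mode, t, B, lam, u) - bound_shift
        if x >= b:
            return 1, n, x, path
        elif x <= -b:
            return -1, n, x, path
    return 0, -1, x, path
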