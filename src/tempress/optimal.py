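"""Optimal expected-gain response-time model, and the inverse design of
reward-decay rates.

With a linearly decaying stake (G_s points at onset, decaying at b
points/s from t_0, floored at zero) and a speed-accuracy tradeoff P(t),
the expected gain of planning to respond at mean time t is

    EG(t) = E_t_plan[ G(t, 1) P(t) + G(t, 0) (1 - P(t)) ]

where G(t, 1) = max(0, G_s - b (t - t_0)+) and G(t, 0) = -G(t, 1).  The
model is parameter-free given the SAT and the schedule; its argmax t_opt
is found by grid search (the reward floor makes EG only piecewise smooth)
plus a local polish.  Response-time dispersion around the planned mean is
either a point mass ("delta", the default) or Gaussian with a given sigma.

``design_decay_rates`` inverts the model: it picks six decay rates such
that accuracy at the optimal response time is linearly spaced between
0.55 and the subject's maximum correct probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, minimize_scalar

from .sat import SATParams, sat_probability
from .task import ScheduleSpec


def _sat_params(sat) -> SATParams:
    return getattr(sat, "params", sat)


def _gain_correct(t, schedule: ScheduleSpec):
    elapsed = np.maximum(0.0, np.asarray(t, float) - schedule.decay_onset)
    return np.maximum(0.0, schedule.initial_reward
                      - schedule.decay_rate * elapsed)


def expected_gain(
    tbar,
    sat,
    schedule: ScheduleSpec,
    dispersion: str = "delta",
    sigma: float | None = None,
):
    """EG(tbar) in points; vectorized over tbar."""
    if schedule.experiment not in ("exp2", "exp3"):
        raise ValueError("expected gain is defined for exp2/exp3 schedules")
    params = _sat_params(sat)

    def eg_point(t):
        p = sat_probability(t, params)
        g = _gain_correct(t, schedule)
        return g * p + (-g) * (1.0 - p)  # = g * (2p - 1)

    if dispersion == "delta":
        out = eg_point(np.asarray(tbar, float))
        return out if out.ndim else float(out)
    if dispersion != "gaussian":
        raise ValueError("dispersion must be 'delta' or 'gaussian'")
    if sigma is None or sigma <= 0:
        raise ValueError("gaussian dispersion needs sigma > 0")
    # Gauss-Legendre quadrature over tbar +- 4 sigma, truncated at t >= 0
    nodes, weights = np.polynomial.legendre.leggauss(61)
    tbar_arr = np.atleast_1d(np.asarray(tbar, float))
    out = np.empty_like(tbar_arr)
    for i, tb in enumerate(tbar_arr):
        lo, hi = max(0.0, tb - 4 * sigma), tb + 4 * sigma
        t = 0.5 * (hi - lo) * nodes + 0.5 * (hi + lo)
        w = 0.5 * (hi - lo) * weights
        dens = np.exp(-0.5 * ((t - tb) / sigma) ** 2) / (
            sigma * np.sqrt(2 * np.pi)
        )
        mass = np.sum(w * dens)
        out[i] = np.sum(w * dens * eg_point(t)) / mass
    return out if np.ndim(tbar) else float(out[0])


@dataclass
class ExpectedGainCurve:
    t_grid: np.ndarray
    eg: np.ndarray
    tbar_opt: float
    degenerate: bool = False

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"tbar": self.t_grid, "eg": self.eg})

    def plot(self, ax=None):
        """Expected gain vs planned mean response time, optimum marked."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.plot(self.t_grid, self.eg, lw=1.5)
        ax.axvline(self.tbar_opt, ls="--", color="0.4")
        ax.set_xlabel("planned mean RT (s)")
        ax.set_ylabel("expected gain (points)")
        return ax


def expected_gain_curve(
    sat,
    schedule: ScheduleSpec,
    dispersion: str = "delta",
    sigma: float | None = None,
    grid_step: float = 0.001,
    t_max: float | None = None,
    polish: bool = True,
) -> ExpectedGainCurve:
    """Grid-search EG over [0, t_max], optionally polishing the argmax by
    bounded scalar optimization.  Ties break toward the smaller tbar
    (first grid argmax).

    ``t_max`` defaults to the reward-zero time, capped at the point where
    the SAT is flat to machine precision (~50 rise constants past the
    decay onset); beyond that cap EG is strictly decreasing whenever the
    decay rate is positive, so the cap never moves the argmax."""
    if t_max is None:
        t_max = _horizon(_sat_params(sat), schedule)
    t = np.arange(0.0, t_max + grid_step / 2, grid_step)
    eg = np.asarray(expected_gain(t, sat, schedule, dispersion, sigma))
    i = int(np.argmax(eg))
    t_opt = float(t[i])
    if np.all(eg <= 0.0):
        return ExpectedGainCurve(t, eg, 0.0, degenerate=True)
    if polish and 0 < i < len(t) - 1:
        res = minimize_scalar(
            lambda x: -expected_gain(x, sat, schedule, dispersion, sigma),
            bounds=(t[i - 1], t[i + 1]),
            method="bounded",
            options={"xatol": 1e-7},
        )
        if -res.fun >= eg[i]:
            t_opt = float(res.x)
    return ExpectedGainCurve(t, eg, t_opt)


def optimal_mean_rt(
    sat,
    schedule: ScheduleSpec,
    dispersion: str = "delta",
    sigma: float | None = None,
    grid_step: float = 0.001,
) -> float:
    """argmax of EG; 0 with a degenerate curve if EG is nowhere positive."""
    return expected_gain_curve(
        sat, schedule, dispersion, sigma, grid_step
    ).tbar_opt


def _horizon(params: SATParams, schedule: ScheduleSpec) -> float:
    # past ~50 rise constants the SAT is flat to machine precision
    return min(schedule.deadline,
               schedule.decay_onset + 50.0 * params.lam + 5.0)


def design_decay_rates(
    sat,
    n_levels: int = 6,
    acc_lo: float = 0.55,
    acc_hi: float | None = None,
    initial_reward: float = 100.0,
    decay_onset: float | None = None,
    tol: float = 1e-3,
    experiment: str = "exp2",
) -> list[float]:
    """Decay rates b_1..b_n (points/s, fastest first) such that accuracy at
    the optimal response time hits targets linearly spaced on
    [acc_lo, acc_hi].

    ``acc_hi`` defaults to the subject's maximum correct probability —
    the SAT evaluated at the longest deadline (4.2 s), capped at 0.95; a
    target at or above the SAT plateau is unattainable in finite time and
    raises, naming the level.  Rates are designed at a reference initial
    stake (default 100 points) with decay onset at the SAT rise point
    delta unless given.
    """
    params = _sat_params(sat)
    if acc_hi is None:
        acc_hi = min(0.95, float(sat_probability(4.2, params)))
    if decay_onset is None:
        decay_onset = params.delta
    if not params.c < acc_lo < 1.0:
        raise ValueError("acc_lo must lie between chance and 1")
    if acc_hi < acc_lo:
        raise ValueError("acc_hi must be at least acc_lo")
    targets = (
        [acc_lo] if n_levels == 1
        else list(np.linspace(acc_lo, acc_hi, n_levels))
    )

    def accuracy_at_opt(b: float) -> float:
        sched = ScheduleSpec(
            experiment, 1,
            deadline=decay_onset + initial_reward / b,
            initial_reward=initial_reward, decay_rate=b,
            decay_onset=decay_onset,
        )
        curve = expected_gain_curve(
            params, sched, grid_step=0.001, t_max=_horizon(params, sched)
        )
        return float(sat_probability(curve.tbar_opt, params))

    rates = []
    for k, a_k in enumerate(targets, start=1):
        if a_k >= params.plateau - 1e-12:
            raise ValueError(
                f"level {k}: target accuracy {a_k:.4f} is not attainable "
                f"(SAT plateau {params.plateau:.4f})"
            )
        # P(t_opt(b)) decreases monotonically in b; bracket then bisect
        b_lo, b_hi = 1e-4, 1e4
        while accuracy_at_opt(b_hi) > a_k and b_hi < 1e8:
            b_hi *= 10
        while accuracy_at_opt(b_lo) < a_k and b_lo > 1e-8:
            b_lo /= 10
        b = brentq(
            lambda bb: accuracy_at_opt(bb) - a_k, b_lo, b_hi,
            xtol=1e-10, rtol=1e-10, maxiter=200,
        )
        if abs(accuracy_at_opt(b) - a_k) > tol:
            raise RuntimeError(
                f"level {k}: bisection failed to reach the target within "
                f"{tol}"
            )
        rates.append(float(b))
    return sorted(rates, reverse=True)  # level 1 = fastest decay
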