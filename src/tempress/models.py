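"""The seven sequential-sampling decision models, simulated at trial level.

Families
--------
``basic``          drift-diffusion to fixed symmetric bounds
``variant_drift``  drift redrawn per trial from Normal(A, sigma_A)
``collapsing``     bounds collapse exponentially, b(t) = B exp(-t/lambda)
``leak``           leaky (Ornstein-Uhlenbeck) integration,
                   tau dx = -x dt + A dt + c dW
``urgency``        decision variable multiplied by a linearly rising
                   urgency signal, y(t) = x(t) * u t, read against fixed B
``leak_urgency``   leaky integration, then the urgency multiplication
``attractor``      noise-driven escape in a tri-stable effective potential
                   G(x) = b (x^2 - beta x^4 + gamma x^6), gated by urgency
                   and, near the deadline, a forcing step

All are integrated by Euler-Maruyama at ``dt`` (default 1 ms) with Gaussian
increments of variance c^2 dt.  The urgency families commit when
|x(t)| * u t exceeds B — identical, trial for trial, to reading x against
the collapsing bound B/(u t).  The attractor commits when |x| passes the
inner inflection point of the outer potential wells.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from . import _kernels as K
from .task import ScheduleSpec, StimulusStream

FAMILIES = (
    "basic",
    "variant_drift",
    "collapsing",
    "leak",
    "urgency",
    "leak_urgency",
    "attractor",
)

PerLevel = Union[float, Sequence[float], Mapping[int, float]]


def _per_level(value: PerLevel, level: int, name: str) -> float:
    if value is None:
        raise ValueError(f"model is missing required parameter {name!r}")
    if isinstance(value, Mapping):
        return float(value[level])
    if isinstance(value, (list, tuple, np.ndarray)):
        return float(value[level - 1])
    return float(value)


def attractor_geometry(beta: float, gamma: float) -> dict:
    """Stationary/inflection points of G(x)/b = x^2 - beta x^4 + gamma x^6.

    Requires beta^2 > 3 gamma (tri-stable at rest: minimum at 0, barrier
    maxima at +-x_barrier, outer minima at +-x_outer).  The commitment
    point x_commit is the inner inflection of the outer well (the larger
    root of G'' = 0), which lies between the barrier and the outer minimum.
    """
    if gamma <= 0 or beta <= 0:
        raise ValueError("attractor potential needs beta > 0 and gamma > 0")
    disc = beta * beta - 3.0 * gamma
    if disc <= 0:
        raise ValueError(
            "potential is not tri-stable: requires beta^2 > 3*gamma"
        )
    x2_barrier = (beta - np.sqrt(disc)) / (3.0 * gamma)
    x2_outer = (beta + np.sqrt(disc)) / (3.0 * gamma)
    disc2 = 9.0 * beta * beta - 15.0 * gamma
    x2_commit = (3.0 * beta + np.sqrt(disc2)) / (15.0 * gamma)
    return {
        "x_barrier": float(np.sqrt(x2_barrier)),
        "x_outer": float(np.sqrt(x2_outer)),
        "x_commit": float(np.sqrt(x2_commit)),
    }


def attractor_gprime(x: np.ndarray, b: float, beta: float, gamma: float):
    """dG/dx for the attractor potential."""
    return b * (2.0 * x - 4.0 * beta * x ** 3 + 6.0 * gamma * x ** 5)


@dataclass(frozen=True)
class ModelSpec:
    """Family tag plus parameters for one decision model.

    ``thresholds`` is the per-schedule decision bound B_k (scalar, list by
    level, or mapping level -> value); for the attractor family it is the
    per-schedule barrier parameter b_k instead, and the geometric
    commitment point plays the role of the bound.
    """

    family: str
    drift: float = 1.0
    noise: float = 1.0
    thresholds: PerLevel = 1.0
    drift_sd: Optional[float] = None          # variant_drift
    collapse_tau: Optional[PerLevel] = None   # collapsing
    leak_tau: Optional[float] = None          # leak / leak_urgency
    urgency_slope: Optional[float] = None     # urgency families + attractor
    att_beta: float = 2.0                     # attractor quartic coefficient
    att_gamma: float = 1.0                    # attractor sextic coefficient
    forcing_amp: Optional[float] = None       # attractor; None -> auto
    forcing_lead: float = 0.050               # F steps on this long pre-deadline
    dt: float = 0.001
    stimulus_gain: Optional[float] = None     # stimulus-driven drift if set
    #: momentary-evidence denominator: "fraction" divides the dominant-
    #: minus-other count by the current visible count (color strength);
    #: "fixed" divides by the steady-state count (persistence / sampling
    #: interval), making each dot's leverage time-invariant — the variant
    #: used for reverse-correlation (kernel) analyses
    evidence_normalization: str = "fraction"
    deadline_commit: bool = False             # commit by sign at deadline
    #: apply the 0.5826 * sigma * sqrt(dt) continuity correction to the
    #: bound, removing the leading-order Euler crossing-detection bias
    boundary_correction: bool = True

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown model family {self.family!r}")
        if self.noise <= 0:
            raise ValueError("noise scale must be positive")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.family == "variant_drift" and (
            self.drift_sd is None or self.drift_sd <= 0
        ):
            raise ValueError("variant_drift needs drift_sd > 0")
        if self.family == "collapsing" and self.collapse_tau is None:
            raise ValueError("collapsing needs collapse_tau")
        if self.family in ("leak", "leak_urgency") and (
            self.leak_tau is None or self.leak_tau <= 0
        ):
            raise ValueError("leak families need leak_tau > 0")
        if self.family in ("urgency", "leak_urgency", "attractor") and (
            self.urgency_slope is None or self.urgency_slope <= 0
        ):
            raise ValueError("urgency/attractor families need urgency_slope > 0")
        if self.family == "attractor":
            attractor_geometry(self.att_beta, self.att_gamma)  # validates
        if self.evidence_normalization not in ("fraction", "fixed"):
            raise ValueError(
                "evidence_normalization must be 'fraction' or 'fixed'"
            )

    def threshold_for(self, level: int) -> float:
        value = _per_level(self.thresholds, level, "thresholds")
        if value <= 0:
            raise ValueError("thresholds must be positive")
        return value

    def collapse_for(self, level: int) -> float:
        return _per_level(self.collapse_tau, level, "collapse_tau")

    # ---- kernel parameter mapping -------------------------------------
    def _modes(self) -> tuple[int, int]:
        drift_mode = (
            K.DRIFT_LEAK
            if self.family in ("leak", "leak_urgency")
            else K.DRIFT_ATTRACTOR
            if self.family == "attractor"
            else K.DRIFT_CONST
        )
        bound_mode = (
            K.BOUND_COLLAPSE
            if self.family == "collapsing"
            else K.BOUND_URGENCY
            if self.family in ("urgency", "leak_urgency")
            else K.BOUND_FIXED
        )
        return drift_mode, bound_mode

    def _kernel_args(self, schedule: ScheduleSpec) -> dict:
        level = schedule.level
        drift_mode, bound_mode = self._modes()
        geom = None
        if self.family == "attractor":
            geom = attractor_geometry(self.att_beta, self.att_gamma)
            bound = geom["x_commit"]
            att_b = self.threshold_for(level)
            f_amp = self.forcing_amp
            if f_amp is None:
                xs = np.linspace(0.0, geom["x_commit"], 200)
                f_amp = 10.0 * float(
                    np.max(np.abs(attractor_gprime(xs, att_b, self.att_beta,
                                                   self.att_gamma)))
                )
            f_onset = max(0.0, schedule.deadline - self.forcing_lead)
        else:
            bound = self.threshold_for(level)
            att_b, f_amp, f_onset = 0.0, 0.0, 1e12
        lam = self.collapse_for(level) if self.family == "collapsing" else 1.0
        u = float(self.urgency_slope) if self.urgency_slope else 1.0
        tau = float(self.leak_tau) if self.leak_tau else 1.0
        sigma = self.noise / tau if self.family in ("leak", "leak_urgency") \
            else self.noise
        shift = 0.5826 * sigma * np.sqrt(self.dt) \
            if self.boundary_correction else 0.0
        return dict(
            bound_shift=float(shift),
            drift_mode=drift_mode,
            bound_mode=bound_mode,
            tau=tau,
            c=float(self.noise),
            B=float(bound),
            lam=float(lam),
            u=u,
            att_b=float(att_b),
            att_beta=float(self.att_beta),
            att_gamma=float(self.att_gamma),
            f_amp=float(f_amp),
            f_onset=float(f_onset),
        )


@dataclass(frozen=True)
class TrialOutcome:
    choice: str  # "dominant" | "other" | "none"
    rt: Optional[float]
    crossed: bool
    trajectory: Optional[np.ndarray] = None


def drift_from_stimulus(stream: StimulusStream, t: float, gain: float) -> float:
    """Momentary drift: gain * (n_dominant - n_other) / total visible dots."""
    from .task import visible_counts

    n_dom, n_oth = visible_counts(stream, t)
    total = n_dom + n_oth
    if total == 0:
        return 0.0
    return gain * (n_dom - n_oth) / total


def stimulus_drift_profile(
    stream: StimulusStream, dt: float, n_t: int, gain: float,
    normalization: str = "fraction",
) -> np.ndarray:
    """Per-integration-step momentary drift from a dot stream.

    Piecewise constant between dot onsets; evaluated at step start times.
    """
    si = stream.sample_interval
    per_window = int(round(stream.persistence / si))
    cum = np.concatenate([[0], np.cumsum(stream.is_dominant.astype(np.int64))])
    t = np.arange(n_t) * dt
    shown = np.minimum(
        np.floor(t / si + 1e-9).astype(np.int64) + 1, stream.n_samples
    )
    expired = np.maximum(shown - per_window, 0)
    n_vis = shown - expired
    n_dom = cum[shown] - cum[expired]
    denom = per_window if normalization == "fixed" else np.maximum(n_vis, 1)
    return gain * (2.0 * n_dom - n_vis) / denom


def simulate_trial(
    model: ModelSpec,
    schedule: ScheduleSpec,
    stream: Optional[StimulusStream] = None,
    rng: np.random.Generator | int | None = None,
    record_path: bool = False,
) -> TrialOutcome:
    """Simulate one trial; noise is drawn from ``rng`` so per-trial
    substreams remain reproducible."""
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    dt = model.dt
    if dt >= schedule.deadline:
        raise ValueError("integration step dt must be smaller than the deadline")
    n_t = int(round(schedule.deadline / dt))
    args = model._kernel_args(schedule)

    if model.stimulus_gain is not None and stream is not None:
        drift_t = stimulus_drift_profile(
            stream, dt, n_t, model.stimulus_gain,
            model.evidence_normalization,
        )
    else:
        a = model.drift
        if model.family == "variant_drift":
            a = rng.normal(model.drift, model.drift_sd)
        drift_t = np.full(n_t, a)

    noise = rng.standard_normal(n_t)
    side, step, x_end, path = K.sim_path(
        noise, drift_t, dt,
        args["drift_mode"], args["bound_mode"], args["tau"], args["c"],
        args["B"], args["lam"], args["u"], args["att_b"], args["att_beta"],
        args["att_gamma"], args["f_amp"], args["f_onset"],
        args["bound_shift"], record_path,
    )
    if side == 0 and model.deadline_commit and x_end != 0.0:
        side = 1 if x_end > 0 else -1
        step = n_t - 1
    if side == 0:
        return TrialOutcome("none", None, False,
                            path if record_path else None)
    choice = "dominant" if side > 0 else "other"
    return TrialOutcome(choice, (step + 1) * dt, True,
                        path if record_path else None)


def simulate_trials(
    model: ModelSpec,
    schedule: ScheduleSpec,
    n_trials: int,
    seed: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Batch constant-drift simulation (compiled); returns (choice, rt)
    with choice +1 = dominant bound, -1 = other, 0 = no crossing."""
    args = model._kernel_args(schedule)
    n_t = int(round(schedule.deadline / model.dt))
    if model.family == "variant_drift":
        drift_rng = np.random.default_rng(np.random.SeedSequence([seed, 17]))
        a_trial = drift_rng.normal(model.drift, model.drift_sd, n_trials)
    else:
        a_trial = np.full(n_trials, model.drift)
    choice, rt = K.sim_batch(
        seed % (2 ** 31), n_trials, n_t, model.dt,
        args["drift_mode"], args["bound_mode"], a_trial, args["tau"],
        args["c"], args["B"], args["lam"], args["u"], args["att_b"],
        args["att_beta"], args["att_gamma"], args["f_amp"], args["f_onset"],
        args["bound_shift"],
    )
    return choice, rt


def records_from_batch(
    choice: np.ndarray, rt: np.ndarray, schedule: ScheduleSpec
) -> pd.DataFrame:
    """Minimal trial table (level, deadline, choice, correct, rt) from a
    batch simulation, in the layout the analysis ops expect."""
    crossed = choice != 0
    return pd.DataFrame(
        {
            "level": schedule.level,
            "deadline": schedule.deadline,
            "choice": np.where(crossed,
                               np.where(choice > 0, "dominant", "other"),
                               "none"),
            "correct": np.where(crossed, choice > 0, None),
            "rt": np.where(crossed, rt, np.nan),
        }
    )


def simulate_records(
    model: ModelSpec,
    schedules: Sequence[ScheduleSpec],
    n_per_schedule: int,
    seed: int,
) -> pd.DataFrame:
    """Concatenated batch simulations across schedules."""
    frames = []
    for i, sched in enumerate(schedules):
        choice, rt = simulate_trials(model, sched, n_per_schedule, seed + i)
        frames.append(records_from_batch(choice, rt, sched))
    return pd.concat(frames, ignore_index=True)


def model_signatures(
    model: ModelSpec,
    schedules: Sequence[ScheduleSpec],
    n_per_schedule: int = 10_000,
    seed: int = 0,
) -> dict[str, pd.DataFrame]:
    """The three diagnostic tables that separate the model families:
    per-schedule SAT points, accuracy in five deadline-proximity bins with
    a slope test, and RT-matched accuracy for adjacent schedules."""
    from .analysis import proximity_performance, rt_match
    from .sat import bin_by_schedule

    if n_per_schedule < 1000:
        raise ValueError("signatures need at least 10^3 trials per schedule")
    records = simulate_records(model, schedules, n_per_schedule, seed)
    valid = records[records.choice != "none"]

    sat_tbl = bin_by_schedule(valid).reset_index()

    prox_rows = []
    for sched in schedules:
        res = proximity_performance(valid, sched.level, n_bins=5)
        for i, (center, acc, n) in enumerate(
            zip(res.bin_centers, res.accuracy, res.n_trials)
        ):
            prox_rows.append(
                dict(level=sched.level, bin=i + 1, rt_center=center,
                     accuracy=acc, n=n, slope=res.slope, p_value=res.p_value)
            )
    prox_tbl = pd.DataFrame(prox_rows)

    match_rows = []
    for fast, slow in zip(schedules[:-1], schedules[1:]):
        pair = rt_match(
            valid[valid.level == fast.level], valid[valid.level == slow.level]
        )
        match_rows.append(
            dict(
                fast_level=fast.level,
                slow_level=slow.level,
                gap=pair.gap,
                acc_fast=pair.acc_fast,
                acc_slow=pair.acc_slow,
                n_fast=pair.n_fast,
                n_slow=pair.n_slow,
                flag=pair.flag,
            )
        )
    match_tbl = pd.DataFrame(match_rows)

    return {"sat": sat_tbl, "proximity": prox_tbl, "rt_matched": match_tbl}


def simulate_stimulus_batch(
    model: ModelSpec,
    schedule: ScheduleSpec,
    n_trials: int,
    seed: int,
    dt: float = 0.005,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Vectorized stimulus-driven simulation for reverse-correlation work.

    Every trial gets its own dot stream; the integrator follows the
    momentary dominant-minus-other dot fraction.  Returns (records, dots)
    where dots[i, j] says whether dot j of trial i was red, and records
    carries choices in color terms (dominant color fixed to red so kernels
    are directly interpretable).

    Leak families use tau dx = (A(t) - x) dt + c dW; the perfect
    integrator is the basic family.  With ``model.deadline_commit`` the
    choice on non-crossing trials is the sign of x at the deadline.
    """
    if model.stimulus_gain is None:
        raise ValueError("stimulus-driven batch needs model.stimulus_gain")
    rng = np.random.default_rng(seed)
    si = 0.05
    n_t = int(round(schedule.deadline / dt))
    n_samples = int(np.floor(schedule.deadline / si + 1e-9)) + 1
    per_window = int(round(2.0 / si))
    q = schedule.dot_ratio

    is_dom = rng.random((n_trials, n_samples)) < q  # red = dominant
    cum = np.concatenate(
        [np.zeros((n_trials, 1), dtype=np.int64),
         np.cumsum(is_dom, axis=1, dtype=np.int64)], axis=1
    )
    t_steps = np.arange(n_t) * dt
    shown = np.minimum(np.floor(t_steps / si + 1e-9).astype(int) + 1, n_samples)
    expired = np.maximum(shown - per_window, 0)
    n_vis = shown - expired

    gain = model.stimulus_gain
    tau = model.leak_tau if model.family in ("leak", "leak_urgency") else None
    c = model.noise
    level = schedule.level
    bound = model.threshold_for(level)
    scale = (c / tau if tau else c) * np.sqrt(dt)
    shift = 0.5826 * scale if model.boundary_correction else 0.0

    x = np.zeros(n_trials)
    done = np.zeros(n_trials, dtype=bool)
    out_choice = np.zeros(n_trials, dtype=np.int8)
    out_rt = np.full(n_trials, np.nan)
    fixed_norm = model.evidence_normalization == "fixed"
    for n in range(n_t):
        n_dom = cum[:, shown[n]] - cum[:, expired[n]]
        denom = per_window if fixed_norm else max(n_vis[n], 1)
        a_t = gain * (2.0 * n_dom - n_vis[n]) / denom
        mu = (a_t - x) / tau if tau else a_t
        x = x + mu * dt + scale * rng.standard_normal(n_trials)
        t = (n + 1) * dt
        if model.family in ("urgency", "leak_urgency"):
            b_t = bound / max(model.urgency_slope * t, 1e-12)
        elif model.family == "collapsing":
            b_t = bound * np.exp(-t / model.collapse_for(level))
        else:
            b_t = bound
        b_t = b_t - shift
        hit_up = (~done) & (x >= b_t)
        hit_lo = (~done) & (x <= -b_t)
        out_choice[hit_up] = 1
        out_choice[hit_lo] = -1
        out_rt[hit_up | hit_lo] = t
        done |= hit_up | hit_lo
        x[done & (out_rt == t)] = np.clip(x[done & (out_rt == t)], -b_t, b_t)
    if model.deadline_commit:
        late = ~done
        out_choice[late] = np.where(x[late] >= 0, 1, -1)
        out_rt[late] = schedule.deadline
        done[late] = True

    crossed = out_choice != 0
    records = pd.DataFrame(
        {
            "level": level,
            "deadline": schedule.deadline,
            "choice": np.where(crossed,
                               np.where(out_choice > 0, "red", "green"),
                               "none"),
            "correct": np.where(crossed, out_choice > 0, None),
            "rt": out_rt,
        }
    )
    return records, is_dom
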