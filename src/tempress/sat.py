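"""Speed-accuracy tradeoff (SAT) estimation.

The SAT is summarized by a shifted-exponential (modified Weibull)
psychometric curve in mean response time t:

    P(t) = c + (1 - c) * beta * (1 - exp(-(t - delta) / lambda)),  t >= delta
    P(t) = c,                                                      t <  delta

with chance level c (0.5 here), rise point delta (s), rise constant
lambda (s), and — in the pooled ten-bin variant — an asymptote scale
beta in [0, 1] capturing the plateau left by leaky integration.  The
per-schedule variant fixes beta = 1.  Parameters are estimated by
maximum binomial likelihood over (mean RT, n_correct / n_trials) bins,
under the constraints delta > 0.2 and lambda > 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize

DELTA_MIN = 0.2
LAMBDA_MIN = 0.001


@dataclass(frozen=True)
class SATParams:
    delta: float
    lam: float
    beta: float = 1.0
    c: float = 0.5
    variant: str = "per_schedule"

    def __post_init__(self) -> None:
        if self.variant not in ("per_schedule", "pooled"):
            raise ValueError("variant must be 'per_schedule' or 'pooled'")
        if self.delta <= DELTA_MIN - 1e-12:
            raise ValueError(f"delta must exceed {DELTA_MIN}")
        if self.lam <= LAMBDA_MIN - 1e-12:
            raise ValueError(f"lambda must exceed {LAMBDA_MIN}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must lie in [0, 1]")
        if self.variant == "per_schedule" and self.beta != 1.0:
            raise ValueError("the per-schedule variant fixes beta = 1")

    @property
    def plateau(self) -> float:
        return self.c + (1.0 - self.c) * self.beta

    def probability(self, t):
        return sat_probability(t, self)


def sat_probability(t, params: SATParams):
    """P(correct | mean RT t); clamped at chance below the rise point."""
    t = np.asarray(t, dtype=float)
    with np.errstate(over="ignore"):  # t << delta overflows, clips to 0
        rise = 1.0 - np.exp(-(t - params.delta) / params.lam)
    p = params.c + (1.0 - params.c) * params.beta * np.clip(rise, 0.0, 1.0)
    return p if p.ndim else float(p)


def bin_by_schedule(records: pd.DataFrame) -> pd.DataFrame:
    """One (mean RT, n, n_correct) bin per schedule level.

    Only responded trials enter; ``records`` needs columns level, rt,
    correct, choice.
    """
    valid = records[(records.choice != "none") & records.rt.notna()]
    if valid.empty:
        raise ValueError("no responded trials to bin")
    out = valid.groupby("level").agg(
        mean_rt=("rt", "mean"),
        n_trials=("rt", "size"),
        n_correct=("correct", "sum"),
    )
    out["n_correct"] = out["n_correct"].astype(int)
    return out.sort_values("mean_rt")


def bin_pooled(records: pd.DataFrame, n_bins: int = 10) -> pd.DataFrame:
    """Pool all schedules and split RTs into ``n_bins`` equal-width bins."""
    valid = records[(records.choice != "none") & records.rt.notna()]
    if valid.empty:
        raise ValueError("no responded trials to bin")
    rt = valid.rt.to_numpy(float)
    edges = np.linspace(rt.min(), rt.max(), n_bins + 1)
    edges[-1] += 1e-9
    idx = np.clip(np.digitize(rt, edges) - 1, 0, n_bins - 1)
    correct = valid.correct.to_numpy(bool)
    rows = []
    for b in range(n_bins):
        m = idx == b
        if not m.any():
            continue
        rows.append(
            dict(bin=b + 1, mean_rt=rt[m].mean(), n_trials=int(m.sum()),
                 n_correct=int(correct[m].sum()))
        )
    return pd.DataFrame(rows).set_index("bin")


def _check_binned(binned: pd.DataFrame) -> pd.DataFrame:
    for col in ("mean_rt", "n_trials", "n_correct"):
        if col not in binned.columns:
            raise ValueError(f"binned table is missing column {col!r}")
    if (binned.n_correct > binned.n_trials).any():
        raise ValueError("n_correct cannot exceed n_trials")
    return binned.sort_values("mean_rt")


class SpeedAccuracyModel:
    """Binomial maximum-likelihood fit of the SAT curve to binned data.

    Parameters
    ----------
    binned : DataFrame with columns mean_rt, n_trials, n_correct
        One row per bin (per schedule for ``per_schedule``, ten pooled RT bins for
        ``pooled``).
    variant : "per_schedule" (delta, lambda free) or "pooled" (adds the plateau beta).
    """

    def __init__(self, binned: pd.DataFrame, variant: str = "per_schedule",
                 c: float = 0.5):
        self.binned = _check_binned(binned)
        if variant not in ("per_schedule", "pooled"):
            raise ValueError("variant must be 'per_schedule' or 'pooled'")
        self.variant = variant
        self.c = c
        k = 2 if variant == "per_schedule" else 3
        if len(self.binned) < k + 1:
            raise ValueError(
                f"need at least {k + 1} bins to fit the {variant} variant"
            )
        self._t = self.binned.mean_rt.to_numpy(float)
        self._n = self.binned.n_trials.to_numpy(float)
        self._k = self.binned.n_correct.to_numpy(float)

    @classmethod
    def from_records(cls, records: pd.DataFrame, variant: str = "per_schedule",
                     n_bins: int = 10) -> "SpeedAccuracyModel":
        binned = (
            bin_by_schedule(records) if variant == "per_schedule"
            else bin_pooled(records, n_bins)
        )
        return cls(binned, variant=variant)

    def _params(self, theta) -> SATParams:
        beta = theta[2] if self.variant == "pooled" else 1.0
        return SATParams(delta=theta[0], lam=theta[1], beta=beta,
                         c=self.c, variant=self.variant)

    def loglike(self, theta) -> float:
        p = sat_probability(self._t, self._params(theta))
        p = np.clip(p, 1e-12, 1.0 - 1e-12)
        return float(
            np.sum(self._k * np.log(p) + (self._n - self._k) * np.log1p(-p))
        )

    def _starts(self) -> np.ndarray:
        # deterministic multi-starts on a log-spaced (delta, lambda) grid
        t_hi = max(self._t.max(), DELTA_MIN + 0.2)
        deltas = np.geomspace(DELTA_MIN + 0.02, max(0.8 * t_hi, 0.3), 4)
        lams = np.geomspace(0.05, max(t_hi, 0.5), 2)
        grid = [(d, l) for d in deltas for l in lams]
        if self.variant == "per_schedule":
            return np.array(grid)
        p_max = np.clip(self._k.sum() / self._n.sum(), 0.55, 0.999)
        beta0 = (p_max - self.c) / (1.0 - self.c)
        return np.array([(d, l, beta0) for d, l in grid])

    def fit(self) -> "SpeedAccuracyResults":
        t_hi = max(self._t.max() * 2.0, 2.0)
        bounds = [(DELTA_MIN + 1e-6, t_hi), (LAMBDA_MIN + 1e-9, 10.0)]
        if self.variant == "pooled":
            bounds.append((0.0, 1.0))
        best = None
        for theta0 in self._starts():
            res = minimize(
                lambda th: -self.loglike(th), theta0, method="L-BFGS-B",
                bounds=bounds,
            )
            cand = (-res.fun, -res.x[0], res)  # ties -> lowest delta
            if best is None or cand[:2] > best[:2]:
                best = cand
        res = best[2]
        params = self._params(res.x)
        at_lambda_bound = res.x[1] > bounds[1][1] * 0.99
        flag = None
        if not res.success:
            flag = f"optimizer: {res.message}"
        elif at_lambda_bound:
            flag = "lambda pinned at upper bound (no SAT signal)"
        return SpeedAccuracyResults(
            model=self, params=params, llf=-res.fun,
            converged=bool(res.success), flag=flag,
        )


@dataclass
class SpeedAccuracyResults:
    model: SpeedAccuracyModel
    params: SATParams
    llf: float
    converged: bool
    flag: str | None = None

    def predict(self, t):
        return sat_probability(t, self.params)

    @property
    def delta(self) -> float:
        return self.params.delta

    @property
    def lam(self) -> float:
        return self.params.lam

    @property
    def beta(self) -> float:
        return self.params.beta

    def plot(self, ax=None):
        """Binned data with the fitted SAT curve."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        b = self.model.binned
        ax.plot(b.mean_rt, b.n_correct / b.n_trials, "o", ms=5)
        t = np.linspace(0.0, float(b.mean_rt.max()) * 1.2, 300)
        ax.plot(t, self.predict(t), lw=1.5)
        ax.set_xlabel("mean RT (s)")
        ax.set_ylabel("P(correct)")
        ax.set_ylim(0.45, 1.02)
        return ax

    def to_dict(self) -> dict:
        return dict(
            c=self.params.c, delta=self.params.delta, lam=self.params.lam,
            beta=self.params.beta, variant=self.params.variant,
            logL=self.llf, converged=self.converged, flag=self.flag,
        )

    def summary(self) -> str:
        p = self.params
        lines = [
            "Speed-accuracy tradeoff fit "
            f"({'per-schedule' if p.variant == 'per_schedule' else 'pooled ten-bin'})",
            f"  bins: {len(self.model.binned)}   logL: {self.llf:.3f}"
            f"   converged: {self.converged}",
            f"  c (chance, fixed)  {p.c:8.3f}",
            f"  delta (rise point) {p.delta:8.4f} s",
            f"  lambda (rise const){p.lam:8.4f} s",
        ]
        if p.variant == "pooled":
            lines.append(
                f"  beta (plateau)     {p.beta:8.4f}"
                f"   -> P(inf) = {p.plateau:.4f}"
            )
        if self.flag:
            lines.append(f"  note: {self.flag}")
        return "\n".join(lines)


def fit_sat(binned: pd.DataFrame, variant: str = "per_schedule") -> SpeedAccuracyResults:
    """Functional wrapper around SpeedAccuracyModel(...).fit()."""
    return SpeedAccuracyModel(binned, variant=variant).fit()
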