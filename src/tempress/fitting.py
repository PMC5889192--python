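"""Fitting decision models to choice/RT summary tables.

The fitting target is a SummaryTable: for every (schedule, RT-quantile
bin k in 1..5) the proportion correct, the mean and SD of RT, and the
trial count, computed from responded trials only.  Model predictions for
the same bins come from the Fokker-Planck first-passage fluxes
(:mod:`tempress.fokker_planck`), conditional on crossing before the
deadline.  The likelihood treats each summary as Gaussian around the
model prediction with the standard summary-statistic variances:
p(1-p)/n for a proportion, sd^2/n for a mean, sd^2/(2n) for an SD
(delta method), all evaluated from the observed table.

``ChoiceRTModel`` is the statsmodels-style entry point: construct from an
observed SummaryTable plus the schedule list, ``fit()`` runs bounded
multi-start maximum likelihood (log-parameterized, data-driven
deterministic starts) and returns a ``ChoiceRTResults`` carrying the
estimates, log-likelihood, parameter count k and AIC = 2k - 2 logL.

Identifiability conventions (reflected in k): the diffusion scale c is
fixed at 1 for every family, and the urgency slope u is fixed at 1 while
fitting the urgency families (only B_k/u is identified).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import norm

from .fokker_planck import fp_propagate, predict_summaries
from .models import FAMILIES, ModelSpec
from .task import ScheduleSpec

#: log-likelihood charged for a predicted-empty bin during optimization
EMPTY_BIN_PENALTY = -50.0


def observed_summaries(
    records: pd.DataFrame, schedules: Sequence[ScheduleSpec], n_bins: int = 5
) -> tuple[pd.DataFrame, dict[int, np.ndarray]]:
    """Equal-count RT-quantile summaries per schedule.

    Returns (table, bin_edges); the outer edges are pinned to 0 and the
    deadline so model mass outside the observed RT range still lands in
    the extreme bins.
    """
    rows = []
    edges_by_level: dict[int, np.ndarray] = {}
    for sched in schedules:
        sub = records[
            (records.level == sched.level)
            & (records.choice != "none")
            & records.rt.notna()
        ]
        if len(sub) < n_bins:
            raise ValueError(
                f"schedule {sched.level}: need at least {n_bins} responded "
                "trials"
            )
        rt = sub.rt.to_numpy(float)
        correct = sub.correct.to_numpy(bool)
        qs = np.quantile(rt, np.linspace(0, 1, n_bins + 1))
        edges = qs.copy()
        edges[0], edges[-1] = 0.0, sched.deadline
        # strictly increasing interior edges
        for i in range(1, n_bins):
            edges[i] = max(edges[i], edges[i - 1] + 1e-6)
        edges_by_level[sched.level] = edges
        idx = np.clip(np.searchsorted(qs, rt, side="right") - 1, 0, n_bins - 1)
        for b in range(n_bins):
            m = idx == b
            n = int(m.sum())
            rows.append(
                dict(
                    schedule=sched.level,
                    bin=b + 1,
                    p_correct=float(correct[m].mean()) if n else np.nan,
                    mean_rt=float(rt[m].mean()) if n else np.nan,
                    sd_rt=float(rt[m].std()) if n else np.nan,
                    n=n,
                )
            )
    return pd.DataFrame(rows), edges_by_level


def summary_loglik(
    predicted: pd.DataFrame,
    observed: pd.DataFrame,
    empty_bin_penalty: float | None = None,
) -> float:
    """Gaussian summary likelihood of ``observed`` under ``predicted``.

    Flagged/empty predicted bins are excluded (spec behavior) unless an
    ``empty_bin_penalty`` is supplied, in which case each contributes that
    fixed amount — the optimizer-facing variant.
    """
    pred_cols = ["schedule", "bin", "p_correct", "mean_rt", "sd_rt"]
    pred = predicted[
        pred_cols + (["flagged"] if "flagged" in predicted.columns else [])
    ].rename(columns={c: c + "_pred" for c in pred_cols[2:]})
    merged = observed.merge(pred, on=["schedule", "bin"],
                            validate="one_to_one")
    if len(merged) != len(observed) or len(merged) != len(predicted):
        raise ValueError("predicted and observed bin structures differ")
    ll = 0.0
    for row in merged.itertuples():
        if getattr(row, "flagged", False) or not np.isfinite(row.p_correct_pred):
            if empty_bin_penalty is not None:
                ll += empty_bin_penalty
            continue
        n = row.n
        sd = max(row.sd_rt, 1e-3)
        var_p = max(row.p_correct * (1 - row.p_correct), 1e-3) / n
        var_m = sd * sd / n
        var_s = sd * sd / (2.0 * n)
        ll += norm.logpdf(row.p_correct, row.p_correct_pred, np.sqrt(var_p))
        ll += norm.logpdf(row.mean_rt, row.mean_rt_pred, np.sqrt(var_m))
        ll += norm.logpdf(row.sd_rt, row.sd_rt_pred, np.sqrt(var_s))
    return float(ll)


# ---------------------------------------------------------------------------
# parameter packing

_BOUNDS = {
    "A": (0.02, 6.0),
    "sigma_A": (0.02, 4.0),
    "tau": (0.05, 6.0),
    "B": (0.05, 6.0),
    "lam": (0.05, 12.0),
    "b_att": (0.2, 30.0),
}


def _param_layout(family: str, n_sched: int) -> list[tuple[str, tuple]]:
    layout = [("A", _BOUNDS["A"])]
    if family == "variant_drift":
        layout.append(("sigma_A", _BOUNDS["sigma_A"]))
    if family in ("leak", "leak_urgency"):
        layout.append(("tau", _BOUNDS["tau"]))
    if family == "attractor":
        layout.append(("u", (0.05, 10.0)))
        layout += [(f"b{k}", _BOUNDS["b_att"]) for k in range(1, n_sched + 1)]
    else:
        layout += [(f"B{k}", _BOUNDS["B"]) for k in range(1, n_sched + 1)]
    if family == "collapsing":
        layout += [(f"lam{k}", _BOUNDS["lam"]) for k in range(1, n_sched + 1)]
    return layout


def _spec_from_values(family: str, values: Mapping[str, float],
                      n_sched: int, dt: float) -> ModelSpec:
    kw: dict = dict(family=family, drift=values["A"], noise=1.0, dt=dt)
    if family == "attractor":
        kw["thresholds"] = [values[f"b{k}"] for k in range(1, n_sched + 1)]
        kw["urgency_slope"] = values["u"]
    else:
        kw["thresholds"] = [values[f"B{k}"] for k in range(1, n_sched + 1)]
    if family == "variant_drift":
        kw["drift_sd"] = values["sigma_A"]
    if family in ("leak", "leak_urgency"):
        kw["leak_tau"] = values["tau"]
    if family == "collapsing":
        kw["collapse_tau"] = [values[f"lam{k}"] for k in range(1, n_sched + 1)]
    if family in ("urgency", "leak_urgency"):
        kw["urgency_slope"] = 1.0  # B_k absorbs the scale
    return ModelSpec(**kw)


class ChoiceRTModel:
    """Maximum-likelihood fit of one model family to a SummaryTable."""

    def __init__(
        self,
        observed: pd.DataFrame,
        family: str,
        schedules: Sequence[ScheduleSpec],
        bin_edges: Mapping[int, np.ndarray],
        dt: float = 0.005,
        n_x: int = 121,
        gh_nodes: int = 7,
    ):
        if family not in FAMILIES:
            raise ValueError(f"unknown family {family!r}")
        levels = {s.level for s in schedules}
        if set(observed.schedule.unique()) != levels:
            raise ValueError("observed table must cover every schedule")
        self.observed = observed
        self.family = family
        self.schedules = list(schedules)
        self.bin_edges = dict(bin_edges)
        self.dt = dt
        self.n_x = n_x
        self.gh_nodes = gh_nodes
        self.layout = _param_layout(family, len(self.schedules))
        # array cache for the optimizer-facing likelihood
        self._obs_cache = {}
        for sched in self.schedules:
            sub = observed.loc[
                observed.schedule == sched.level
            ].sort_values("bin")
            n = sub.n.to_numpy(float)
            p = sub.p_correct.to_numpy(float)
            sd = np.maximum(sub.sd_rt.to_numpy(float), 1e-3)
            self._obs_cache[sched.level] = dict(
                p=p, m=sub.mean_rt.to_numpy(float), s=sd, n=n,
                var_p=np.maximum(p * (1 - p), 1e-3) / n,
                var_m=sd * sd / n, var_s=sd * sd / (2 * n),
                edges=np.asarray(self.bin_edges[sched.level], float),
            )

    @property
    def k_params(self) -> int:
        return len(self.layout)

    def _unpack(self, theta: np.ndarray) -> dict[str, float]:
        return {
            name: float(np.exp(t))
            for (name, _), t in zip(self.layout, theta)
        }

    def spec(self, theta: np.ndarray) -> ModelSpec:
        return _spec_from_values(
            self.family, self._unpack(theta), len(self.schedules), self.dt
        )

    def predict(self, theta: np.ndarray) -> pd.DataFrame:
        spec = self.spec(theta)
        frames = []
        for sched in self.schedules:
            fp = fp_propagate(spec, sched, n_x=self.n_x, dt=self.dt,
                              gh_nodes=self.gh_nodes)
            frames.append(
                predict_summaries(fp, sched, self.bin_edges[sched.level])
            )
        return pd.concat(frames, ignore_index=True)

    def loglike(self, theta: np.ndarray) -> float:
        """Optimizer-facing likelihood: identical quantities to
        ``summary_loglik`` of ``predict``, computed without the frame
        plumbing, with predicted-empty bins charged EMPTY_BIN_PENALTY."""
        try:
            spec = self.spec(theta)
        except ValueError:
            return -1e9
        ll = 0.0
        _log2pi = np.log(2 * np.pi)
        for sched in self.schedules:
            try:
                fp = fp_propagate(spec, sched, n_x=self.n_x, dt=self.dt,
                                  gh_nodes=self.gh_nodes)
            except (RuntimeError, ValueError):
                return -1e9
            o = self._obs_cache[sched.level]
            edges = o["edges"]
            n_bins = len(edges) - 1
            idx = np.clip(np.searchsorted(edges, fp.t, side="right") - 1,
                          0, n_bins - 1)
            w = fp.flux_up + fp.flux_lo
            mass = np.bincount(idx, weights=w, minlength=n_bins)
            up = np.bincount(idx, weights=fp.flux_up, minlength=n_bins)
            wt = np.bincount(idx, weights=w * fp.t, minlength=n_bins)
            wt2 = np.bincount(idx, weights=w * fp.t ** 2, minlength=n_bins)
            for b in range(n_bins):
                if mass[b] < 1e-12:
                    ll += EMPTY_BIN_PENALTY
                    continue
                p_hat = up[b] / mass[b]
                m_hat = wt[b] / mass[b]
                v_hat = max(wt2[b] / mass[b] - m_hat * m_hat, 0.0)
                s_hat = np.sqrt(v_hat)
                ll -= 0.5 * ((o["p"][b] - p_hat) ** 2 / o["var_p"][b]
                             + np.log(o["var_p"][b]) + _log2pi)
                ll -= 0.5 * ((o["m"][b] - m_hat) ** 2 / o["var_m"][b]
                             + np.log(o["var_m"][b]) + _log2pi)
                ll -= 0.5 * ((o["s"][b] - s_hat) ** 2 / o["var_s"][b]
                             + np.log(o["var_s"][b]) + _log2pi)
        return float(ll)

    # ---- deterministic data-driven starts -----------------------------
    def _moment_guesses(self) -> tuple[float, dict[int, float], dict[int, float]]:
        """Crude per-schedule (A, B) from basic-DDM closed-form moments."""
        A_list, B_by, m_by = [], {}, {}
        for sched in self.schedules:
            sub = self.observed[self.observed.schedule == sched.level]
            n = sub.n.sum()
            p = float(np.clip((sub.p_correct * sub.n).sum() / n, 0.55, 0.97))
            m = float((sub.mean_rt * sub.n).sum() / n)
            theta = 0.5 * np.log(p / (1 - p))  # = A*B at c=1
            B = float(np.sqrt(theta * m / np.tanh(theta)))
            B_by[sched.level] = np.clip(B, *_BOUNDS["B"])
            m_by[sched.level] = m
            A_list.append(theta / max(B, 1e-6))
        A0 = float(np.clip(np.median(A_list), *_BOUNDS["A"]))
        return A0, B_by, m_by

    def starts(self) -> list[np.ndarray]:
        A0, B_by, m_by = self._moment_guesses()
        fam = self.family
        vecs = []
        for a_scale in (0.4, 0.7, 1.0, 2.0):
            for b_scale in (0.7, 1.0, 1.4):
                for aux in (0.0, 1.0):
                    values: dict[str, float] = {"A": A0 * a_scale}
                    for i, sched in enumerate(self.schedules, start=1):
                        B = B_by[sched.level] * b_scale
                        if fam in ("urgency", "leak_urgency"):
                            # bound B/(u t) ~ basic B at the mean RT
                            B = B * m_by[sched.level]
                        if fam == "attractor":
                            values[f"b{i}"] = (2.0 + 4.0 * aux) * b_scale
                        else:
                            values[f"B{i}"] = B
                        if fam == "collapsing":
                            values[f"lam{i}"] = 0.4 + 1.2 * aux
                    if fam == "variant_drift":
                        values["sigma_A"] = (0.3 + 0.9 * aux) * max(A0, 0.3)
                    if fam in ("leak", "leak_urgency"):
                        values["tau"] = 0.25 + 0.75 * aux
                    if fam == "attractor":
                        values["u"] = 0.5 + 1.5 * aux
                    vec = np.array([
                        np.log(np.clip(values[name], lo + 1e-9, hi - 1e-9))
                        for name, (lo, hi) in self.layout
                    ])
                    vecs.append(vec)
        # drop duplicates (aux unused by some families), preserve order
        uniq, seen = [], set()
        for v in vecs:
            key = tuple(np.round(v, 10))
            if key not in seen:
                seen.add(key)
                uniq.append(v)
        return uniq

    def fit(self, n_polish: int = 2, maxfun: int = 400) -> "ChoiceRTResults":
        starts = self.starts()
        scored = sorted(
            ((self.loglike(v), tuple(v), v) for v in starts),
            key=lambda s: (-s[0], s[1]),
        )
        if all(not np.isfinite(s[0]) or s[0] <= -1e9 for s in scored):
            raise RuntimeError("all multi-starts failed to evaluate")
        log_bounds = [
            (np.log(lo), np.log(hi)) for _, (lo, hi) in self.layout
        ]
        best = None
        any_success = False
        for _, _, v in scored[:n_polish]:
            res = minimize(
                lambda th: -self.loglike(th), v, method="L-BFGS-B",
                bounds=log_bounds,
                options={"maxfun": maxfun, "ftol": 1e-10, "gtol": 1e-7},
            )
            any_success = any_success or res.success
            cand = (-res.fun, tuple(res.x), res)
            if best is None or cand[0] > best[0] or (
                cand[0] == best[0] and cand[1] < best[1]
            ):
                best = cand
        llf, _, res = best
        values = self._unpack(res.x)
        k = self.k_params
        return ChoiceRTResults(
            model=self, family=self.family, params=values,
            theta=np.asarray(res.x), llf=float(llf), k=k,
            aic=2.0 * k - 2.0 * float(llf), converged=bool(any_success),
        )


@dataclass
class ChoiceRTResults:
    model: ChoiceRTModel
    family: str
    params: dict[str, float]
    theta: np.ndarray
    llf: float
    k: int
    aic: float
    converged: bool

    @property
    def spec(self) -> ModelSpec:
        return self.model.spec(self.theta)

    def predicted(self) -> pd.DataFrame:
        return self.model.predict(self.theta)

    def summary(self) -> str:
        lines = [
            f"{self.family} fit to choice/RT summaries",
            f"  k = {self.k}   logL = {self.llf:.3f}   AIC = {self.aic:.3f}"
            f"   converged: {self.converged}",
        ]
        for name, value in self.params.items():
            lines.append(f"  {name:>8s} = {value:.4f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return dict(family=self.family, params=self.params, logL=self.llf,
                    k=self.k, AIC=self.aic, converged=self.converged)


def fit_model(
    family: str,
    observed: pd.DataFrame,
    schedules: Sequence[ScheduleSpec],
    bin_edges: Mapping[int, np.ndarray],
    **kwargs,
) -> ChoiceRTResults:
    fit_kwargs = {
        k: kwargs.pop(k) for k in ("n_polish", "maxfun") if k in kwargs
    }
    return ChoiceRTModel(
        observed, family, schedules, bin_edges, **kwargs
    ).fit(**fit_kwargs)


def compare_models(results: Sequence[ChoiceRTResults]) -> pd.DataFrame:
    """Ranking table, ascending AIC."""
    df = pd.DataFrame(
        [dict(family=r.family, k=r.k, logL=r.llf, AIC=r.aic) for r in results]
    ).sort_values("AIC", kind="stable", ignore_index=True)
    df["delta_AIC"] = df.AIC - df.AIC.iloc[0]
    return df
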