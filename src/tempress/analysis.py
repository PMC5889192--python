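"""Behavioral statistics for time-pressure sessions.

Covers the standard analyses for this task family: accuracy as the
deadline approaches (five RT bins per schedule with a slope test),
RT-matching of adjacent schedules so accuracy can be compared at fixed
integration time, psychophysical kernels (logistic regression of choice
on time-binned stimulus evidence counting back from the response), and
conditional RT contrasts (correct vs error, sequential effects) with
exact sign tests and Cohen's d.

"Normalized RT" throughout is RT divided by the trial's available time
(the hard deadline, or the reward-zero time), which puts schedules on a
common scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats


# ---------------------------------------------------------------------------
# deadline-proximity performance


@dataclass
class ProximityResult:
    level: int
    bin_centers: np.ndarray
    accuracy: np.ndarray
    n_trials: np.ndarray
    slope: float
    p_value: float
    dropped_bins: int = 0


def proximity_performance(
    records: pd.DataFrame, level: int, n_bins: int = 5
) -> ProximityResult:
    """Accuracy in equal-width RT bins over [0, deadline] for one schedule,
    with the OLS slope of accuracy on bin-center RT and its two-sided
    t-test.  Empty bins are dropped (counted in ``dropped_bins``)."""
    sub = records[
        (records.level == level) & (records.choice != "none")
        & records.rt.notna()
    ]
    if len(sub) < n_bins:
        raise ValueError(f"schedule {level}: need at least {n_bins} trials")
    deadline = float(sub.deadline.iloc[0])
    edges = np.linspace(0.0, deadline, n_bins + 1)
    rt = sub.rt.to_numpy(float)
    correct = sub.correct.to_numpy(bool)
    idx = np.clip(np.digitize(rt, edges) - 1, 0, n_bins - 1)

    centers, acc, ns = [], [], []
    for b in range(n_bins):
        m = idx == b
        if not m.any():
            continue
        centers.append(0.5 * (edges[b] + edges[b + 1]))
        acc.append(correct[m].mean())
        ns.append(int(m.sum()))
    centers, acc, ns = map(np.asarray, (centers, acc, ns))
    if len(centers) < n_bins:
        import warnings

        warnings.warn(
            f"schedule {level}: {n_bins - len(centers)} empty RT bin(s) "
            "dropped", stacklevel=2,
        )
    if len(centers) >= 3 and np.ptp(acc) > 0:
        reg = stats.linregress(centers, acc)
        slope, p = float(reg.slope), float(reg.pvalue)
    elif len(centers) >= 2 and np.ptp(acc) == 0:
        slope, p = 0.0, 1.0
    else:
        slope, p = np.nan, np.nan
    return ProximityResult(
        level=level, bin_centers=centers, accuracy=acc, n_trials=ns,
        slope=slope, p_value=p, dropped_bins=n_bins - len(centers),
    )


# ---------------------------------------------------------------------------
# RT matching


@dataclass
class MatchedPair:
    idx_fast: np.ndarray
    idx_slow: np.ndarray
    gap: float
    acc_fast: float
    acc_slow: float
    n_fast: int
    n_slow: int
    flag: Optional[str] = None


def _empty_pair(flag: str) -> MatchedPair:
    e = np.array([], dtype=int)
    return MatchedPair(e, e, np.nan, np.nan, np.nan, 0, 0, flag=flag)


def rt_match(records_fast: pd.DataFrame, records_slow: pd.DataFrame) -> MatchedPair:
    """Trim two adjacent-schedule trial sets to (nearly) equal mean RT.

    First keep only the overlap — fast trials with RT >= min(slow RT),
    slow trials with RT <= max(fast RT) — then greedily remove the
    largest-RT trial from the slow set and the smallest-RT trial from the
    fast set, alternating, as long as a removal strictly shrinks the
    absolute mean-RT gap.  Stops when neither side's removal improves.
    """
    fast = records_fast[(records_fast.choice != "none")
                        & records_fast.rt.notna()]
    slow = records_slow[(records_slow.choice != "none")
                        & records_slow.rt.notna()]
    if fast.empty or slow.empty:
        return _empty_pair("empty input")
    rt_f = fast.rt.to_numpy(float)
    rt_s = slow.rt.to_numpy(float)
    keep_f = np.where(rt_f >= rt_s.min() - 1e-12)[0]
    keep_s = np.where(rt_s <= rt_f.max() + 1e-12)[0]
    if keep_f.size == 0 or keep_s.size == 0:
        return _empty_pair("no RT overlap")

    # sorted index lists; fast drops from the front, slow from the back
    order_f = keep_f[np.argsort(rt_f[keep_f], kind="stable")]
    order_s = keep_s[np.argsort(rt_s[keep_s], kind="stable")]
    lo_f, hi_s = 0, len(order_s)
    sum_f = float(rt_f[order_f].sum())
    sum_s = float(rt_s[order_s].sum())
    n_f, n_s = len(order_f), len(order_s)

    def gap(sf, nf, ss, ns):
        return abs(ss / ns - sf / nf)

    current = gap(sum_f, n_f, sum_s, n_s)
    turn_slow = True  # start by trimming the slow set
    while True:
        improved = False
        for attempt in range(2):
            trim_slow = turn_slow if attempt == 0 else not turn_slow
            if trim_slow and n_s > 1:
                cand = gap(sum_f, n_f, sum_s - rt_s[order_s[hi_s - 1]], n_s - 1)
                if cand < current - 1e-15:
                    hi_s -= 1
                    sum_s -= rt_s[order_s[hi_s]]
                    n_s -= 1
                    current = cand
                    improved = True
                    turn_slow = False
                    break
            elif not trim_slow and n_f > 1:
                cand = gap(sum_f - rt_f[order_f[lo_f]], n_f - 1, sum_s, n_s)
                if cand < current - 1e-15:
                    sum_f -= rt_f[order_f[lo_f]]
                    lo_f += 1
                    n_f -= 1
                    current = cand
                    improved = True
                    turn_slow = True
                    break
        if not improved:
            break

    sel_f = order_f[lo_f:]
    sel_s = order_s[:hi_s]
    acc_f = float(fast.correct.to_numpy(bool)[sel_f].mean())
    acc_s = float(slow.correct.to_numpy(bool)[sel_s].mean())
    return MatchedPair(
        idx_fast=sel_f, idx_slow=sel_s, gap=current,
        acc_fast=acc_f, acc_slow=acc_s, n_fast=int(n_f), n_slow=int(n_s),
    )


# ---------------------------------------------------------------------------
# psychophysical kernel


@dataclass
class KernelWeights:
    level: int
    bin_width: float
    weights: np.ndarray           # raw logistic coefficients, recent first
    normalized: np.ndarray        # divided by max |weight|
    n_trials: int
    flag: Optional[str] = None

    @property
    def lags(self) -> np.ndarray:
        """Lag-bin centers (s before the response)."""
        return (np.arange(len(self.weights)) + 0.5) * self.bin_width


def evidence_kernel(
    records: pd.DataFrame,
    dots: np.ndarray,
    level: int,
    bin_width: float = 0.200,
    sample_interval: float = 0.050,
    ridge: float = 1e-3,
) -> KernelWeights:
    """Logistic regression of choice (red = 1) on the proportion of red
    dots whose onsets fall in successive ``bin_width`` windows counting
    back from the response.

    ``dots[i, j]`` is True if dot j (onset j * sample_interval) of trial i
    was red; rows align with ``records``.  Lag windows that precede trial
    onset are coded at the neutral proportion.  The weight count is
    floor(max RT / bin_width); weights are also returned normalized to a
    maximum absolute value of 1.  On separation or non-convergence the
    fit falls back to an L2-penalized one and is flagged.
    """
    import statsmodels.api as sm

    sub = records[(records.level == level) & (records.choice != "none")
                  & records.rt.notna()]
    if sub.empty:
        raise ValueError("no responded trials for this schedule")
    rows = sub.index.to_numpy()
    rt = sub.rt.to_numpy(float)
    y = (sub.choice.to_numpy() == "red").astype(float)
    n_lags = int(np.floor(rt.max() / bin_width + 1e-9))
    per_bin = int(round(bin_width / sample_interval))

    X = np.zeros((len(sub), n_lags))
    for i, (row, t_resp) in enumerate(zip(rows, rt)):
        onsets_shown = int(np.floor(t_resp / sample_interval + 1e-9)) + 1
        trial_dots = dots[row, :onsets_shown].astype(float)
        for j in range(n_lags):
            hi = t_resp - j * bin_width
            lo = hi - bin_width
            a = max(int(np.ceil(lo / sample_interval - 1e-9)), 0)
            b = int(np.floor(hi / sample_interval + 1e-9)) + 1
            b = min(b, onsets_shown)
            if b > a:
                X[i, j] = trial_dots[a:b].mean() - 0.5
            # windows before trial onset stay at the neutral 0

    X_design = sm.add_constant(X, has_constant="add")
    flag = None
    try:
        fit = sm.Logit(y, X_design).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", False):
            raise RuntimeError("no convergence")
        coefs = fit.params[1:]
    except Exception:
        fit = sm.Logit(y, X_design).fit_regularized(
            alpha=ridge, L1_wt=0.0, disp=0, maxiter=500
        )
        coefs = np.asarray(fit.params)[1:]
        flag = f"ridge fallback (alpha={ridge})"

    coefs = np.asarray(coefs, float)
    denom = np.max(np.abs(coefs))
    normalized = coefs / denom if denom > 0 else coefs.copy()
    return KernelWeights(
        level=level, bin_width=bin_width, weights=coefs,
        normalized=normalized, n_trials=len(sub), flag=flag,
    )


def kernel_decay_constant(kernel: KernelWeights, lag_min: float = 2.0):
    """Exponential time constant of the kernel tail (lags beyond the dot
    persistence, where a leaky integrator's weights decay as exp(-lag/tau)).
    Fitted by least squares on log-weights of positive-weight bins."""
    lags = kernel.lags
    w = kernel.weights
    m = (lags >= lag_min) & (w > 0)
    if m.sum() < 2:
        return np.nan
    slope = stats.linregress(lags[m], np.log(w[m])).slope
    if slope >= 0:
        return np.inf
    return float(-1.0 / slope)


# ---------------------------------------------------------------------------
# conditional RT contrasts


@dataclass
class ConditionalRTResult:
    condition: str
    per_subject: pd.DataFrame      # one row per subject: mean difference
    difference: float              # across-subject mean difference
    p_value: Optional[float]      # exact two-sided sign test (>=2 subjects)
    cohens_d: Optional[float]
    flag: Optional[str] = None


def _normalized_rt(df: pd.DataFrame, normalization: str) -> np.ndarray:
    rt = df.rt.to_numpy(float)
    if normalization == "available_time":
        return rt / df.deadline.to_numpy(float)
    if normalization == "none":
        return rt
    raise ValueError("normalization must be 'available_time' or 'none'")


def sign_test(n_positive: int, n_total: int) -> float:
    """Exact two-sided sign test p-value."""
    return float(stats.binomtest(n_positive, n_total, 0.5,
                                 alternative="two-sided").pvalue)


def conditional_rt_stats(
    records: pd.DataFrame,
    condition: str = "correct_vs_error",
    normalization: str = "available_time",
) -> ConditionalRTResult:
    """Per-subject RT differences between two trial conditions, with an
    exact two-sided sign test across subjects and Cohen's d.

    condition:
      * ``correct_vs_error`` — mean normalized RT, correct minus error
      * ``prev_outcome``     — median RT after a correct minus after an
        incorrect previous trial
      * ``prev_schedule``    — median RT after a slower-than-median minus
        after a faster previous schedule
    """
    valid = records[(records.choice != "none") & records.rt.notna()].copy()
    if valid.empty:
        raise ValueError("no responded trials")
    valid["nrt"] = _normalized_rt(valid, normalization)

    if "subject_id" not in valid.columns:
        valid["subject_id"] = "s0"
    diffs = []
    for subject, df in valid.groupby("subject_id"):
        if condition == "correct_vs_error":
            a = df.loc[df.correct.astype(bool), "nrt"]
            b = df.loc[~df.correct.astype(bool), "nrt"]
            if len(a) < 2 or len(b) < 2:
                continue
            diffs.append((subject, a.mean() - b.mean()))
        elif condition in ("prev_outcome", "prev_schedule"):
            df = df.sort_values(["block_index", "trial_index"]) \
                if {"block_index", "trial_index"} <= set(df.columns) else df
            prev = df.shift(1)
            same_block = (
                prev.block_index == df.block_index
                if "block_index" in df.columns else pd.Series(True, df.index)
            )
            ok = prev.rt.notna() & same_block
            if condition == "prev_outcome":
                grp_a = df.loc[ok & prev.correct.astype("boolean").fillna(False).astype(bool), "nrt"]
                grp_b = df.loc[ok & ~prev.correct.astype("boolean").fillna(True).astype(bool), "nrt"]
            else:
                mid = df.level.median()
                grp_a = df.loc[ok & (prev.level > mid), "nrt"]
                grp_b = df.loc[ok & (prev.level <= mid), "nrt"]
            if len(grp_a) < 2 or len(grp_b) < 2:
                continue
            diffs.append((subject, grp_a.median() - grp_b.median()))
        else:
            raise ValueError(f"unknown condition {condition!r}")

    per_subject = pd.DataFrame(diffs, columns=["subject_id", "difference"])
    if per_subject.empty:
        raise ValueError("not enough trials per cell in any subject")
    d_all = per_subject.difference.to_numpy(float)
    mean_diff = float(d_all.mean())
    if len(d_all) >= 2:
        nonzero = d_all[d_all != 0]
        p = sign_test(int((nonzero > 0).sum()), len(nonzero)) \
            if len(nonzero) else 1.0
        sd = d_all.std(ddof=1)
        d = float(mean_diff / sd) if sd > 0 else None
        flag = None
    else:
        p, d = None, None
        flag = "single subject: sign test skipped"
    return ConditionalRTResult(
        condition=condition, per_subject=per_subject,
        difference=mean_diff, p_value=p, cohens_d=d, flag=flag,
    )
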