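"""Behavioral statistics: proximity bins, RT matching, kernels, RT contrasts."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import comb

from tempress import (
    ModelSpec,
    ScheduleSpec,
    conditional_rt_stats,
    evidence_kernel,
    kernel_decay_constant,
    proximity_performance,
    rt_match,
)
from tempress.analysis import sign_test
from tempress.models import simulate_stimulus_batch

SCHED6 = ScheduleSpec("exp1", 6, 4.2)


def records_frame(rt, correct, level=3):
    rt = np.asarray(rt, float)
    return pd.DataFrame(dict(
        level=level, deadline=0.7 * level, rt=rt,
        correct=np.asarray(correct, bool),
        choice=np.where(np.isnan(rt), "none", "red"),
    ))


class TestProximity:
    def test_constant_accuracy_gives_flat_slope(self):
        rng = np.random.default_rng(0)
        edges = np.linspace(0, 2.1, 6)
        rt, correct = [], []
        for b in range(5):  # 200 trials per bin, exactly 150 correct
            rt.append(rng.uniform(edges[b] + 1e-3, edges[b + 1] - 1e-3, 200))
            correct.append(np.arange(200) < 150)
        res = proximity_performance(
            records_frame(np.concatenate(rt), np.concatenate(correct)), 3
        )
        assert res.slope == pytest.approx(0.0, abs=1e-12)
        assert res.p_value > 0.99

    def test_planted_decline_is_detected(self):
        rng = np.random.default_rng(1)
        n = 1000
        rt = rng.uniform(0.05, 2.05, n)
        p = 0.95 - 0.25 * rt / 2.1  # linear decline in accuracy
        correct = rng.random(n) < p
        res = proximity_performance(records_frame(rt, correct), 3)
        assert res.slope < 0
        assert res.p_value < 0.05

    def test_bin_membership_matches_recount(self):
        rng = np.random.default_rng(2)
        rt = rng.uniform(0.0, 2.1, 500)
        correct = rng.random(500) < 0.8
        res = proximity_performance(records_frame(rt, correct), 3)
        edges = np.linspace(0, 2.1, 6)
        for b, (acc, n) in enumerate(zip(res.accuracy, res.n_trials)):
            sel = (rt >= edges[b]) & (rt < edges[b + 1])
            assert n == sel.sum()
            assert acc == pytest.approx(correct[sel].mean())

    def test_too_few_trials_rejected(self):
        with pytest.raises(ValueError):
            proximity_performance(records_frame([0.5], [True]), 3)


class TestRTMatch:
    def test_identical_multisets_need_no_removal(self):
        rts = [0.3, 0.5, 0.9, 1.2]
        a = records_frame(rts, [True] * 4, level=2)
        b = records_frame(rts, [False] * 4, level=3)
        pair = rt_match(a, b)
        assert pair.gap == pytest.approx(0.0)
        assert pair.n_fast == 4 and pair.n_slow == 4

    def test_hand_traceable_toy_case(self):
        fast = records_frame([0.5, 0.6], [True, False], level=1)
        slow = records_frame([0.6, 0.9], [True, True], level=2)
        pair = rt_match(fast, slow)
        # overlap filter keeps {0.6} and {0.6}: gap is exactly zero
        assert pair.n_fast == 1 and pair.n_slow == 1
        assert pair.gap == pytest.approx(0.0)

    def test_no_overlap_is_flagged(self):
        fast = records_frame([0.1, 0.2], [True, True], level=1)
        slow = records_frame([0.9, 1.0], [True, True], level=2)
        assert rt_match(fast, slow).flag == "no RT overlap"

    def test_greedy_near_exhaustive_optimum(self):
        # the reachable configurations are prefix-removals from either
        # end; enumerate them all on small instances
        rng = np.random.default_rng(3)
        for trial in range(10):
            nf, ns = rng.integers(4, 9), rng.integers(4, 9)
            f = np.sort(rng.uniform(0.2, 1.2, nf))
            s = np.sort(rng.uniform(0.5, 1.8, ns))
            f = f[f >= s.min()]
            s = s[s <= f.max()] if len(f) else s
            if len(f) == 0 or len(s) == 0:
                continue
            best = min(
                abs(s[: len(s) - j].mean() - f[i:].mean())
                for i in range(len(f))
                for j in range(len(s))
            )
            pair = rt_match(
                records_frame(f, [True] * len(f), 1),
                records_frame(s, [True] * len(s), 2),
            )
            assert pair.gap <= best * 1.1 + 1e-9

    def test_accepted_steps_never_increase_gap(self):
        rng = np.random.default_rng(4)
        f = rng.uniform(0.2, 1.0, 200)
        s = rng.uniform(0.4, 1.6, 200)
        pair = rt_match(
            records_frame(f, rng.random(200) < 0.8, 1),
            records_frame(s, rng.random(200) < 0.9, 2),
        )
        raw_gap = abs(f[f >= s.min()].mean() - s[s <= f.max()].mean())
        assert pair.gap <= raw_gap + 1e-12


class TestKernel:
    def test_stimulus_independent_choices_give_null_weights(self):
        rng = np.random.default_rng(5)
        n = 4000
        dots = rng.random((n, 85)) < 0.57
        rec = pd.DataFrame(dict(
            level=6, deadline=4.2,
            choice=np.where(rng.random(n) < 0.5, "red", "green"),
            correct=True, rt=np.full(n, 4.2),
        ))
        k = evidence_kernel(rec, dots, 6)
        assert np.max(np.abs(k.weights)) < 0.5
        assert not np.any(np.abs(k.weights) / max(np.abs(k.weights).max(),
                                                  1e-9) > 1.0 + 1e-9)

    def test_perfect_integrator_kernel_is_flat_in_the_tail(self):
        m = ModelSpec("basic", noise=0.25, thresholds=50.0,
                      stimulus_gain=8.0, deadline_commit=True,
                      evidence_normalization="fixed")
        rec, dots = simulate_stimulus_batch(m, SCHED6, 10_000, seed=6)
        k = evidence_kernel(rec, dots, 6)
        tail = k.normalized[k.lags >= 2.0]
        assert tail.std() / tail.mean() < 0.2

    def test_leak_kernel_decays_with_the_integration_constant(self):
        tau = 0.5
        m = ModelSpec("leak", noise=0.25, leak_tau=tau, thresholds=50.0,
                      stimulus_gain=8.0, deadline_commit=True,
                      evidence_normalization="fixed")
        rec, dots = simulate_stimulus_batch(m, SCHED6, 10_000, seed=7)
        k = evidence_kernel(rec, dots, 6)
        fitted = kernel_decay_constant(k, lag_min=2.0)
        assert fitted == pytest.approx(tau, rel=0.25)

    def test_normalization_has_unit_maximum(self):
        m = ModelSpec("basic", noise=0.25, thresholds=50.0,
                      stimulus_gain=8.0, deadline_commit=True,
                      evidence_normalization="fixed")
        rec, dots = simulate_stimulus_batch(m, SCHED6, 2000, seed=8)
        k = evidence_kernel(rec, dots, 6)
        assert np.max(np.abs(k.normalized)) == pytest.approx(1.0)


class TestPooledPsychometric:
    def test_leak_accuracy_plateaus_in_late_bins(self):
        from tempress import ScheduleSpec, simulate_trials
        from tempress.sat import bin_pooled

        m = ModelSpec("leak", drift=0.5, noise=0.4, leak_tau=0.3,
                      thresholds=1.0)
        ch, rt = simulate_trials(m, SCHED6, 100_000, seed=10)
        ok = ch != 0
        rec = pd.DataFrame(dict(
            level=6, deadline=4.2, rt=rt[ok], correct=ch[ok] == 1,
            choice="x",
        ))
        pooled = bin_pooled(rec, n_bins=10).sort_index()
        acc = pooled.n_correct / pooled.n_trials
        n = pooled.n_trials
        last_two = acc.iloc[-2:].to_numpy()
        se = np.sqrt(0.25 * (1 / n.iloc[-1] + 1 / n.iloc[-2]))
        assert abs(last_two[1] - last_two[0]) < 3 * se

    def test_integrator_accuracy_is_nondecreasing_in_rt(self):
        from tempress import simulate_trials

        # fixed-bound diffusion: accuracy flat/nondecreasing across RT
        m = ModelSpec("basic", drift=1.0, noise=1.0, thresholds=1.0)
        ch, rt = simulate_trials(m, SCHED6, 100_000, seed=11)
        ok = ch != 0
        rec = pd.DataFrame(dict(
            level=6, deadline=4.2, rt=rt[ok], correct=ch[ok] == 1,
            choice="x",
        ))
        from tempress.sat import bin_pooled

        pooled = bin_pooled(rec, n_bins=10).sort_index()
        pooled = pooled[pooled.n_trials >= 200]
        acc = (pooled.n_correct / pooled.n_trials).to_numpy()
        se = np.sqrt(0.25 / pooled.n_trials.to_numpy())
        drops = acc[1:] - acc[:-1]
        assert np.all(drops > -3 * np.sqrt(se[1:] ** 2 + se[:-1] ** 2))


class TestConditionalRT:
    def test_exact_sign_test_matches_binomial_enumeration(self):
        # 15 of 19 subjects positive: exact two-sided binomial value
        p = sign_test(15, 19)
        tail = sum(comb(19, k) for k in range(15, 20)) / 2**19
        assert p == pytest.approx(min(1.0, 2 * tail), rel=1e-9)

    def test_symmetric_conditions_are_null(self, multi_subject_records):
        res = conditional_rt_stats(multi_subject_records,
                                   condition="correct_vs_error")
        assert abs(res.difference) < 0.02
        assert res.p_value > 0.05

    def test_planted_post_error_slowing_is_detected(self):
        # +50 ms after correct trials, 20 subjects; detect in >= 90% of
        # replicates
        detected = 0
        for rep in range(10):
            rng = np.random.default_rng(100 + rep)
            frames = []
            for subj in range(20):
                n = 150
                correct = rng.random(n) < 0.7
                rt = rng.normal(0.9, 0.15, n)
                prev_correct = np.roll(correct, 1)
                rt[prev_correct] += 0.05
                rt[0] = 0.9
                frames.append(pd.DataFrame(dict(
                    subject_id=f"s{subj}", block_index=0,
                    trial_index=np.arange(n), level=3, deadline=2.1,
                    choice="red", correct=correct, rt=np.clip(rt, 0.05, 2.0),
                )))
            res = conditional_rt_stats(pd.concat(frames, ignore_index=True),
                                       condition="prev_outcome",
                                       normalization="none")
            if res.p_value < 0.05 and res.difference > 0:
                detected += 1
        assert detected >= 9

    def test_single_subject_skips_sign_test(self):
        rng = np.random.default_rng(9)
        n = 100
        rec = pd.DataFrame(dict(
            subject_id="only", level=3, deadline=2.1, choice="red",
            correct=rng.random(n) < 0.7, rt=rng.uniform(0.2, 2.0, n),
            block_index=0, trial_index=np.arange(n),
        ))
        res = conditional_rt_stats(rec)
        assert res.p_value is None
        assert res.flag is not None

    def test_prev_schedule_contrast_runs(self, multi_subject_records):
        res = conditional_rt_stats(multi_subject_records,
                                   condition="prev_schedule")
        assert res.p_value is not None
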