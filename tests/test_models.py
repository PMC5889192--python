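"""Trial-level simulation of the seven decision models."""

import numpy as np
import pytest

from tempress import (
    ModelSpec,
    ScheduleSpec,
    drift_from_stimulus,
    generate_stimulus,
    simulate_trial,
    simulate_trials,
)
from tempress.models import (
    attractor_geometry,
    simulate_stimulus_batch,
    stimulus_drift_profile,
)

SCHED3 = ScheduleSpec("exp1", 3, 2.1)
SCHED6 = ScheduleSpec("exp1", 6, 4.2)


class TestModelSpec:
    def test_family_specific_requirements(self):
        with pytest.raises(ValueError):
            ModelSpec("variant_drift", drift=1.0)  # no drift_sd
        with pytest.raises(ValueError):
            ModelSpec("collapsing", drift=1.0)     # no collapse_tau
        with pytest.raises(ValueError):
            ModelSpec("leak", drift=1.0)           # no leak_tau
        with pytest.raises(ValueError):
            ModelSpec("urgency", drift=1.0)        # no urgency_slope
        with pytest.raises(ValueError):
            ModelSpec("nonsense")

    def test_dt_must_fit_inside_deadline(self):
        m = ModelSpec("basic", dt=1.0)
        with pytest.raises(ValueError):
            simulate_trial(m, ScheduleSpec("exp1", 1, 0.7), rng=0)

    def test_per_level_thresholds(self):
        m = ModelSpec("basic", thresholds=[0.5, 0.6, 0.7, 0.8, 0.9, 1.0])
        assert m.threshold_for(3) == 0.7
        assert ModelSpec("basic", thresholds=1.2).threshold_for(5) == 1.2

    def test_attractor_potential_must_be_tristable(self):
        with pytest.raises(ValueError, match="tri-stable"):
            ModelSpec("attractor", att_beta=1.0, att_gamma=1.0,
                      urgency_slope=1.0)

    def test_attractor_geometry_ordering(self):
        g = attractor_geometry(2.0, 1.0)
        assert 0 < g["x_barrier"] < g["x_commit"] < g["x_outer"]


class TestStimulusDrift:
    def test_equal_counts_give_zero(self):
        s = generate_stimulus(0.57, 2.1, rng=0)
        s.is_dominant[:] = [i % 2 == 0 for i in range(s.n_samples)]
        # t = 1.0: 21 dots visible, 11 dominant vs 10 other
        assert drift_from_stimulus(s, 1.0, gain=1.0) == pytest.approx(1 / 21)
        s.is_dominant[:20] = [i % 2 == 0 for i in range(20)]
        s.is_dominant[20] = False  # now 10 vs 11
        assert drift_from_stimulus(s, 0.975, gain=1.0) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_zero_gain_kills_drift(self):
        s = generate_stimulus(0.57, 2.1, rng=1)
        for t in (0.0, 0.5, 1.7):
            assert drift_from_stimulus(s, t, gain=0.0) == 0.0

    def test_steady_state_expectation_near_ratio_contrast(self):
        # at 40 visible dots with q = 0.57, E[(n_dom - n_oth)/40] = 0.14
        rng = np.random.default_rng(5)
        vals = []
        for _ in range(3000):
            s = generate_stimulus(0.57, 2.6, rng=rng, dominant_color="red")
            vals.append(drift_from_stimulus(s, 2.5, gain=1.0))
        assert np.mean(vals) == pytest.approx(0.14, abs=0.01)

    def test_profile_matches_pointwise_op(self):
        s = generate_stimulus(0.57, 2.1, rng=2)
        prof = stimulus_drift_profile(s, dt=0.01, n_t=210, gain=1.5)
        for step in (0, 37, 120, 209):
            assert prof[step] == pytest.approx(
                drift_from_stimulus(s, step * 0.01, gain=1.5)
            )


class TestBasicDDM:
    def test_zero_drift_is_unbiased(self):
        m = ModelSpec("basic", drift=0.0, noise=1.0, thresholds=1.0)
        ch, _ = simulate_trials(m, SCHED6, 100_000, seed=21)
        crossed = ch != 0
        p = (ch == 1).sum() / crossed.sum()
        assert p == pytest.approx(0.5, abs=3 * 0.5 / np.sqrt(crossed.sum()))

    def test_matches_wiener_first_passage_moments(self):
        # closed forms for the two-boundary Wiener process, long horizon
        A, a, c = 1.0, 1.0, 1.0
        m = ModelSpec("basic", drift=A, noise=c, thresholds=a, dt=1e-4)
        sched = ScheduleSpec("exp1", 6, 4.2)
        ch, rt = simulate_trials(m, sched, 100_000, seed=22)
        crossed = ch != 0
        assert crossed.mean() > 0.999
        p_up = (ch == 1).sum() / crossed.sum()
        p_true = 1 / (1 + np.exp(-2 * A * a / c**2))
        mdt_true = (a / A) * np.tanh(A * a / c**2)
        assert p_up == pytest.approx(p_true, rel=0.02)
        assert rt[crossed].mean() == pytest.approx(mdt_true, rel=0.02)

    def test_same_seed_is_deterministic(self):
        m = ModelSpec("basic", drift=1.0, noise=1.0, thresholds=1.0)
        a = simulate_trials(m, SCHED3, 500, seed=3)
        b = simulate_trials(m, SCHED3, 500, seed=3)
        assert np.array_equal(a[0], b[0])
        assert np.array_equal(a[1], b[1], equal_nan=True)

    def test_rt_bounded_by_deadline(self, reference_models):
        for m in reference_models.values():
            _, rt = simulate_trials(m, SCHED3, 2000, seed=4)
            ok = ~np.isnan(rt)
            assert (rt[ok] <= SCHED3.deadline + 1e-9).all()

    def test_dt_convergence_of_accuracy(self):
        accs = {}
        for dt in (0.001, 0.0005):
            m = ModelSpec("basic", drift=1.0, noise=1.0, thresholds=1.0,
                          dt=dt)
            ch, _ = simulate_trials(m, SCHED3, 100_000, seed=31)
            accs[dt] = (ch == 1).sum() / (ch != 0).sum()
        assert abs(accs[0.001] - accs[0.0005]) < 0.005


class TestLeak:
    def test_late_accuracy_is_stationary(self):
        # once the OU integrator has equilibrated (t >> tau), accuracy no
        # longer improves with decision time
        tau = 0.3
        m = ModelSpec("leak", drift=0.5, noise=0.4, leak_tau=tau,
                      thresholds=1.0)
        ch, rt = simulate_trials(m, SCHED6, 200_000, seed=41)
        crossed = ch != 0
        acc, n = {}, {}
        for k in (4, 8):
            lo, hi = (k - 1) * tau, (k + 1) * tau
            sel = crossed & (rt >= lo) & (rt < hi)
            assert sel.sum() > 1000
            acc[k] = (ch[sel] == 1).mean()
            n[k] = sel.sum()
        mc_err = 3 * np.sqrt(0.25 * (1 / n[4] + 1 / n[8]))
        assert abs(acc[4] - acc[8]) < mc_err


class TestUrgency:
    def test_equivalent_to_collapsing_bound_trial_for_trial(self):
        # y(t) = x(t) * u t crossing B is the same event as x(t) crossing
        # B / (u t); check against an independent pure-python evaluation
        # on shared noise
        from tempress._kernels import sim_path

        rng = np.random.default_rng(8)
        for _ in range(50):
            noise = rng.standard_normal(2100)
            # independent pure-python oracle: multiply x by the urgency
            # signal and read it against the fixed bound B
            x, hit = 0.0, None
            for n in range(2100):
                x += 1.0 * 0.001 + np.sqrt(0.001) * noise[n]
                t = (n + 1) * 0.001
                if abs(x) * 1.3 * t >= 1.0:
                    hit = (np.sign(x), n)
                    break
            # implementation: x against the moving bound B / (u t)
            side, step, _, _ = sim_path(
                noise, np.full(2100, 1.0), 0.001, 0, 2, 1.0, 1.0, 1.0, 1.0,
                1.3, 0.0, 2.0, 1.0, 0.0, 1e12, 0.0, False,
            )
            if hit is None:
                assert side == 0
            else:
                assert side == hit[0] and step == hit[1]


class TestVariantDrift:
    def test_errors_are_slower_than_corrects(self):
        m = ModelSpec("variant_drift", drift=1.0, drift_sd=1.0, noise=1.0,
                      thresholds=1.0)
        ch, rt = simulate_trials(m, SCHED6, 50_000, seed=51)
        rt_correct = rt[ch == 1].mean()
        rt_error = rt[ch == -1].mean()
        assert rt_error > rt_correct + 0.05


class TestAttractor:
    def test_rest_state_is_stable_at_low_noise(self):
        # no urgency/forcing, zero input: the particle stays in the
        # central basin over a deadline horizon in >= 99% of trials
        m = ModelSpec(
            "attractor", drift=0.0, noise=0.2, thresholds=2.0,
            urgency_slope=1e-9, forcing_amp=0.0,
        )
        ch, _ = simulate_trials(m, SCHED6, 5000, seed=61)
        assert (ch == 0).mean() >= 0.99

    def test_forcing_commits_before_deadline(self, reference_models):
        m = reference_models["attractor"]
        ch, rt = simulate_trials(m, SCHED3, 5000, seed=62)
        # the forcing step drives the vast majority of trials to commit
        assert (ch != 0).mean() > 0.5
        assert np.nanmax(rt) <= SCHED3.deadline + 1e-9


class TestStimulusDriven:
    def test_deadline_commit_labels_all_trials(self):
        m = ModelSpec("basic", noise=0.25, thresholds=50.0,
                      stimulus_gain=8.0, deadline_commit=True,
                      evidence_normalization="fixed")
        rec, dots = simulate_stimulus_batch(m, SCHED6, 2000, seed=71)
        assert (rec.choice != "none").all()
        assert rec.correct.mean() > 0.75  # follows the dominant color

    def test_stimulus_coupling_beats_chance_with_bounds(self):
        m = ModelSpec("basic", noise=0.3, thresholds=0.6,
                      stimulus_gain=8.0, evidence_normalization="fixed")
        rec, _ = simulate_stimulus_batch(m, SCHED6, 2000, seed=72)
        responded = rec[rec.choice != "none"]
        assert responded.correct.mean() > 0.6
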