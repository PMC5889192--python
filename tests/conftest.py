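import numpy as np
import pandas as pd
import pytest

from tempress import ModelSpec, make_schedules


@pytest.fixture(scope="session")
def exp1_schedules():
    return make_schedules("exp1")


@pytest.fixture(scope="session")
def reference_models():
    """Reference parameterizations used for cross-model comparisons.

    Chosen to produce plausible behavior under the task's schedules:
    accuracies in the 0.7-0.9 range and response times well inside the
    deadlines (see docs/methods.md).
    """
    return {
        "basic": ModelSpec("basic", drift=1.0, noise=1.0, thresholds=1.0),
        "variant_drift": ModelSpec(
            "variant_drift", drift=1.0, drift_sd=1.0, noise=1.0,
            thresholds=1.0,
        ),
        "collapsing": ModelSpec(
            "collapsing", drift=1.0, noise=1.0, thresholds=1.5,
            collapse_tau=[0.35, 0.70, 1.05, 1.40, 1.75, 2.10],
        ),
        "leak": ModelSpec(
            "leak", drift=1.0, noise=1.0, leak_tau=0.4, thresholds=1.2,
        ),
        "urgency": ModelSpec(
            "urgency", drift=1.0, noise=1.0, thresholds=1.0,
            urgency_slope=1.0,
        ),
        "leak_urgency": ModelSpec(
            "leak_urgency", drift=1.0, noise=1.0, leak_tau=0.4,
            urgency_slope=1.0,
            thresholds=[0.35, 0.45, 0.55, 0.65, 0.75, 0.85],
        ),
        "attractor": ModelSpec(
            "attractor", drift=0.5, noise=0.45, thresholds=2.0,
            urgency_slope=0.5,
        ),
    }


@pytest.fixture()
def multi_subject_records():
    """Twelve simulated subjects with RTs spread over six schedules."""
    rng = np.random.default_rng(99)
    frames = []
    for subj in range(12):
        n = 240
        level = rng.integers(1, 7, n)
        deadline = 0.7 * level
        rt = rng.uniform(0.15, deadline - 0.05)
        frames.append(pd.DataFrame(dict(
            subject_id=f"s{subj}",
            block_index=np.repeat(np.arange(n // 24), 24),
            trial_index=np.tile(np.arange(24), n // 24),
            level=level, deadline=deadline,
            choice=np.where(rng.random(n) < 0.5, "red", "green"),
            correct=rng.random(n) < 0.8,
            rt=rt,
        )))
    return pd.concat(frames, ignore_index=True)
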