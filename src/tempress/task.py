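"""Task synthesis: schedules, dot-stimulus streams, reward functions and
full synthetic sessions.

The experimental design being emulated: an observer watches colored dots
(red/green) appear one at a time at 20 Hz, each dot staying visible for
2.0 s, and must report the dominant color of the underlying urn (dominant
fraction ``q``, typically 0.57).  Time pressure is manipulated either by a
hard response deadline (Experiment 1: six deadlines, 0.7 s to 4.2 s) or by
a reward that decays linearly to zero at one of six rates (Experiment 2),
with Experiment 3 a mathematically equivalent gamble without dots.  A
synthetic "subject" is any of the sequential-sampling decision models in
:mod:`tempress.models`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

EXPERIMENTS = ("exp1", "exp2", "exp3", "pretest")

#: deadline grid for Experiment 1 / pre-test (seconds per level step)
DEADLINE_STEP = 0.7
#: stimulus sampling interval (s): one new dot every 50 ms (20 Hz)
SAMPLE_INTERVAL = 0.050
#: how long each dot stays visible (s)
PERSISTENCE = 2.0
#: dominant-color fraction used in the main experiments (57:43 urn)
DEFAULT_DOT_RATIO = 0.57
#: fixed gain/loss magnitude (points) for exp1/pretest, and the penalty
#: applied when no response is made before the deadline
FIXED_REWARD = 60.0

PRETEST_DEADLINES = (0.7, 2.1, 3.5)
PRETEST_RATIOS = (0.60, 0.57, 0.54)


@dataclass(frozen=True)
class ScheduleSpec:
    """One time-pressure condition.

    For exp1/pretest ``deadline`` is a hard response deadline.  For
    exp2/exp3 ``deadline`` is the time at which the reward reaches zero,
    i.e. ``decay_onset + initial_reward / decay_rate``.
    """

    experiment: str
    level: int
    deadline: float
    initial_reward: Optional[float] = None
    decay_rate: Optional[float] = None
    decay_onset: float = 0.0
    dot_ratio: float = DEFAULT_DOT_RATIO

    def __post_init__(self) -> None:
        if self.experiment not in EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.deadline <= 0:
            raise ValueError("deadline must be positive")
        n_levels = 3 if self.experiment == "pretest" else 6
        if not 1 <= self.level <= n_levels:
            raise ValueError(f"level must be in 1..{n_levels}")
        if self.experiment == "exp1":
            expected = DEADLINE_STEP * self.level
            if abs(self.deadline - expected) > 1e-12:
                raise ValueError(
                    f"exp1 level {self.level} must have deadline {expected}"
                )
        if self.experiment in ("exp2", "exp3"):
            if self.initial_reward is None or self.decay_rate is None:
                raise ValueError("exp2/exp3 schedules need initial_reward and decay_rate")
            if self.initial_reward <= 0 or self.decay_rate <= 0:
                raise ValueError("initial_reward and decay_rate must be positive")
            if self.decay_onset < 0:
                raise ValueError("decay_onset must be nonnegative")

    def with_initial_reward(self, g_s: float) -> "ScheduleSpec":
        """Same decay rate/onset, different initial stake (reward-zero time moves)."""
        if self.experiment not in ("exp2", "exp3"):
            raise ValueError("only exp2/exp3 schedules carry an initial reward")
        return replace(
            self,
            initial_reward=g_s,
            deadline=self.decay_onset + g_s / self.decay_rate,
        )


@dataclass(frozen=True)
class StimulusStream:
    """Per-trial dot sequence: one new dot every ``sample_interval`` seconds,
    starting at t = 0, each visible for ``persistence`` seconds."""

    q: float
    dominant_color: str  # "red" | "green"
    onsets: np.ndarray  # seconds, multiples of sample_interval
    is_dominant: np.ndarray  # bool per dot
    duration: float
    sample_interval: float = SAMPLE_INTERVAL
    persistence: float = PERSISTENCE

    @property
    def n_samples(self) -> int:
        return len(self.onsets)

    @property
    def colors(self) -> np.ndarray:
        """Dot colors as strings, in onset order."""
        other = "green" if self.dominant_color == "red" else "red"
        return np.where(self.is_dominant, self.dominant_color, other)


def make_schedules(
    experiment: str,
    sat=None,
    decay_rates: Optional[Sequence[float]] = None,
    initial_reward: float = 100.0,
    decay_onset: Optional[float] = None,
) -> list[ScheduleSpec]:
    """Build the per-level schedule list for one experiment.

    exp1: six hard deadlines 0.7k s.  pretest: deadlines 0.7/2.1/3.5 s.
    exp2/exp3: six reward-decay rates, either given explicitly or designed
    from a fitted speed-accuracy tradeoff via
    :func:`tempress.optimal.design_decay_rates`.
    """
    if experiment == "exp1":
        return [
            ScheduleSpec("exp1", k, DEADLINE_STEP * k) for k in range(1, 7)
        ]
    if experiment == "pretest":
        return [
            ScheduleSpec("pretest", k, d)
            for k, d in enumerate(PRETEST_DEADLINES, start=1)
        ]
    if experiment in ("exp2", "exp3"):
        if decay_rates is None:
            if sat is None:
                raise ValueError(
                    "exp2/exp3 schedules need decay_rates or a fitted SAT"
                )
            from .optimal import design_decay_rates

            decay_rates = design_decay_rates(sat)
            if decay_onset is None:
                decay_onset = sat.delta
        if len(decay_rates) != 6:
            raise ValueError("exp2/exp3 require exactly 6 decay rates")
        if decay_onset is None:
            decay_onset = sat.delta if sat is not None else 0.0
        # level 1 = fastest decay = greatest time pressure
        rates = sorted(decay_rates, reverse=True)
        return [
            ScheduleSpec(
                experiment,
                k,
                deadline=decay_onset + initial_reward / b,
                initial_reward=initial_reward,
                decay_rate=b,
                decay_onset=decay_onset,
            )
            for k, b in enumerate(rates, start=1)
        ]
    raise ValueError(f"unknown experiment {experiment!r}")


def generate_stimulus(
    q: float,
    duration: float,
    rng: np.random.Generator | int,
    dominant_color: Optional[str] = None,
    sample_interval: float = SAMPLE_INTERVAL,
    persistence: float = PERSISTENCE,
) -> StimulusStream:
    """Draw one dot stream: floor(duration/sample_interval)+1 i.i.d. samples,
    each dominant-colored with probability ``q``."""
    if not 0.5 < q < 1.0:
        raise ValueError("dot ratio q must lie strictly between 0.5 and 1")
    if duration <= 0:
        raise ValueError("duration must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    n = int(np.floor(duration / sample_interval + 1e-9)) + 1
    onsets = np.arange(n) * sample_interval
    is_dominant = rng.random(n) < q
    if dominant_color is None:
        dominant_color = "red" if rng.random() < 0.5 else "green"
    elif dominant_color not in ("red", "green"):
        raise ValueError("dominant_color must be 'red' or 'green'")
    return StimulusStream(
        q=q,
        dominant_color=dominant_color,
        onsets=onsets,
        is_dominant=is_dominant,
        duration=duration,
        sample_interval=sample_interval,
        persistence=persistence,
    )


def visible_counts(stream: StimulusStream, t: float) -> tuple[int, int]:
    """Dots visible at time ``t``: onset <= t < onset + persistence.

    Returns (n_dominant, n_other).  Under the default 20 Hz / 2.0 s design
    the total climbs by one every 50 ms and saturates at 40 from t = 2.0 s.
    """
    if t < 0:
        raise ValueError("t must be nonnegative")
    visible = (stream.onsets <= t + 1e-12) & (t < stream.onsets + stream.persistence - 1e-12)
    n_dom = int(np.count_nonzero(stream.is_dominant & visible))
    n_oth = int(np.count_nonzero(visible)) - n_dom
    return n_dom, n_oth


def reward_at(t: float, correct: bool, schedule: ScheduleSpec) -> float:
    """Signed reward (points) for responding at time ``t``.

    Correct: max(0, G_s - b*(t - t_0)+); incorrect: the mirror-image loss.
    Both gain and loss decay toward zero and stay there.
    """
    if schedule.experiment not in ("exp2", "exp3"):
        raise ValueError("reward_at applies to exp2/exp3 schedules only")
    if t < 0:
        raise ValueError("t must be nonnegative")
    elapsed = max(0.0, t - schedule.decay_onset)
    magnitude = max(0.0, schedule.initial_reward - schedule.decay_rate * elapsed)
    return magnitude if correct else -magnitude


@dataclass(frozen=True)
class SessionDesign:
    """Block/trial layout of one session.

    exp1: 10 blocks x 36 trials, each of 6 deadlines 6x per block.
    exp2/exp3: 10 x 36, each (initial reward in {50,100}) x (6 rates) 3x
    per block.  pretest: 9 blocks x 36 over a 3 (ratio) x 3 (window) grid,
    one ratio per block in the fixed cycle 60:40, 57:43, 54:46.
    """

    experiment: str
    n_blocks: int
    trials_per_block: int
    initial_rewards: tuple[float, ...] = ()

    @classmethod
    def for_experiment(cls, experiment: str) -> "SessionDesign":
        if experiment == "exp1":
            return cls("exp1", 10, 36)
        if experiment in ("exp2", "exp3"):
            return cls(experiment, 10, 36, initial_rewards=(50.0, 100.0))
        if experiment == "pretest":
            return cls("pretest", 9, 36)
        raise ValueError(f"unknown experiment {experiment!r}")

    @property
    def n_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def block_conditions(self, block: int, rng: np.random.Generator):
        """Shuffled (level, initial_reward, dot_ratio) tuples for one block."""
        if self.experiment == "exp1":
            levels = np.repeat(np.arange(1, 7), self.trials_per_block // 6)
            rng.shuffle(levels)
            return [(int(k), None, None) for k in levels]
        if self.experiment in ("exp2", "exp3"):
            combos = [
                (k, g)
                for k in range(1, 7)
                for g in self.initial_rewards
                for _ in range(self.trials_per_block // (6 * len(self.initial_rewards)))
            ]
            idx = rng.permutation(len(combos))
            return [(combos[i][0], combos[i][1], None) for i in idx]
        # pretest: ratio fixed per block (cycling), window random within block
        ratio = PRETEST_RATIOS[block % 3]
        levels = np.repeat(np.arange(1, 4), self.trials_per_block // 3)
        rng.shuffle(levels)
        return [(int(k), None, ratio) for k in levels]


@dataclass
class Session:
    """A simulated session: tidy trial table plus the generating dot streams."""

    records: pd.DataFrame
    streams: dict[int, StimulusStream] = field(default_factory=dict)

    def streams_frame(self) -> pd.DataFrame:
        """Long-format sidecar table (trial_id, onset_s, color)."""
        rows = []
        for trial_id, s in self.streams.items():
            colors = s.colors
            for onset, color in zip(s.onsets, colors):
                rows.append((trial_id, float(onset), color))
        return pd.DataFrame(rows, columns=["trial_id", "onset_s", "color"])


def _trial_rng(seed: int, block: int, trial: int) -> np.random.Generator:
    # keyed substreams: adding analyses never perturbs later trials' draws
    # (trial = 0 keys the block-level shuffle stream)
    return np.random.default_rng(
        np.random.SeedSequence([seed, block, trial])
    )


def simulate_session(
    model,
    design: SessionDesign,
    schedules: Sequence[ScheduleSpec],
    seed: int,
    sat=None,
    subject_id: str = "sim",
    keep_streams: bool = True,
) -> Session:
    """Run a full synthetic session with ``model`` as the subject.

    ``schedules`` holds one ScheduleSpec per level (the exp2/exp3 per-trial
    initial reward is substituted from the design grid).  exp3 requires a
    fitted SAT (win probability at response time t is SAT(t)); its trials
    carry no dot stream.
    """
    from .models import simulate_trial

    by_level = {s.level: s for s in schedules}
    n_levels = 3 if design.experiment == "pretest" else 6
    if set(by_level) != set(range(1, n_levels + 1)):
        raise ValueError("schedules must cover each level exactly once")
    if design.experiment == "exp3" and sat is None:
        raise ValueError("exp3 sessions need a fitted SAT for win probabilities")

    rows = []
    streams: dict[int, StimulusStream] = {}
    trial_id = 0
    for block in range(design.n_blocks):
        block_rng = _trial_rng(seed, block, 0)
        conditions = design.block_conditions(block, block_rng)
        for trial, (level, g_s, ratio) in enumerate(conditions):
            rng = _trial_rng(seed, block, trial + 1)
            schedule = by_level[level]
            if g_s is not None:
                schedule = schedule.with_initial_reward(g_s)
            if ratio is not None:
                schedule = replace(schedule, dot_ratio=ratio)

            stream = None
            if design.experiment != "exp3":
                stream = generate_stimulus(
                    schedule.dot_ratio, schedule.deadline, rng
                )
            outcome = simulate_trial(model, schedule, stream=stream, rng=rng)

            if design.experiment == "exp3":
                if outcome.crossed:
                    choice = "accept"
                    rt = outcome.rt
                    p_win = sat.probability(rt)
                    correct = bool(rng.random() < p_win)
                    reward = reward_at(rt, correct, schedule)
                else:
                    choice, rt, correct = "none", np.nan, None
                    reward = reward_at(schedule.deadline, False, schedule)
            else:
                if outcome.crossed:
                    rt = outcome.rt
                    dom = stream.dominant_color
                    oth = "green" if dom == "red" else "red"
                    choice = dom if outcome.choice == "dominant" else oth
                    correct = outcome.choice == "dominant"
                    if design.experiment == "exp2":
                        reward = reward_at(rt, correct, schedule)
                    else:
                        reward = FIXED_REWARD if correct else -FIXED_REWARD
                else:
                    choice, rt, correct = "none", np.nan, None
                    if design.experiment == "exp2":
                        reward = reward_at(schedule.deadline, False, schedule)
                    else:
                        reward = -FIXED_REWARD

            rows.append(
                dict(
                    subject_id=subject_id,
                    trial_index=trial,
                    block_index=block,
                    experiment=design.experiment,
                    level=level,
                    deadline=schedule.deadline,
                    initial_reward=schedule.initial_reward,
                    decay_rate=schedule.decay_rate,
                    decay_onset=schedule.decay_onset,
                    dot_ratio=schedule.dot_ratio,
                    choice=choice,
                    correct=correct,
                    rt=rt,
                    reward_outcome=reward,
                    stimulus_ref=trial_id if stream is not None else -1,
                )
            )
            if stream is not None and keep_streams:
                streams[trial_id] = stream
            trial_id += 1

    records = pd.DataFrame(rows)
    return Session(records=records, streams=streams)


def write_trials(session: Session, path) -> None:
    session.records.to_csv(path, index=False)


def write_streams(session: Session, path) -> None:
    session.streams_frame().to_csv(path, index=False)
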