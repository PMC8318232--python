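"""Four-armed bandit task: stimuli, schedules and reward generation.

The task presents two of four stimuli on each trial.  The four stimuli pay
integer point rewards drawn from approximately Gaussian distributions in a
2x2 design: mean 60 or 40 points ("high"/"low" value) crossed with standard
deviation 20 or 5 points ("risky"/"safe").  Trials are organised into three
conditions by the value classes of the shown pair: *different* (one high,
one low), *both-high* and *both-low*.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "StimulusSpec",
    "STIMULI",
    "ORDERED_PAIRS",
    "SessionData",
    "build_schedule",
    "classify_condition",
    "sample_reward",
    "sessions_to_frame",
    "frame_to_sessions",
    "write_sessions",
    "read_sessions",
]

REWARD_MIN = 1
REWARD_MAX = 99

CONDITION_DIFFERENT = "different"
CONDITION_BOTH_HIGH = "both-high"
CONDITION_BOTH_LOW = "both-low"

TRIAL_COLUMNS = [
    "participant",
    "block",
    "trial",
    "stim_left",
    "stim_right",
    "condition",
    "choice",
    "reward",
]
#: Columns of a single session's trial table (participant id lives on the
#: SessionData object, not in the table).
SESSION_COLUMNS = TRIAL_COLUMNS[1:]


@dataclass(frozen=True)
class StimulusSpec:
    """Generative description of one bandit arm."""

    stimulus_id: int
    mean: float
    sd: float
    risk_class: str  # "risky" or "safe"
    value_class: str  # "high" or "low"


#: Canonical stimulus set.  Odd ids are risky (sd 20), even ids safe (sd 5);
#: ids 1-2 are high value (mean 60), ids 3-4 low value (mean 40).
STIMULI: dict[int, StimulusSpec] = {
    1: StimulusSpec(1, 60.0, 20.0, "risky", "high"),
    2: StimulusSpec(2, 60.0, 5.0, "safe", "high"),
    3: StimulusSpec(3, 40.0, 20.0, "risky", "low"),
    4: StimulusSpec(4, 40.0, 5.0, "safe", "low"),
}

#: The 12 ordered pairs of distinct stimuli (presentation order matters,
#: e.g. (1, 2) and (2, 1) are scheduled separately).
ORDERED_PAIRS: list[tuple[int, int]] = [
    p for p in itertools.permutations(STIMULI, 2)
]


@dataclass(eq=False)  # identity semantics: trial tables don't compare by ==
class SessionData:
    """All trials of one participant, ordered by (block, trial)."""

    participant_id: str
    trials: pd.DataFrame
    rng_seed: int | None = None
    stimuli: dict[int, StimulusSpec] = field(default_factory=lambda: dict(STIMULI))

    def __post_init__(self) -> None:
        missing = [c for c in SESSION_COLUMNS if c not in self.trials.columns]
        if missing:
            raise ValueError(f"session trials missing columns: {missing}")

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    def condition_trials(self, condition: str) -> pd.DataFrame:
        return self.trials[self.trials["condition"] == condition]


def classify_condition(pair: tuple[int, int]) -> str:
    """Classify an ordered stimulus pair into one of the three conditions."""
    a, b = pair
    if a == b:
        raise ValueError(f"pair members must be distinct, got {pair}")
    if a not in STIMULI or b not in STIMULI:
        raise ValueError(f"unknown stimulus ids in pair {pair}")
    classes = {STIMULI[a].value_class, STIMULI[b].value_class}
    if classes == {"high"}:
        return CONDITION_BOTH_HIGH
    if classes == {"low"}:
        return CONDITION_BOTH_LOW
    return CONDITION_DIFFERENT


def build_schedule(
    n_blocks: int = 4, reps_per_pair: int = 10, seed: int | None = None
) -> pd.DataFrame:
    """Build a balanced pseudo-random trial schedule.

    Every one of the 12 ordered pairs occurs exactly ``reps_per_pair`` times
    within each block, in an independently shuffled order per block.  The
    defaults give the standard session: 4 blocks of 120 trials.

    Returns a DataFrame with columns ``block``, ``trial`` (both 1-based)
    ``stim_left``, ``stim_right`` and ``condition``.
    """
    if n_blocks < 1 or reps_per_pair < 1:
        raise ValueError(
            f"n_blocks and reps_per_pair must be positive, got "
            f"({n_blocks}, {reps_per_pair})"
        )
    rng = np.random.default_rng(seed)
    rows = []
    base = ORDERED_PAIRS * reps_per_pair
    for block in range(1, n_blocks + 1):
        order = rng.permutation(len(base))
        for trial, idx in enumerate(order, start=1):
            left, right = base[idx]
            rows.append(
                (block, trial, left, right, classify_condition((left, right)))
            )
    return pd.DataFrame(
        rows, columns=["block", "trial", "stim_left", "stim_right", "condition"]
    )


def sample_reward(spec: StimulusSpec, rng: np.random.Generator) -> int:
    """Draw one integer reward: Gaussian, rounded, clipped to [1, 99]."""
    r = rng.normal(spec.mean, spec.sd)
    return int(np.clip(np.rint(r), REWARD_MIN, REWARD_MAX))


def sample_rewards(spec: StimulusSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Vectorised version of :func:`sample_reward` (n draws)."""
    r = rng.normal(spec.mean, spec.sd, size=n)
    return np.clip(np.rint(r), REWARD_MIN, REWARD_MAX).astype(np.int64)


# ---------------------------------------------------------------------------
# CSV dialect: participant,block,trial,stim_left,stim_right,condition,choice,reward
# "left/right" is the ordered-pair presentation order; the choice is recorded
# by stimulus id, not by side.


def sessions_to_frame(sessions: list[SessionData]) -> pd.DataFrame:
    frames = []
    for s in sessions:
        df = s.trials.copy()
        df["participant"] = s.participant_id
        frames.append(df[TRIAL_COLUMNS])
    return pd.concat(frames, ignore_index=True)


def frame_to_sessions(df: pd.DataFrame) -> list[SessionData]:
    sessions = []
    for pid, grp in df.groupby("participant", sort=False):
        trials = (
            grp[SESSION_COLUMNS]
            .sort_values(["block", "trial"])
            .reset_index(drop=True)
        )
        sessions.append(SessionData(participant_id=str(pid), trials=trials))
    return sessions


def write_sessions(sessions: list[SessionData], path) -> None:
    sessions_to_frame(sessions).to_csv(path, index=False)


def read_sessions(path) -> list[SessionData]:
    return frame_to_sessions(pd.read_csv(path))
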