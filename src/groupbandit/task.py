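"""Two-armed bandit environment with scheduled reversals.

The task presents two options ("left" and "right"); at every trial one of
them is advantageous (default 70% win probability) and the other
disadvantageous (default 30%).  The roles swap after each scheduled
reversal trial, so a session consists of alternating segments.  Rewards
are Bernoulli and recorded on a 0/1 scale; the points shown to players
(default 10 per win) are display metadata only.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import ConfigurationError

#: Canonical arm labels, in internal index order.
ARMS = ("left", "right")
LEFT, RIGHT = 0, 1


def arm_index(arm: int | str) -> int:
    """Normalize an arm given as label or index to the internal 0/1 index."""
    if isinstance(arm, str):
        try:
            return ARMS.index(arm)
        except ValueError:
            raise ConfigurationError(f"unknown arm label {arm!r}") from None
    arm = int(arm)
    if arm not in (LEFT, RIGHT):
        raise ConfigurationError(f"arm index must be 0 or 1, got {arm}")
    return arm


@dataclasses.dataclass(frozen=True)
class TaskConfig:
    """Static description of one bandit session.

    Trials are 1-based in configuration and reports.  A reversal listed at
    trial ``r`` means the arm roles swap *after* trial ``r`` (the swap is
    effective from trial ``r + 1``), so the default ``(30, 70)`` makes the
    initial arm advantageous for trials 1-30 and 71-100.
    """

    n_trials: int = 100
    p_advantageous: float = 0.70
    p_disadvantageous: float = 0.30
    reversal_trials: tuple[int, ...] = (30, 70)
    initial_advantageous_arm: str = "right"
    reward_points: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(self, "reversal_trials", tuple(int(r) for r in self.reversal_trials))
        if self.n_trials < 1:
            raise ConfigurationError(f"n_trials must be >= 1, got {self.n_trials}")
        if not (0.0 <= self.p_disadvantageous < self.p_advantageous <= 1.0):
            raise ConfigurationError(
                "need 0 <= p_disadvantageous < p_advantageous <= 1, got "
                f"({self.p_disadvantageous}, {self.p_advantageous})"
            )
        prev = 0
        for r in self.reversal_trials:
            if not (1 <= r <= self.n_trials - 1):
                raise ConfigurationError(
                    f"reversal trial {r} outside valid range [1, {self.n_trials - 1}]"
                )
            if r <= prev:
                raise ConfigurationError(
                    f"reversal_trials must be strictly increasing, got {self.reversal_trials}"
                )
            prev = r
        if self.initial_advantageous_arm not in ARMS:
            raise ConfigurationError(
                f"initial_advantageous_arm must be one of {ARMS}, "
                f"got {self.initial_advantageous_arm!r}"
            )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["reversal_trials"] = list(self.reversal_trials)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "TaskConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown task config keys: {sorted(unknown)}")
        return cls(**{k: d[k] for k in d})


@dataclasses.dataclass(frozen=True)
class Schedule:
    """Per-trial win probabilities, one row per trial, columns (left, right)."""

    win_prob: np.ndarray

    def __post_init__(self) -> None:
        wp = np.asarray(self.win_prob, dtype=float)
        if wp.ndim != 2 or wp.shape[1] != 2:
            raise ConfigurationError(f"win_prob must have shape (n_trials, 2), got {wp.shape}")
        object.__setattr__(self, "win_prob", wp)

    @property
    def n_trials(self) -> int:
        return self.win_prob.shape[0]

    @property
    def n_segments(self) -> int:
        """Number of constant-probability stretches (reversals + 1)."""
        changes = np.any(self.win_prob[1:] != self.win_prob[:-1], axis=1)
        return int(changes.sum()) + 1

    def advantageous_arm(self, trial: int) -> int:
        """Internal index of the better arm at 0-based ``trial``."""
        return int(np.argmax(self.win_prob[trial]))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": np.arange(1, self.n_trials + 1),
                "p_left": self.win_prob[:, LEFT],
                "p_right": self.win_prob[:, RIGHT],
            }
        )


def build_schedule(config: TaskConfig) -> Schedule:
    """Expand a :class:`TaskConfig` into per-trial win probabilities."""
    n = config.n_trials
    wp = np.empty((n, 2), dtype=float)
    bounds = (0, *config.reversal_trials, n)
    adv0 = arm_index(config.initial_advantageous_arm)
    for seg, (start, stop) in enumerate(zip(bounds[:-1], bounds[1:])):
        adv = adv0 if seg % 2 == 0 else 1 - adv0
        wp[start:stop, adv] = config.p_advantageous
        wp[start:stop, 1 - adv] = config.p_disadvantageous
    return Schedule(win_prob=wp)


def sample_reward(
    schedule: Schedule, trial: int, arm: int | str, rng: np.random.Generator
) -> int:
    """Draw the Bernoulli reward for choosing ``arm`` at 0-based ``trial``."""
    if not (0 <= trial < schedule.n_trials):
        raise IndexError(f"trial {trial} outside schedule of {schedule.n_trials} trials")
    p = schedule.win_prob[trial, arm_index(arm)]
    return int(rng.random() < p)


def oracle_expected_performance(schedule: Schedule) -> float:
    """Expected rewarded-trial count of a policy always on the better arm."""
    return float(schedule.win_prob.max(axis=1).sum())
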