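"""The :class:`Session` container: one unit's full choice/reward record."""

from __future__ import annotations

import dataclasses
from typing import Any

import numpy as np

from .errors import DataError
from .task import Schedule


@dataclasses.dataclass
class Session:
    """One decision-making unit's run through the bandit.

    A unit is an individual, a dyad, or a triad; ``size`` equals the number
    of members.  ``choices`` holds internal arm indices (0 = left,
    1 = right) and ``rewards`` 0/1 outcomes, one per trial.  For synthetic
    data, ``ground_truth`` carries the generating parameters and the
    coherence level; it is absent for externally loaded data.
    """

    unit_id: str
    size: int
    member_ids: tuple[str, ...]
    choices: np.ndarray
    rewards: np.ndarray
    schedule: Schedule | None = None
    test_id: int | None = None
    ground_truth: dict[str, Any] | None = None

    def __post_init__(self) -> None:
        self.choices = np.asarray(self.choices, dtype=np.int64)
        self.rewards = np.asarray(self.rewards, dtype=np.int64)
        self.member_ids = tuple(self.member_ids)
        if self.choices.shape != self.rewards.shape or self.choices.ndim != 1:
            raise DataError(
                f"session {self.unit_id}: choices {self.choices.shape} and "
                f"rewards {self.rewards.shape} must be equal-length vectors"
            )
        if self.member_ids and self.size != len(self.member_ids):
            raise DataError(
                f"session {self.unit_id}: size {self.size} != "
                f"{len(self.member_ids)} member ids"
            )
        if self.size not in (1, 2, 3):
            raise DataError(f"session {self.unit_id}: size must be 1, 2 or 3")
        bad = np.setdiff1d(np.unique(self.rewards), [0, 1])
        if bad.size:
            raise DataError(f"session {self.unit_id}: non-binary rewards {bad.tolist()}")
        bad = np.setdiff1d(np.unique(self.choices), [0, 1])
        if bad.size:
            raise DataError(f"session {self.unit_id}: non-binary choices {bad.tolist()}")
        if self.test_id is None:
            self.test_id = self.size

    @property
    def n_trials(self) -> int:
        return int(self.choices.shape[0])

    @property
    def performance(self) -> int:
        """Count of rewarded trials (total points = 10 x this count)."""
        return int(self.rewards.sum())
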