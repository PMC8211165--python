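"""CSV readers and writers for sessions, rosters, and ground truth.

The on-disk layout is deliberately plain: a long trials table (one row
per unit x trial) with columns ``unit_id, size, trial, choice, reward``
and optional ``p_left, p_right`` schedule columns; a units table with
``unit_id, size, member_ids, test_id``; and, for synthetic data, a
ground-truth table with one row per unit member.  Write-then-read is an
identity on choices, rewards, and metadata.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .sessions import Session
from .task import ARMS, Schedule

REQUIRED_COLUMNS = ("unit_id", "size", "trial", "choice", "reward")


def write_sessions(sessions: Iterable[Session], path: str | Path) -> None:
    """Write sessions as a long trials CSV."""
    parts = []
    for s in sessions:
        wp = s.schedule.win_prob if s.schedule is not None else None
        part = pd.DataFrame(
            {
                "unit_id": s.unit_id,
                "size": s.size,
                "trial": np.arange(1, s.n_trials + 1),
                "choice": [ARMS[c] for c in s.choices],
                "reward": s.rewards,
            }
        )
        if wp is not None:
            part["p_left"] = wp[:, 0]
            part["p_right"] = wp[:, 1]
        parts.append(part)
    if parts:
        frame = pd.concat(parts, ignore_index=True)
    else:
        frame = pd.DataFrame(columns=list(REQUIRED_COLUMNS))
    frame.to_csv(path, index=False)


def write_units(sessions: Sequence[Session], path: str | Path) -> None:
    pd.DataFrame(
        {
            "unit_id": [s.unit_id for s in sessions],
            "size": [s.size for s in sessions],
            "member_ids": ["|".join(s.member_ids) for s in sessions],
            "test_id": [s.test_id for s in sessions],
        }
    ).to_csv(path, index=False)


def read_units(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path, dtype={"unit_id": str, "member_ids": str})
    missing = {"unit_id", "size", "member_ids"} - set(frame.columns)
    if missing:
        raise DataError(f"units file {path} missing columns {sorted(missing)}")
    return frame


def read_sessions(path: str | Path, units: pd.DataFrame | None = None) -> list[Session]:
    """Parse a trials CSV back into :class:`Session` objects.

    Validates column presence, 0/1 rewards, known arm labels, and a
    gap-free 1..T trial index per unit; errors name the offending row
    (1-based, excluding the header).  ``units`` optionally supplies member
    rosters and test ids.
    """
    frame = pd.read_csv(path, dtype={"unit_id": str}, float_precision="round_trip")
    missing = set(REQUIRED_COLUMNS) - set(frame.columns)
    if missing:
        raise DataError(f"sessions file {path} missing columns {sorted(missing)}")

    bad = ~frame["reward"].isin([0, 1])
    if bad.any():
        row = int(frame.index[bad][0]) + 1
        raise DataError(
            f"{path}: invalid reward {frame.loc[row - 1, 'reward']!r} at data row {row}"
        )
    label_to_idx = {label: i for i, label in enumerate(ARMS)}
    label_to_idx.update({"0": 0, "1": 1, 0: 0, 1: 1})
    bad = ~frame["choice"].isin(label_to_idx)
    if bad.any():
        row = int(frame.index[bad][0]) + 1
        raise DataError(
            f"{path}: invalid choice {frame.loc[row - 1, 'choice']!r} at data row {row}"
        )

    roster: dict[str, tuple[str, ...]] = {}
    test_ids: dict[str, int] = {}
    if units is not None:
        for _, r in units.iterrows():
            members = str(r["member_ids"]).split("|") if r["member_ids"] else []
            roster[str(r["unit_id"])] = tuple(members)
            if "test_id" in units.columns and not pd.isna(r.get("test_id")):
                test_ids[str(r["unit_id"])] = int(r["test_id"])

    has_schedule = {"p_left", "p_right"}.issubset(frame.columns)
    sessions = []
    for unit_id, g in frame.groupby("unit_id", sort=False):
        trials = g["trial"].to_numpy()
        expected = np.arange(1, len(g) + 1)
        if not np.array_equal(trials, expected):
            first_bad = int(np.argmax(trials != expected))
            row = int(g.index[first_bad]) + 1
            raise DataError(
                f"{path}: unit {unit_id!r} has a gap or disorder in its trial "
                f"index at data row {row} (expected trial {expected[first_bad]}, "
                f"got {trials[first_bad]})"
            )
        sizes = g["size"].unique()
        if len(sizes) != 1:
            raise DataError(f"{path}: unit {unit_id!r} has inconsistent sizes {sizes}")
        size = int(sizes[0])
        schedule = None
        if has_schedule:
            schedule = Schedule(win_prob=g[["p_left", "p_right"]].to_numpy(dtype=float))
        member_ids = roster.get(unit_id) or tuple(f"{unit_id}.m{i + 1}" for i in range(size))
        sessions.append(
            Session(
                unit_id=str(unit_id),
                size=size,
                member_ids=member_ids,
                choices=np.array([label_to_idx[c] for c in g["choice"]]),
                rewards=g["reward"].to_numpy(),
                schedule=schedule,
                test_id=test_ids.get(unit_id),
            )
        )
    return sessions


def write_ground_truth(dataset, path: str | Path) -> None:
    dataset.ground_truth_frame().to_csv(path, index=False)
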