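"""Synthetic individual, dyad, and triad sessions under learning coherence.

The generator stands in for human behavioral data that are not publicly
available.  Each member of a unit carries private Q-learning parameters
drawn from a population distribution.  A per-size *coherence* parameter
``c`` controls how the unit chooses:

* with probability ``c`` the trial is decided by a **consensus policy** --
  a softmax over the member-averaged action values with the
  member-averaged inverse temperature, after which **every** member
  integrates the outcome into their private values;
* otherwise a uniformly drawn member's own policy controls the trial and
  **only that member** updates their values.

The second clause is what makes incoherence costly: when control drifts
from member to member, no one accumulates a complete learning history, so
each member's value estimates are trained on a fragment of the session
and go stale between their turns.  Singleton units always follow (and
learn from) their own policy, so individuals are coherent by construction
regardless of ``c``.  Setting ``shared_updates=True`` restores the
variant in which all members update on every trial.

Defaults mimic the study design: 100-trial sessions with 70/30 reward
probabilities reversing after trials 30 and 70; 322 individual sessions,
138 dyads, 108 triads; coherence 1 / 0.1 / 0.9 for sizes 1 / 2 / 3; and
group members drawn from the pool of participants who also played alone.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DesignError
from .qlearning import (
    MODEL_ASYMMETRIC,
    MODEL_SIMPLE,
    MODELS,
    AsymParams,
    Params,
    SimpleParams,
)
from .sessions import Session
from .task import ARMS, Schedule, TaskConfig, build_schedule

__all__ = [
    "PopulationSpec",
    "MemberProfile",
    "GroupDesign",
    "Dataset",
    "simulate_agent_session",
    "simulate_group_session",
    "generate_dataset",
]


@dataclasses.dataclass(frozen=True)
class PopulationSpec:
    """Population distributions for member-level learning parameters.

    Learning rates follow Beta(2, 2) (broad, mean 0.5), inverse
    temperatures Gamma(shape 2, scale 2.5) (mean 5, long right tail), and
    the choice-trace increment Normal(0, 0.1): weakly informative choices
    centered on the magnitudes typical of human fits in this task, without
    asserting any particular study's estimates.
    """

    alpha_a: float = 2.0
    alpha_b: float = 2.0
    beta_shape: float = 2.0
    beta_scale: float = 2.5
    phi_mean: float = 0.0
    phi_sd: float = 0.1

    def __post_init__(self) -> None:
        for name in ("alpha_a", "alpha_b", "beta_shape", "beta_scale", "phi_sd"):
            if getattr(self, name) <= 0:
                raise DesignError(f"population hyperparameter {name} must be > 0")

    def draw(self, model_id: str, rng: np.random.Generator) -> Params:
        """Draw one member's parameters, truncated to model bounds."""
        if model_id == MODEL_SIMPLE:
            return SimpleParams(
                alpha=self._draw_rate(rng),
                beta=float(rng.gamma(self.beta_shape, self.beta_scale)),
            )
        if model_id == MODEL_ASYMMETRIC:
            return AsymParams(
                alpha_plus=self._draw_rate(rng),
                alpha_minus=self._draw_rate(rng),
                beta=float(rng.gamma(self.beta_shape, self.beta_scale)),
                phi=float(rng.normal(self.phi_mean, self.phi_sd)),
            )
        raise DesignError(f"unknown model_id {model_id!r}; expected one of {MODELS}")

    def _draw_rate(self, rng: np.random.Generator) -> float:
        # Beta draws land in the open interval almost surely; clip the
        # pathological float-rounding edge away from 0.
        return float(min(max(rng.beta(self.alpha_a, self.alpha_b), 1e-12), 1.0))


@dataclasses.dataclass(frozen=True)
class MemberProfile:
    member_id: str
    true_params: Params


DEFAULT_COHERENCE: Mapping[int, float] = {1: 1.0, 2: 0.1, 3: 0.9}


@dataclasses.dataclass
class GroupDesign:
    """Full specification of one synthetic dataset."""

    n_individual_sessions: int = 322
    n_dyads: int = 138
    n_triads: int = 108
    coherence: Mapping[int, float] = dataclasses.field(
        default_factory=lambda: dict(DEFAULT_COHERENCE)
    )
    population: PopulationSpec = dataclasses.field(default_factory=PopulationSpec)
    membership_overlap: bool = True
    model_id: str = MODEL_SIMPLE
    task: TaskConfig = dataclasses.field(default_factory=TaskConfig)
    seed: int = 0
    shared_updates: bool = False

    def __post_init__(self) -> None:
        for name in ("n_individual_sessions", "n_dyads", "n_triads"):
            if getattr(self, name) < 0:
                raise DesignError(f"{name} must be >= 0")
        self.coherence = {int(k): float(v) for k, v in dict(self.coherence).items()}
        for size, c in self.coherence.items():
            if not (0.0 <= c <= 1.0):
                raise DesignError(f"coherence for size {size} must be in [0, 1], got {c}")
        for size in (1, 2, 3):
            self.coherence.setdefault(size, DEFAULT_COHERENCE[size])
        if self.model_id not in MODELS:
            raise DesignError(f"unknown model_id {self.model_id!r}")
        if self.membership_overlap:
            largest = 3 if self.n_triads else (2 if self.n_dyads else 1)
            if (self.n_dyads or self.n_triads) and self.n_individual_sessions < largest:
                raise DesignError(
                    "membership_overlap requires at least as many individual "
                    "sessions as the largest group size"
                )


def _policy_prob_left(q: Sequence[float], beta: float) -> float:
    """P(choose left) under a two-option softmax; overflow-safe logistic."""
    z = beta * (q[0] - q[1])
    if z >= 0:
        return 1.0 / (1.0 + math.exp(-z)) if z < 500 else 1.0
    return math.exp(z) / (1.0 + math.exp(z)) if z > -500 else 0.0


def _update_member(q: list[float], choice: int, reward: int, params: Params) -> None:
    d = reward - q[choice]
    if isinstance(params, SimpleParams):
        q[choice] += params.alpha * d
    else:
        rate = params.alpha_plus if d >= 0 else params.alpha_minus
        q[choice] += rate * d + params.phi


def simulate_group_session(
    members: Sequence[MemberProfile],
    coherence: float,
    model_id: str | None = None,
    task: TaskConfig | None = None,
    rng: np.random.Generator | int | None = None,
    *,
    unit_id: str = "unit",
    schedule: Schedule | None = None,
    shared_updates: bool = False,
    test_id: int | None = None,
) -> Session:
    """Simulate one unit's session under the coherence-mixture policy.

    Singleton units consume the random stream exactly as
    :func:`simulate_agent_session` does (no coherence or controller draws),
    so a one-member group with any ``c`` reproduces the solo agent
    trajectory under the same seed.
    """
    members = list(members)
    if not members:
        raise DesignError("simulate_group_session needs at least one member")
    if len(members) > 3:
        raise DesignError(f"units larger than 3 are not supported, got {len(members)}")
    if not (0.0 <= coherence <= 1.0):
        raise DesignError(f"coherence must be in [0, 1], got {coherence}")
    for m in members:
        if model_id is not None and m.true_params.model_id != model_id:
            raise DesignError(
                f"member {m.member_id} has {m.true_params.model_id!r} parameters, "
                f"expected {model_id!r}"
            )
    task = task or TaskConfig()
    rng = np.random.default_rng(rng)
    if schedule is None:
        schedule = build_schedule(task)
    wp = schedule.win_prob
    n_members = len(members)
    params = [m.true_params for m in members]
    betas = [p.beta for p in params]
    mean_beta = sum(betas) / n_members
    qs = [[0.0, 0.0] for _ in range(n_members)]

    choices = np.empty(task.n_trials, dtype=np.int64)
    rewards = np.empty(task.n_trials, dtype=np.int64)
    for t in range(task.n_trials):
        if n_members == 1:
            p_left = _policy_prob_left(qs[0], betas[0])
            updaters = (0,)
        elif rng.random() < coherence:
            mean_q = (
                sum(q[0] for q in qs) / n_members,
                sum(q[1] for q in qs) / n_members,
            )
            p_left = _policy_prob_left(mean_q, mean_beta)
            updaters = range(n_members)
        else:
            k = int(rng.integers(n_members))
            p_left = _policy_prob_left(qs[k], betas[k])
            updaters = range(n_members) if shared_updates else (k,)
        choice = 0 if rng.random() < p_left else 1
        reward = int(rng.random() < wp[t, choice])
        choices[t] = choice
        rewards[t] = reward
        for i in updaters:
            _update_member(qs[i], choice, reward, params[i])

    return Session(
        unit_id=unit_id,
        size=n_members,
        member_ids=tuple(m.member_id for m in members),
        choices=choices,
        rewards=rewards,
        schedule=schedule,
        test_id=test_id,
        ground_truth={
            "model_id": params[0].model_id,
            "coherence": float(coherence),
            "shared_updates": bool(shared_updates),
            "members": [
                {"member_id": m.member_id, **m.true_params.as_dict()} for m in members
            ],
        },
    )


def simulate_agent_session(
    params: Params,
    model_id: str | None = None,
    task: TaskConfig | None = None,
    rng: np.random.Generator | int | None = None,
    *,
    unit_id: str = "agent",
    schedule: Schedule | None = None,
) -> Session:
    """Simulate a solo agent: choices sampled from its softmax each trial."""
    profile = MemberProfile(member_id=f"{unit_id}.m1", true_params=params)
    return simulate_group_session(
        [profile],
        coherence=1.0,
        model_id=model_id,
        task=task,
        rng=rng,
        unit_id=unit_id,
        schedule=schedule,
    )


@dataclasses.dataclass
class Dataset:
    """A generated collection of sessions plus its member roster."""

    sessions: list[Session]
    members: list[MemberProfile]
    design: GroupDesign

    def __iter__(self):
        return iter(self.sessions)

    def __len__(self) -> int:
        return len(self.sessions)

    def trials_frame(self) -> pd.DataFrame:
        """Long table: one row per (unit, trial)."""
        parts = []
        for s in self.sessions:
            wp = s.schedule.win_prob if s.schedule is not None else np.full((s.n_trials, 2), np.nan)
            parts.append(
                pd.DataFrame(
                    {
                        "unit_id": s.unit_id,
                        "size": s.size,
                        "trial": np.arange(1, s.n_trials + 1),
                        "choice": [ARMS[c] for c in s.choices],
                        "reward": s.rewards,
                        "p_left": wp[:, 0],
                        "p_right": wp[:, 1],
                    }
                )
            )
        if not parts:
            return pd.DataFrame(
                columns=["unit_id", "size", "trial", "choice", "reward", "p_left", "p_right"]
            )
        return pd.concat(parts, ignore_index=True)

    def units_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "unit_id": [s.unit_id for s in self.sessions],
                "size": [s.size for s in self.sessions],
                "member_ids": ["|".join(s.member_ids) for s in self.sessions],
                "test_id": [s.test_id for s in self.sessions],
            }
        )

    def ground_truth_frame(self) -> pd.DataFrame:
        """One row per (unit, member) with the generating parameters."""
        rows = []
        for s in self.sessions:
            gt = s.ground_truth or {}
            for m in gt.get("members", []):
                rows.append(
                    {
                        "unit_id": s.unit_id,
                        "size": s.size,
                        "model_id": gt.get("model_id"),
                        "coherence": gt.get("coherence"),
                        **m,
                    }
                )
        return pd.DataFrame(rows)


def generate_dataset(
    design: GroupDesign, rng: np.random.Generator | int | None = None
) -> Dataset:
    """Generate the full labeled dataset a :class:`GroupDesign` describes.

    Fully reproducible from ``design.seed`` when ``rng`` is omitted.  With
    ``membership_overlap`` (the default), group members are drawn from the
    pool of participants who have individual sessions, so every dyad and
    triad has members with solo records -- mirroring a design in which
    everyone plays alone once and group rosters overlap the solo sample.
    """
    if rng is None:
        rng = np.random.default_rng(design.seed)
    else:
        rng = np.random.default_rng(rng)

    n_pool = design.n_individual_sessions
    if not design.membership_overlap:
        n_pool += 2 * design.n_dyads + 3 * design.n_triads
    n_pool = max(n_pool, 3 if design.n_triads else (2 if design.n_dyads else 1), 1)
    members = [
        MemberProfile(
            member_id=f"m{i + 1:04d}",
            true_params=design.population.draw(design.model_id, rng),
        )
        for i in range(n_pool)
    ]

    sessions: list[Session] = []
    schedule = build_schedule(design.task)
    for i in range(design.n_individual_sessions):
        sessions.append(
            simulate_group_session(
                [members[i]],
                coherence=design.coherence[1],
                task=design.task,
                rng=rng,
                unit_id=f"ind{i + 1:04d}",
                schedule=schedule,
                shared_updates=design.shared_updates,
                test_id=1,
            )
        )
    pool_idx = np.arange(
        design.n_individual_sessions if design.membership_overlap else n_pool
    )
    for size, count, prefix, test_id in (
        (2, design.n_dyads, "dyad", 2),
        (3, design.n_triads, "tri", 3),
    ):
        for i in range(count):
            roster = [members[j] for j in rng.choice(pool_idx, size=size, replace=False)]
            sessions.append(
                simulate_group_session(
                    roster,
                    coherence=design.coherence[size],
                    task=design.task,
                    rng=rng,
                    unit_id=f"{prefix}{i + 1:04d}",
                    schedule=schedule,
                    shared_updates=design.shared_updates,
                    test_id=test_id,
                )
            )
    return Dataset(sessions=sessions, members=members, design=design)
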