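"""Action-value learning rules and the softmax choice policy.

Two model variants are supported:

* **simple** -- one learning rate ``alpha`` applied to the reward
  prediction error of the chosen arm, plus an inverse temperature
  ``beta`` in the softmax.
* **asymmetric** -- separate learning rates for non-negative
  (``alpha_plus``) and negative (``alpha_minus``) prediction errors, and
  an additive choice-trace increment ``phi`` applied to the chosen arm's
  value on every update, capturing choice autocorrelation
  (perseveration when positive).

In both models the unchosen arm's value is left untouched, initial
values are zero, and rewards enter on a 0/1 scale.  The zero
prediction-error boundary uses the ``alpha_plus`` branch.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, DataError

MODEL_SIMPLE = "simple"
MODEL_ASYMMETRIC = "asymmetric"
MODELS = (MODEL_SIMPLE, MODEL_ASYMMETRIC)

LOG_HALF = math.log(0.5)


@dataclasses.dataclass(frozen=True)
class SimpleParams:
    """Parameters of the single-learning-rate model."""

    alpha: float
    beta: float

    model_id = MODEL_SIMPLE

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha <= 1.0):
            raise ConfigurationError(f"alpha must be in (0, 1], got {self.alpha}")
        if self.beta < 0.0:
            raise ConfigurationError(f"beta must be >= 0, got {self.beta}")

    def as_dict(self) -> dict:
        return {"alpha": self.alpha, "beta": self.beta}


@dataclasses.dataclass(frozen=True)
class AsymParams:
    """Parameters of the asymmetric (valence-dependent) model."""

    alpha_plus: float
    alpha_minus: float
    beta: float
    phi: float = 0.0

    model_id = MODEL_ASYMMETRIC

    def __post_init__(self) -> None:
        for name in ("alpha_plus", "alpha_minus"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ConfigurationError(f"{name} must be in (0, 1], got {v}")
        if self.beta < 0.0:
            raise ConfigurationError(f"beta must be >= 0, got {self.beta}")
        if not math.isfinite(self.phi):
            raise ConfigurationError(f"phi must be finite, got {self.phi}")

    @property
    def positivity_bias(self) -> float:
        return self.alpha_plus - self.alpha_minus

    def as_dict(self) -> dict:
        return {
            "alpha_plus": self.alpha_plus,
            "alpha_minus": self.alpha_minus,
            "beta": self.beta,
            "phi": self.phi,
        }


Params = SimpleParams | AsymParams


@dataclasses.dataclass(frozen=True)
class QState:
    """Action values for the two arms at a given (1-based) trial."""

    q: tuple[float, float] = (0.0, 0.0)
    trial: int = 1


@dataclasses.dataclass(frozen=True)
class UpdateTrace:
    """Bookkeeping of one value update."""

    delta: float
    branch: str  # "simple", "plus" or "minus"


def _check_choice_reward(choice: int, reward: int) -> None:
    if choice not in (0, 1):
        raise DataError(f"choice must be 0 or 1, got {choice}")
    if reward not in (0, 1):
        raise DataError(f"reward must be 0 or 1, got {reward}")


def softmax_policy(state: QState | Sequence[float], beta: float) -> np.ndarray:
    """Choice probabilities over the two arms under the softmax rule.

    Stabilized with max-subtraction so large ``beta * Q`` never overflows.
    """
    if beta < 0.0:
        raise ConfigurationError(f"beta must be >= 0, got {beta}")
    q = np.asarray(state.q if isinstance(state, QState) else state, dtype=float)
    if q.shape != (2,) or not np.all(np.isfinite(q)):
        raise DataError(f"need two finite action values, got {q}")
    x = beta * q
    x -= x.max()
    e = np.exp(x)
    return e / e.sum()


def update_simple(
    state: QState, choice: int, reward: int, params: SimpleParams
) -> tuple[QState, UpdateTrace]:
    """One delta-rule update of the chosen arm's value."""
    _check_choice_reward(choice, reward)
    q = list(state.q)
    delta = reward - q[choice]
    q[choice] += params.alpha * delta
    return QState(q=(q[0], q[1]), trial=state.trial + 1), UpdateTrace(delta, "simple")


def update_asymmetric(
    state: QState, choice: int, reward: int, params: AsymParams
) -> tuple[QState, UpdateTrace]:
    """Valence-dependent update with additive choice trace.

    Non-negative prediction errors (inclusive of zero) use ``alpha_plus``;
    negative ones use ``alpha_minus``.  ``phi`` is added to the chosen
    arm's value on every update.
    """
    _check_choice_reward(choice, reward)
    q = list(state.q)
    delta = reward - q[choice]
    if delta >= 0:
        q[choice] += params.alpha_plus * delta + params.phi
        branch = "plus"
    else:
        q[choice] += params.alpha_minus * delta + params.phi
        branch = "minus"
    return QState(q=(q[0], q[1]), trial=state.trial + 1), UpdateTrace(delta, branch)


def _log_sigmoid(z: float) -> float:
    """log(1 / (1 + exp(-z))), overflow-safe."""
    if z >= 0.0:
        return -math.log1p(math.exp(-z))
    return z - math.log1p(math.exp(z))


def loglik_simple(
    choices: Sequence[int], rewards: Sequence[int], alpha: float, beta: float
) -> float:
    """Log-likelihood of a choice sequence under the simple model.

    Scalar-loop implementation kept free of array overhead: it sits in the
    innermost loop of MAP optimization and MCMC.
    """
    q0 = 0.0
    q1 = 0.0
    ll = 0.0
    for c, r in zip(choices, rewards):
        if c:
            ll += _log_sigmoid(beta * (q1 - q0))
            q1 += alpha * (r - q1)
        else:
            ll += _log_sigmoid(beta * (q0 - q1))
            q0 += alpha * (r - q0)
    return ll


def loglik_asymmetric(
    choices: Sequence[int],
    rewards: Sequence[int],
    alpha_plus: float,
    alpha_minus: float,
    beta: float,
    phi: float,
) -> float:
    """Log-likelihood of a choice sequence under the asymmetric model."""
    q0 = 0.0
    q1 = 0.0
    ll = 0.0
    for c, r in zip(choices, rewards):
        if c:
            ll += _log_sigmoid(beta * (q1 - q0))
            d = r - q1
            q1 += (alpha_plus if d >= 0 else alpha_minus) * d + phi
        else:
            ll += _log_sigmoid(beta * (q0 - q1))
            d = r - q0
            q0 += (alpha_minus if d < 0 else alpha_plus) * d + phi
    return ll


def session_loglik(session, params: Params, model_id: str | None = None) -> float:
    """Log-likelihood of an observed session under ``params``.

    ``session`` is anything with ``choices`` and ``rewards`` attributes (or
    a ``(choices, rewards)`` pair).  Values are updated sequentially from
    zero using the observed choices and rewards; each trial contributes the
    log softmax probability of the observed choice.
    """
    if hasattr(session, "choices"):
        choices, rewards = session.choices, session.rewards
    else:
        choices, rewards = session
    if len(choices) != len(rewards):
        raise DataError(
            f"choices and rewards lengths differ: {len(choices)} vs {len(rewards)}"
        )
    if model_id is not None and model_id != params.model_id:
        raise ConfigurationError(
            f"model_id {model_id!r} does not match params of type {params.model_id!r}"
        )
    choices = [int(c) for c in choices]
    rewards = [int(r) for r in rewards]
    for i, (c, r) in enumerate(zip(choices, rewards)):
        if c not in (0, 1) or r not in (0, 1):
            raise DataError(f"non-binary choice/reward at trial {i + 1}: ({c}, {r})")
    if isinstance(params, SimpleParams):
        return loglik_simple(choices, rewards, params.alpha, params.beta)
    return loglik_asymmetric(
        choices, rewards, params.alpha_plus, params.alpha_minus, params.beta, params.phi
    )
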