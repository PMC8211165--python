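"""Per-session parameter estimation and model-evidence proxies.

Parameters are estimated by maximum a posteriori (MAP): the product of
the session likelihood and independent priors -- Beta on learning rates,
Gamma on the inverse temperature, Normal on the choice-trace increment --
is maximized over multiple random restarts on an unconstrained
reparameterization (logit for rates, log for the inverse temperature,
identity for the choice trace).

Model comparison uses the widely applicable Bayesian information
criterion (WBIC): the posterior is tempered at inverse temperature
``1 / log(n_trials)``, sampled with random-walk Metropolis, and the WBIC
is the tempered-posterior mean of the *untempered* log-likelihood.  Under
this sign convention higher is better, and for a 100-trial session the
values sit on the log-likelihood scale (around -50 for near-chance
behavior).
"""

from __future__ import annotations

import dataclasses
import math
import warnings
from typing import Sequence

import numpy as np
import scipy.optimize
import scipy.stats

from .errors import ConfigurationError, DataError, FitError
from .qlearning import (
    MODEL_ASYMMETRIC,
    MODEL_SIMPLE,
    MODELS,
    AsymParams,
    Params,
    SimpleParams,
    loglik_asymmetric,
    loglik_simple,
    session_loglik,
)

__all__ = [
    "PriorSpec",
    "FitResult",
    "McmcSettings",
    "WBICResult",
    "ModelComparison",
    "log_posterior",
    "fit_map",
    "compute_wbic",
    "compare_models",
]

_RATE_CLIP = 1e-12
_LOG_BETA_CLIP = 30.0


@dataclasses.dataclass(frozen=True)
class PriorSpec:
    """Hyperparameters of the independent parameter priors.

    Defaults are weakly informative: Beta(2, 2) on learning rates,
    Gamma(shape 2, scale 3) on the inverse temperature, Normal(0, 1) on
    the choice trace.  An infinite ``beta_scale`` or ``phi_sd`` denotes an
    improper flat prior on that coordinate (useful to check that MAP with
    flat priors coincides with maximum likelihood).
    """

    alpha_a: float = 2.0
    alpha_b: float = 2.0
    beta_shape: float = 2.0
    beta_scale: float = 3.0
    phi_mean: float = 0.0
    phi_sd: float = 1.0

    def __post_init__(self) -> None:
        for name in ("alpha_a", "alpha_b", "beta_shape", "beta_scale", "phi_sd"):
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"prior hyperparameter {name} must be > 0")

    @classmethod
    def flat(cls) -> "PriorSpec":
        """Uniform priors: Beta(1, 1) rates, flat improper beta and phi."""
        return cls(
            alpha_a=1.0,
            alpha_b=1.0,
            beta_shape=1.0,
            beta_scale=math.inf,
            phi_sd=math.inf,
        )

    # -- log densities ---------------------------------------------------
    def _log_rate_prior(self, x: float) -> float:
        if not (0.0 < x <= 1.0):
            return -math.inf
        a, b = self.alpha_a, self.alpha_b
        norm = math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)
        term_a = 0.0 if a == 1.0 else (a - 1.0) * math.log(x)
        if x == 1.0:
            term_b = 0.0 if b == 1.0 else -math.inf
        else:
            term_b = (b - 1.0) * math.log1p(-x)
        return norm + term_a + term_b

    def _log_beta_prior(self, x: float) -> float:
        if x < 0.0:
            return -math.inf
        k, theta = self.beta_shape, self.beta_scale
        if math.isinf(theta):
            return 0.0  # improper flat prior on [0, inf)
        if x == 0.0:
            if k > 1.0:
                return -math.inf
            if k == 1.0:
                return -math.log(theta)
            return math.inf
        return (k - 1.0) * math.log(x) - x / theta - k * math.log(theta) - math.lgamma(k)

    def _log_phi_prior(self, x: float) -> float:
        if math.isinf(self.phi_sd):
            return 0.0
        z = (x - self.phi_mean) / self.phi_sd
        return -0.5 * z * z - math.log(self.phi_sd) - 0.5 * math.log(2.0 * math.pi)

    def log_prior(self, params: Params) -> float:
        if isinstance(params, SimpleParams):
            return self._log_rate_prior(params.alpha) + self._log_beta_prior(params.beta)
        return (
            self._log_rate_prior(params.alpha_plus)
            + self._log_rate_prior(params.alpha_minus)
            + self._log_beta_prior(params.beta)
            + self._log_phi_prior(params.phi)
        )


def log_posterior(
    params, session, priors: PriorSpec, model_id: str | None = None
) -> float:
    """Unnormalized log posterior; ``-inf`` outside the parameter support.

    ``params`` may be a params object or a plain mapping of parameter
    values; mappings whose values violate the model bounds (for example
    a learning rate of 1.5) evaluate to ``-inf`` rather than raising.
    """
    if not isinstance(params, (SimpleParams, AsymParams)):
        d = dict(params)
        cls = AsymParams if (model_id == MODEL_ASYMMETRIC or "alpha_plus" in d) else SimpleParams
        try:
            params = cls(**d)
        except ConfigurationError:
            return -math.inf
    lp = priors.log_prior(params)
    if lp == -math.inf:
        return -math.inf
    return lp + session_loglik(session, params, model_id)


# -- unconstrained reparameterization ------------------------------------


def _sigmoid(x: float) -> float:
    if x >= 0:
        v = 1.0 / (1.0 + math.exp(-x)) if x < 500 else 1.0
    else:
        v = math.exp(x) / (1.0 + math.exp(x)) if x > -500 else 0.0
    return min(max(v, _RATE_CLIP), 1.0 - _RATE_CLIP)


def _logit(p: float) -> float:
    p = min(max(p, _RATE_CLIP), 1.0 - _RATE_CLIP)
    return math.log(p / (1.0 - p))


def _n_params(model_id: str) -> int:
    return 2 if model_id == MODEL_SIMPLE else 4


def _from_unconstrained(x: Sequence[float], model_id: str) -> Params:
    if model_id == MODEL_SIMPLE:
        return SimpleParams(
            alpha=_sigmoid(x[0]),
            beta=math.exp(min(max(x[1], -_LOG_BETA_CLIP), _LOG_BETA_CLIP)),
        )
    return AsymParams(
        alpha_plus=_sigmoid(x[0]),
        alpha_minus=_sigmoid(x[1]),
        beta=math.exp(min(max(x[2], -_LOG_BETA_CLIP), _LOG_BETA_CLIP)),
        phi=float(x[3]),
    )


def _to_unconstrained(params: Params) -> np.ndarray:
    if isinstance(params, SimpleParams):
        return np.array([_logit(params.alpha), math.log(max(params.beta, 1e-12))])
    return np.array(
        [
            _logit(params.alpha_plus),
            _logit(params.alpha_minus),
            math.log(max(params.beta, 1e-12)),
            params.phi,
        ]
    )


def _session_arrays(session) -> tuple[list[int], list[int]]:
    if hasattr(session, "choices"):
        choices, rewards = session.choices, session.rewards
    else:
        choices, rewards = session
    choices = [int(c) for c in choices]
    rewards = [int(r) for r in rewards]
    if len(choices) != len(rewards):
        raise DataError("choices and rewards lengths differ")
    return choices, rewards


def _make_loglik(choices: list[int], rewards: list[int], model_id: str):
    if model_id == MODEL_SIMPLE:
        return lambda p: loglik_simple(choices, rewards, p.alpha, p.beta)
    return lambda p: loglik_asymmetric(
        choices, rewards, p.alpha_plus, p.alpha_minus, p.beta, p.phi
    )


@dataclasses.dataclass(frozen=True)
class FitResult:
    model_id: str
    map_params: Params
    log_posterior: float
    log_likelihood: float
    n_restarts: int
    best_restart_index: int
    converged: bool


def _draw_start(model_id: str, rng: np.random.Generator) -> np.ndarray:
    """Dispersed starting point on the unconstrained scale."""
    alpha = rng.uniform(0.05, 0.95)
    beta = math.exp(rng.uniform(math.log(0.3), math.log(15.0)))
    if model_id == MODEL_SIMPLE:
        return np.array([_logit(alpha), math.log(beta)])
    alpha2 = rng.uniform(0.05, 0.95)
    phi = rng.normal(0.0, 0.3)
    return np.array([_logit(alpha), _logit(alpha2), math.log(beta), phi])


def fit_map(
    session,
    model_id: str = MODEL_SIMPLE,
    priors: PriorSpec | None = None,
    n_restarts: int = 10,
    rng: np.random.Generator | int | None = None,
    tol: float = 1e-6,
) -> FitResult:
    """MAP estimate of one session's parameters by multi-start L-BFGS.

    Deterministic given the seed: restarts are drawn from ``rng`` and the
    best local optimum (highest log posterior) is returned.
    """
    if model_id not in MODELS:
        raise ConfigurationError(f"unknown model_id {model_id!r}")
    if n_restarts < 1:
        raise ConfigurationError("n_restarts must be >= 1")
    priors = priors or PriorSpec()
    rng = np.random.default_rng(rng)
    choices, rewards = _session_arrays(session)
    loglik = _make_loglik(choices, rewards, model_id)

    def objective(x: np.ndarray) -> float:
        p = _from_unconstrained(x, model_id)
        lp = priors.log_prior(p)
        if lp == -math.inf:
            return 1e12
        return -(lp + loglik(p))

    best: tuple[float, np.ndarray, int] | None = None
    any_success = False
    for i in range(n_restarts):
        x0 = _draw_start(model_id, rng)
        try:
            res = scipy.optimize.minimize(
                objective, x0, method="L-BFGS-B", options={"ftol": tol, "maxiter": 500}
            )
        except (ValueError, FloatingPointError):  # pragma: no cover - defensive
            continue
        if not np.isfinite(res.fun):
            continue
        any_success = any_success or bool(res.success)
        if best is None or res.fun < best[0]:
            best = (float(res.fun), res.x.copy(), i)
    if best is None:
        raise FitError(
            f"all {n_restarts} restarts failed for model {model_id!r} "
            f"on a session of {len(choices)} trials"
        )
    fun, x, idx = best
    params = _from_unconstrained(x, model_id)
    ll = loglik(params)
    return FitResult(
        model_id=model_id,
        map_params=params,
        log_posterior=-fun,
        log_likelihood=ll,
        n_restarts=n_restarts,
        best_restart_index=idx,
        converged=any_success,
    )


@dataclasses.dataclass(frozen=True)
class McmcSettings:
    """Random-walk Metropolis settings for the tempered posterior."""

    n_samples: int = 5000
    burn_in: int = 1000
    proposal_scale: float = 0.35

    def __post_init__(self) -> None:
        if self.n_samples < 1 or self.burn_in < 0:
            raise ConfigurationError("need n_samples >= 1 and burn_in >= 0")
        if self.proposal_scale <= 0:
            raise ConfigurationError("proposal_scale must be > 0")


@dataclasses.dataclass(frozen=True)
class WBICResult:
    model_id: str
    wbic: float
    temperature: float
    n_samples: int
    burn_in: int
    acceptance_rate: float
    seed: int | None = None


def compute_wbic(
    session,
    model_id: str = MODEL_SIMPLE,
    priors: PriorSpec | None = None,
    mcmc: McmcSettings | None = None,
    rng: np.random.Generator | int | None = None,
) -> WBICResult:
    """WBIC of one session under one model.

    Runs random-walk Metropolis on the unconstrained scale targeting
    ``prior x likelihood^(1/log n)`` (with the change-of-variables
    Jacobian), then averages the untempered log-likelihood over the
    post-burn-in samples.
    """
    if model_id not in MODELS:
        raise ConfigurationError(f"unknown model_id {model_id!r}")
    priors = priors or PriorSpec()
    mcmc = mcmc or McmcSettings()
    seed = rng if isinstance(rng, (int, np.integer)) else None
    rng = np.random.default_rng(rng)
    choices, rewards = _session_arrays(session)
    n = len(choices)
    if n < 2:
        raise DataError(f"WBIC needs at least 2 trials, got {n}")
    temperature = 1.0 / math.log(n)
    loglik = _make_loglik(choices, rewards, model_id)
    dim = _n_params(model_id)

    def log_target_and_ll(x: np.ndarray) -> tuple[float, float]:
        p = _from_unconstrained(x, model_id)
        lp = priors.log_prior(p)
        if lp == -math.inf:
            return -math.inf, -math.inf
        # Jacobian of (logit, log, identity) transforms.
        if isinstance(p, SimpleParams):
            jac = math.log(p.alpha) + math.log1p(-p.alpha) + math.log(p.beta)
        else:
            jac = (
                math.log(p.alpha_plus)
                + math.log1p(-p.alpha_plus)
                + math.log(p.alpha_minus)
                + math.log1p(-p.alpha_minus)
                + math.log(p.beta)
            )
        ll = loglik(p)
        return temperature * ll + lp + jac, ll

    # Start from the prior center (alpha 0.5, beta at the prior mean or 3).
    beta0 = (
        priors.beta_shape * priors.beta_scale if math.isfinite(priors.beta_scale) else 3.0
    )
    x = np.zeros(dim)
    x[dim - 2 if dim == 4 else 1] = math.log(max(beta0, 0.1))
    cur_target, cur_ll = log_target_and_ll(x)
    total = mcmc.burn_in + mcmc.n_samples
    accepted = 0
    ll_sum = 0.0
    for step in range(total):
        prop = x + mcmc.proposal_scale * rng.standard_normal(dim)
        prop_target, prop_ll = log_target_and_ll(prop)
        if prop_target - cur_target >= math.log(rng.random()):
            x = prop
            cur_target, cur_ll = prop_target, prop_ll
            accepted += 1
        if step >= mcmc.burn_in:
            ll_sum += cur_ll
    acceptance = accepted / total
    if not (0.05 < acceptance < 0.95):
        warnings.warn(
            f"WBIC chain acceptance rate {acceptance:.3f} outside (0.05, 0.95); "
            "consider retuning proposal_scale",
            RuntimeWarning,
            stacklevel=2,
        )
    return WBICResult(
        model_id=model_id,
        wbic=ll_sum / mcmc.n_samples,
        temperature=temperature,
        n_samples=mcmc.n_samples,
        burn_in=mcmc.burn_in,
        acceptance_rate=acceptance,
        seed=seed,
    )


@dataclasses.dataclass(frozen=True)
class ModelComparison:
    statistic: float
    df: int
    p_value: float
    mean_simple: float
    mean_asymmetric: float


def _wbic_values(values: Sequence) -> np.ndarray:
    vals = np.asarray(
        [v.wbic if isinstance(v, WBICResult) else float(v) for v in values], dtype=float
    )
    if vals.size == 0:
        raise DataError("compare_models needs non-empty WBIC lists")
    return vals


def compare_models(wbic_simple: Sequence, wbic_asym: Sequence) -> ModelComparison:
    """Pooled-variance two-sample t-test on per-session WBIC values.

    Degrees of freedom are ``n1 + n2 - 2``.  Identical samples with zero
    pooled variance are reported as ``t = 0, p = 1``.
    """
    a = _wbic_values(wbic_simple)
    b = _wbic_values(wbic_asym)
    n1, n2 = a.size, b.size
    df = n1 + n2 - 2
    if df < 1:
        raise DataError("compare_models needs at least 3 values in total")
    v1 = a.var(ddof=1) if n1 > 1 else 0.0
    v2 = b.var(ddof=1) if n2 > 1 else 0.0
    pooled = ((n1 - 1) * v1 + (n2 - 1) * v2) / df
    se = math.sqrt(pooled * (1.0 / n1 + 1.0 / n2))
    diff = a.mean() - b.mean()
    if se == 0.0:
        t = 0.0 if diff == 0.0 else math.copysign(math.inf, diff)
    else:
        t = diff / se
    p = 1.0 if t == 0.0 else 2.0 * scipy.stats.t.sf(abs(t), df)
    return ModelComparison(
        statistic=float(t),
        df=df,
        p_value=float(min(p, 1.0)),
        mean_simple=float(a.mean()),
        mean_asymmetric=float(b.mean()),
    )
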