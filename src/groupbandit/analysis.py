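"""Group-size statistics: omnibus and pairwise rank tests, within-group
contrasts, positivity-bias tests, and identity-link Poisson regressions
of performance.

Performance is the count of rewarded trials in a session (points divide
by the per-win display value).  Between-condition comparisons use the
Kruskal-Wallis test followed by pairwise Wilcoxon rank-sum tests with
Bonferroni adjustment.  Within-group contrasts compare a group-level
quantity against an aggregate (max / min / mean) of its members'
individual values, as a two-sample rank test in its chi-square df = 1
form by default (a paired signed-rank variant is available, since the
vectors are naturally paired).  Regressions are Poisson GLMs with an
identity link, so coefficients live directly on the count scale.
"""

from __future__ import annotations

import dataclasses
import itertools
import math
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
from scipy.special import gammaln

from .errors import DataError, DesignError

__all__ = [
    "TestSummary",
    "RegressionTable",
    "performance",
    "kruskal_wallis",
    "pairwise_wilcoxon_bonferroni",
    "within_group_contrast",
    "positivity_bias_test",
    "poisson_regression",
    "REGRESSION_SPECS",
]


def performance(session) -> int:
    """Number of rewarded trials in a session."""
    rewards = np.asarray(session.rewards if hasattr(session, "rewards") else session)
    bad = np.setdiff1d(np.unique(rewards), [0, 1])
    if bad.size:
        raise DataError(f"non-binary rewards {bad.tolist()}")
    return int(rewards.sum())


@dataclasses.dataclass(frozen=True)
class TestSummary:
    """One hypothesis test's outcome."""

    name: str
    statistic: float
    df: int | None
    p_raw: float
    p_adjusted: float | None = None
    comparison: tuple[str, str] | None = None
    direction: str | None = None
    degenerate: bool = False

    def __post_init__(self) -> None:
        if self.p_adjusted is not None and self.p_adjusted < self.p_raw - 1e-15:
            raise DataError("adjusted p-value below raw p-value")


def _as_groups(samples) -> dict[str, np.ndarray]:
    if isinstance(samples, Mapping):
        items = samples.items()
    else:
        items = ((str(i + 1), s) for i, s in enumerate(samples))
    groups = {}
    for label, values in items:
        arr = np.asarray(values, dtype=float).ravel()
        if arr.size == 0:
            raise DataError(f"group {label!r} has no observations")
        groups[str(label)] = arr
    if len(groups) < 2:
        raise DataError("need at least 2 groups")
    return groups


def kruskal_wallis(samples) -> TestSummary:
    """Kruskal-Wallis H test (midrank tie correction, chi-square p)."""
    groups = _as_groups(samples)
    arrays = list(groups.values())
    df = len(arrays) - 1
    pooled = np.concatenate(arrays)
    if np.all(pooled == pooled[0]):
        return TestSummary("kruskal_wallis", 0.0, df, 1.0, degenerate=True)
    h, p = scipy.stats.kruskal(*arrays)
    return TestSummary("kruskal_wallis", float(h), df, float(p))


def _rank_sum_pair(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum p (exact for small tie-free samples)."""
    res = scipy.stats.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def pairwise_wilcoxon_bonferroni(samples) -> list[TestSummary]:
    """All pairwise rank-sum tests with Bonferroni-adjusted p-values."""
    groups = _as_groups(samples)
    pairs = list(itertools.combinations(groups, 2))
    m = len(pairs)
    out = []
    for a, b in pairs:
        x, y = groups[a], groups[b]
        if np.all(np.concatenate([x, y]) == x.flat[0]):
            stat, p = 0.0, 1.0
        else:
            stat, p = _rank_sum_pair(x, y)
        out.append(
            TestSummary(
                name="wilcoxon_rank_sum",
                statistic=stat,
                df=None,
                p_raw=p,
                p_adjusted=min(1.0, m * p),
                comparison=(a, b),
                direction=_direction(x, y, a, b),
            )
        )
    return out


def _direction(x: np.ndarray, y: np.ndarray, label_x: str, label_y: str) -> str | None:
    ranks = scipy.stats.rankdata(np.concatenate([x, y]))
    mx, my = ranks[: x.size].mean(), ranks[x.size :].mean()
    if mx == my:
        return None
    return f"{label_x}_higher" if mx > my else f"{label_y}_higher"


def within_group_contrast(
    group_values: Sequence[float],
    member_aggregate: Sequence[float],
    paired: bool = False,
    name: str = "within_group_contrast",
) -> TestSummary:
    """Compare group-level values with a member aggregate.

    Default is the two-sample rank test in its chi-square (df = 1) form:
    a Kruskal-Wallis test on the two vectors.  ``paired=True`` runs the
    Wilcoxon signed-rank test on the per-unit differences instead, which
    respects the natural pairing.
    """
    g = np.asarray(group_values, dtype=float).ravel()
    a = np.asarray(member_aggregate, dtype=float).ravel()
    if g.size != a.size:
        raise DataError(f"length mismatch: {g.size} group vs {a.size} aggregate values")
    if g.size == 0:
        raise DataError("empty contrast vectors")
    direction = _direction(g, a, "group", "aggregate")
    if paired:
        diff = g - a
        if np.all(diff == 0.0):
            return TestSummary(name, 0.0, None, 1.0, direction=None, degenerate=True)
        stat, p = scipy.stats.wilcoxon(diff, alternative="two-sided")
        return TestSummary(name, float(stat), None, float(p), direction=direction)
    pooled = np.concatenate([g, a])
    if np.all(pooled == pooled[0]):
        return TestSummary(name, 0.0, 1, 1.0, direction=None, degenerate=True)
    h, p = scipy.stats.kruskal(g, a)
    if p >= 0.999:
        direction = None
    return TestSummary(name, float(h), 1, float(p), direction=direction)


def positivity_bias_test(deltas: Sequence[float]) -> TestSummary:
    """One-sample signed-rank test of median positivity bias = 0."""
    d = np.asarray(deltas, dtype=float).ravel()
    if d.size == 0:
        raise DataError("positivity_bias_test needs a non-empty vector")
    if np.all(d == 0.0):
        return TestSummary("positivity_bias", 0.0, None, 1.0, degenerate=True)
    stat, p = scipy.stats.wilcoxon(d, alternative="two-sided")
    med = float(np.median(d))
    direction = "positive" if med > 0 else ("negative" if med < 0 else None)
    return TestSummary("positivity_bias", float(stat), None, float(p), direction=direction)


# -- Poisson regression ---------------------------------------------------

REGRESSION_SPECS = ("dummies1", "dummies2", "quadratic")

_MODEL_COVARIATES = {
    "simple": ("alpha", "beta"),
    "asymmetric": ("pos_bias", "beta", "phi"),
}


@dataclasses.dataclass(frozen=True)
class RegressionTable:
    """Identity-link Poisson GLM results."""

    params: pd.DataFrame  # index term, columns estimate/se/z/p
    aic: float
    log_likelihood: float
    spec: str
    link: str
    n: int
    converged: bool

    @property
    def coef(self) -> pd.Series:
        return self.params["estimate"]


def _design_matrix(
    records: pd.DataFrame, spec: str, covariates: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    n = len(records)
    cols: list[tuple[str, np.ndarray]] = [("const", np.ones(n))]
    for c in covariates:
        if c not in records.columns:
            raise DesignError(f"covariate column {c!r} missing from records")
        cols.append((c, records[c].to_numpy(dtype=float)))
    size = records["size"].to_numpy(dtype=float)
    if spec == "dummies1":  # dyad baseline
        cols.append(("individual", (size == 1).astype(float)))
        cols.append(("triad", (size == 3).astype(float)))
    elif spec == "dummies2":  # individual baseline
        cols.append(("dyad", (size == 2).astype(float)))
        cols.append(("triad", (size == 3).astype(float)))
    elif spec == "quadratic":
        cols.append(("size", size))
        cols.append(("size_sq", size**2))
    elif spec == "intercept":
        pass
    else:
        raise DesignError(f"unknown regression spec {spec!r}; expected one of "
                          f"{REGRESSION_SPECS + ('intercept',)}")
    names = [c[0] for c in cols]
    X = np.column_stack([c[1] for c in cols])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise DesignError(f"design matrix for spec {spec!r} is rank deficient")
    return X, names


def _poisson_identity_loglik(y: np.ndarray, mu: np.ndarray) -> float:
    return float(np.sum(y * np.log(mu) - mu - gammaln(y + 1.0)))


def poisson_regression(
    records: pd.DataFrame,
    spec: str = "quadratic",
    model_id: str | None = None,
    covariates: Sequence[str] | None = None,
    response: str = "performance",
    max_iter: int = 200,
    tol: float = 1e-10,
) -> RegressionTable:
    """Identity-link Poisson GLM of performance counts.

    Fitted by Fisher scoring (IRLS) with step-halving to keep all fitted
    means positive.  ``spec`` selects the group-size terms: ``dummies1``
    (individual and triad dummies, dyad baseline), ``dummies2`` (dyad and
    triad dummies, individual baseline), ``quadratic`` (size and size
    squared) or ``intercept`` (none).  ``covariates`` lists extra columns;
    when omitted, ``model_id`` supplies that model's learning parameters
    (``alpha``/``beta`` for simple, ``pos_bias``/``beta``/``phi`` for
    asymmetric).
    """
    if covariates is None:
        covariates = _MODEL_COVARIATES.get(model_id, ()) if model_id else ()
    y = records[response].to_numpy(dtype=float)
    if y.size == 0:
        raise DataError("empty records table")
    if np.any(y < 0) or np.any(y != np.round(y)):
        raise DataError("performance must hold non-negative integer counts")
    X, names = _design_matrix(records, spec, covariates)
    k = X.shape[1]

    # Start from OLS; fall back to a flat intercept if it predicts
    # non-positive means anywhere.
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    mu = X @ beta
    if np.any(mu <= 0):
        beta = np.zeros(k)
        beta[0] = max(y.mean(), 0.5)
        mu = X @ beta
    ll = _poisson_identity_loglik(y, np.maximum(mu, 1e-10))
    converged = False
    for _ in range(max_iter):
        w = 1.0 / mu
        fisher = X.T @ (X * w[:, None])
        score = X.T @ ((y - mu) * w)
        try:
            step = np.linalg.solve(fisher, score)
        except np.linalg.LinAlgError as exc:
            raise DesignError(f"singular Fisher information in spec {spec!r}") from exc
        lam = 1.0
        for _ in range(50):
            cand = beta + lam * step
            mu_c = X @ cand
            if np.all(mu_c > 0):
                ll_c = _poisson_identity_loglik(y, mu_c)
                if ll_c >= ll - 1e-9:
                    break
            lam *= 0.5
        else:
            converged = True  # no admissible improvement left
            break
        improvement = ll_c - ll
        beta, mu, ll = cand, mu_c, ll_c
        if abs(improvement) < tol and np.max(np.abs(lam * step)) < 1e-8:
            converged = True
            break

    w = 1.0 / mu
    fisher = X.T @ (X * w[:, None])
    cov = np.linalg.inv(fisher)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * scipy.stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {"estimate": beta, "se": se, "z": z, "p": p}, index=pd.Index(names, name="term")
    )
    aic = -2.0 * ll + 2.0 * k
    return RegressionTable(
        params=table,
        aic=float(aic),
        log_likelihood=float(ll),
        spec=spec,
        link="identity",
        n=int(y.size),
        converged=converged,
    )
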