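"""Independent reference implementations used only to cross-check the
package: a literal trial-by-trial likelihood loop built on numpy/scipy
primitives, and an exact rank-sum enumeration for tiny samples."""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.special import softmax


def loglik_bruteforce(choices, rewards, params: dict, model: str) -> float:
    """Trial-by-trial log-likelihood straight from the update equations."""
    q = np.zeros(2)
    ll = 0.0
    for c, r in zip(choices, rewards):
        p = softmax(params["beta"] * q)
        ll += math.log(p[c])
        d = r - q[c]
        if model == "simple":
            q[c] = q[c] + params["alpha"] * d
        else:
            rate = params["alpha_plus"] if d >= 0 else params["alpha_minus"]
            q[c] = q[c] + rate * d + params["phi"]
    return ll


def exact_ranksum_p(x, y) -> float:
    """Two-sided exact Wilcoxon rank-sum p-value by full enumeration.

    Valid for tie-free pooled samples; feasible for n + m <= ~12.
    """
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    assert len(set(pooled)) == len(pooled), "enumeration oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    n = len(x)
    observed = sum(ranks[v] for v in x)
    all_ranks = list(ranks.values())
    stats = [sum(c) for c in itertools.combinations(all_ranks, n)]
    mean = n * (len(pooled) + 1) / 2.0
    extreme = sum(abs(s - mean) >= abs(observed - mean) - 1e-12 for s in stats)
    return extreme / len(stats)
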