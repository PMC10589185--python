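"""Rank-based comparison tests and the non-inferiority bound.

The Mann-Whitney U test is implemented directly because its contract here
includes exact permutation enumeration (with midrank ties) for small
samples, falling back to the tie-corrected normal approximation with
continuity correction for larger ones.  Kruskal-Wallis delegates to scipy's
tie-corrected H statistic.  Non-inferiority of a test success proportion
against a reference uses a one-sided 95% lower Wald bound on the difference
minus the margin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb, sqrt

import numpy as np
from scipy import stats as sps

EXACT_LIMIT = 12  # pooled size at or below which the exact enumeration runs


@dataclass(frozen=True)
class RankTestResult:
    statistic: float
    p_value: float
    method: str


def _u_statistic(ranks: np.ndarray, n_x: int) -> float:
    """U for the first sample from pooled midranks: rank-sum minus n(n+1)/2."""
    return float(np.sum(ranks[:n_x]) - n_x * (n_x + 1) / 2.0)


def mann_whitney_u(x, y) -> RankTestResult:
    """Two-sided Mann-Whitney U test with midrank ties.

    Exact permutation p-value (all C(n+m, n) group assignments) when
    n + m <= 12; otherwise normal approximation with tie-corrected variance
    and a 0.5 continuity correction.  U is reported for the first sample
    (number of (x, y) pairs with x > y, ties counted half).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = len(x), len(y)
    if n < 1 or m < 1:
        raise ValueError("each sample needs at least one observation")
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    u_obs = _u_statistic(ranks, n)
    mean_u = n * m / 2.0

    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both samples; p = 1")
        return RankTestResult(u_obs, 1.0, "degenerate")

    if n + m <= EXACT_LIMIT:
        # enumerate every assignment of pooled ranks to the x-group
        indices = np.arange(n + m)
        total = comb(n + m, n)
        threshold = abs(u_obs - mean_u) - 1e-12
        extreme = 0
        for chosen in combinations(indices, n):
            u = float(np.sum(ranks[list(chosen)]) - n * (n + 1) / 2.0)
            if abs(u - mean_u) >= threshold:
                extreme += 1
        return RankTestResult(u_obs, extreme / total, "exact")

    # tie-corrected normal approximation
    big_n = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (big_n * (big_n - 1))
    var_u = n * m / 12.0 * ((big_n + 1) - tie_term)
    z = (u_obs - mean_u - 0.5 * np.sign(u_obs - mean_u)) / sqrt(var_u)
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return RankTestResult(u_obs, p, "normal")


def kruskal_wallis(groups) -> RankTestResult:
    """Tie-corrected Kruskal-Wallis H with a chi-square p (k-1 df)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("kruskal_wallis needs at least 2 groups")
    pooled = np.concatenate(groups)
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across groups; H = 0")
        return RankTestResult(0.0, 1.0, "degenerate")
    h, p = sps.kruskal(*groups)
    return RankTestResult(float(h), float(p), "chi-square")


@dataclass(frozen=True)
class NoninferiorityResult:
    lower_bound: float
    non_inferior: bool
    p_test: float
    p_ref: float
    margin: float
    z: float = 1.645


def _variance_part(successes: int, n: int) -> float:
    p = successes / n
    if p in (0.0, 1.0):
        # add-2 adjustment keeps the variance away from a degenerate zero
        p = (successes + 1) / (n + 2)
    return p * (1.0 - p) / n


def noninferiority_lower_bound(
    successes_test: int,
    n_test: int,
    successes_ref: int,
    n_ref: int,
    delta: float = -0.10,
) -> NoninferiorityResult:
    """One-sided 95% lower Wald bound on (p_test - p_ref - delta).

    ``delta`` is the non-inferiority margin as a (negative) proportion, e.g.
    -0.10 for a 10-point margin.  Non-inferiority is declared when the bound
    exceeds zero.
    """
    for s, n, name in ((successes_test, n_test, "test"), (successes_ref, n_ref, "reference")):
        if n <= 0:
            raise ValueError(f"{name} sample size must be positive")
        if not 0 <= s <= n:
            raise ValueError(f"{name} successes must lie in [0, n]")
    p_test = successes_test / n_test
    p_ref = successes_ref / n_ref
    z = 1.645
    se = sqrt(_variance_part(successes_test, n_test) + _variance_part(successes_ref, n_ref))
    bound = (p_test - p_ref - delta) - z * se
    return NoninferiorityResult(
        lower_bound=bound,
        non_inferior=bound > 0,
        p_test=p_test,
        p_ref=p_ref,
        margin=delta,
        z=z,
    )
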