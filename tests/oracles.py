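"""Brute-force oracles, independent of the library code paths they check.

Everything here enumerates exhaustively or uses closed forms; nothing calls
into the simulation or test routines under test.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter

import numpy as np


def uniform_partition_distribution(m: int, n: int) -> dict[tuple[int, ...], float]:
    """Distribution of sorted nonzero group sizes when m slugs each pick one
    of n anemones uniformly and independently (all n**m assignments)."""
    dist: dict[tuple[int, ...], float] = {}
    w = 1.0 / n**m
    for assignment in itertools.product(range(n), repeat=m):
        counts = np.bincount(assignment, minlength=n)
        key = tuple(sorted((int(c) for c in counts if c > 0), reverse=True))
        dist[key] = dist.get(key, 0.0) + w
    return dist


def crp_partition_distribution(m: int, alpha: float) -> dict[tuple[int, ...], float]:
    """Distribution of sorted group sizes under sequential CRP seating,
    enumerated over every seating decision path."""
    dist: dict[tuple[int, ...], float] = {}

    def rec(sizes: tuple[int, ...], prob: float, k: int) -> None:
        if k == m:
            key = tuple(sorted(sizes, reverse=True))
            dist[key] = dist.get(key, 0.0) + prob
            return
        denom = k + alpha
        for i in range(len(sizes)):
            rec(sizes[:i] + (sizes[i] + 1,) + sizes[i + 1 :], prob * sizes[i] / denom, k + 1)
        rec(sizes + (1,), prob * alpha / denom, k + 1)

    rec((1,), 1.0, 1)
    return dist


def crp_partition_probability_closed_form(sizes: tuple[int, ...], alpha: float) -> float:
    """Closed-form CRP probability of an (unordered) group-size multiset:
    EPPF times the number of set partitions with those block sizes."""
    m = sum(sizes)
    k = len(sizes)
    num = alpha**k * math.prod(math.factorial(s - 1) for s in sizes)
    den = math.prod(alpha + j for j in range(m))
    mult = math.factorial(m) / (
        math.prod(math.factorial(s) for s in sizes)
        * math.prod(math.factorial(c) for c in Counter(sizes).values())
    )
    return mult * num / den


def binomial_two_sided_pvalue(k: int, n: int, p: float) -> float:
    """Two-sided binomial p by direct enumeration of all n+1 outcomes
    (minimum-likelihood rule, with a relative tolerance for float ties)."""
    from scipy.stats import binom

    probs = binom.pmf(np.arange(n + 1), n, p)
    return float(probs[probs <= probs[k] * (1 + 1e-12)].sum())


def wilcoxon_exact_bruteforce(values, mu0: float) -> tuple[float, float]:
    """(V, two-sided exact p) by enumerating all 2^n sign patterns.

    Requires untied absolute deviations. Two-sided p is the probability,
    under random signs, of a positive-rank sum at least as far from its
    null mean n(n+1)/4 as the observed one.
    """
    d = np.asarray(values, dtype=float) - mu0
    d = d[d != 0]
    n = len(d)
    order = np.argsort(np.abs(d))
    ranks = np.empty(n)
    ranks[order] = np.arange(1, n + 1)
    v_obs = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    hits = 0
    for signs in itertools.product((0, 1), repeat=n):
        v = float(sum(r for r, s in zip(ranks, signs) if s))
        if abs(v - mu) >= abs(v_obs - mu) - 1e-12:
            hits += 1
    return v_obs, hits / 2**n
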