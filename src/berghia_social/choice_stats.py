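"""Statistical tests used on the choice-assay and group-feeding tables.

Three tests cover the published comparisons: the exact binomial proportion
test against chance (two-sided by the minimum-likelihood rule, with a
Clopper-Pearson or Jeffreys 95% interval on the proportion), Welch's
unequal-variance two-sample t-test, and the one-sample Wilcoxon signed-rank
test (normal approximation with continuity and tie corrections, effect size
r = z / sqrt(n); exact sign-flip enumeration available for small untied
samples).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportion_confint

from .trial_data import ChoiceRecord, choice_tallies

__all__ = [
    "BinomialResult",
    "TwoSampleResult",
    "SignedRankResult",
    "exact_binomial_test",
    "welch_t_test",
    "wilcoxon_one_sample",
    "log_latencies",
    "binomial_table",
]


@dataclass(frozen=True)
class BinomialResult:
    """Exact binomial test of k successes in n trials against ``p_null``."""

    k: int
    n: int
    p_null: float
    p_value: float
    ci_low: float
    ci_high: float
    ci_method: str

    @property
    def proportion(self) -> float:
        return self.k / self.n

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TwoSampleResult:
    """Welch two-sample t-test summary (fractional df by Welch-Satterthwaite)."""

    t_stat: float
    df: float
    p_value: float
    mean_a: float
    mean_b: float

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class SignedRankResult:
    """One-sample Wilcoxon signed-rank summary.

    ``statistic_V`` is the sum of the (mid)ranks of positive deviations from
    the tested location; at most n(n+1)/2, attained when every value lies
    above it.
    """

    statistic_V: float
    z: float
    p_value: float
    effect_size_r: float
    n_used: int
    method: str

    def to_dict(self) -> dict:
        return asdict(self)


def exact_binomial_test(
    k: int, n: int, p_null: float = 0.5, ci_method: str = "clopper-pearson"
) -> BinomialResult:
    """Two-sided exact binomial test with a 95% interval on the proportion.

    The p-value sums the probabilities of all outcomes no more likely than
    the observed one (the minimum-likelihood rule); at ``p_null = 0.5`` this
    coincides with doubling the smaller tail, capped at 1. The interval is
    Clopper-Pearson by default; ``ci_method="jeffreys"`` gives the Bayesian
    Jeffreys-prior interval instead (the p-value is unaffected).
    """
    if not 0 <= k <= n:
        raise ValueError(f"k={k} outside [0, n={n}]")
    if not 0 < p_null < 1:
        raise ValueError("p_null must be strictly between 0 and 1")
    res = stats.binomtest(k, n, p_null, alternative="two-sided")
    if ci_method == "clopper-pearson":
        ci = res.proportion_ci(confidence_level=0.95, method="exact")
        lo, hi = float(ci.low), float(ci.high)
    elif ci_method == "jeffreys":
        lo, hi = proportion_confint(k, n, alpha=0.05, method="jeffreys")
        lo, hi = float(lo), float(hi)
    else:
        raise ValueError("ci_method must be 'clopper-pearson' or 'jeffreys'")
    return BinomialResult(
        k=k, n=n, p_null=p_null, p_value=float(res.pvalue),
        ci_low=lo, ci_high=hi, ci_method=ci_method,
    )


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> TwoSampleResult:
    """Welch's t-test (unequal variances), two-sided.

    Degenerate samples with zero variance in both groups and equal means are
    reported as t = 0, p = 1 rather than an undefined ratio.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample must contain at least two values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return TwoSampleResult(
            t_stat=0.0, df=float(len(a) + len(b) - 2), p_value=1.0,
            mean_a=float(a.mean()), mean_b=float(b.mean()),
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    return TwoSampleResult(
        t_stat=float(res.statistic),
        df=float(res.df),
        p_value=float(res.pvalue),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
    )


def _exact_signed_rank_pvalue(ranks: np.ndarray, v: float) -> float:
    """Two-sided exact p over all sign patterns: P(|V - mu| >= |v - mu|).

    Ranks must be the integers 1..n (no ties). Dynamic programme over the
    distribution of the positive-rank sum.
    """
    n = len(ranks)
    total = n * (n + 1) // 2
    pmf = np.zeros(total + 1)
    pmf[0] = 1.0
    for r in range(1, n + 1):
        shifted = np.zeros_like(pmf)
        shifted[r:] = pmf[:-r]
        pmf = 0.5 * (pmf + shifted)
    mu = total / 2.0
    support = np.arange(total + 1)
    return float(pmf[np.abs(support - mu) >= abs(v - mu) - 1e-12].sum())


def wilcoxon_one_sample(
    values: Sequence[float], mu0: float = 0.5, method: str = "approx"
) -> SignedRankResult:
    """One-sample Wilcoxon signed-rank test of location ``mu0``.

    Values equal to ``mu0`` are dropped. ``method="approx"`` (default) uses
    the normal approximation with continuity correction and tie-corrected
    variance, midranks for tied absolute deviations, and reports the effect
    size r = z / sqrt(n). ``method="exact"`` enumerates the sign-flip
    distribution (n <= 25, no ties); its z and r are taken from the
    approximation for comparability.
    """
    d = np.asarray(values, dtype=float) - mu0
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all values equal mu0: no nonzero deviations to rank")
    ranks = stats.rankdata(np.abs(d))
    v = float(ranks[d > 0].sum())
    mu = n * (n + 1) / 4.0
    # tie-corrected variance of V under the symmetric null
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum() / 48.0
    sigma = np.sqrt(n * (n + 1) * (2 * n + 1) / 24.0 - tie_term)
    if sigma == 0:
        raise ValueError("zero variance: all absolute deviations tied at one rank")
    cc = 0.5 * np.sign(v - mu)
    z = (v - mu - cc) / sigma if v != mu else 0.0
    r = z / np.sqrt(n)
    if method == "approx":
        p = float(2 * stats.norm.sf(abs(z)))
        p = min(p, 1.0)
    elif method == "exact":
        if n > 25:
            raise ValueError("exact enumeration supported for n <= 25 only")
        if not np.allclose(np.sort(ranks), np.arange(1, n + 1)):
            raise ValueError("exact enumeration requires untied absolute deviations")
        p = _exact_signed_rank_pvalue(ranks, v)
    else:
        raise ValueError("method must be 'approx' or 'exact'")
    return SignedRankResult(
        statistic_V=v, z=float(z), p_value=p, effect_size_r=float(r),
        n_used=n, method=method,
    )


def log_latencies(latencies: Sequence[float]) -> np.ndarray:
    """Natural-log transform of choice latencies (normalising helper).

    Zero or negative latencies are rejected; location tests on latencies
    operate on this scale.
    """
    x = np.asarray(latencies, dtype=float)
    if (x <= 0).any():
        raise ValueError("latencies must be positive for the log transform")
    return np.log(x)


def binomial_table(
    records: Sequence[ChoiceRecord],
    p_null: float = 0.5,
    ci_method: str = "clopper-pearson",
) -> pd.DataFrame:
    """Exact binomial test for every assay condition in ``records``.

    One row per condition, in first-appearance order, with the tallies and
    the test summary (omitted trials excluded from counts).
    """
    tallies = choice_tallies(records)
    out = []
    for _, row in tallies.iterrows():
        res = exact_binomial_test(
            int(row["n_social"]), int(row["n_tested"]), p_null, ci_method
        )
        out.append(
            {
                **row.to_dict(),
                "proportion_social": res.proportion,
                "p_value": res.p_value,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
            }
        )
    return pd.DataFrame(out)
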