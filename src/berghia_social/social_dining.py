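"""Social dining model: Chinese-restaurant-process seating over finite prey.

Slugs are seated sequentially. With ``k`` slugs already feeding, the next
slug joins the group on occupied anemone ``i`` (current size ``m_i``) with
probability ``m_i / (k + alpha)`` and starts a new group with probability
``alpha / (k + alpha)``, the new anemone drawn uniformly from those still
unoccupied; the first slug seats uniformly at random. The denominator is
(number already seated) + alpha — the standard CRP normalisation, which is
the only reading under which the sequential probabilities sum to one. The
model assumes at least as many anemones as slugs (n >= m), so an unoccupied
anemone always exists.

Small concentration parameters produce strong aggregation (alpha -> 0 seats
everyone on one anemone); large ones approach independent singleton seating.
The concentration parameter is estimated by moment matching: bisection on
alpha until the Monte-Carlo expectation of the dataset statistic equals the
observed one, using common random numbers so the objective is a fixed,
monotone-decreasing function of alpha.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .null_model import STATISTICS, MonteCarloResult, NullConfig, OccupancyVector

__all__ = [
    "SDMConfig",
    "AlphaFit",
    "sdm_assign",
    "sdm_dataset_stats",
    "sdm_pvalue",
    "estimate_alpha",
]


@dataclass(frozen=True)
class SDMConfig:
    """Design of a social-dining-model Monte-Carlo run (see :class:`NullConfig`)."""

    alpha: float
    m: int
    n: int
    trials_per_dataset: int
    n_datasets: int = 100_000
    seed: int = 0
    feeders_per_trial: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError("alpha must be positive")
        for name in ("m", "n", "trials_per_dataset", "n_datasets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.m > self.n:
            raise ValueError(
                f"model assumption violated: m={self.m} slugs exceed n={self.n} anemones"
            )
        if self.feeders_per_trial is not None:
            object.__setattr__(self, "feeders_per_trial", tuple(self.feeders_per_trial))
            if len(self.feeders_per_trial) != self.trials_per_dataset:
                raise ValueError("feeders_per_trial length must equal trials_per_dataset")
            if any(not 1 <= f <= self.m for f in self.feeders_per_trial):
                raise ValueError("each feeders_per_trial entry must be in 1..m")

    def trial_sizes(self) -> tuple[int, ...]:
        return self.feeders_per_trial or (self.m,) * self.trials_per_dataset


@dataclass(frozen=True)
class AlphaFit:
    """Result of the bisection moment-matching fit of the concentration parameter."""

    alpha_hat: float
    target_stat: float
    achieved_stat: float
    statistic: str
    iterations: int
    bracket_lo: float
    bracket_hi: float
    tolerance: float
    n_datasets_per_eval: int
    seed: int
    converged: bool

    def to_dict(self) -> dict:
        return {
            "alpha_hat": self.alpha_hat,
            "target_stat": self.target_stat,
            "achieved_stat": self.achieved_stat,
            "statistic": self.statistic,
            "iterations": self.iterations,
            "bracket_lo": self.bracket_lo,
            "bracket_hi": self.bracket_hi,
            "tolerance": self.tolerance,
            "n_datasets_per_eval": self.n_datasets_per_eval,
            "seed": self.seed,
            "converged": self.converged,
        }

    def to_json(self, path: Optional[str | Path] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


def sdm_assign(
    m: int, n: int, alpha: float, rng: np.random.Generator
) -> OccupancyVector:
    """Seat ``m`` slugs over ``n`` labeled anemones by the sequential rule."""
    if not alpha > 0:
        raise ValueError("alpha must be positive")
    if m > n:
        raise ValueError(f"model assumption violated: m={m} > n={n}")
    counts = np.zeros(n, dtype=np.int64)
    counts[rng.integers(n)] = 1
    for k in range(1, m):
        u = rng.random() * (k + alpha)
        if u < k:  # join an occupied anemone w.p. proportional to occupancy
            idx = int(np.searchsorted(np.cumsum(counts), u, side="right"))
            counts[idx] += 1
        else:  # open a new group on a uniformly chosen empty anemone
            empty = np.flatnonzero(counts == 0)
            counts[empty[rng.integers(len(empty))]] = 1
    return OccupancyVector(counts)


def _crp_group_sizes(
    n_trials: int, m: int, alpha: float, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised CRP seating of ``m`` slugs in each of ``n_trials`` trials.

    Anemone identities are irrelevant to group-size statistics, so only the
    multiset of group sizes is tracked. Returns (group-size array of shape
    (n_trials, m), number of groups per trial).
    """
    counts = np.zeros((n_trials, m), dtype=np.int64)
    counts[:, 0] = 1
    n_groups = np.ones(n_trials, dtype=np.int64)
    for k in range(1, m):
        u = rng.random(n_trials) * (k + alpha)
        join = u < k
        cum = np.cumsum(counts, axis=1)
        idx = (u[:, None] >= cum).sum(axis=1)  # group hit by u, for joiners
        joiners = np.nonzero(join)[0]
        counts[joiners, idx[joiners]] += 1
        openers = np.nonzero(~join)[0]
        counts[openers, n_groups[openers]] = 1
        n_groups[openers] += 1
    return counts, n_groups


def _batch_stats(config: SDMConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    D, T = config.n_datasets, config.trials_per_dataset
    sizes = config.trial_sizes()
    means = np.empty((D, T))
    maxes = np.empty((D, T))
    by_size: dict[int, list[int]] = {}
    for j, s in enumerate(sizes):
        by_size.setdefault(s, []).append(j)
    for s, cols in sorted(by_size.items()):
        gs, ng = _crp_group_sizes(D * len(cols), s, config.alpha, rng)
        means[:, cols] = (s / ng).reshape(D, len(cols))
        maxes[:, cols] = gs.max(axis=1).reshape(D, len(cols))
    return means.mean(axis=1), maxes.mean(axis=1)


def sdm_dataset_stats(config: SDMConfig, rng: np.random.Generator) -> tuple[float, float]:
    """One simulated dataset; returns (mean_of_means, mean_of_max)."""
    one = replace(config, n_datasets=1)
    mean_s, max_s = _batch_stats(one, rng)
    return float(mean_s[0]), float(max_s[0])


def sdm_pvalue(observed: float, statistic: str, config: SDMConfig) -> MonteCarloResult:
    """Upper-tail Monte-Carlo probability of ``observed`` under the SDM.

    Same ``>=`` convention as :func:`berghia_social.null_model.null_pvalue`.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    rng = np.random.default_rng(config.seed)
    mean_s, max_s = _batch_stats(config, rng)
    sample = mean_s if statistic == "mean" else max_s
    p = float(np.count_nonzero(sample >= observed)) / config.n_datasets
    cfg = {
        "alpha": config.alpha,
        "m": config.m,
        "n": config.n,
        "trials_per_dataset": config.trials_per_dataset,
        "n_datasets": config.n_datasets,
        "seed": config.seed,
        "feeders_per_trial": list(config.feeders_per_trial)
        if config.feeders_per_trial
        else None,
    }
    return MonteCarloResult(
        observed_stat=float(observed),
        statistic=statistic,
        null_sample=sample,
        p_value=p,
        model="sdm",
        config=cfg,
    )


def _expectation(
    alpha: float,
    m: int,
    n: int,
    trials_per_dataset: int,
    n_datasets: int,
    seed: int,
    statistic: str,
    feeders_per_trial: Optional[Sequence[int]],
) -> float:
    cfg = SDMConfig(
        alpha=alpha,
        m=m,
        n=n,
        trials_per_dataset=trials_per_dataset,
        n_datasets=n_datasets,
        seed=seed,
        feeders_per_trial=tuple(feeders_per_trial) if feeders_per_trial else None,
    )
    # common random numbers: a fresh generator with the same seed every call
    mean_s, max_s = _batch_stats(cfg, np.random.default_rng(seed))
    return float((mean_s if statistic == "mean" else max_s).mean())


def estimate_alpha(
    target_stat: float,
    m: int,
    n: int,
    trials_per_dataset: int,
    n_datasets_per_eval: int = 10_000,
    tolerance: float = 1e-3,
    bracket: tuple[float, float] = (1e-6, 1e3),
    seed: int = 0,
    max_iterations: int = 100,
    statistic: str = "mean",
    feeders_per_trial: Optional[Sequence[int]] = None,
) -> AlphaFit:
    """Fit the concentration parameter by bisection moment matching.

    Bisects on alpha until the Monte-Carlo expectation of the chosen dataset
    statistic (default: dataset mean of per-trial mean group sizes, the
    headline statistic, whose expectation is strictly decreasing in alpha)
    is within ``tolerance`` of ``target_stat``. Every evaluation reuses the
    same random-number seed, making the objective deterministic in alpha.

    If the bracket cannot straddle the target, the fit is pinned at the
    nearer endpoint with ``converged=False``; running out of iterations also
    clears the flag.
    """
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    lo, hi = bracket
    if not 0 < lo < hi:
        raise ValueError("bracket must satisfy 0 < lo < hi")
    sizes = tuple(feeders_per_trial) if feeders_per_trial else (m,) * trials_per_dataset
    # attainable range of the mean statistic: alpha->inf gives all singletons
    # (stat 1), alpha->0 a single group per trial (stat mean of trial sizes)
    if statistic == "mean":
        upper = float(np.mean(sizes))
        if not 1.0 < target_stat < upper:
            raise ValueError(
                f"target {target_stat} outside the attainable range (1, {upper})"
            )

    def g(alpha: float) -> float:
        return _expectation(
            alpha, m, n, trials_per_dataset, n_datasets_per_eval, seed,
            statistic, feeders_per_trial,
        )

    g_lo, g_hi = g(lo), g(hi)
    iterations = 2
    if not (g_hi <= target_stat <= g_lo):  # expectation decreases in alpha
        pin = lo if abs(g_lo - target_stat) <= abs(g_hi - target_stat) else hi
        return AlphaFit(
            alpha_hat=pin,
            target_stat=target_stat,
            achieved_stat=g_lo if pin == lo else g_hi,
            statistic=statistic,
            iterations=iterations,
            bracket_lo=lo,
            bracket_hi=hi,
            tolerance=tolerance,
            n_datasets_per_eval=n_datasets_per_eval,
            seed=seed,
            converged=False,
        )
    mid, g_mid = lo, g_lo
    converged = False
    while iterations < max_iterations:
        mid = 0.5 * (lo + hi)
        g_mid = g(mid)
        iterations += 1
        if abs(g_mid - target_stat) <= tolerance:
            converged = True
            break
        if g_mid > target_stat:
            lo = mid
        else:
            hi = mid
    return AlphaFit(
        alpha_hat=mid,
        target_stat=target_stat,
        achieved_stat=g_mid,
        statistic=statistic,
        iterations=iterations,
        bracket_lo=bracket[0],
        bracket_hi=bracket[1],
        tolerance=tolerance,
        n_datasets_per_eval=n_datasets_per_eval,
        seed=seed,
        converged=converged,
    )
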