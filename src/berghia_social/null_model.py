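"""Independent-choice null model for feeding-group formation.

Under the null hypothesis each slug selects one of the ``n`` anemones
independently and uniformly, P(slug selects anemone i) = 1/n. A simulated
trial is one such assignment; its statistics are the mean group size over
occupied anemones and the maximum occupancy. A simulated *dataset* is a set
of trials matching the experimental design, summarised by the dataset mean
of the per-trial mean (or maximum) group sizes. Monte-Carlo tail
probabilities compare an observed dataset statistic against many simulated
datasets with a ``>=`` (same-or-larger) convention and no pseudo-count, so
a p-value of exactly 0 is possible.

By default each simulated trial assigns only the number of slugs observed
actively feeding in the corresponding experimental trial
(``feeders_per_trial``); non-feeding slugs carry no information about prey
choice, and the published tail probabilities are reproduced only under this
conditioning. Setting ``feeders_per_trial=None`` assigns all ``m`` slugs in
every trial (sensitivity variant).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "NullConfig",
    "OccupancyVector",
    "MonteCarloResult",
    "STATISTICS",
    "assign_uniform",
    "group_statistics",
    "simulate_dataset_stats",
    "null_pvalue",
    "exact_null_distribution",
    "expected_stats",
]

#: Dataset-level statistics: dataset mean of per-trial mean / max group size.
STATISTICS = ("mean", "max")

_ENUM_GUARD = 10**7


@dataclass(frozen=True)
class NullConfig:
    """Design of a null-model Monte-Carlo run.

    ``m`` and ``n`` are slugs and anemones per trial; ``feeders_per_trial``
    optionally fixes, per trial, how many of the ``m`` slugs feed (length
    must equal ``trials_per_dataset``; each entry in 1..m).
    """

    m: int
    n: int
    trials_per_dataset: int
    n_datasets: int = 100_000
    seed: int = 0
    feeders_per_trial: Optional[tuple[int, ...]] = None

    def __post_init__(self) -> None:
        for name in ("m", "n", "trials_per_dataset", "n_datasets"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if self.feeders_per_trial is not None:
            object.__setattr__(self, "feeders_per_trial", tuple(self.feeders_per_trial))
            if len(self.feeders_per_trial) != self.trials_per_dataset:
                raise ValueError(
                    "feeders_per_trial length must equal trials_per_dataset"
                )
            if any(not 1 <= f <= self.m for f in self.feeders_per_trial):
                raise ValueError("each feeders_per_trial entry must be in 1..m")

    def trial_sizes(self) -> tuple[int, ...]:
        return self.feeders_per_trial or (self.m,) * self.trials_per_dataset


@dataclass(frozen=True)
class OccupancyVector:
    """Per-anemone predator counts for one simulated trial."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=np.int64)
        if c.ndim != 1 or (c < 0).any():
            raise ValueError("counts must be a 1-D vector of non-negative integers")
        object.__setattr__(self, "counts", c)

    @property
    def n_feeding(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class MonteCarloResult:
    """Observed statistic, simulated null sample, and upper-tail probability.

    ``p_value`` is the fraction of simulated dataset statistics that are
    ``>=`` the observed one (no add-one correction; may be exactly 0).
    """

    observed_stat: float
    statistic: str
    null_sample: np.ndarray
    p_value: float
    model: str
    config: dict

    def to_dict(self, include_sample: bool = False) -> dict:
        d = {
            "observed_stat": self.observed_stat,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "model": self.model,
            "n_datasets": int(len(self.null_sample)),
            "null_sample_mean": float(np.mean(self.null_sample)),
            "null_sample_sd": float(np.std(self.null_sample, ddof=1)),
            "config": self.config,
        }
        if include_sample:
            d["null_sample"] = np.asarray(self.null_sample).tolist()
        return d

    def to_json(self, path: Optional[str | Path] = None, include_sample: bool = False) -> str:
        text = json.dumps(self.to_dict(include_sample=include_sample), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    def histogram_csv(self, path: str | Path, bins: int = 50) -> None:
        """Write a fixed-width histogram of the null sample (bin_left, count)."""
        counts, edges = np.histogram(self.null_sample, bins=bins)
        with open(path, "w") as fh:
            fh.write("bin_left,bin_right,count\n")
            for lo, hi, c in zip(edges[:-1], edges[1:], counts):
                fh.write(f"{lo},{hi},{c}\n")


def assign_uniform(m: int, n: int, rng: np.random.Generator) -> OccupancyVector:
    """Assign ``m`` slugs independently and uniformly among ``n`` anemones."""
    if m < 1 or n < 1:
        raise ValueError("m and n must be positive")
    counts = rng.multinomial(m, np.full(n, 1.0 / n))
    return OccupancyVector(counts)


def group_statistics(occ: OccupancyVector | np.ndarray) -> tuple[float, int]:
    """(mean group size over occupied anemones, largest group size)."""
    counts = occ.counts if isinstance(occ, OccupancyVector) else np.asarray(occ)
    total = counts.sum()
    if total == 0:
        raise ValueError("no feeding groups: occupancy vector is all zero")
    occupied = int(np.count_nonzero(counts))
    return float(total) / occupied, int(counts.max())


def _batch_stats(config: NullConfig, rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Simulate all datasets at once; returns the two dataset-statistic vectors."""
    D, T, n = config.n_datasets, config.trials_per_dataset, config.n
    sizes = config.trial_sizes()
    p = np.full(n, 1.0 / n)
    means = np.empty((D, T))
    maxes = np.empty((D, T))
    # group trials by feeder count so each multinomial call is one batch
    by_size: dict[int, list[int]] = {}
    for j, s in enumerate(sizes):
        by_size.setdefault(s, []).append(j)
    for s, cols in sorted(by_size.items()):
        c = rng.multinomial(s, p, size=(D, len(cols)))
        occupied = np.count_nonzero(c, axis=2)
        means[:, cols] = s / occupied
        maxes[:, cols] = c.max(axis=2)
    return means.mean(axis=1), maxes.mean(axis=1)


def simulate_dataset_stats(
    config: NullConfig, rng: np.random.Generator
) -> tuple[float, float]:
    """One simulated dataset; returns (mean_of_means, mean_of_max)."""
    one = replace(config, n_datasets=1)
    mean_s, max_s = _batch_stats(one, rng)
    return float(mean_s[0]), float(max_s[0])


def null_pvalue(observed: float, statistic: str, config: NullConfig) -> MonteCarloResult:
    """Upper-tail Monte-Carlo probability of ``observed`` under the null.

    ``statistic`` is ``"mean"`` (dataset mean of per-trial mean group sizes)
    or ``"max"`` (dataset mean of per-trial maximum group sizes).
    """
    if statistic not in STATISTICS:
        raise ValueError(f"statistic must be one of {STATISTICS}")
    rng = np.random.default_rng(config.seed)
    mean_s, max_s = _batch_stats(config, rng)
    sample = mean_s if statistic == "mean" else max_s
    p = float(np.count_nonzero(sample >= observed)) / config.n_datasets
    cfg = {
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
        model="null",
        config=cfg,
    )


def exact_null_distribution(m: int, n: int) -> dict[tuple[float, int], float]:
    """Exhaustive distribution of (mean_group, max_group) under uniform choice.

    Enumerates all ``n**m`` equiprobable assignments; intended as a
    brute-force oracle for small problems (guarded at ``n**m <= 1e7``).
    """
    if m < 1 or n < 1:
        raise ValueError("m and n must be positive")
    if n**m > _ENUM_GUARD:
        raise ValueError(
            f"n**m = {n**m} exceeds the enumeration guard ({_ENUM_GUARD}); "
            "use Monte-Carlo simulation instead"
        )
    dist: dict[tuple[float, int], float] = {}
    weight = 1.0 / n**m
    for assignment in itertools.product(range(n), repeat=m):
        counts = np.bincount(assignment, minlength=n)
        key = group_statistics(counts)
        dist[key] = dist.get(key, 0.0) + weight
    return dist


def expected_stats(dist: dict[tuple[float, int], float]) -> tuple[float, float]:
    """(E[mean_group], E[max_group]) of an exact distribution."""
    e_mean = sum(k[0] * p for k, p in dist.items())
    e_max = sum(k[1] * p for k, p in dist.items())
    return float(e_mean), float(e_max)
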