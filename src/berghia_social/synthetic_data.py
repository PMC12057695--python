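"""Generators for study-shaped synthetic data with known ground truth.

Three generators mirror the three experimental designs: group-feeding
trials (``m`` slugs over ``n`` anemones seated by either the uniform null
or the social dining model, with independent per-slug non-feeding),
two-alternative choice records (Bernoulli outcomes), and per-individual
repeated-choice scores (Beta-Bernoulli, with a heterogeneity dial for
between-individual preference variation). All outputs are deterministic
functions of their spec, including the seed.

Non-feeding is modelled as independent thinning of the slugs before
seating — a modelling convenience (the experiments record non-feeders but
no mechanism), not a claim about the animals. Synthetic max group size is
the endpoint maximum occupancy, consistent with the simulation models.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .null_model import assign_uniform, group_statistics
from .social_dining import sdm_assign
from .trial_data import ChoiceRecord, FeedingTrial, TrialDataset

__all__ = [
    "GroupGenSpec",
    "ChoiceGenSpec",
    "ScoreGenSpec",
    "gen_group_trials",
    "gen_choice_records",
    "gen_individual_scores",
    "write_spec_sidecar",
]


@dataclass(frozen=True)
class GroupGenSpec:
    """Spec for synthetic group-feeding trials.

    ``model`` is ``"null"`` (uniform independent choice) or ``"sdm"``
    (CRP seating, requires ``alpha`` and ``n >= m``). ``feeding_prob`` is
    the per-slug probability of feeding at the endpoint (1 = everyone
    feeds, matching the models' own assumption).
    """

    model: str
    m: int = 8
    n: int = 8
    n_trials: int = 15
    feeding_prob: float = 1.0
    alpha: Optional[float] = None
    deprivation_days: int = 7
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in ("null", "sdm"):
            raise ValueError("model must be 'null' or 'sdm'")
        if self.model == "sdm":
            if self.alpha is None or self.alpha <= 0:
                raise ValueError("model='sdm' requires a positive alpha")
            if self.m > self.n:
                raise ValueError("model='sdm' requires n >= m")
        elif self.alpha is not None:
            raise ValueError("alpha is only meaningful for model='sdm'")
        if not 0 < self.feeding_prob <= 1:
            raise ValueError("feeding_prob must be in (0, 1]")
        for name in ("m", "n", "n_trials"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ChoiceGenSpec:
    """Spec for synthetic two-alternative choice records."""

    p_social: float = 0.5
    n_records: int = 24
    assay: str = "FC"
    deprivation_days: int = 7
    acclimation: str = "ASW"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.p_social <= 1:
            raise ValueError("p_social must be in [0, 1]")
        if self.n_records < 1:
            raise ValueError("n_records must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class ScoreGenSpec:
    """Spec for per-individual repeated-choice scores.

    Each individual draws a social-choice probability once — shared
    p = 0.5 at ``heterogeneity = 0``, otherwise from a symmetric Beta with
    total concentration ``1/heterogeneity`` (large heterogeneity pushes
    individual preferences towards 0 or 1, i.e. a bimodal score
    distribution) — then makes ``n_tests`` independent choices.
    """

    n_individuals: int = 24
    n_tests: int = 4
    heterogeneity: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be positive")
        if self.n_tests < 0:
            raise ValueError("n_tests must be non-negative")
        if self.heterogeneity < 0:
            raise ValueError("heterogeneity must be non-negative")

    def to_dict(self) -> dict:
        return asdict(self)


def gen_group_trials(spec: GroupGenSpec) -> TrialDataset:
    """Simulate a dataset of group-feeding trials under a known model.

    Each trial thins the ``m`` slugs by ``feeding_prob``, seats the feeders
    by the chosen model, and records the endpoint mean and maximum group
    sizes plus the non-feeder count. A trial in which no slug feeds is kept,
    with missing group statistics.
    """
    rng = np.random.default_rng(spec.seed)
    trials = []
    for tid in range(1, spec.n_trials + 1):
        feeders = (
            spec.m
            if spec.feeding_prob == 1.0
            else int(rng.binomial(spec.m, spec.feeding_prob))
        )
        if feeders == 0:
            mean_g, max_g = None, None
        else:
            if spec.model == "null":
                occ = assign_uniform(feeders, spec.n, rng)
            else:
                occ = sdm_assign(feeders, spec.n, spec.alpha, rng)
            mean_g, max_g = group_statistics(occ)
        trials.append(
            FeedingTrial(
                trial_id=tid,
                deprivation_days=spec.deprivation_days,
                n_slugs=spec.m,
                n_anemones=spec.n,
                max_group_size=max_g,
                mean_group_size=mean_g,
                n_not_feeding=spec.m - feeders,
            )
        )
    return TrialDataset(f"synthetic_{spec.model}", tuple(trials))


def gen_choice_records(spec: ChoiceGenSpec) -> list[ChoiceRecord]:
    """Independent Bernoulli(p_social) choice outcomes."""
    rng = np.random.default_rng(spec.seed)
    draws = rng.random(spec.n_records) < spec.p_social
    return [
        ChoiceRecord(
            assay=spec.assay,
            deprivation_days=spec.deprivation_days,
            acclimation=spec.acclimation,
            chose_social=bool(b),
        )
        for b in draws
    ]


def gen_individual_scores(spec: ScoreGenSpec) -> pd.DataFrame:
    """Per-individual social-choice counts over repeated tests.

    Returns a table with columns ``individual``, ``true_p`` (the latent
    per-individual social-choice probability) and ``score`` (0..n_tests).
    """
    rng = np.random.default_rng(spec.seed)
    if spec.heterogeneity == 0:
        p = np.full(spec.n_individuals, 0.5)
    else:
        a = 1.0 / (2.0 * spec.heterogeneity)  # symmetric Beta(a, a)
        p = rng.beta(a, a, size=spec.n_individuals)
    if spec.n_tests == 0:
        scores = np.zeros(spec.n_individuals, dtype=int)
    else:
        scores = rng.binomial(spec.n_tests, p)
    return pd.DataFrame(
        {
            "individual": np.arange(1, spec.n_individuals + 1),
            "true_p": p,
            "score": scores,
        }
    )


def write_spec_sidecar(spec, path: str | Path) -> Path:
    """Write a generator spec next to its output file for provenance."""
    path = Path(path)
    sidecar = path.with_suffix(path.suffix + ".spec.json")
    sidecar.write_text(json.dumps(spec.to_dict(), indent=2) + "\n")
    return sidecar
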