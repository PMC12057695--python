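"""Domain types and I/O for group-feeding trials and two-alternative choice assays.

The group-feeding (GF) assay places ``m`` food-deprived *Berghia stephanieae*
in an arena with ``n`` equally spaced *Exaiptasia diaphana* anemones at a 1:1
predator:prey ratio. Each trial is summarised by two scalars — the largest
co-feeding group observed at any point during the trial (``max_group_size``)
and the mean size of the groups actively feeding at the trial endpoint
(``mean_group_size``) — plus the number of slugs not feeding at the endpoint.

Choice assays offer a single slug two anemones differing by one manipulated
cue (slime trail, feeding conspecific, injury); the tables record, per assay
condition, how many slugs selected the "social" option and how many trials
were omitted because no choice was made.

The study's published trial tables ship as package fixtures; see
:func:`load_packaged_trials` and :func:`load_packaged_choices`.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, asdict, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FeedingTrial",
    "TrialDataset",
    "DatasetSummary",
    "ChoiceRecord",
    "ASSAY_CODES",
    "ACCLIMATION_MEDIA",
    "load_trials",
    "write_trials",
    "summarize",
    "load_choices",
    "write_choices",
    "choice_tallies",
    "load_packaged_trials",
    "load_packaged_choices",
    "packaged_trials_path",
    "packaged_choices_path",
]

#: Valid two-alternative choice assay codes: slime trail, feeding conspecific,
#: both, bisected anemone, "munched" (conspecific-injured) anemone.
ASSAY_CODES = ("ST", "FC", "ST+FC", "BA", "MA")

#: Acclimation media: plain artificial seawater or anemone-treated water.
ACCLIMATION_MEDIA = ("ASW", "ATW")

_TRIAL_COLUMNS = (
    "trial_id",
    "deprivation_days",
    "n_slugs",
    "n_anemones",
    "max_group_size",
    "mean_group_size",
    "n_not_feeding",
)

_CHOICE_COLUMNS = (
    "assay",
    "deprivation_days",
    "acclimation",
    "n_tested",
    "n_social",
    "n_omitted",
)


class TrialDataError(ValueError):
    """Raised when a trial or choice table cannot be loaded or validated."""


@dataclass(frozen=True)
class FeedingTrial:
    """One group-feeding arena trial (one row of the published trial table).

    ``max_group_size`` and ``mean_group_size`` may be ``None`` only for
    synthetic trials in which no slug fed (the published table has none).
    """

    trial_id: int
    deprivation_days: int
    n_slugs: int
    n_anemones: int
    max_group_size: Optional[int]
    mean_group_size: Optional[float]
    n_not_feeding: int

    def __post_init__(self) -> None:
        if self.n_slugs < 1 or self.n_anemones < 1:
            raise TrialDataError(
                f"trial {self.trial_id}: slug and anemone counts must be positive"
            )
        if not 0 <= self.n_not_feeding <= self.n_slugs:
            raise TrialDataError(
                f"trial {self.trial_id}: n_not_feeding={self.n_not_feeding} "
                f"outside [0, n_slugs={self.n_slugs}]"
            )
        if (self.max_group_size is None) != (self.mean_group_size is None):
            raise TrialDataError(
                f"trial {self.trial_id}: group statistics must be jointly "
                "present or jointly missing"
            )
        if self.max_group_size is None:
            if self.n_not_feeding != self.n_slugs:
                raise TrialDataError(
                    f"trial {self.trial_id}: missing group statistics are only "
                    "valid when no slug fed"
                )
            return
        if not 1 <= self.max_group_size <= self.n_slugs:
            raise TrialDataError(
                f"trial {self.trial_id}: max_group_size={self.max_group_size} "
                f"outside [1, n_slugs={self.n_slugs}]"
            )
        if self.n_not_feeding < self.n_slugs and self.mean_group_size < 1:
            raise TrialDataError(
                f"trial {self.trial_id}: mean_group_size={self.mean_group_size} < 1 "
                "with at least one feeding slug"
            )
        # The published table contains one trial whose whole-trial maximum is
        # smaller than its endpoint mean (max recorded over time, mean at the
        # endpoint only). Preserve such rows verbatim; warn, never reject.
        if self.max_group_size < self.mean_group_size:
            warnings.warn(
                f"trial {self.trial_id}: max_group_size ({self.max_group_size}) < "
                f"mean_group_size ({self.mean_group_size}); kept as printed "
                "(max is over-time, mean is endpoint-only)",
                stacklevel=2,
            )

    @property
    def n_feeding(self) -> int:
        """Number of slugs actively feeding at the trial endpoint."""
        return self.n_slugs - self.n_not_feeding


@dataclass(frozen=True)
class TrialDataset:
    """An ordered, non-empty collection of feeding trials under one label."""

    label: str
    trials: tuple[FeedingTrial, ...]

    def __post_init__(self) -> None:
        if not self.trials:
            raise TrialDataError(f"dataset {self.label!r} is empty")
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            raise TrialDataError(f"dataset {self.label!r} has duplicate trial_ids")

    def __len__(self) -> int:
        return len(self.trials)

    def subset(self, deprivation_days: int, label: Optional[str] = None) -> "TrialDataset":
        """Trials for one food-deprivation condition, order preserved."""
        kept = tuple(t for t in self.trials if t.deprivation_days == deprivation_days)
        return TrialDataset(label or f"{deprivation_days}-day", kept)

    @property
    def mean_group_sizes(self) -> np.ndarray:
        return np.array([t.mean_group_size for t in self.trials], dtype=float)

    @property
    def max_group_sizes(self) -> np.ndarray:
        return np.array([t.max_group_size for t in self.trials], dtype=float)

    @property
    def feeders_per_trial(self) -> tuple[int, ...]:
        """Endpoint feeder count per trial (slugs minus non-feeders)."""
        return tuple(t.n_feeding for t in self.trials)


@dataclass(frozen=True)
class DatasetSummary:
    """Column-wise aggregates of per-trial group-size statistics.

    Standard deviations use the sample (n−1) convention; a single-trial
    dataset reports them as NaN. Medians use the midpoint convention for
    even n.
    """

    label: str
    n_trials: int
    mean_of_means: float
    median_of_means: float
    sd_of_means: float
    mean_of_max: float
    median_of_max: float
    sd_of_max: float

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, path: Optional[str | Path] = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text


@dataclass(frozen=True)
class ChoiceRecord:
    """One two-alternative choice trial.

    ``chose_social`` is ``True``/``False`` for a completed trial and ``None``
    for an omitted one (no choice within the cutoff); omitted trials are
    excluded from test counts. Latency and anemone diameters are optional —
    the published tables do not print them per trial.
    """

    assay: str
    deprivation_days: int
    acclimation: str
    chose_social: Optional[bool]
    latency_s: Optional[float] = None
    chosen_diameter_cm: Optional[float] = None
    other_diameter_cm: Optional[float] = None

    def __post_init__(self) -> None:
        if self.assay not in ASSAY_CODES:
            raise TrialDataError(
                f"unknown assay code {self.assay!r}; valid codes: {', '.join(ASSAY_CODES)}"
            )
        if self.acclimation not in ACCLIMATION_MEDIA:
            raise TrialDataError(
                f"unknown acclimation {self.acclimation!r}; valid: {', '.join(ACCLIMATION_MEDIA)}"
            )
        if self.latency_s is not None and self.latency_s < 0:
            raise TrialDataError("latency_s must be non-negative")
        for name in ("chosen_diameter_cm", "other_diameter_cm"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise TrialDataError(f"{name} must be positive when present")


def _read_csv(path: str | Path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise TrialDataError(f"{path}: empty file") from exc
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise TrialDataError(f"{path}: missing column(s) {', '.join(missing)}")
    return df


def _require_number(df: pd.DataFrame, col: str, path: Path) -> pd.Series:
    s = pd.to_numeric(df[col], errors="coerce")
    bad = s.isna() & df[col].notna()
    if bad.any():
        row = int(bad.idxmax())
        raise TrialDataError(
            f"{path}: non-numeric value {df[col][row]!r} in column {col!r}, row {row}"
        )
    return s


def load_trials(path: str | Path, label: Optional[str] = None) -> TrialDataset:
    """Read a group-feeding trial table (CSV, one row per trial).

    Requires the seven columns of :class:`FeedingTrial`. Rows where the
    whole-trial max is below the endpoint mean load with a warning; rows with
    missing/non-numeric cells raise :class:`TrialDataError` naming the
    offending row and column. Row order is preserved.
    """
    path = Path(path)
    df = _read_csv(path, _TRIAL_COLUMNS)
    if len(df) == 0:
        raise TrialDataError(f"{path}: no trial rows")
    cols = {c: _require_number(df, c, path) for c in _TRIAL_COLUMNS}
    trials = []
    for i in range(len(df)):
        vals = {c: cols[c][i] for c in _TRIAL_COLUMNS}
        missing_stats = pd.isna(vals["max_group_size"]) and pd.isna(vals["mean_group_size"])
        for c in _TRIAL_COLUMNS:
            if pd.isna(vals[c]) and not (
                missing_stats and c in ("max_group_size", "mean_group_size")
            ):
                raise TrialDataError(f"{path}: missing value in column {c!r}, row {i}")
        trials.append(
            FeedingTrial(
                trial_id=int(vals["trial_id"]),
                deprivation_days=int(vals["deprivation_days"]),
                n_slugs=int(vals["n_slugs"]),
                n_anemones=int(vals["n_anemones"]),
                max_group_size=None if missing_stats else int(vals["max_group_size"]),
                mean_group_size=None if missing_stats else float(vals["mean_group_size"]),
                n_not_feeding=int(vals["n_not_feeding"]),
            )
        )
    return TrialDataset(label or path.stem, tuple(trials))


def write_trials(dataset: TrialDataset, path: str | Path) -> None:
    """Write a trial table in the CSV schema :func:`load_trials` reads."""
    rows = []
    for t in dataset.trials:
        d = asdict(t)
        rows.append(d)
    df = pd.DataFrame(rows, columns=list(_TRIAL_COLUMNS))
    # integers stay integers; the mean column is the only float one
    df.to_csv(path, index=False)


def summarize(dataset: TrialDataset) -> DatasetSummary:
    """Aggregate per-trial group-size statistics for one dataset.

    Trials without group statistics (synthetic zero-feeder trials) are
    excluded from the aggregates.
    """
    fed = [t for t in dataset.trials if t.mean_group_size is not None]
    if not fed:
        raise TrialDataError(f"dataset {dataset.label!r} has no trials with feeding slugs")
    means = np.array([t.mean_group_size for t in fed], dtype=float)
    maxes = np.array([t.max_group_size for t in fed], dtype=float)

    def _sd(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1)) if len(x) > 1 else float("nan")

    return DatasetSummary(
        label=dataset.label,
        n_trials=len(fed),
        mean_of_means=float(means.mean()),
        median_of_means=float(np.median(means)),
        sd_of_means=_sd(means),
        mean_of_max=float(maxes.mean()),
        median_of_max=float(np.median(maxes)),
        sd_of_max=_sd(maxes),
    )


def load_choices(path: str | Path) -> list[ChoiceRecord]:
    """Read a choice-assay table (CSV, one row per assay condition).

    The table mirrors the published format: assay code, deprivation days,
    acclimation medium, sample size, social selections, omitted trials. Each
    row is expanded to individual :class:`ChoiceRecord` objects (``n_social``
    social choices, ``n_tested − n_social`` non-social, ``n_omitted``
    no-choice records), so per-assay tallies are reconstructible.
    """
    path = Path(path)
    df = _read_csv(path, _CHOICE_COLUMNS)
    records: list[ChoiceRecord] = []
    for i, row in df.iterrows():
        assay = str(row["assay"])
        if assay not in ASSAY_CODES:
            raise TrialDataError(
                f"{path}: unknown assay code {assay!r} in row {i}; "
                f"valid codes: {', '.join(ASSAY_CODES)}"
            )
        n = int(row["n_tested"])
        k = int(row["n_social"])
        omitted = int(row["n_omitted"])
        if not 0 <= k <= n:
            raise TrialDataError(f"{path}: row {i}: n_social outside [0, n_tested]")
        common = dict(
            assay=assay,
            deprivation_days=int(row["deprivation_days"]),
            acclimation=str(row["acclimation"]),
        )
        records.extend(ChoiceRecord(chose_social=True, **common) for _ in range(k))
        records.extend(ChoiceRecord(chose_social=False, **common) for _ in range(n - k))
        records.extend(ChoiceRecord(chose_social=None, **common) for _ in range(omitted))
    return records


def choice_tallies(records: Iterable[ChoiceRecord]) -> pd.DataFrame:
    """Per-condition tallies (n_tested, n_social, n_omitted) from records.

    Conditions absent from ``records`` simply do not appear (zero counts).
    Rows are ordered by first appearance, matching the source table.
    """
    order: list[tuple] = []
    tally: dict[tuple, list[int]] = {}
    for r in records:
        key = (r.assay, r.deprivation_days, r.acclimation)
        if key not in tally:
            tally[key] = [0, 0, 0]
            order.append(key)
        if r.chose_social is None:
            tally[key][2] += 1
        else:
            tally[key][0] += 1
            tally[key][1] += int(r.chose_social)
    rows = [
        dict(
            assay=k[0],
            deprivation_days=k[1],
            acclimation=k[2],
            n_tested=tally[k][0],
            n_social=tally[k][1],
            n_omitted=tally[k][2],
        )
        for k in order
    ]
    return pd.DataFrame(rows, columns=list(_CHOICE_COLUMNS))


def write_choices(records: Iterable[ChoiceRecord], path: str | Path) -> None:
    """Write the per-condition tally table :func:`load_choices` reads."""
    choice_tallies(records).to_csv(path, index=False)


def _data_path(name: str) -> Path:
    return Path(str(resources.files("berghia_social.data").joinpath(name)))


def packaged_trials_path() -> Path:
    """Path of the packaged group-feeding trial table (28 trials)."""
    return _data_path("group_feeding_trials.csv")


def packaged_choices_path() -> Path:
    """Path of the packaged choice-assay table (10 assay conditions)."""
    return _data_path("choice_assays.csv")


def load_packaged_trials() -> TrialDataset:
    """The study's 28 group-feeding trials (15 seven-day, 13 three-day)."""
    return load_trials(packaged_trials_path(), label="group_feeding")


def load_packaged_choices() -> list[ChoiceRecord]:
    """The study's two-alternative choice assay outcomes, as records."""
    return load_choices(packaged_choices_path())
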