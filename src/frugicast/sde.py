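"""Seed dispersal effectiveness (SDE) from field-style tables.

SDE for a frugivore–plant pair is the product of a quantitative component
(qSDE: seeds dispersed per 10 observation hours, itself the product of the
visitation rate and the mean seed load per visit) and a qualitative
component (the proportion of gut-passed seeds that germinate in trials).
For multi-seeded infructescences the per-visit seed load is derived from
morphometrics: beak volume modelled as a cone, ``BV = (1/3) π r² h``,
divided by the pulp volume holding one viable seed gives seeds per peck
for birds; mandible length divided by the fruit length holding one seed
gives seeds per bite for primates.

The module also provides effectiveness-landscape isoclines (curves of
constant qSDE × quality) and interaction sampling completeness via the
Chao lower-bound richness estimator and sample coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "BeakGeometry",
    "MandibleGeometry",
    "SeedIntakeConstants",
    "FocalObservationRecord",
    "GerminationTrial",
    "SDEProfile",
    "CompletenessEstimate",
    "beak_volume",
    "seeds_per_peck",
    "seeds_per_bite",
    "visitation_rate",
    "quantitative_component",
    "qualitative_component",
    "germination_curve",
    "sde_score",
    "isocline",
    "chao_asymptotic_richness",
    "sampling_completeness",
    "build_sde_profiles",
]

CONTROL = "CONTROL"


@dataclass(frozen=True)
class BeakGeometry:
    """Bird beak modelled as a cone: ``r`` = half beak width (mm) measured
    between commissures, ``h`` = culmen length (mm), the cone height."""

    r: float
    h: float

    def __post_init__(self) -> None:
        if self.r < 0 or self.h < 0:
            raise ValueError("beak dimensions must be non-negative")


@dataclass(frozen=True)
class MandibleGeometry:
    """Primate mandible length ``L`` in mm."""

    L: float

    def __post_init__(self) -> None:
        if self.L < 0:
            raise ValueError("mandible length must be non-negative")


@dataclass(frozen=True)
class SeedIntakeConstants:
    """Fruit-side conversion constants.

    ``pulp_volume_per_seed``: mm³ of fresh pulp per viable seed (default 150).
    ``fruit_length_per_seed``: mm of fruit length per seed (default 0.9).
    """

    pulp_volume_per_seed: float = 150.0
    fruit_length_per_seed: float = 0.9

    def __post_init__(self) -> None:
        if self.pulp_volume_per_seed <= 0 or self.fruit_length_per_seed <= 0:
            raise ValueError("intake constants must be strictly positive")


@dataclass
class FocalObservationRecord:
    """One focal-tree watch: visits by one frugivore to one plant.

    ``seeds_per_visit`` is either a sequence of per-visit seed loads or a
    single pre-computed mean.
    """

    plant_id: str
    frugivore_id: str
    n_visits: int
    observation_hours: float
    seeds_per_visit: Sequence[float] | float | None = None

    def __post_init__(self) -> None:
        if self.n_visits < 0:
            raise ValueError("n_visits must be non-negative")
        if self.observation_hours <= 0:
            raise ValueError("observation_hours must be positive")
        if self.seeds_per_visit is not None and not np.isscalar(self.seeds_per_visit):
            loads = np.asarray(self.seeds_per_visit, dtype=float)
            if np.any(loads < 0):
                raise ValueError("seed loads must be non-negative")

    def mean_seed_load(self) -> float:
        if self.seeds_per_visit is None:
            raise ValueError(
                f"no seed loads recorded for {self.frugivore_id} on {self.plant_id}"
            )
        if np.isscalar(self.seeds_per_visit):
            val = float(self.seeds_per_visit)
            if val < 0:
                raise ValueError("mean seed load must be non-negative")
            return val
        loads = np.asarray(self.seeds_per_visit, dtype=float)
        if loads.size == 0:
            raise ValueError("empty seed-load list")
        return float(loads.mean())


@dataclass
class GerminationTrial:
    """One germination treatment: ``treatment`` is a frugivore id (gut-passed
    seeds) or ``CONTROL`` (intact fruit); ``germination_days`` holds the check
    day of each seed that germinated."""

    treatment: str
    seeds_tested: int
    germination_days: Sequence[int] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if self.seeds_tested <= 0:
            raise ValueError("seeds_tested must be positive")
        days = tuple(int(d) for d in self.germination_days)
        if len(days) > self.seeds_tested:
            raise ValueError("more germinations than seeds tested")
        if any(d < 0 for d in days):
            raise ValueError("germination day indices must be non-negative")
        self.germination_days = days


@dataclass
class SDEProfile:
    """Per (frugivore, plant) effectiveness summary.

    ``qual`` and ``sde`` are ``None`` when the frugivore lacks feeding-trial
    data — absent, not zero, so downstream SDE maps can exclude the species
    while qSDE maps retain it.
    """

    frugivore_id: str
    plant_id: str
    qsde: float
    qual: float | None = None
    sde: float | None = None

    def __post_init__(self) -> None:
        if self.qsde < 0:
            raise ValueError("qsde must be non-negative")
        if (self.qual is None) != (self.sde is None):
            raise ValueError("sde must be present exactly when qual is present")
        if self.qual is not None:
            if not 0 <= self.qual <= 1:
                raise ValueError("qual must lie in [0, 1]")
            if not math.isclose(self.sde, self.qsde * self.qual, rel_tol=1e-9, abs_tol=1e-12):
                raise ValueError("sde must equal qsde * qual")


@dataclass(frozen=True)
class CompletenessEstimate:
    """Sampling completeness of an interaction network."""

    observed_richness: int
    asymptotic_richness: float
    SC: float
    coverage: float

    def __post_init__(self) -> None:
        if self.asymptotic_richness < self.observed_richness:
            raise ValueError("asymptotic richness cannot fall below observed")
        if not 0 < self.SC <= 1:
            raise ValueError("SC must lie in (0, 1]")
        if not 0 <= self.coverage <= 1:
            raise ValueError("coverage must lie in [0, 1]")


# ---------------------------------------------------------------------------
# Quantitative component


def beak_volume(geometry: BeakGeometry) -> float:
    """Beak volume in mm³ under the cone model, ``(1/3) π r² h``."""
    return (math.pi / 3.0) * geometry.r**2 * geometry.h


def seeds_per_peck(
    bv: float, constants: SeedIntakeConstants = SeedIntakeConstants()
) -> float:
    """Seeds ingested per peck: beak volume over pulp volume per seed.

    Kept as a real number; rounding to whole seeds would bias qSDE downward
    for small-beaked species.
    """
    if bv < 0:
        raise ValueError("beak volume must be non-negative")
    return bv / constants.pulp_volume_per_seed


def seeds_per_bite(
    geometry: MandibleGeometry, constants: SeedIntakeConstants = SeedIntakeConstants()
) -> float:
    """Seeds ingested per bite: mandible length over fruit length per seed."""
    return geometry.L / constants.fruit_length_per_seed


def visitation_rate(record: FocalObservationRecord) -> float:
    """Visits per 10 observation hours."""
    return record.n_visits * 10.0 / record.observation_hours


def quantitative_component(
    record: FocalObservationRecord | Iterable[FocalObservationRecord],
) -> float:
    """qSDE: visitation rate (visits / 10 h) × mean seeds dispersed per visit.

    Given several records for the same frugivore–plant pair, visits and
    hours are pooled before the rate is formed, and the seed-load mean is
    visit-weighted — one long watch and the same watch split in two give
    identical qSDE.
    """
    records = [record] if isinstance(record, FocalObservationRecord) else list(record)
    if not records:
        raise ValueError("at least one observation record required")
    total_visits = sum(r.n_visits for r in records)
    total_hours = sum(r.observation_hours for r in records)
    if total_visits == 0:
        return 0.0
    # visit-weighted mean seed load over records that saw visits
    num = 0.0
    for r in records:
        if r.n_visits > 0:
            num += r.n_visits * r.mean_seed_load()
    mean_load = num / total_visits
    return total_visits * 10.0 / total_hours * mean_load


# ---------------------------------------------------------------------------
# Qualitative component


def qualitative_component(trial: GerminationTrial) -> float:
    """Proportion of tested seeds that germinated, in [0, 1]."""
    return len(trial.germination_days) / trial.seeds_tested


def germination_curve(
    trial: GerminationTrial, check_interval: int = 2
) -> pd.Series:
    """Cumulative germination proportion at each check.

    Time points are multiples of ``check_interval`` (default 2 days —
    germination checks every other day); a seed first seen germinated at
    check ``t`` counts at ``t``.  The series is non-decreasing and its last
    value equals :func:`qualitative_component`.
    """
    if check_interval <= 0:
        raise ValueError("check_interval must be positive")
    if not trial.germination_days:
        return pd.Series([0.0], index=pd.Index([0], name="day"), name="cum_prop")
    days = np.asarray(trial.germination_days)
    # snap each germination day up to its check day
    checks = np.ceil(days / check_interval).astype(int) * check_interval
    last = int(checks.max())
    grid = np.arange(0, last + check_interval, check_interval)
    cum = np.array([(checks <= t).sum() for t in grid]) / trial.seeds_tested
    return pd.Series(cum, index=pd.Index(grid, name="day"), name="cum_prop")


def sde_score(qsde: float, qual: float) -> float:
    """SDE = quantitative × qualitative component."""
    if qsde < 0:
        raise ValueError("qsde must be non-negative")
    if not 0 <= qual <= 1:
        raise ValueError("qual must lie in [0, 1]")
    return qsde * qual


def isocline(level: float, qsde_grid: Sequence[float]) -> np.ndarray:
    """Points of equal effectiveness in the (qSDE, quality) landscape.

    Returns an array of ``(qsde, qual)`` pairs with ``qual = level / qsde``;
    pairs whose quality would exceed 1 are dropped (they lie outside the
    landscape).
    """
    if level < 0:
        raise ValueError("isocline level must be non-negative")
    q = np.asarray(qsde_grid, dtype=float)
    if np.any(q <= 0):
        raise ValueError("qsde grid values must be strictly positive")
    qual = level / q
    keep = qual <= 1.0
    return np.column_stack([q[keep], qual[keep]])


# ---------------------------------------------------------------------------
# Sampling completeness


def _frequency_counts(counts: Sequence[int]) -> tuple[np.ndarray, int, int]:
    c = np.asarray(counts, dtype=int)
    if c.size == 0:
        raise ValueError("at least one interaction required")
    if np.any(c < 1):
        raise ValueError("interaction counts must be positive integers")
    f1 = int((c == 1).sum())
    f2 = int((c == 2).sum())
    return c, f1, f2


def chao_asymptotic_richness(counts: Sequence[int]) -> float:
    """Chao lower-bound estimate of asymptotic interaction richness (q = 0).

    ``S_obs + f1²/(2 f2)`` from singleton/doubleton counts; when no
    doubletons exist the bias-corrected form ``S_obs + f1 (f1 − 1)/2`` is
    used instead.
    """
    c, f1, f2 = _frequency_counts(counts)
    s_obs = c.size
    if f2 > 0:
        return s_obs + f1**2 / (2.0 * f2)
    return s_obs + f1 * (f1 - 1) / 2.0


def sampling_completeness(counts: Sequence[int]) -> CompletenessEstimate:
    """Observed/asymptotic richness ratio plus estimated sample coverage.

    Coverage is ``1 − (f1/n) · (n−1) f1 / ((n−1) f1 + 2 f2)`` with ``n`` the
    total number of interaction events.
    """
    c, f1, f2 = _frequency_counts(counts)
    s_obs = c.size
    n = int(c.sum())
    asym = chao_asymptotic_richness(counts)
    sc = s_obs / asym
    if f1 == 0:
        coverage = 1.0
    else:
        denom = (n - 1) * f1 + 2.0 * f2
        # n = 1 makes the correction factor 0/0; take its limiting value 1
        factor = (n - 1) * f1 / denom if denom > 0 else 1.0
        coverage = 1.0 - (f1 / n) * factor
    return CompletenessEstimate(
        observed_richness=s_obs, asymptotic_richness=asym, SC=sc, coverage=coverage
    )


# ---------------------------------------------------------------------------
# Table-level assembly


def build_sde_profiles(
    observations: pd.DataFrame, germination: pd.DataFrame | None = None
) -> list[SDEProfile]:
    """Assemble per-pair SDE profiles from field tables.

    ``observations`` needs columns ``plant_id, frugivore_id, n_visits,
    observation_hours, seeds_per_visit`` (seed loads as a scalar mean or a
    ``;``-separated list).  ``germination`` needs ``plant_id, treatment,
    seeds_tested, germination_days`` (``;``-separated day list); the
    ``CONTROL`` treatment is ignored here.  Frugivores without a matching
    germination treatment get an absent qualitative component.
    """
    required = {"plant_id", "frugivore_id", "n_visits", "observation_hours", "seeds_per_visit"}
    missing = required - set(observations.columns)
    if missing:
        raise ValueError(f"observations table missing columns: {sorted(missing)}")

    quals: dict[tuple[str, str], float] = {}
    if germination is not None:
        for _, row in germination.iterrows():
            if str(row["treatment"]) == CONTROL:
                continue
            trial = GerminationTrial(
                treatment=str(row["treatment"]),
                seeds_tested=int(row["seeds_tested"]),
                germination_days=_parse_day_list(row["germination_days"]),
            )
            quals[(str(row["plant_id"]), trial.treatment)] = qualitative_component(trial)

    profiles: list[SDEProfile] = []
    for (plant, frug), group in observations.groupby(["plant_id", "frugivore_id"], sort=True):
        records = [
            FocalObservationRecord(
                plant_id=str(plant),
                frugivore_id=str(frug),
                n_visits=int(row["n_visits"]),
                observation_hours=float(row["observation_hours"]),
                seeds_per_visit=_parse_loads(row["seeds_per_visit"]),
            )
            for _, row in group.iterrows()
        ]
        qsde = quantitative_component(records)
        qual = quals.get((str(plant), str(frug)))
        profiles.append(
            SDEProfile(
                frugivore_id=str(frug),
                plant_id=str(plant),
                qsde=qsde,
                qual=qual,
                sde=None if qual is None else qsde * qual,
            )
        )
    return profiles


def profiles_to_frame(profiles: Iterable[SDEProfile]) -> pd.DataFrame:
    """SDE profile table with columns frugivore_id, plant_id, qsde, qual, sde."""
    return pd.DataFrame(
        [
            {
                "frugivore_id": p.frugivore_id,
                "plant_id": p.plant_id,
                "qsde": p.qsde,
                "qual": np.nan if p.qual is None else p.qual,
                "sde": np.nan if p.sde is None else p.sde,
            }
            for p in profiles
        ]
    )


def _parse_loads(value) -> Sequence[float] | float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, str):
        parts = [p for p in value.split(";") if p.strip() != ""]
        return [float(p) for p in parts]
    return float(value)


def _parse_day_list(value) -> tuple[int, ...]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "":
        return ()
    if isinstance(value, str):
        return tuple(int(float(p)) for p in value.split(";") if p.strip() != "")
    return (int(value),)
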