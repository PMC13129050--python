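"""Richness- and function-based forecasts from binary range maps.

Overlaying frugivore range maps on a focal plant's range gives, per grid
cell, the disperser richness (count of co-occurring frugivores) and the
dispersal function: the sum over present frugivores of each species'
effectiveness weight (qSDE or SDE), i.e. cellwise
``SD_P,C = Σ_f Hs_f,C × w_f`` with ``Hs`` the 0/1 presence of frugivore
``f``.  Species without feeding-trial data carry no SDE weight and are
excluded from SDE maps (but kept in qSDE maps).  Change summaries compare
current and future scenarios as percentages of the current value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .grids import BinaryRangeMap, GridSpec, check_same_grid
from .sde import SDEProfile

__all__ = [
    "RichnessMap",
    "FunctionMap",
    "OverlapSummary",
    "ChangeSummary",
    "range_area",
    "cooccurrence",
    "richness_map",
    "function_map",
    "percent_change",
    "assemblage_change",
]

METRICS = ("qsde", "sde")


@dataclass
class RichnessMap:
    """Frugivore count per cell, masked (NaN) outside the plant's range."""

    counts: np.ndarray
    plant_id: str
    scenario: str
    grid: GridSpec = field(repr=False)


@dataclass
class FunctionMap:
    """Summed effectiveness weights per cell, masked outside the plant range."""

    values: np.ndarray
    metric: str
    plant_id: str
    scenario: str
    grid: GridSpec = field(repr=False)

    def __post_init__(self) -> None:
        if self.metric not in METRICS:
            raise ValueError(f"metric must be one of {METRICS}")


@dataclass(frozen=True)
class OverlapSummary:
    """Range intersection of one plant–frugivore pair."""

    plant_id: str
    frugivore_id: str
    scenario: str
    intersection_area: float  # km²
    pct_of_plant_range: float

    def __post_init__(self) -> None:
        if not 0 <= self.pct_of_plant_range <= 100:
            raise ValueError("percentage must lie in [0, 100]")


@dataclass(frozen=True)
class ChangeSummary:
    """Current-to-future change for one species or assemblage metric."""

    entity: str
    metric: str
    scenario: str
    current_value: float
    future_value: float
    pct_change: float


def range_area(range_map: BinaryRangeMap, grid: GridSpec | None = None) -> float:
    """Area of the mapped range in km² (presence cells × cell area)."""
    if grid is not None and grid != range_map.grid:
        raise ValueError("grid does not match the map's GridSpec")
    g = grid or range_map.grid
    return range_map.n_cells * g.cell_area


def cooccurrence(plant: BinaryRangeMap, animal: BinaryRangeMap) -> OverlapSummary:
    """Intersection of a plant and frugivore range under one scenario."""
    check_same_grid(plant.grid, animal.grid)
    if plant.scenario != animal.scenario:
        raise ValueError(
            f"scenario mismatch: {plant.scenario!r} vs {animal.scenario!r}"
        )
    inter = int(np.sum((plant.presence == 1) & (animal.presence == 1)))
    n_plant = plant.n_cells
    pct = 100.0 * inter / n_plant if n_plant else 0.0
    return OverlapSummary(
        plant_id=plant.species_id,
        frugivore_id=animal.species_id,
        scenario=plant.scenario,
        intersection_area=inter * plant.grid.cell_area,
        pct_of_plant_range=pct,
    )


def richness_map(plant: BinaryRangeMap, animals: Sequence[BinaryRangeMap]) -> RichnessMap:
    """Number of frugivore species present per cell of the plant's range."""
    _check_aligned(plant, animals)
    counts = np.zeros(plant.grid.shape, dtype=float)
    for a in animals:
        counts += a.presence
    counts[plant.presence == 0] = np.nan
    return RichnessMap(counts, plant.species_id, plant.scenario, plant.grid)


def function_map(
    plant: BinaryRangeMap,
    animals: Sequence[BinaryRangeMap],
    profiles: Iterable[SDEProfile],
    metric: str = "qsde",
    mask_to_plant: bool = True,
) -> FunctionMap:
    """Cellwise dispersal function: Σ over frugivores of presence × weight.

    ``metric="qsde"`` uses each species' quantitative score; ``metric="sde"``
    uses the combined score and silently drops species whose SDE is absent
    (no feeding-trial data).  With ``mask_to_plant=False`` the sum is
    reported everywhere (the "beyond the plant's projected range" variant);
    otherwise cells outside the plant range are NaN.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}")
    _check_aligned(plant, animals)
    weights = _weights_for(plant.species_id, profiles, metric)
    eligible = [a for a in animals if weights.get(a.species_id) is not None]
    if metric == "sde" and not eligible:
        raise ValueError("no frugivore has an SDE weight for this plant")
    values = np.zeros(plant.grid.shape, dtype=float)
    for a in eligible:
        values += a.presence * weights[a.species_id]
    if mask_to_plant:
        values[plant.presence == 0] = np.nan
    return FunctionMap(values, metric, plant.species_id, plant.scenario, plant.grid)


def percent_change(current: float | np.ndarray, future: float | np.ndarray):
    """Percentage change relative to the current value.

    For arrays, cells whose current value is 0 (or NaN) are undefined and
    returned as NaN — they are excluded from any downstream per-cell model.
    """
    if np.isscalar(current):
        if current <= 0:
            raise ValueError("percent change undefined for current <= 0")
        return 100.0 * (future - current) / current
    current = np.asarray(current, dtype=float)
    future = np.asarray(future, dtype=float)
    out = np.full(current.shape, np.nan)
    ok = np.isfinite(current) & np.isfinite(future) & (current > 0)
    out[ok] = 100.0 * (future[ok] - current[ok]) / current[ok]
    return out


def assemblage_change(
    plant_by_scenario: dict[str, BinaryRangeMap],
    animals_by_scenario: dict[str, Sequence[BinaryRangeMap]],
    profiles: Iterable[SDEProfile],
    metric: str = "qsde",
    scenarios: Sequence[str] = ("moderate", "business-as-usual"),
) -> list[ChangeSummary]:
    """Range-wide change in per-species contributions and the assemblage total.

    For each future scenario: each species' contribution is its weight times
    its in-range presence-cell count under that scenario's plant range
    (Σ_C Hs_f,C × w_f); the assemblage value is the total over species.
    Changes are percentages of the current value; species with zero current
    contribution are reported with ``pct_change = NaN``.
    """
    profiles = list(profiles)
    if "current" not in plant_by_scenario:
        raise ValueError("current scenario maps are required")
    for scen in scenarios:
        if scen not in plant_by_scenario or scen not in animals_by_scenario:
            raise ValueError(f"missing maps for scenario {scen!r}")

    def species_totals(scen: str) -> dict[str, float]:
        plant = plant_by_scenario[scen]
        weights = _weights_for(plant.species_id, profiles, metric)
        totals = {}
        for a in animals_by_scenario[scen]:
            w = weights.get(a.species_id)
            if w is None:
                continue
            in_range = int(np.sum((plant.presence == 1) & (a.presence == 1)))
            totals[a.species_id] = in_range * w
        return totals

    cur = species_totals("current")
    out: list[ChangeSummary] = []
    plant_id = plant_by_scenario["current"].species_id
    for scen in scenarios:
        fut = species_totals(scen)
        for sp in cur:
            c, f = cur[sp], fut.get(sp, 0.0)
            pct = 100.0 * (f - c) / c if c > 0 else float("nan")
            out.append(ChangeSummary(sp, metric, scen, c, f, pct))
        c_tot, f_tot = sum(cur.values()), sum(fut.values())
        pct = 100.0 * (f_tot - c_tot) / c_tot if c_tot > 0 else float("nan")
        out.append(
            ChangeSummary(f"assemblage:{plant_id}", metric, scen, c_tot, f_tot, pct)
        )
    return out


def changes_to_frame(changes: Iterable[ChangeSummary]) -> pd.DataFrame:
    return pd.DataFrame([c.__dict__ for c in changes])


def _check_aligned(plant: BinaryRangeMap, animals: Sequence[BinaryRangeMap]) -> None:
    check_same_grid(plant.grid, *(a.grid for a in animals))
    for a in animals:
        if a.scenario != plant.scenario:
            raise ValueError(
                f"scenario mismatch: plant {plant.scenario!r} vs "
                f"{a.species_id} {a.scenario!r}"
            )


def _weights_for(
    plant_id: str, profiles: Iterable[SDEProfile], metric: str
) -> dict[str, float | None]:
    weights: dict[str, float | None] = {}
    for p in profiles:
        if p.plant_id != plant_id:
            continue
        weights[p.frugivore_id] = p.qsde if metric == "qsde" else p.sde
    return weights
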