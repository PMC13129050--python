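"""End-to-end study on a simulated dataset.

Runs the whole chain the package exists for: SDE profiles from the
observation and germination tables, per-species range maps from the SDM
ensemble (or the known truth, for oracle runs), richness and function
maps per scenario, the decoupling index with its classification, and the
robust regression of functional change on richness change over stable
cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import decoupling as dec
from . import forecast as fc
from .grids import BinaryRangeMap
from .sde import SDEProfile, build_sde_profiles
from .sdm import PredictorStack, fit_species_sdm
from .simulate import SimulatedDataset, apply_climate_shift

__all__ = ["StudyResult", "run_study"]

FUTURE_SCENARIOS = ("moderate", "business-as-usual")


@dataclass
class StudyResult:
    """Everything the pipeline produces for one plant."""

    profiles: list[SDEProfile]
    range_maps: dict[tuple[str, str], BinaryRangeMap]  # (species, scenario)
    richness: dict[tuple[str, str], fc.RichnessMap]  # (metric, scenario)
    function: dict[tuple[str, str], fc.FunctionMap]  # (metric, scenario)
    decoupling_maps: dict[tuple[str, str], dec.DecouplingMap]
    classifications: dict[tuple[str, str], dec.DecouplingClassification]
    regressions: dict[tuple[str, str], dec.RobustFit] = field(default_factory=dict)
    changes: list[fc.ChangeSummary] = field(default_factory=list)

    def median_decoupling(self, metric: str = "qsde", scenario: str = "business-as-usual"):
        d = self.decoupling_maps[(metric, scenario)]
        vals = d.D[d.domain & np.isfinite(d.D)]
        return float(np.median(vals))


def run_study(
    dataset: SimulatedDataset,
    n_replicates: int = 15,
    algorithms=("logistic",),
    split: float = 0.75,
    pad: float = 10.0,
    thin_distance: float | None = None,
    epsilon: float = 0.05,
    metrics=("qsde", "sde"),
    seed: int = 0,
    use_truth_ranges: bool = False,
) -> StudyResult:
    """Run SDE scoring, range modelling, forecasting and decoupling.

    With ``use_truth_ranges=True`` the simulator's true range maps stand in
    for the SDM stage, which isolates the forecasting and decoupling
    machinery from model error.
    """
    landscape = dataset.landscape
    grid = landscape.grid
    scenarios = ("current", *FUTURE_SCENARIOS)

    profiles = build_sde_profiles(dataset.observations, dataset.germination)

    # --- range maps -------------------------------------------------------
    range_maps: dict[tuple[str, str], BinaryRangeMap] = {}
    if use_truth_ranges:
        for (sp, scen), m in dataset.truth_ranges.items():
            range_maps[(sp, scen)] = m
    else:
        stacks = {
            scen: PredictorStack(grid, apply_climate_shift(landscape, scen))
            for scen in scenarios
        }
        rng = np.random.default_rng(seed)
        for sp in dataset.species:
            pts = dataset.occurrences.query("species == @sp.species_id")[["x", "y"]].to_numpy()
            maps = fit_species_sdm(
                pts,
                stacks,
                species_id=sp.species_id,
                n_replicates=n_replicates,
                algorithms=algorithms,
                split=split,
                thin_distance=thin_distance,
                pad=pad,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
            for scen, m in maps.items():
                range_maps[(sp.species_id, scen)] = m

    plant_id = dataset.plant_id
    frug_ids = [s.species_id for s in dataset.frugivores]
    with_sde = {
        p.frugivore_id for p in profiles if p.plant_id == plant_id and p.sde is not None
    }

    def animal_maps(scen: str, metric: str) -> list[BinaryRangeMap]:
        ids = frug_ids if metric == "qsde" else [f for f in frug_ids if f in with_sde]
        return [range_maps[(f, scen)] for f in ids]

    # --- richness / function / decoupling per metric and scenario --------
    richness: dict[tuple[str, str], fc.RichnessMap] = {}
    function: dict[tuple[str, str], fc.FunctionMap] = {}
    dmaps: dict[tuple[str, str], dec.DecouplingMap] = {}
    classes: dict[tuple[str, str], dec.DecouplingClassification] = {}
    regressions: dict[tuple[str, str], dec.RobustFit] = {}

    for metric in metrics:
        for scen in scenarios:
            plant_map = range_maps[(plant_id, scen)]
            animals = animal_maps(scen, metric)
            # the SDE-based richness layer counts only frugivores with
            # feeding-trial data, so both layers describe the same pool
            richness[(metric, scen)] = fc.richness_map(plant_map, animals)
            function[(metric, scen)] = fc.function_map(
                plant_map, animals, profiles, metric=metric
            )
            domain = (plant_map.presence == 1) & np.isfinite(
                function[(metric, scen)].values
            )
            if domain.any():
                f_norm = dec.minmax_normalize(
                    function[(metric, scen)].values, domain, source_metric=metric
                )
                r_norm = dec.minmax_normalize(
                    richness[(metric, scen)].counts, domain, source_metric="richness"
                )
                dmaps[(metric, scen)] = dec.decoupling_index(
                    f_norm, r_norm, metric=metric, scenario=scen
                )
                classes[(metric, scen)] = dec.classify_decoupling(
                    dmaps[(metric, scen)], epsilon=epsilon
                )

        # regressions of per-cell % change on stable cells, per future scenario
        for scen in FUTURE_SCENARIOS:
            stable = dec.stable_cells(
                range_maps[(plant_id, "current")], range_maps[(plant_id, scen)]
            )
            if not stable.any():
                continue
            df_fun = fc.percent_change(
                np.where(stable, function[(metric, "current")].values, np.nan),
                np.where(stable, function[(metric, scen)].values, np.nan),
            )
            df_ric = fc.percent_change(
                np.where(stable, richness[(metric, "current")].counts, np.nan),
                np.where(stable, richness[(metric, scen)].counts, np.nan),
            )
            ok = np.isfinite(df_fun) & np.isfinite(df_ric)
            if ok.sum() >= 3 and np.ptp(df_ric[ok]) > 0:
                regressions[(metric, scen)] = dec.fit_richness_function_model(
                    df_fun[ok], df_ric[ok]
                )

    changes = []
    for metric in metrics:
        plant_by_scen = {s: range_maps[(plant_id, s)] for s in scenarios}
        animals_by_scen = {s: animal_maps(s, metric) for s in scenarios}
        changes.extend(
            fc.assemblage_change(
                plant_by_scen, animals_by_scen, profiles, metric=metric,
                scenarios=FUTURE_SCENARIOS,
            )
        )

    return StudyResult(
        profiles=profiles,
        range_maps=range_maps,
        richness=richness,
        function=function,
        decoupling_maps=dmaps,
        classifications=classes,
        regressions=regressions,
        changes=changes,
    )
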