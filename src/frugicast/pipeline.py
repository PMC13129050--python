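"""File-driven pipeline orchestration.

Six stages — simulate, sde, sdm, forecast, decouple, report — each of
which consumes and produces files only, so synthetic and real inputs can
be mixed freely.  A stage is skipped when its outputs already exist and
are newer than all of its inputs (delete an intermediate to regenerate it
and everything downstream).  A run manifest records the config hash and a
checksum of every output, so identical config + seed reproduces identical
checksums for deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import decoupling as dec
from . import forecast as fc
from .config import PipelineConfig
from .grids import SCENARIOS, BinaryRangeMap, GridSpec
from .raster_io import read_raster, write_raster
from .sde import SDEProfile, build_sde_profiles, profiles_to_frame
from .sdm import PredictorStack, fit_species_sdm
from .simulate import apply_climate_shift, scenario_preset

log = logging.getLogger(__name__)

__all__ = ["run_pipeline", "STAGES"]

FUTURE = ("moderate", "business-as-usual")
METRICS = ("qsde", "sde")


@dataclass
class StageIO:
    """Declared inputs and outputs of one stage for freshness checking."""

    inputs: list[Path]
    outputs: list[Path]

    def is_fresh(self) -> bool:
        if not self.outputs or not all(p.exists() for p in self.outputs):
            return False
        out_mtime = min(p.stat().st_mtime for p in self.outputs)
        in_mtime = max((p.stat().st_mtime for p in self.inputs if p.exists()), default=0.0)
        return out_mtime >= in_mtime


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _scen_slug(scenario: str) -> str:
    return scenario.replace("-", "_")


class _Paths:
    def __init__(self, cfg: PipelineConfig):
        self.root = Path(cfg.out_dir)
        self.data = self.root / "data"
        self.layers = self.data / "layers"
        self.truth = self.data / "truth"
        self.ranges = self.root / "ranges"
        self.forecast = self.root / "forecast"
        self.decouple = self.root / "decoupling"
        self.report = self.root / "report"
        self.ext = cfg.raster_format

    def layer(self, name: str, scenario: str) -> Path:
        return self.layers / f"{name}_{_scen_slug(scenario)}.{self.ext}"

    def range_map(self, species: str, scenario: str) -> Path:
        return self.ranges / f"range_{species}_{_scen_slug(scenario)}.{self.ext}"


# ---------------------------------------------------------------------------
# Stages


def _stage_simulate(cfg: PipelineConfig, p: _Paths) -> list[Path]:
    s = cfg.simulate
    ds = scenario_preset(
        s.preset,
        seed=cfg.seed,
        n_rows=s.n_rows,
        n_cols=s.n_cols,
        n_occurrences=s.n_occurrences,
        observation_hours=s.observation_hours,
        n_trial_seeds=s.n_trial_seeds,
    )
    for d in (p.data, p.layers, p.truth):
        d.mkdir(parents=True, exist_ok=True)
    outputs: list[Path] = []

    def save_csv(df: pd.DataFrame, path: Path) -> None:
        df.to_csv(path, index=False)
        outputs.append(path)

    save_csv(ds.occurrences, p.data / "occurrences.csv")
    save_csv(ds.observations, p.data / "observations.csv")
    save_csv(ds.germination, p.data / "germination.csv")
    save_csv(
        pd.DataFrame(
            [{"species_id": sp.species_id, "role": sp.role} for sp in ds.species]
        ),
        p.data / "species.csv",
    )
    for scen in SCENARIOS:
        for name, layer in apply_climate_shift(ds.landscape, scen).items():
            outputs.append(write_raster(layer, ds.landscape.grid, p.layer(name, scen)))
    for (sp, scen), m in ds.truth_ranges.items():
        path = p.truth / f"range_{sp}_{_scen_slug(scen)}.{p.ext}"
        outputs.append(write_raster(m.presence.astype(float), m.grid, path))
    snap = p.data / "config_snapshot.yaml"
    # snapshot the scientific settings only: out_dir is environment, and
    # including it would break checksum reproducibility across directories
    snapshot = {k: v for k, v in cfg.to_dict().items() if k != "out_dir"}
    snap.write_text(yaml.safe_dump(snapshot, sort_keys=True))
    outputs.append(snap)
    return outputs


def _stage_sde(cfg: PipelineConfig, p: _Paths) -> list[Path]:
    obs = pd.read_csv(p.data / "observations.csv").fillna({"seeds_per_visit": ""})
    germ = pd.read_csv(p.data / "germination.csv").fillna({"germination_days": ""})
    profiles = build_sde_profiles(obs, germ)
    out = p.root / "sde_profiles.csv"
    profiles_to_frame(profiles).to_csv(out, index=False)
    return [out]


def _load_stacks(cfg: PipelineConfig, p: _Paths) -> tuple[dict[str, PredictorStack], GridSpec]:
    stacks: dict[str, PredictorStack] = {}
    grid = None
    for scen in SCENARIOS:
        layers = {}
        for path in sorted(p.layers.glob(f"*_{_scen_slug(scen)}.{p.ext}")):
            name = path.stem.rsplit(f"_{_scen_slug(scen)}", 1)[0]
            arr, spec = read_raster(path)
            layers[name] = arr
            grid = grid or spec
        if not layers:
            raise FileNotFoundError(f"no predictor layers found for scenario {scen!r}")
        stacks[scen] = PredictorStack(grid, layers)
    return stacks, grid


def _stage_sdm(cfg: PipelineConfig, p: _Paths) -> list[Path]:
    stacks, grid = _load_stacks(cfg, p)
    occ = pd.read_csv(p.data / "occurrences.csv")
    p.ranges.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed + 1)
    outputs = []
    for species, group in occ.groupby("species", sort=True):
        maps = fit_species_sdm(
            group[["x", "y"]].to_numpy(),
            stacks,
            species_id=str(species),
            n_replicates=cfg.sdm.n_replicates,
            algorithms=cfg.sdm.algorithms,
            split=cfg.sdm.split,
            thin_distance=cfg.sdm.thin_distance,
            pad=cfg.sdm.pad,
            seed=int(rng.integers(0, 2**31 - 1)),
        )
        for scen, m in maps.items():
            path = p.range_map(str(species), scen)
            outputs.append(write_raster(m.presence.astype(float), grid, path))
    return outputs


def _load_ranges(p: _Paths, species: list[str], grid: GridSpec) -> dict:
    maps = {}
    for sp in species:
        for scen in SCENARIOS:
            arr, spec = read_raster(p.range_map(sp, scen))
            maps[(sp, scen)] = BinaryRangeMap(
                np.nan_to_num(arr).astype(np.int8), sp, scen, grid
            )
    return maps


def _load_profiles(p: _Paths) -> list[SDEProfile]:
    df = pd.read_csv(p.root / "sde_profiles.csv")
    profiles = []
    for _, r in df.iterrows():
        qual = None if pd.isna(r["qual"]) else float(r["qual"])
        profiles.append(
            SDEProfile(
                frugivore_id=str(r["frugivore_id"]),
                plant_id=str(r["plant_id"]),
                qsde=float(r["qsde"]),
                qual=qual,
                sde=None if qual is None else float(r["sde"]),
            )
        )
    return profiles


def _species_roles(p: _Paths) -> tuple[str, list[str]]:
    sp = pd.read_csv(p.data / "species.csv")
    plants = sp.loc[sp.role == "plant", "species_id"].tolist()
    frugs = sp.loc[sp.role == "frugivore", "species_id"].tolist()
    if len(plants) != 1:
        raise ValueError("pipeline currently expects exactly one focal plant")
    return plants[0], frugs


def _stage_forecast(cfg: PipelineConfig, p: _Paths) -> list[Path]:
    _, grid = _load_stacks(cfg, p)
    plant_id, frug_ids = _species_roles(p)
    ranges = _load_ranges(p, [plant_id, *frug_ids], grid)
    profiles = _load_profiles(p)
    with_sde = {pr.frugivore_id for pr in profiles if pr.sde is not None}
    p.forecast.mkdir(parents=True, exist_ok=True)
    outputs, overlaps, changes = [], [], []
    for metric in METRICS:
        ids = frug_ids if metric == "qsde" else [f for f in frug_ids if f in with_sde]
        for scen in SCENARIOS:
            plant = ranges[(plant_id, scen)]
            animals = [ranges[(f, scen)] for f in ids]
            rich = fc.richness_map(plant, animals)
            func = fc.function_map(plant, animals, profiles, metric=metric)
            outputs.append(
                write_raster(rich.counts, grid, p.forecast / f"richness_{metric}_{_scen_slug(scen)}.{p.ext}")
            )
            outputs.append(
                write_raster(func.values, grid, p.forecast / f"function_{metric}_{_scen_slug(scen)}.{p.ext}")
            )
            if metric == "qsde":
                overlaps.extend(
                    fc.cooccurrence(plant, a).__dict__ for a in animals
                )
        changes.extend(
            fc.assemblage_change(
                {s: ranges[(plant_id, s)] for s in SCENARIOS},
                {s: [ranges[(f, s)] for f in ids] for s in SCENARIOS},
                profiles,
                metric=metric,
                scenarios=FUTURE,
            )
        )
    ov = p.forecast / "overlap.csv"
    pd.DataFrame(overlaps).to_csv(ov, index=False)
    ch = p.forecast / "changes.csv"
    fc.changes_to_frame(changes).to_csv(ch, index=False)
    outputs.extend([ov, ch])
    return outputs


def _stage_decouple(cfg: PipelineConfig, p: _Paths) -> list[Path]:
    _, grid = _load_stacks(cfg, p)
    plant_id, _ = _species_roles(p)
    p.decouple.mkdir(parents=True, exist_ok=True)
    outputs, class_rows, reg_rows = [], [], []
    cur_rng, _ = read_raster(p.range_map(plant_id, "current"))
    for metric in METRICS:
        for scen in SCENARIOS:
            rich, _ = read_raster(p.forecast / f"richness_{metric}_{_scen_slug(scen)}.{p.ext}")
            func, _ = read_raster(p.forecast / f"function_{metric}_{_scen_slug(scen)}.{p.ext}")
            domain = np.isfinite(rich) & np.isfinite(func)
            if not domain.any():
                continue
            f_norm = dec.minmax_normalize(func, domain, source_metric=metric)
            r_norm = dec.minmax_normalize(rich, domain, source_metric="richness")
            dmap = dec.decoupling_index(f_norm, r_norm, metric=metric, scenario=scen)
            outputs.append(
                write_raster(dmap.D, grid, p.decouple / f"D_{metric}_{_scen_slug(scen)}.{p.ext}")
            )
            cl = dec.classify_decoupling(dmap, epsilon=cfg.decoupling.epsilon)
            class_rows.append(
                {
                    "metric": metric, "scenario": scen, "epsilon": cl.epsilon,
                    "pct_over": cl.pct_over, "pct_match": cl.pct_match,
                    "pct_under": cl.pct_under,
                }
            )
            hist = dec.histogram_frame(dmap, grid)
            hp = p.decouple / f"histogram_{metric}_{_scen_slug(scen)}.csv"
            hist.to_csv(hp, index=False)
            outputs.append(hp)
        for scen in FUTURE:
            fut_rng, _ = read_raster(p.range_map(plant_id, scen))
            stable = (np.nan_to_num(cur_rng) == 1) & (np.nan_to_num(fut_rng) == 1)
            if not stable.any():
                continue
            rich_c, _ = read_raster(p.forecast / f"richness_{metric}_current.{p.ext}")
            func_c, _ = read_raster(p.forecast / f"function_{metric}_current.{p.ext}")
            rich_f, _ = read_raster(p.forecast / f"richness_{metric}_{_scen_slug(scen)}.{p.ext}")
            func_f, _ = read_raster(p.forecast / f"function_{metric}_{_scen_slug(scen)}.{p.ext}")
            d_fun = fc.percent_change(np.where(stable, func_c, np.nan), np.where(stable, func_f, np.nan))
            d_ric = fc.percent_change(np.where(stable, rich_c, np.nan), np.where(stable, rich_f, np.nan))
            ok = np.isfinite(d_fun) & np.isfinite(d_ric)
            if ok.sum() < 3 or np.ptp(d_ric[ok]) == 0:
                continue
            fit = dec.fit_richness_function_model(d_fun[ok], d_ric[ok])
            reg_rows.append(
                {
                    "metric": metric, "scenario": scen, "slope": fit.slope,
                    "intercept": fit.intercept, "r_squared": fit.r_squared,
                    "hc3_se_intercept": fit.hc3_se[0], "hc3_se_slope": fit.hc3_se[1],
                    "p_intercept": fit.p_values[0], "p_slope": fit.p_values[1],
                    "n_cells": fit.n,
                }
            )
    cp = p.decouple / "classification.csv"
    pd.DataFrame(class_rows).to_csv(cp, index=False)
    rp = p.decouple / "regression.csv"
    pd.DataFrame(reg_rows).to_csv(rp, index=False)
    outputs.extend([cp, rp])
    return outputs


def _stage_report(cfg: PipelineConfig, p: _Paths) -> list[Path]:
    p.report.mkdir(parents=True, exist_ok=True)
    outputs = []
    for src, dst in (
        (p.root / "sde_profiles.csv", p.report / "sde_profiles.csv"),
        (p.forecast / "changes.csv", p.report / "species_changes.csv"),
        (p.decouple / "classification.csv", p.report / "decoupling_fractions.csv"),
        (p.decouple / "regression.csv", p.report / "richness_function_regression.csv"),
    ):
        dst.write_text(src.read_text())
        outputs.append(dst)
    return outputs


STAGES = {
    "simulate": _stage_simulate,
    "sde": _stage_sde,
    "sdm": _stage_sdm,
    "forecast": _stage_forecast,
    "decouple": _stage_decouple,
    "report": _stage_report,
}

_STAGE_ORDER = ["simulate", "sde", "sdm", "forecast", "decouple", "report"]


def _declared_io(stage: str, cfg: PipelineConfig, p: _Paths) -> StageIO:
    data_csvs = [p.data / n for n in ("occurrences.csv", "observations.csv", "germination.csv", "species.csv")]
    layer_files = sorted(p.layers.glob(f"*.{p.ext}"))
    range_files = sorted(p.ranges.glob(f"*.{p.ext}"))
    forecast_files = sorted(p.forecast.glob("*"))
    if stage == "simulate":
        return StageIO([], data_csvs + [p.data / "config_snapshot.yaml"])
    if stage == "sde":
        return StageIO(data_csvs, [p.root / "sde_profiles.csv"])
    if stage == "sdm":
        return StageIO(data_csvs + layer_files, range_files)
    if stage == "forecast":
        return StageIO(
            [p.root / "sde_profiles.csv", *range_files],
            [p.forecast / "overlap.csv", p.forecast / "changes.csv"],
        )
    if stage == "decouple":
        return StageIO(
            forecast_files,
            [p.decouple / "classification.csv", p.decouple / "regression.csv"],
        )
    if stage == "report":
        return StageIO(
            [p.decouple / "classification.csv", p.decouple / "regression.csv"],
            [p.report / "sde_profiles.csv", p.report / "decoupling_fractions.csv"],
        )
    raise ValueError(f"unknown stage {stage!r}")


def run_pipeline(
    cfg: PipelineConfig, stages: list[str] | None = None, force: bool = False
) -> dict:
    """Execute the pipeline (or the named stages) and write a run manifest.

    Fresh stages (outputs present and newer than inputs) are skipped unless
    ``force``.  Returns the manifest dict; it is also written to
    ``<out_dir>/manifest.json``.
    """
    p = _Paths(cfg)
    p.root.mkdir(parents=True, exist_ok=True)
    todo = stages or _STAGE_ORDER
    unknown = set(todo) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")

    manifest_path = p.root / "manifest.json"
    manifest = (
        json.loads(manifest_path.read_text()) if manifest_path.exists() else {"stages": {}}
    )
    cfg_blob = json.dumps(cfg.to_dict(), sort_keys=True).encode()
    manifest["config_hash"] = hashlib.sha256(cfg_blob).hexdigest()
    manifest["version"] = __version__

    for stage in _STAGE_ORDER:
        if stage not in todo:
            continue
        io = _declared_io(stage, cfg, p)
        if not force and io.is_fresh() and stage in manifest["stages"]:
            log.info("stage %s is fresh; skipping", stage)
            continue
        log.info("running stage %s", stage)
        try:
            outputs = STAGES[stage](cfg, p)
        except Exception as exc:  # annotate with the failing stage, then halt
            raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
        manifest["stages"][stage] = {
            "completed_at": time.strftime("%Y-%m-%dT%H:%M:%S"),
            "outputs": {str(path.relative_to(p.root)): _sha256(path) for path in outputs},
        }
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
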