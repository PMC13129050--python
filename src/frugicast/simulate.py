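"""Virtual landscapes, species, and observation data with known truth.

Every pipeline stage can be exercised without external downloads: the
generator builds climate surfaces (smooth directional gradients plus a
spatially autocorrelated noise field) under a current climate and shifted
future scenarios, species with Gaussian niche responses to each climate
layer, presence points sampled proportional to true suitability,
Poisson-count focal visitation records with per-visit seed loads, and
binomial germination trials.  The true suitability surfaces, range maps,
qSDE weights and germination probabilities are retained so estimators
downstream can be scored for bias.

Observation models: visits to a focal plant over ``hours`` of watching are
Poisson with mean ``rate × hours / 10`` (rates are expressed per 10 h, the
field convention); seeds per visit are Poisson around the species' load
mean; germination counts are binomial and germination days geometric on
the 2-day check grid.

``scenario_preset`` packages three assemblage archetypes: evenly shared
dispersal contributions, a dominant contributor that is climate-resilient
(broad thermal niche — the jussara-palm pattern, where a few resilient
thrushes carry most of the function), and a dominant contributor that is
the most climate-sensitive species.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .grids import SCENARIOS, BinaryRangeMap, GridSpec
from .sde import GerminationTrial

__all__ = [
    "LayerGradient",
    "ScenarioShift",
    "VirtualLandscape",
    "VirtualSpecies",
    "SimulatedDataset",
    "make_landscape",
    "true_suitability",
    "true_range",
    "apply_climate_shift",
    "sample_occurrences",
    "simulate_focal_observations",
    "simulate_germination",
    "scenario_preset",
    "PRESETS",
]

#: Suitability level above which a cell belongs to a species' true range.
TRUE_RANGE_THRESHOLD = 0.5

#: Germination checks happen every other day.
CHECK_INTERVAL_DAYS = 2


@dataclass(frozen=True)
class LayerGradient:
    """Planar climate surface: ``base + dx·x̂ + dy·ŷ`` with x̂, ŷ the
    fractional position across the grid, plus smooth noise of the given SD."""

    base: float
    dx: float = 0.0
    dy: float = 0.0
    noise_sd: float = 0.0
    noise_correlation_cells: float = 5.0


@dataclass(frozen=True)
class ScenarioShift:
    """Per-layer transform ``value × mult + add`` for one future scenario."""

    add: dict[str, float] = field(default_factory=dict)
    mult: dict[str, float] = field(default_factory=dict)


@dataclass
class VirtualLandscape:
    """Current climate layers plus registered future shifts, on one grid."""

    grid: GridSpec
    layers: dict[str, np.ndarray]
    shifts: dict[str, ScenarioShift] = field(default_factory=dict)

    def layer_names(self) -> list[str]:
        return list(self.layers)


@dataclass
class VirtualSpecies:
    """A species with a Gaussian niche per climate layer.

    ``niche`` maps layer name → (optimum, breadth); suitability is the
    product over layers of ``exp(−(value − optimum)² / (2 breadth²))``.
    ``visit_rate`` (visits per 10 h) and ``seed_load_mean`` (seeds per
    visit) define the true quantitative contribution
    ``qsde_weight = visit_rate × seed_load_mean``; ``germination_p`` is the
    true post-gut-passage germination probability (None when the species
    has no feeding-trial data).
    """

    species_id: str
    role: str  # "plant" or "frugivore"
    niche: dict[str, tuple[float, float]]
    visit_rate: float = 0.0
    seed_load_mean: float = 0.0
    germination_p: float | None = None
    detection_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.role not in ("plant", "frugivore"):
            raise ValueError("role must be 'plant' or 'frugivore'")
        for layer, (_, breadth) in self.niche.items():
            if breadth <= 0:
                raise ValueError(f"niche breadth for {layer!r} must be positive")
        if self.germination_p is not None and not 0 <= self.germination_p <= 1:
            raise ValueError("germination_p must lie in [0, 1]")

    @property
    def qsde_weight(self) -> float:
        return self.visit_rate * self.seed_load_mean


@dataclass
class SimulatedDataset:
    """A complete synthetic study: landscape, species, tables, and truth."""

    landscape: VirtualLandscape
    species: list[VirtualSpecies]
    plant_id: str
    occurrences: pd.DataFrame  # species, x, y
    observations: pd.DataFrame  # focal-watch table
    germination: pd.DataFrame  # trial table
    truth_suitability: dict[tuple[str, str], np.ndarray]  # (species, scenario)
    truth_ranges: dict[tuple[str, str], BinaryRangeMap]

    @property
    def frugivores(self) -> list[VirtualSpecies]:
        return [s for s in self.species if s.role == "frugivore"]

    @property
    def plant(self) -> VirtualSpecies:
        return next(s for s in self.species if s.species_id == self.plant_id)


# ---------------------------------------------------------------------------
# Landscape


def make_landscape(
    n_rows: int,
    n_cols: int,
    gradient_spec: dict[str, LayerGradient],
    shifts: dict[str, ScenarioShift] | None = None,
    seed: int | np.random.Generator = 0,
) -> VirtualLandscape:
    """Build climate layers from directional gradients plus smooth noise.

    The noise field is white noise smoothed with a Gaussian kernel (spatial
    correlation length in cells per layer spec) and rescaled to exactly the
    requested SD, so layer statistics match the spec regardless of the
    kernel.  Bit-reproducible under the seed.
    """
    grid = GridSpec(n_rows=n_rows, n_cols=n_cols)
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    xs = np.arange(n_cols) / max(n_cols - 1, 1)
    ys = np.arange(n_rows) / max(n_rows - 1, 1)
    xg, yg = np.meshgrid(xs, ys)
    layers: dict[str, np.ndarray] = {}
    for name, g in gradient_spec.items():
        surface = g.base + g.dx * xg + g.dy * yg
        if g.noise_sd > 0:
            noise = rng.standard_normal(grid.shape)
            noise = gaussian_filter(noise, sigma=g.noise_correlation_cells, mode="reflect")
            sd = noise.std()
            if sd > 0:
                noise *= g.noise_sd / sd
            surface = surface + noise
        layers[name] = surface
    return VirtualLandscape(grid=grid, layers=layers, shifts=dict(shifts or {}))


def apply_climate_shift(landscape: VirtualLandscape, scenario: str) -> dict[str, np.ndarray]:
    """Layers under a scenario: identity for ``current``, otherwise the
    registered per-layer ``value × mult + add`` transform."""
    if scenario == "current":
        return {k: v.copy() for k, v in landscape.layers.items()}
    if scenario not in landscape.shifts:
        raise ValueError(
            f"unknown scenario {scenario!r}; registered: "
            f"{['current', *landscape.shifts]}"
        )
    shift = landscape.shifts[scenario]
    out = {}
    for name, layer in landscape.layers.items():
        out[name] = layer * shift.mult.get(name, 1.0) + shift.add.get(name, 0.0)
    return out


def true_suitability(
    species: VirtualSpecies, landscape: VirtualLandscape, scenario: str = "current"
) -> np.ndarray:
    """Gaussian niche response, in (0, 1]: product over layers of
    ``exp(−(layer − optimum)²/(2·breadth²))``."""
    layers = apply_climate_shift(landscape, scenario)
    for name in species.niche:
        if name not in layers:
            raise ValueError(f"species niche references unknown layer {name!r}")
    suit = np.ones(landscape.grid.shape)
    for name, (opt, breadth) in species.niche.items():
        suit *= np.exp(-((layers[name] - opt) ** 2) / (2.0 * breadth**2))
    return suit


def true_range(
    species: VirtualSpecies,
    landscape: VirtualLandscape,
    scenario: str = "current",
    threshold: float = TRUE_RANGE_THRESHOLD,
) -> BinaryRangeMap:
    """True 0/1 range: cells whose true suitability reaches the threshold."""
    suit = true_suitability(species, landscape, scenario)
    return BinaryRangeMap(
        (suit >= threshold).astype(np.int8), species.species_id, scenario, landscape.grid
    )


# ---------------------------------------------------------------------------
# Observation processes


def sample_occurrences(
    suitability: np.ndarray,
    n: int,
    grid: GridSpec,
    detection_rate: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Presence points: cells drawn with probability ∝ suitability ×
    detection rate, each point jittered uniformly within its cell."""
    if n < 1:
        raise ValueError("n must be at least 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    p = np.asarray(suitability, dtype=float).ravel() * detection_rate
    total = p.sum()
    if total <= 0:
        raise ValueError("suitability is zero everywhere; cannot sample")
    idx = rng.choice(p.size, size=n, p=p / total)
    row, col = np.unravel_index(idx, grid.shape)
    x0, y0 = grid.origin
    s = grid.cell_size
    xs = x0 + (col + rng.random(n)) * s
    ys = y0 + (row + rng.random(n)) * s
    return np.column_stack([xs, ys])


def simulate_focal_observations(
    frugivores: list[VirtualSpecies],
    plant_id: str,
    hours: float = 240.0,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Focal-watch table: per frugivore, visits ~ Poisson(rate × hours/10)
    and per-visit seed loads ~ Poisson(load mean), as one table row with
    loads ``;``-joined (the CSV convention of the observations table)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    rows = []
    for sp in frugivores:
        n_visits = int(rng.poisson(sp.visit_rate * hours / 10.0))
        loads = rng.poisson(sp.seed_load_mean, size=n_visits) if n_visits else []
        rows.append(
            {
                "plant_id": plant_id,
                "frugivore_id": sp.species_id,
                "n_visits": n_visits,
                "observation_hours": hours,
                "seeds_per_visit": ";".join(str(int(v)) for v in loads),
            }
        )
    return pd.DataFrame(rows)


def simulate_germination(
    p_true: float,
    n_seeds: int,
    mean_delay_days: float = 10.0,
    seed: int | np.random.Generator = 0,
    treatment: str = "treatment",
) -> GerminationTrial:
    """Binomial germination with geometric delays on the 2-day check grid."""
    if not 0 <= p_true <= 1:
        raise ValueError("p_true must lie in [0, 1]")
    if n_seeds < 1:
        raise ValueError("n_seeds must be at least 1")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    k = int(rng.binomial(n_seeds, p_true))
    p_check = min(1.0, CHECK_INTERVAL_DAYS / max(mean_delay_days, CHECK_INTERVAL_DAYS))
    days = CHECK_INTERVAL_DAYS * rng.geometric(p_check, size=k) if k else np.array([], int)
    return GerminationTrial(
        treatment=treatment, seeds_tested=n_seeds, germination_days=[int(d) for d in days]
    )


def _germination_table(
    frugivores: list[VirtualSpecies],
    plant_id: str,
    n_seeds: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    rows = []
    for sp in frugivores:
        if sp.germination_p is None:
            continue
        trial = simulate_germination(
            sp.germination_p, n_seeds, seed=rng, treatment=sp.species_id
        )
        rows.append(
            {
                "plant_id": plant_id,
                "treatment": sp.species_id,
                "seeds_tested": n_seeds,
                "germination_days": ";".join(str(d) for d in trial.germination_days),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Presets

#: Default desk-scale world.
DEFAULT_GRADIENTS = {
    "temperature": LayerGradient(base=12.0, dx=0.0, dy=12.0, noise_sd=0.4),
    "precipitation": LayerGradient(base=800.0, dx=400.0, dy=0.0, noise_sd=25.0),
}

#: Warming trajectories: a moderate (~2.1 °C) and a business-as-usual
#: (~2.4 °C) pathway, with mild drying.
DEFAULT_SHIFTS = {
    "moderate": ScenarioShift(add={"temperature": 2.1}, mult={"precipitation": 0.97}),
    "business-as-usual": ScenarioShift(
        add={"temperature": 2.4}, mult={"precipitation": 0.94}
    ),
}

PRESETS = ("even_contributions", "skewed_resilient_key", "skewed_sensitive_key")


def _preset_species(name: str) -> list[VirtualSpecies]:
    """Species pools for the three assemblage archetypes.

    The plant has a broad niche centred cool of the landscape midpoint so
    its range persists (but contracts) under warming.  Frugivore thermal
    optima are spread across the plant's range; breadths and contribution
    weights implement the archetype.
    """
    plant = VirtualSpecies(
        "plant_1",
        "plant",
        niche={"temperature": (17.0, 4.0), "precipitation": (1000.0, 300.0)},
    )
    precip_niche = (1000.0, 350.0)
    species = [plant]
    if name == "even_contributions":
        # ten interchangeable dispersers: equal weights, similar breadths
        optima = np.linspace(14.0, 20.0, 10)
        for i, opt in enumerate(optima):
            species.append(
                VirtualSpecies(
                    f"frug_{i + 1:02d}",
                    "frugivore",
                    niche={"temperature": (float(opt), 2.5), "precipitation": precip_niche},
                    visit_rate=2.0,
                    seed_load_mean=5.0,
                    germination_p=0.6,
                )
            )
    elif name in ("skewed_resilient_key", "skewed_sensitive_key"):
        if name == "skewed_resilient_key":
            # broad-niched dominant holding ~75% of total weight
            dom_niche = (15.0, 4.0)
        else:
            # dominant is also the most climate-sensitive (narrowest niche)
            dom_niche = (14.0, 1.2)
        species.append(
            VirtualSpecies(
                "frug_dom",
                "frugivore",
                niche={"temperature": dom_niche, "precipitation": precip_niche},
                visit_rate=20.0,
                seed_load_mean=15.0,
                germination_p=0.7,
            )
        )
        optima = np.linspace(14.0, 20.0, 11)
        rates = np.linspace(0.8, 1.2, 11)
        for i, (opt, rate) in enumerate(zip(optima, rates)):
            species.append(
                VirtualSpecies(
                    f"frug_{i + 1:02d}",
                    "frugivore",
                    niche={"temperature": (float(opt), 2.2), "precipitation": precip_niche},
                    visit_rate=float(rate),
                    seed_load_mean=9.0,
                    germination_p=0.5,
                )
            )
    else:
        raise ValueError(f"unknown preset {name!r}; available: {PRESETS}")
    return species


def scenario_preset(
    name: str,
    seed: int = 0,
    n_rows: int = 100,
    n_cols: int = 100,
    n_occurrences: int = 300,
    observation_hours: float = 240.0,
    n_trial_seeds: int = 50,
) -> SimulatedDataset:
    """A full simulated study under one assemblage archetype.

    Defaults: 100×100 cells, two climate layers, 300 presence points per
    species, 240 focal observation hours per frugivore, 50 seeds per
    germination treatment.
    """
    species = _preset_species(name)
    rng = np.random.default_rng(seed)
    landscape = make_landscape(
        n_rows, n_cols, DEFAULT_GRADIENTS, shifts=DEFAULT_SHIFTS, seed=rng
    )
    plant_id = species[0].species_id
    frugivores = [s for s in species if s.role == "frugivore"]

    occ_rows = []
    truth_suit: dict[tuple[str, str], np.ndarray] = {}
    truth_rng: dict[tuple[str, str], BinaryRangeMap] = {}
    for sp in species:
        for scen in SCENARIOS:
            suit = true_suitability(sp, landscape, scen)
            truth_suit[(sp.species_id, scen)] = suit
            truth_rng[(sp.species_id, scen)] = BinaryRangeMap(
                (suit >= TRUE_RANGE_THRESHOLD).astype(np.int8),
                sp.species_id,
                scen,
                landscape.grid,
            )
        pts = sample_occurrences(
            truth_suit[(sp.species_id, "current")],
            n_occurrences,
            landscape.grid,
            detection_rate=sp.detection_rate,
            seed=rng,
        )
        occ_rows.append(
            pd.DataFrame({"species": sp.species_id, "x": pts[:, 0], "y": pts[:, 1]})
        )

    observations = simulate_focal_observations(
        frugivores, plant_id, hours=observation_hours, seed=rng
    )
    germination = _germination_table(frugivores, plant_id, n_trial_seeds, rng)
    return SimulatedDataset(
        landscape=landscape,
        species=species,
        plant_id=plant_id,
        occurrences=pd.concat(occ_rows, ignore_index=True),
        observations=observations,
        germination=germination,
        truth_suitability=truth_suit,
        truth_ranges=truth_rng,
    )
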