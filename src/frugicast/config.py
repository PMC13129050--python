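"""Pipeline configuration (YAML-backed, validated on load).

Unknown keys are rejected so typos fail loudly; a seed is mandatory
because every stochastic stage draws from it.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "SDMSettings", "SimulateSettings", "DecouplingSettings"]


@dataclass
class SimulateSettings:
    preset: str = "even_contributions"
    n_rows: int = 100
    n_cols: int = 100
    n_occurrences: int = 300
    observation_hours: float = 240.0
    n_trial_seeds: int = 50


@dataclass
class SDMSettings:
    n_replicates: int = 15
    algorithms: list[str] = field(default_factory=lambda: ["logistic"])
    split: float = 0.75
    pad: float = 10.0
    r_threshold: float = 0.6
    thin_distance: float | None = None

    def __post_init__(self) -> None:
        if not 0 < self.split < 1:
            raise ValueError("split must lie in (0, 1)")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")


@dataclass
class DecouplingSettings:
    epsilon: float = 0.05

    def __post_init__(self) -> None:
        if self.epsilon < 0:
            raise ValueError("epsilon must be non-negative")


@dataclass
class PipelineConfig:
    out_dir: str
    seed: int
    simulate: SimulateSettings = field(default_factory=SimulateSettings)
    sdm: SDMSettings = field(default_factory=SDMSettings)
    decoupling: DecouplingSettings = field(default_factory=DecouplingSettings)
    raster_format: str = "asc"

    def __post_init__(self) -> None:
        if self.raster_format not in ("asc", "tif"):
            raise ValueError("raster_format must be 'asc' or 'tif'")

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        data = dict(data)
        if "seed" not in data:
            raise ValueError("config must set a seed")
        known = {"out_dir", "seed", "simulate", "sdm", "decoupling", "raster_format"}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, sub in (
            ("simulate", SimulateSettings),
            ("sdm", SDMSettings),
            ("decoupling", DecouplingSettings),
        ):
            if key in data:
                section = dict(data[key])
                fields = {f for f in sub.__dataclass_fields__}
                bad = set(section) - fields
                if bad:
                    raise ValueError(f"unknown {key} config keys: {sorted(bad)}")
                data[key] = sub(**section)
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        if not isinstance(data, dict):
            raise ValueError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))
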