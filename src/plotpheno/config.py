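"""Declarative run configuration with paper-anchored defaults.

Every knob defaults to the published value where one exists: 1600 px
tiles with 1/4 overlap, the 60% merge rule, 700/400 px plot crops, and
1.9 mm/px ground resolution.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class SimulatorConfig:
    rows: int = 4
    cols: int = 4
    plot_width_m: float = 2.4
    plot_height_m: float = 2.0
    interplot_gap_m: float = 0.4
    plant_spacing_m: float = 0.2
    gsd_mm_per_px: float = 1.9
    rotation_deg: float = 0.0
    center_jitter_frac: float = 0.0
    dropout_rate: float = 0.0
    panicle_density_per_m2: float = 300.0
    stage: str = "first_third"


@dataclass
class TilingConfig:
    tile_size: int = 1600
    overlap_fraction: float = 0.25


@dataclass
class DetectorConfig:
    name: str = "baseline"
    min_area_px: float = 500.0
    exg_offset: float = 0.0
    struct_px: int = 9
    score_threshold: float = 0.5


@dataclass
class MergeConfig:
    overlap_threshold: float = 0.60
    overlap_measure: str = "min_area_fraction"


@dataclass
class GridConfig:
    uniform_boundaries: bool = False
    claim_radius_factor: float = 0.5


@dataclass
class QuantConfig:
    crop_px: int = 700
    crop_px_small: int = 400
    gsd_mm_per_px: float = 1.9
    score_threshold: float = 0.5


@dataclass
class EvalConfig:
    iou_thresholds: list[float] = field(default_factory=lambda: [0.5, 0.75])


@dataclass
class RunConfig:
    simulator: SimulatorConfig = field(default_factory=SimulatorConfig)
    tiling: TilingConfig = field(default_factory=TilingConfig)
    detector: DetectorConfig = field(default_factory=DetectorConfig)
    merge: MergeConfig = field(default_factory=MergeConfig)
    grid: GridConfig = field(default_factory=GridConfig)
    quant: QuantConfig = field(default_factory=QuantConfig)
    evaluation: EvalConfig = field(default_factory=EvalConfig)
    seed: int = 0

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kwargs = {}
        sections = {
            "simulator": SimulatorConfig,
            "tiling": TilingConfig,
            "detector": DetectorConfig,
            "merge": MergeConfig,
            "grid": GridConfig,
            "quant": QuantConfig,
            "evaluation": EvalConfig,
        }
        for name, klass in sections.items():
            if name in d:
                kwargs[name] = klass(**d[name])
        if "seed" in d:
            kwargs["seed"] = int(d["seed"])
        return cls(**kwargs)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
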