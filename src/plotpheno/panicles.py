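"""Panicle-level quantities: counts, density per area, angle-class scheme.

PNpA (panicle number per unit area, count/m²) is the yield component the
pipeline ultimately reports, either from detections over a fixed crop or
from the traditional k-plant field-sampling estimator.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .detect import DetectionSet
from .staging import StageLabel


class AngleClass(str, Enum):
    """Panicle curvature class: angle between panicle and the vertical."""

    DEG0 = "deg0"
    DEG15 = "deg15"
    DEG45 = "deg45"
    DEG90 = "deg90"


#: class centers in degrees, ascending
ANGLE_CLASS_CENTERS: dict[AngleClass, float] = {
    AngleClass.DEG0: 0.0,
    AngleClass.DEG15: 15.0,
    AngleClass.DEG45: 45.0,
    AngleClass.DEG90: 90.0,
}

_ORDERED_CLASSES = list(ANGLE_CLASS_CENTERS)
# bin edges at midpoints of adjacent centers; an angle on an edge rounds up
_EDGES = (7.5, 30.0, 67.5)

#: plants per m² implied by the two trial spacings (20 cm and 13 cm grids)
PLANT_DENSITY_FIELD1 = 1.0 / (0.20 * 0.20)  # 25 /m²
PLANT_DENSITY_FIELD2 = 1.0 / (0.13 * 0.13)  # ~59.2 /m²


@dataclass(frozen=True)
class PNpARecord:
    plot_id: str
    panicle_count: int
    reference_area_m2: float
    pnpa: float
    stage: Optional[StageLabel] = None

    def __post_init__(self) -> None:
        if self.reference_area_m2 <= 0:
            raise ValueError("reference area must be positive")


@dataclass(frozen=True)
class PlantSample:
    """Per-plant panicle counts for one plot, with the stand density."""

    plot_id: str
    per_plant_panicles: tuple[int, ...]
    plants_per_m2: float

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.per_plant_panicles):
            raise ValueError("panicle counts must be non-negative")
        if self.plants_per_m2 <= 0:
            raise ValueError("plant density must be positive")


def count_panicles(detections: DetectionSet, score_threshold: float = 0.0) -> int:
    """Number of panicle instances at or above the score threshold."""
    return sum(1 for i in detections.instances if i.score >= score_threshold)


def pnpa_from_crop(
    count: int,
    crop_px: int,
    gsd_mm_per_px: float,
    plot_id: str = "",
    stage: Optional[StageLabel] = None,
) -> PNpARecord:
    """PNpA over a square crop of ``crop_px`` pixels at the given GSD."""
    if crop_px <= 0 or gsd_mm_per_px <= 0:
        raise ValueError("crop size and gsd must be positive")
    area_m2 = (crop_px * gsd_mm_per_px / 1000.0) ** 2
    return PNpARecord(plot_id, count, area_m2, count / area_m2, stage)


def pnpa_from_plant_sample(
    sample: PlantSample,
    k: int = 6,
    seed: Optional[int] = None,
) -> PNpARecord:
    """Traditional estimator: mean panicles over k sampled plants x density.

    Plants are drawn without replacement; ``seed`` fixes the draw.
    """
    n = len(sample.per_plant_panicles)
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} recorded plants")
    rng = np.random.default_rng(seed)
    idx = rng.choice(n, size=k, replace=False)
    mean_per_plant = float(np.mean([sample.per_plant_panicles[i] for i in idx]))
    pnpa = mean_per_plant * sample.plants_per_m2
    # reference area: the ground area occupied by one plant times k
    area = k / sample.plants_per_m2
    count = int(round(mean_per_plant * k))
    return PNpARecord(sample.plot_id, count, area, pnpa)


def angle_to_class(angle_deg: float) -> AngleClass:
    """Nearest angle class; edge angles (7.5, 30, 67.5) round upward."""
    if not (0.0 <= angle_deg <= 90.0):
        raise ValueError(f"angle {angle_deg} outside [0, 90]")
    i = int(np.searchsorted(_EDGES, angle_deg, side="left"))
    if i < len(_EDGES) and angle_deg == _EDGES[i]:
        i += 1
    return _ORDERED_CLASSES[i]


def predict_plot_class(per_panicle_classes: Sequence[AngleClass]) -> AngleClass:
    """Plot-level label: modal class, ties broken toward the larger angle."""
    if not per_panicle_classes:
        raise ValueError("no panicle classes given")
    counts = {c: 0 for c in _ORDERED_CLASSES}
    for c in per_panicle_classes:
        counts[AngleClass(c)] += 1
    best = max(_ORDERED_CLASSES, key=lambda c: (counts[c], ANGLE_CLASS_CENTERS[c]))
    return best
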