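"""Synthetic UAV-style field mosaics with exact ground truth.

Renders an axis-misaligned rectangular grid of textured plots on a flat
soil background, together with plot boxes, panicle records and per-plot
calendars.  Geometry is the quantity under test downstream, so appearance
is deliberately schematic: filled rectangles with per-pixel hue noise and
elliptical panicle blobs, no radiometric realism.

Truth boxes are axis-aligned in the pre-rotation frame; the applied
rotation is stored as an affine transform on both the truth and the
returned mosaic, matching the pipeline's rotate-then-segment order.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .detect import (
    PANICLE_CATEGORY,
    PLOT_CATEGORY,
    DetectionInstance,
    DetectionSet,
    write_coco,
    write_labelme,
)
from .errors import FormatError, RasterSizeError
from .mosaic import AffineTransform2D, Mosaic, Tile
from .panicles import AngleClass, ANGLE_CLASS_CENTERS
from .staging import PlotCalendar, StageLabel

_STAGE_PALETTES = {
    # (canopy RGB, speck RGB or None)
    StageLabel.FIRST_THIRD: ((60, 150, 60), None),
    StageLabel.SECOND_THIRD: ((60, 150, 60), (210, 215, 140)),
    StageLabel.FINAL_THIRD: ((140, 135, 55), (225, 190, 90)),
}
_SOIL_RGB = (60, 55, 45)


@dataclass(frozen=True)
class SyntheticFieldConfig:
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
    stage: StageLabel = StageLabel.FIRST_THIRD
    angle_class_mix: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    seed: int = 0
    fhs_day_range: tuple[int, int] = (88, 96)
    ms_day_range: tuple[int, int] = (118, 126)
    max_pixels: float = 6e8

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("rows and cols must be at least 1")
        for name in ("plot_width_m", "plot_height_m", "interplot_gap_m",
                     "plant_spacing_m", "gsd_mm_per_px"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.dropout_rate < 1):
            raise ValueError("dropout_rate must be in [0, 1)")
        if abs(sum(self.angle_class_mix) - 1.0) > 1e-9:
            raise ValueError("angle_class_mix must sum to 1")
        if self.panicle_density_per_m2 < 0:
            raise ValueError("panicle density must be non-negative")
        StageLabel(self.stage)

    @property
    def plot_width_px(self) -> float:
        return self.plot_width_m * 1000.0 / self.gsd_mm_per_px

    @property
    def plot_height_px(self) -> float:
        return self.plot_height_m * 1000.0 / self.gsd_mm_per_px

    @property
    def gap_px(self) -> float:
        return self.interplot_gap_m * 1000.0 / self.gsd_mm_per_px

    @property
    def pitch_px(self) -> tuple[float, float]:
        return (self.plot_width_px + self.gap_px, self.plot_height_px + self.gap_px)


def field1_config(**overrides) -> SyntheticFieldConfig:
    """The 2.4 m x 2 m / 40 cm gap trial layout at 1.9 mm/px."""
    return SyntheticFieldConfig(**overrides)


def field2_config(**overrides) -> SyntheticFieldConfig:
    """The 1 m x 1 m / 30 cm gap layout (13 cm plant spacing)."""
    base = dict(
        plot_width_m=1.0, plot_height_m=1.0, interplot_gap_m=0.3, plant_spacing_m=0.13
    )
    base.update(overrides)
    return SyntheticFieldConfig(**base)


@dataclass(frozen=True)
class PanicleRecord:
    center: tuple[float, float]  # px, pre-rotation frame
    axes: tuple[float, float]  # ellipse semi-axes, px
    angle_class: AngleClass


@dataclass
class SyntheticFieldTruth:
    """Exact ground truth for one generated field (pre-rotation frame)."""

    plot_boxes: np.ndarray  # (rows*cols, 4) half-open, row-major cells
    plot_centers: np.ndarray  # (rows, cols, 2)
    panicles_per_plot: list[list[PanicleRecord]]
    calendar: list[PlotCalendar]
    transform: AffineTransform2D
    config: SyntheticFieldConfig = field(repr=False, default=None)

    @property
    def n_plots(self) -> int:
        return len(self.plot_boxes)


def _layout(config: SyntheticFieldConfig, rng: np.random.Generator):
    w, h = config.plot_width_px, config.plot_height_px
    gap = config.gap_px
    px, py = config.pitch_px
    jitter = config.center_jitter_frac
    margin = gap + max(px, py) * jitter
    centers = np.empty((config.rows, config.cols, 2))
    for i in range(config.rows):
        for j in range(config.cols):
            cx = margin + w / 2.0 + j * px
            cy = margin + h / 2.0 + i * py
            if jitter > 0:
                cx += rng.uniform(-jitter, jitter) * px
                cy += rng.uniform(-jitter, jitter) * py
            centers[i, j] = (cx, cy)
    boxes = np.empty((config.rows * config.cols, 4))
    boxes[:, 0] = centers[..., 0].ravel() - w / 2.0
    boxes[:, 1] = centers[..., 1].ravel() - h / 2.0
    boxes[:, 2] = centers[..., 0].ravel() + w / 2.0
    boxes[:, 3] = centers[..., 1].ravel() + h / 2.0
    width0 = 2 * margin + (config.cols - 1) * px + w
    height0 = 2 * margin + (config.rows - 1) * py + h
    return boxes, centers, width0, height0


def generate_field(config: SyntheticFieldConfig) -> tuple[Mosaic, SyntheticFieldTruth]:
    """Render a synthetic field mosaic and return it with exact truth.

    Deterministic: the same config (including seed) yields bit-identical
    raster and truth.
    """
    from skimage.draw import ellipse as draw_ellipse
    from skimage.draw import polygon as draw_polygon

    rng = np.random.default_rng(config.seed)
    boxes, centers, width0, height0 = _layout(config, rng)

    # forward transform: rotate about the pre-rotation canvas center, then
    # shift so the rotated canvas sits at non-negative coordinates
    rot = AffineTransform2D.rotation(
        config.rotation_deg, ((width0 - 1) / 2.0, (height0 - 1) / 2.0)
    )
    corners = np.array(
        [[0, 0], [width0 - 1, 0], [0, height0 - 1], [width0 - 1, height0 - 1]]
    )
    mapped = rot.apply(corners)
    mins, maxs = mapped.min(axis=0), mapped.max(axis=0)
    transform = AffineTransform2D.translation(-mins[0], -mins[1]).compose(rot)
    out_w = int(np.ceil(maxs[0] - mins[0])) + 1
    out_h = int(np.ceil(maxs[1] - mins[1])) + 1
    if out_w * out_h > config.max_pixels:
        raise RasterSizeError(
            f"raster {out_w}x{out_h} exceeds max_pixels={config.max_pixels:.0f}"
        )

    raster = np.empty((out_h, out_w, 3), dtype=np.uint8)
    raster[:] = _SOIL_RGB
    canopy, speck = _STAGE_PALETTES[StageLabel(config.stage)]

    # plots: rotated rectangles rasterized directly on the final canvas
    for box in boxes:
        x0, y0, x1, y1 = box
        poly = transform.apply(
            np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])
        )
        rr, cc = draw_polygon(poly[:, 1], poly[:, 0], shape=(out_h, out_w))
        noise = rng.integers(-12, 13, size=(rr.size, 3), dtype=np.int16)
        raster[rr, cc] = np.clip(np.asarray(canopy, dtype=np.int16) + noise, 0, 255).astype(np.uint8)

    # panicles: Poisson counts per plot, centers strictly inside the box
    area_m2 = config.plot_width_m * config.plot_height_m
    classes = list(ANGLE_CLASS_CENTERS)
    panicles_per_plot: list[list[PanicleRecord]] = []
    for box in boxes:
        x0, y0, x1, y1 = box
        n = int(rng.poisson(config.panicle_density_per_m2 * area_m2))
        records = []
        for _ in range(n):
            cx = rng.uniform(x0 + 1.0, x1 - 1.0)
            cy = rng.uniform(y0 + 1.0, y1 - 1.0)
            a = rng.uniform(25.0, 40.0) / config.gsd_mm_per_px  # semi-major, px
            b = a * rng.uniform(0.35, 0.6)
            cls = classes[int(rng.choice(4, p=config.angle_class_mix))]
            records.append(PanicleRecord((cx, cy), (a, b), cls))
            if speck is not None:
                gcx, gcy = transform.apply([(cx, cy)])[0]
                tilt = np.deg2rad(ANGLE_CLASS_CENTERS[cls] + config.rotation_deg)
                rr, cc = draw_ellipse(gcy, gcx, b, a, shape=(out_h, out_w), rotation=tilt)
                raster[rr, cc] = speck
        panicles_per_plot.append(records)

    # per-plot calendars spread uniformly over the configured ranges
    calendar = []
    for k in range(len(boxes)):
        fhs = int(rng.integers(config.fhs_day_range[0], config.fhs_day_range[1]))
        ms = int(rng.integers(config.ms_day_range[0], config.ms_day_range[1]))
        calendar.append(PlotCalendar(plot_id=f"plot_{k:04d}", fhs_day=fhs, ms_day=ms))

    truth = SyntheticFieldTruth(
        plot_boxes=boxes,
        plot_centers=centers,
        panicles_per_plot=panicles_per_plot,
        calendar=calendar,
        transform=transform,
        config=config,
    )
    return Mosaic(raster, config.gsd_mm_per_px, transform), truth


def simulate_detections(
    truth: SyntheticFieldTruth,
    jitter_px: float = 0.0,
    dropout_rate: float = 0.0,
    split_rate: float = 0.0,
    seed: int = 0,
) -> DetectionSet:
    """Plot detections derived from truth boxes, bypassing imagery.

    Boxes are translated by centred Gaussian noise (sigma ``jitter_px``);
    a ``dropout_rate`` fraction (rounded count) is deleted; a
    ``split_rate`` fraction is emitted as two overlapping fragments (the
    left and right 80% of the box) emulating cross-tile duplicates.
    """
    for name, rate in (("dropout_rate", dropout_rate), ("split_rate", split_rate)):
        if not (0 <= rate <= 1):
            raise ValueError(f"{name} must be in [0, 1]")
    rng = np.random.default_rng(seed)
    n = truth.n_plots
    n_drop = int(round(dropout_rate * n))
    dropped = set(rng.choice(n, size=n_drop, replace=False).tolist()) if n_drop else set()
    survivors = [i for i in range(n) if i not in dropped]
    n_split = int(round(split_rate * len(survivors)))
    split_ids = (
        set(rng.choice(len(survivors), size=n_split, replace=False).tolist())
        if n_split
        else set()
    )
    instances = []
    for pos, i in enumerate(survivors):
        x0, y0, x1, y1 = truth.plot_boxes[i]
        if jitter_px > 0:
            dx, dy = rng.normal(0.0, jitter_px, size=2)
            x0, y0, x1, y1 = x0 + dx, y0 + dy, x1 + dx, y1 + dy
        if pos in split_ids:
            w = x1 - x0
            instances.append(DetectionInstance(box=(x0, y0, x0 + 0.8 * w, y1)))
            instances.append(DetectionInstance(box=(x1 - 0.8 * w, y0, x1, y1)))
        else:
            instances.append(DetectionInstance(box=(x0, y0, x1, y1)))
    return DetectionSet(instances, frame="mosaic")


class SyntheticTileDetector:
    """Truth-backed per-tile detector for pipeline tests and benchmarks.

    Emits, for each tile, every truth plot box at least
    ``min_fragment_frac``-visible in the tile (with per-plot Gaussian box
    jitter and a globally dropped fraction), mapped into the current mosaic
    frame.  Satisfies the ``detector(tile, mosaic)`` contract of
    :func:`plotpheno.gridseg.segment_plots`.
    """

    def __init__(
        self,
        truth: SyntheticFieldTruth,
        jitter_px: float = 0.0,
        dropout_rate: float = 0.0,
        seed: int = 0,
        min_fragment_frac: float = 0.25,
    ):
        rng = np.random.default_rng(seed)
        n = truth.n_plots
        n_drop = int(round(dropout_rate * n))
        dropped = (
            set(rng.choice(n, size=n_drop, replace=False).tolist()) if n_drop else set()
        )
        self.boxes = []
        for i in range(n):
            if i in dropped:
                continue
            box = truth.plot_boxes[i].copy()
            if jitter_px > 0:
                dx, dy = rng.normal(0.0, jitter_px, size=2)
                box += np.array([dx, dy, dx, dy])
            self.boxes.append(box)
        self.min_fragment_frac = min_fragment_frac

    def __call__(self, tile: Tile, mosaic: Mosaic) -> DetectionSet:
        # the mosaic's accumulated transform maps truth frame -> raster frame
        to_raster = mosaic.transform
        tx0, ty0 = tile.offset
        th, tw = tile.raster.shape[:2]
        out = DetectionSet([], frame="tile")
        for box in self.boxes:
            x0, y0, x1, y1 = box
            pts = to_raster.apply(
                np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]])
            )
            bx0, by0 = pts.min(axis=0)
            bx1, by1 = pts.max(axis=0)
            ix0, iy0 = max(bx0, tx0), max(by0, ty0)
            ix1, iy1 = min(bx1, tx0 + tw), min(by1, ty0 + th)
            if ix1 <= ix0 or iy1 <= iy0:
                continue
            frac = ((ix1 - ix0) * (iy1 - iy0)) / ((bx1 - bx0) * (by1 - by0))
            if frac < self.min_fragment_frac:
                continue
            # emit the whole box (not clipped to the tile): repeated
            # emissions from overlapping tiles are then exact duplicates,
            # which the 60% overlap rule merges by construction
            out.instances.append(
                DetectionInstance(
                    box=(bx0 - tx0, by0 - ty0, bx1 - tx0, by1 - ty0),
                    score=1.0,
                    label=PLOT_CATEGORY,
                    source_tile=tile.index,
                )
            )
        return out


def truth_boxes_in_frame(truth: SyntheticFieldTruth, mosaic: Mosaic) -> np.ndarray:
    """Axis-aligned bounds of the truth plot boxes in ``mosaic``'s frame."""
    to_raster = mosaic.transform
    out = np.empty_like(truth.plot_boxes)
    for k, (x0, y0, x1, y1) in enumerate(truth.plot_boxes):
        pts = to_raster.apply(np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1]]))
        out[k] = (*pts.min(axis=0), *pts.max(axis=0))
    return out


def _truth_to_detection_set(truth: SyntheticFieldTruth, category: str) -> DetectionSet:
    insts = []
    if category == PLOT_CATEGORY:
        for box in truth.plot_boxes:
            insts.append(DetectionInstance(box=tuple(box), label=PLOT_CATEGORY))
    elif category == PANICLE_CATEGORY:
        for records in truth.panicles_per_plot:
            for rec in records:
                cx, cy = rec.center
                a, b = rec.axes
                insts.append(
                    DetectionInstance(
                        box=(cx - a, cy - a, cx + a, cy + a), label=PANICLE_CATEGORY
                    )
                )
    else:
        raise FormatError(f"unknown category '{category}'")
    return DetectionSet(insts, frame="mosaic")


def write_truth(
    truth: SyntheticFieldTruth,
    format: str,
    path: str | Path,
    category: str = PLOT_CATEGORY,
) -> None:
    """Serialize truth annotations as COCO or LabelMe JSON."""
    dets = _truth_to_detection_set(truth, category)
    if format == "coco":
        write_coco(dets, path)
    elif format == "labelme":
        write_labelme(dets, path)
    else:
        raise FormatError(f"unsupported truth format '{format}'")


def write_calendar_csv(truth: SyntheticFieldTruth, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["plot_id", "fhs_day", "ms_day"])
        for cal in truth.calendar:
            writer.writerow([cal.plot_id, cal.fhs_day, cal.ms_day])


def read_calendar_csv(path: str | Path) -> list[PlotCalendar]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(
                PlotCalendar(row["plot_id"], float(row["fhs_day"]), float(row["ms_day"]))
            )
    return out
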