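"""Plot-grid recovery: cross-tile merge, line fitting, grid completion.

This is the heart of the pipeline.  Tile-level plot detections are merged
(two instances whose overlap exceeds a threshold are fragments of one
plot), grid lines are fitted through the merged centroids row- and
column-wise, and missed plots are completed from the line intersections
with boundaries sized by the mean detected plot.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np

from .detect import DetectionInstance, DetectionSet, PLOT_CATEGORY
from .errors import (
    BoundsError,
    FrameError,
    GridUndeterminedError,
    InsufficientGridError,
    PipelineStageError,
)
from .mosaic import (
    AffineTransform2D,
    Mosaic,
    Tile,
    estimate_orientation,
    rotate_mosaic,
    tile_mosaic,
    to_mosaic_frame,
)


@dataclass(frozen=True)
class MergeParams:
    overlap_threshold: float = 0.60
    overlap_measure: str = "min_area_fraction"  # or "iou"

    def __post_init__(self) -> None:
        if not (0 < self.overlap_threshold <= 1):
            raise ValueError("overlap_threshold must be in (0, 1]")
        if self.overlap_measure not in ("min_area_fraction", "iou"):
            raise ValueError(f"unknown overlap measure '{self.overlap_measure}'")


@dataclass
class GridLine:
    """A fitted near-axis-aligned line through member centers.

    Row lines are ``y = slope * x + intercept``; column lines are
    ``x = slope * y + intercept``.
    """

    orientation: str  # {"row", "col"}
    slope: float
    intercept: float
    member_ids: list[int]
    residual_rms: float = 0.0


@dataclass
class PlotGrid:
    row_lines: list[GridLine]
    col_lines: list[GridLine]
    centers: np.ndarray  # (n_rows, n_cols, 2)
    provenance: np.ndarray  # (n_rows, n_cols) of {"detected", "completed"}
    mean_size: tuple[float, float]  # (w_bar, h_bar) over detected plots
    boundaries: np.ndarray  # (n_rows, n_cols, 4)
    to_original: AffineTransform2D = field(default_factory=AffineTransform2D.identity)

    @property
    def shape(self) -> tuple[int, int]:
        return self.centers.shape[:2]

    @property
    def n_plots(self) -> int:
        return self.centers.shape[0] * self.centers.shape[1]


# ---------------------------------------------------------------------------
# Merging


def _pair_overlap(a: DetectionInstance, b: DetectionInstance, measure: str) -> float:
    ax0, ay0, ax1, ay1 = a.box
    bx0, by0, bx1, by1 = b.box
    ix0, iy0 = max(ax0, bx0), max(ay0, by0)
    ix1, iy1 = min(ax1, bx1), min(ay1, by1)
    if ix1 <= ix0 or iy1 <= iy0:
        return 0.0
    use_masks = a.mask is not None and b.mask is not None
    if use_masks:
        h, w = int(np.ceil(iy1 - iy0)), int(np.ceil(ix1 - ix0))

        def sub(inst: DetectionInstance) -> np.ndarray:
            ox = int(round(ix0 - inst.box[0]))
            oy = int(round(iy0 - inst.box[1]))
            return inst.mask[oy : oy + h, ox : ox + w]

        sa, sb = sub(a), sub(b)
        hh = min(sa.shape[0], sb.shape[0])
        ww = min(sa.shape[1], sb.shape[1])
        inter = float(np.logical_and(sa[:hh, :ww], sb[:hh, :ww]).sum())
        area_a, area_b = float(a.mask.sum()), float(b.mask.sum())
    else:
        inter = (ix1 - ix0) * (iy1 - iy0)
        area_a = (ax1 - ax0) * (ay1 - ay0)
        area_b = (bx1 - bx0) * (by1 - by0)
    if measure == "min_area_fraction":
        denom = min(area_a, area_b)
    else:
        denom = area_a + area_b - inter
    return inter / denom if denom > 0 else 0.0


def _merge_component(members: list[DetectionInstance]) -> DetectionInstance:
    if len(members) == 1:
        return members[0]
    x0 = min(m.box[0] for m in members)
    y0 = min(m.box[1] for m in members)
    x1 = max(m.box[2] for m in members)
    y1 = max(m.box[3] for m in members)
    mask = None
    if all(m.mask is not None for m in members):
        ix0, iy0 = int(np.floor(x0)), int(np.floor(y0))
        ix1, iy1 = int(np.ceil(x1)), int(np.ceil(y1))
        x0, y0, x1, y1 = float(ix0), float(iy0), float(ix1), float(iy1)
        mask = np.zeros((iy1 - iy0, ix1 - ix0), dtype=bool)
        for m in members:
            ox = int(round(m.box[0])) - ix0
            oy = int(round(m.box[1])) - iy0
            mh, mw = m.mask.shape
            mask[oy : oy + mh, ox : ox + mw] |= m.mask
    return DetectionInstance(
        box=(x0, y0, x1, y1),
        mask=mask,
        score=max(m.score for m in members),
        label=members[0].label,
        source_tile=None,
    )


def merge_detections(detections: DetectionSet, params: MergeParams = MergeParams()) -> DetectionSet:
    """Collapse groups of mutually overlapping instances into single plots.

    Builds a graph with an edge wherever the pairwise overlap measure
    exceeds the threshold; each connected component becomes one instance
    (union mask / bounding box of the union, max member score).  The output
    is sorted canonically and therefore independent of input order.
    """
    if detections.frame != "mosaic":
        raise FrameError("merge_detections requires mosaic-frame detections")
    insts = detections.instances
    n = len(insts)
    parent = list(range(n))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    # sort-by-x sweep keeps the pair loop near-linear on grid layouts
    order = sorted(range(n), key=lambda k: insts[k].box[0])
    for a_pos, i in enumerate(order):
        for j in order[a_pos + 1 :]:
            if insts[j].box[0] >= insts[i].box[2]:
                break
            if _pair_overlap(insts[i], insts[j], params.overlap_measure) > params.overlap_threshold:
                parent[find(i)] = find(j)

    groups: dict[int, list[DetectionInstance]] = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(insts[i])
    merged = [_merge_component(g) for g in groups.values()]
    merged.sort(key=lambda m: (m.box[0], m.box[1], m.box[2], m.box[3], -m.score))
    return DetectionSet(merged, frame="mosaic", image_id=detections.image_id)


# ---------------------------------------------------------------------------
# Row/column clustering and line fitting


def _split_threshold(diffs: np.ndarray) -> Optional[float]:
    """Two-class split of consecutive gaps (between-class variance maximum).

    Returns the gap threshold separating within-group spacing from the grid
    pitch, or None when the gaps carry no two-scale structure (single
    group).  Robust to duplicate centroids from unmerged cross-tile
    fragments, whose gaps sit between jitter scale and pitch scale.
    """
    d = np.sort(diffs)
    n = len(d)
    if d[-1] <= 0:
        return None
    best_k, best_var = None, -1.0
    for k in range(1, n):  # small class d[:k], large class d[k:]
        m1, m2 = d[:k].mean(), d[k:].mean()
        var = k * (n - k) * (m2 - m1) ** 2
        if var > best_var:
            best_var, best_k = var, k
    small, large = d[:best_k], d[best_k:]
    # demand clear scale separation, else treat as one group
    if small.max() > 0 and large.min() < 3.0 * small.max():
        return None
    return float((small.max() + large.min()) / 2.0)


def _cluster_1d(values: np.ndarray) -> list[list[int]]:
    order = np.argsort(values, kind="stable")
    v = values[order]
    if len(v) < 2:
        return [order.tolist()]
    diffs = np.diff(v)
    if diffs.max() <= 0:
        return [order.tolist()]
    if diffs.min() / diffs.max() > 0.75:
        # all gaps alike and nonzero: a single rank of plots at grid pitch
        return [[int(i)] for i in order]
    thr = _split_threshold(diffs)
    if thr is None:
        return [order.tolist()]
    groups: list[list[int]] = [[int(order[0])]]
    for k, d in enumerate(diffs):
        if d > thr:
            groups.append([])
        groups[-1].append(int(order[k + 1]))
    return groups


def cluster_rows_cols(centers: Sequence[tuple[float, float]]) -> tuple[list[list[int]], list[list[int]]]:
    """Group center indices into rows (by y) and columns (by x).

    Rows/columns are split at gaps large relative to the estimated grid
    pitch; every center lands in exactly one row and one column group.
    """
    pts = np.asarray(centers, dtype=float)
    if len(pts) < 4:
        raise InsufficientGridError(f"need >= 4 centers, got {len(pts)}")
    rows = _cluster_1d(pts[:, 1])
    cols = _cluster_1d(pts[:, 0])
    return rows, cols


def fit_grid_lines(
    groups: list[list[int]],
    centers: Sequence[tuple[float, float]],
    orientation: str,
) -> list[GridLine]:
    """Least-squares line per group; singleton groups get slope 0.

    For rows the fit is y over x; for columns x over y.
    """
    pts = np.asarray(centers, dtype=float)
    lines = []
    for g in groups:
        sub = pts[g]
        if orientation == "row":
            ind, dep = sub[:, 0], sub[:, 1]
        else:
            ind, dep = sub[:, 1], sub[:, 0]
        if len(g) < 2 or np.ptp(ind) == 0:
            slope, intercept = 0.0, float(dep.mean())
        else:
            slope, intercept = np.polyfit(ind, dep, 1)
        resid = dep - (slope * ind + intercept)
        lines.append(
            GridLine(
                orientation=orientation,
                slope=float(slope),
                intercept=float(intercept),
                member_ids=list(g),
                residual_rms=float(np.sqrt(np.mean(resid**2))),
            )
        )
    return lines


def _intersect(row: GridLine, col: GridLine) -> tuple[float, float]:
    # y = a1 x + b1 ;  x = a2 y + b2
    a1, b1, a2, b2 = row.slope, row.intercept, col.slope, col.intercept
    denom = 1.0 - a1 * a2
    if abs(denom) < 1e-9:
        raise GridUndeterminedError("row and column lines are parallel")
    x = (a2 * b1 + b2) / denom
    return (x, a1 * x + b1)


def complete_grid(
    row_lines: list[GridLine],
    col_lines: list[GridLine],
    detected: DetectionSet,
    uniform_boundaries: bool = False,
    claim_radius_factor: float = 0.5,
) -> PlotGrid:
    """Fill the grid from line intersections and size missed plots.

    Every row/column line intersection is a cell center.  A cell is
    "detected" when a detection centroid lies within
    ``claim_radius_factor * min(mean_w, mean_h)`` of it (nearest wins, one
    detection claims one cell); remaining cells are "completed" with
    mean-size boundaries centred on the intersection.
    """
    if not row_lines or not col_lines:
        raise GridUndeterminedError("need at least one row line and one col line")
    rows = sorted(row_lines, key=lambda l: l.intercept)
    cols = sorted(col_lines, key=lambda l: l.intercept)
    nr, nc = len(rows), len(cols)
    centers = np.empty((nr, nc, 2))
    for i, rl in enumerate(rows):
        for j, cl in enumerate(cols):
            centers[i, j] = _intersect(rl, cl)

    insts = detected.instances
    if not insts:
        raise InsufficientGridError("no detections to size the grid from")
    widths = np.array([m.box[2] - m.box[0] for m in insts])
    heights = np.array([m.box[3] - m.box[1] for m in insts])
    w_bar, h_bar = float(widths.mean()), float(heights.mean())
    radius = claim_radius_factor * min(w_bar, h_bar)

    cents = np.array([m.centroid() for m in insts])
    flat = centers.reshape(-1, 2)
    d = np.linalg.norm(cents[:, None, :] - flat[None, :, :], axis=2)
    pairs = [
        (d[k, c], k, c)
        for k in range(len(insts))
        for c in range(len(flat))
        if d[k, c] <= radius
    ]
    pairs.sort()
    cell_owner: dict[int, int] = {}
    used_insts: set[int] = set()
    for dist, k, c in pairs:
        if c in cell_owner or k in used_insts:
            continue
        cell_owner[c] = k
        used_insts.add(k)

    provenance = np.full((nr, nc), "completed", dtype=object)
    boundaries = np.empty((nr, nc, 4))
    for c in range(len(flat)):
        i, j = divmod(c, nc)
        cx, cy = flat[c]
        if c in cell_owner:
            provenance[i, j] = "detected"
            if uniform_boundaries:
                boundaries[i, j] = (cx - w_bar / 2, cy - h_bar / 2, cx + w_bar / 2, cy + h_bar / 2)
            else:
                boundaries[i, j] = insts[cell_owner[c]].box
        else:
            boundaries[i, j] = (cx - w_bar / 2, cy - h_bar / 2, cx + w_bar / 2, cy + h_bar / 2)
    return PlotGrid(
        row_lines=rows,
        col_lines=cols,
        centers=centers,
        provenance=provenance,
        mean_size=(w_bar, h_bar),
        boundaries=boundaries,
    )


# ---------------------------------------------------------------------------
# End-to-end orchestration


def segment_plots(
    mosaic: Mosaic,
    detector: Callable[[Tile, Mosaic], DetectionSet],
    tile_size: int = 1600,
    overlap_fraction: float = 0.25,
    merge_params: MergeParams = MergeParams(),
    score_threshold: float = 0.5,
    uniform_boundaries: bool = False,
) -> PlotGrid:
    """Rotate, tile, detect, merge, fit and complete — the full grid pipeline.

    Returns the grid in the rotated (axis-aligned) frame; the grid's
    ``to_original`` transform maps its coordinates back to the input mosaic.
    Stage failures are re-raised as :class:`PipelineStageError` tagged with
    the stage name.
    """

    def run(stage: str, fn, *args, **kwargs):
        try:
            return fn(*args, **kwargs)
        except PipelineStageError:
            raise
        except Exception as exc:
            raise PipelineStageError(stage, exc) from exc

    angle = run("orientation", estimate_orientation, mosaic)
    rotated = run("rotation", rotate_mosaic, mosaic, -angle)
    tiles = run("tiling", tile_mosaic, rotated, tile_size, overlap_fraction)

    def detect_all() -> DetectionSet:
        out = DetectionSet([], frame="mosaic")
        for tile in tiles:
            ds = detector(tile, rotated)
            for inst in ds.instances:
                if inst.score < score_threshold:
                    continue
                out.instances.append(
                    DetectionInstance(
                        box=to_mosaic_frame(inst.box, tile),
                        mask=inst.mask,
                        score=inst.score,
                        label=inst.label,
                        source_tile=tile.index,
                    )
                )
        return out

    dets = run("detection", detect_all)
    merged = run("merge", merge_detections, dets, merge_params)
    cents = [m.centroid() for m in merged.instances]
    row_groups, col_groups = run("clustering", cluster_rows_cols, cents)
    row_lines = run("fitting", fit_grid_lines, row_groups, cents, "row")
    col_lines = run("fitting", fit_grid_lines, col_groups, cents, "col")
    grid = run(
        "completion",
        complete_grid,
        row_lines,
        col_lines,
        merged,
        uniform_boundaries,
    )
    # rotated frame -> input mosaic frame
    step = rotated.transform.compose(mosaic.transform.inverse())
    grid.to_original = step.inverse()
    return grid


def crop_plot(
    mosaic: Mosaic,
    boundary: Sequence[float],
    out_size_px: int,
) -> tuple[np.ndarray, tuple[int, int]]:
    """Square crop of ``out_size_px`` centred on a boundary, zero-padded.

    Returns the crop and its (x0, y0) offset in the mosaic frame (may be
    negative when padding was applied on the top/left).
    """
    if out_size_px < 1:
        raise ValueError("out_size_px must be positive")
    x0b, y0b, x1b, y1b = boundary
    cx = int(round((x0b + x1b) / 2.0))
    cy = int(round((y0b + y1b) / 2.0))
    if not (0 <= cx < mosaic.width and 0 <= cy < mosaic.height):
        raise BoundsError(f"crop center ({cx}, {cy}) outside mosaic")
    half = out_size_px // 2
    x0, y0 = cx - half, cy - half
    x1, y1 = x0 + out_size_px, y0 + out_size_px
    crop = np.zeros((out_size_px, out_size_px, 3), dtype=mosaic.raster.dtype)
    sx0, sy0 = max(x0, 0), max(y0, 0)
    sx1, sy1 = min(x1, mosaic.width), min(y1, mosaic.height)
    crop[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = mosaic.raster[sy0:sy1, sx0:sx1]
    return crop, (x0, y0)


# ---------------------------------------------------------------------------
# Serialization


def grid_to_json(grid: PlotGrid, path: str | Path) -> None:
    doc = {
        "row_lines": [
            {"slope": l.slope, "intercept": l.intercept, "members": l.member_ids,
             "residual_rms": l.residual_rms}
            for l in grid.row_lines
        ],
        "col_lines": [
            {"slope": l.slope, "intercept": l.intercept, "members": l.member_ids,
             "residual_rms": l.residual_rms}
            for l in grid.col_lines
        ],
        "centers": grid.centers.tolist(),
        "provenance": grid.provenance.tolist(),
        "mean_size": list(grid.mean_size),
        "boundaries": grid.boundaries.tolist(),
        "to_original": grid.to_original.matrix.tolist(),
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def grid_boundaries_as_detections(grid: PlotGrid) -> DetectionSet:
    insts = []
    for i in range(grid.shape[0]):
        for j in range(grid.shape[1]):
            insts.append(
                DetectionInstance(box=tuple(grid.boundaries[i, j]), label=PLOT_CATEGORY)
            )
    return DetectionSet(insts, frame="mosaic")
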