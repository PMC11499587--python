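"""Detection contract, a classical baseline plot detector, and annotation IO.

The trained instance-segmentation stages are pluggable here: anything that
produces a :class:`DetectionSet` per tile can drive the grid pipeline.
External detectors are bridged through the COCO readers.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import scipy.ndimage as ndi

from .errors import FormatError, ParseError
from .mosaic import Tile, excess_green

PLOT_CATEGORY = "plot"
PANICLE_CATEGORY = "panicle"


@dataclass
class DetectionInstance:
    """One detected instance: half-open box, optional mask, score, label.

    ``mask`` (if present) is a binary raster in the box frame with shape
    ``(y_max - y_min, x_max - x_min)``.
    """

    box: tuple[float, float, float, float]
    mask: Optional[np.ndarray] = None
    score: float = 1.0
    label: str = PLOT_CATEGORY
    source_tile: Optional[tuple[int, int]] = None

    def __post_init__(self) -> None:
        x0, y0, x1, y1 = self.box
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"degenerate box {self.box}")
        if not (0.0 <= self.score <= 1.0):
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.mask is not None:
            h = int(round(y1 - y0))
            w = int(round(x1 - x0))
            if self.mask.shape != (h, w):
                raise ValueError(
                    f"mask shape {self.mask.shape} does not match box {self.box}"
                )

    @property
    def area(self) -> float:
        if self.mask is not None:
            return float(self.mask.sum())
        x0, y0, x1, y1 = self.box
        return float((x1 - x0) * (y1 - y0))

    def centroid(self) -> tuple[float, float]:
        """Mask centroid (pixel centers) when available, else box center."""
        x0, y0, x1, y1 = self.box
        if self.mask is not None and self.mask.any():
            r, c = np.nonzero(self.mask)
            return (x0 + c.mean() + 0.5, y0 + r.mean() + 0.5)
        return ((x0 + x1) / 2.0, (y0 + y1) / 2.0)


@dataclass
class DetectionSet:
    instances: list[DetectionInstance] = field(default_factory=list)
    frame: str = "mosaic"  # {"tile", "mosaic"}
    image_id: Optional[str] = None

    def __len__(self) -> int:
        return len(self.instances)

    def filtered(self, score_threshold: float) -> "DetectionSet":
        kept = [i for i in self.instances if i.score >= score_threshold]
        return DetectionSet(kept, frame=self.frame, image_id=self.image_id)


# ---------------------------------------------------------------------------
# Classical baseline detector


def _box_close_open(mask: np.ndarray, size: int) -> np.ndarray:
    """Binary closing then opening with a square structuring element.

    Implemented as separable max/min filters, equivalent to dilation and
    erosion with a ``size x size`` box.
    """
    if size <= 1:
        return mask
    m = mask.astype(np.uint8)
    m = ndi.minimum_filter(ndi.maximum_filter(m, size=size), size=size)  # close
    m = ndi.maximum_filter(ndi.minimum_filter(m, size=size), size=size)  # open
    return m.astype(bool)


def detect_plots_baseline(
    tile: Tile,
    min_area_px: float = 500.0,
    exg_offset: float = 0.0,
    struct_px: int = 9,
) -> DetectionSet:
    """Threshold-and-morphology plot detector for vegetated rectangles.

    Excess-green index -> Otsu threshold shifted by ``exg_offset`` ->
    close/open with a square element of side ``struct_px`` -> hole filling
    -> connected components.  Components of at least ``min_area_px`` become
    instances; the score is the area ratio to the largest component.
    """
    from skimage.filters import threshold_otsu

    if tile.raster.ndim != 3 or tile.raster.shape[2] != 3:
        raise FormatError("baseline detector requires an RGB tile")
    exg = excess_green(tile.raster)
    out = DetectionSet([], frame="tile")
    if exg.max() == exg.min():
        return out
    thr = threshold_otsu(exg) + exg_offset
    mask = exg > thr
    mask = _box_close_open(mask, struct_px)
    mask = ndi.binary_fill_holes(mask)
    labels, n = ndi.label(mask)
    if n == 0:
        return out
    areas = np.bincount(labels.ravel())[1:]
    max_area = float(areas.max())
    slices = ndi.find_objects(labels)
    for lab, (sl, area) in enumerate(zip(slices, areas), start=1):
        if area < min_area_px:
            continue
        comp = labels[sl] == lab
        y0, y1 = sl[0].start, sl[0].stop
        x0, x1 = sl[1].start, sl[1].stop
        out.instances.append(
            DetectionInstance(
                box=(float(x0), float(y0), float(x1), float(y1)),
                mask=comp,
                score=float(area) / max_area,
                label=PLOT_CATEGORY,
                source_tile=tile.index,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Polygon rasterization (even-odd fill, half-open pixel convention)


def rasterize_polygons(
    rings: Iterable[np.ndarray],
    box: tuple[int, int, int, int],
) -> np.ndarray:
    """Rasterize polygon rings into a binary mask over ``box``.

    A pixel ``(x, y)`` is set when its center ``(x + 0.5, y + 0.5)`` lies
    inside the even-odd union of the rings; overlapping rings toggle
    (even-odd rule).  ``box`` is half-open.
    """
    from skimage.measure import grid_points_in_poly

    x0, y0, x1, y1 = box
    h, w = y1 - y0, x1 - x0
    mask = np.zeros((h, w), dtype=bool)
    for ring in rings:
        ring = np.asarray(ring, dtype=float).reshape(-1, 2)  # (x, y)
        verts_rc = np.column_stack([ring[:, 1] - y0 - 0.5, ring[:, 0] - x0 - 0.5])
        mask ^= grid_points_in_poly((h, w), verts_rc)
    return mask


def polygon_bounds(rings: Iterable[np.ndarray]) -> tuple[int, int, int, int]:
    pts = np.concatenate([np.asarray(r, dtype=float).reshape(-1, 2) for r in rings])
    return (
        int(np.floor(pts[:, 0].min())),
        int(np.floor(pts[:, 1].min())),
        int(np.ceil(pts[:, 0].max())),
        int(np.ceil(pts[:, 1].max())),
    )


def _mask_to_polygons(inst: DetectionInstance) -> list[list[float]]:
    """COCO-style flat [x0, y0, x1, y1, ...] polygons for an instance."""
    x0, y0, x1, y1 = inst.box
    if inst.mask is None or inst.mask.all():
        return [[x0, y0, x1, y0, x1, y1, x0, y1]]
    from skimage.measure import find_contours

    padded = np.pad(inst.mask.astype(float), 1)
    polys = []
    for contour in find_contours(padded, 0.5):
        # contour coords: (row, col) in padded index space; pixel (r, c) of
        # the mask sits at padded index (r + 1, c + 1), whose global pixel
        # center is (x0 + c + 0.5, y0 + r + 0.5).
        xs = contour[:, 1] - 1 + x0 + 0.5
        ys = contour[:, 0] - 1 + y0 + 0.5
        polys.append(np.column_stack([xs, ys]).ravel().tolist())
    return polys or [[x0, y0, x1, y0, x1, y1, x0, y1]]


# ---------------------------------------------------------------------------
# COCO / LabelMe IO


def write_coco(
    dets: DetectionSet,
    path: str | Path,
    image_size: Optional[tuple[int, int]] = None,
    categories: tuple[str, ...] = (PLOT_CATEGORY, PANICLE_CATEGORY),
) -> None:
    """Write a COCO instance JSON (bbox + polygon segmentation)."""
    cat_ids = {name: i + 1 for i, name in enumerate(categories)}
    width, height = image_size if image_size else (0, 0)
    doc = {
        "images": [
            {"id": 1, "file_name": dets.image_id or "image", "width": width, "height": height}
        ],
        "annotations": [],
        "categories": [{"id": i, "name": n} for n, i in cat_ids.items()],
    }
    for k, inst in enumerate(dets.instances, start=1):
        x0, y0, x1, y1 = inst.box
        doc["annotations"].append(
            {
                "id": k,
                "image_id": 1,
                "category_id": cat_ids.get(inst.label, 1),
                "bbox": [x0, y0, x1 - x0, y1 - y0],
                "area": inst.area,
                "segmentation": _mask_to_polygons(inst),
                "score": inst.score,
                "iscrowd": 0,
            }
        )
    Path(path).write_text(json.dumps(doc, sort_keys=True))


def _instance_from_coco_ann(ann: dict, cat_names: dict[int, str]) -> DetectionInstance:
    try:
        x, y, w, h = ann["bbox"]
    except (KeyError, ValueError) as exc:
        raise ParseError(f"annotation {ann.get('id', '?')}: bad bbox") from exc
    box = (float(x), float(y), float(x) + float(w), float(y) + float(h))
    mask = None
    seg = ann.get("segmentation")
    if seg:
        if not isinstance(seg, list):
            raise ParseError(f"annotation {ann.get('id', '?')}: unsupported segmentation")
        ix0, iy0, ix1, iy1 = (
            int(np.floor(box[0])),
            int(np.floor(box[1])),
            int(np.ceil(box[2])),
            int(np.ceil(box[3])),
        )
        rings = [np.asarray(p, dtype=float).reshape(-1, 2) for p in seg]
        mask = rasterize_polygons(rings, (ix0, iy0, ix1, iy1))
        box = (float(ix0), float(iy0), float(ix1), float(iy1))
    label = cat_names.get(ann.get("category_id", -1), PLOT_CATEGORY)
    score = float(ann.get("score", 1.0))
    return DetectionInstance(box=box, mask=mask, score=score, label=label)


def read_coco_detections(path: str | Path) -> DetectionSet:
    """Read COCO instance JSON or a COCO results list (bbox-only allowed)."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: malformed JSON ({exc})") from exc
    if isinstance(doc, list):  # COCO results format
        insts = []
        for ann in doc:
            x, y, w, h = ann["bbox"]
            insts.append(
                DetectionInstance(
                    box=(float(x), float(y), float(x) + float(w), float(y) + float(h)),
                    score=float(ann.get("score", 1.0)),
                    label=PLOT_CATEGORY if ann.get("category_id", 1) == 1 else PANICLE_CATEGORY,
                )
            )
        return DetectionSet(insts, frame="mosaic")
    if "annotations" not in doc or "categories" not in doc:
        raise ParseError(f"{path}: missing 'annotations' or 'categories'")
    cat_names = {c["id"]: c["name"] for c in doc["categories"]}
    insts = [_instance_from_coco_ann(a, cat_names) for a in doc["annotations"]]
    image_id = doc["images"][0]["file_name"] if doc.get("images") else None
    return DetectionSet(insts, frame="mosaic", image_id=image_id)


def read_labelme(path: str | Path) -> DetectionSet:
    """Read a LabelMe JSON (rectangle and polygon shapes)."""
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise ParseError(f"{path}: malformed JSON ({exc})") from exc
    insts = []
    for k, shape in enumerate(doc.get("shapes", [])):
        pts = np.asarray(shape.get("points", []), dtype=float)
        kind = shape.get("shape_type", "polygon")
        label = shape.get("label", PLOT_CATEGORY)
        if kind == "rectangle":
            if pts.shape != (2, 2):
                raise ParseError(f"shape {k}: rectangle needs 2 points")
            x0, y0 = pts.min(axis=0)
            x1, y1 = pts.max(axis=0)
            insts.append(DetectionInstance(box=(x0, y0, x1, y1), label=label))
        elif kind == "polygon":
            if pts.shape[0] < 3:
                raise ParseError(f"shape {k}: polygon needs >= 3 points")
            box = polygon_bounds([pts])
            mask = rasterize_polygons([pts], box)
            insts.append(
                DetectionInstance(box=tuple(map(float, box)), mask=mask, label=label)
            )
        else:
            raise ParseError(f"shape {k}: unsupported shape_type '{kind}'")
    return DetectionSet(insts, frame="mosaic", image_id=doc.get("imagePath"))


def write_labelme(
    dets: DetectionSet,
    path: str | Path,
    image_size: Optional[tuple[int, int]] = None,
) -> None:
    width, height = image_size if image_size else (0, 0)
    shapes = []
    for inst in dets.instances:
        x0, y0, x1, y1 = inst.box
        shapes.append(
            {
                "label": inst.label,
                "points": [[x0, y0], [x1, y1]],
                "shape_type": "rectangle",
                "group_id": None,
                "flags": {},
            }
        )
    doc = {
        "version": "5.0.1",
        "flags": {},
        "shapes": shapes,
        "imagePath": dets.image_id or "image",
        "imageData": None,
        "imageHeight": height,
        "imageWidth": width,
    }
    Path(path).write_text(json.dumps(doc, sort_keys=True))
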