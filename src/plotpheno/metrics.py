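"""Evaluation suite: distances, IoU, detection matching, AP/AR, regression
and classification metrics, improvement arithmetic, sampling stability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import numpy as np
from scipy import stats

from .detect import DetectionInstance, DetectionSet
from .errors import FrameError, UndefinedMetricError
from .gridseg import PlotGrid


def euclidean_distance(p: Sequence[float], q: Sequence[float]) -> float:
    """Plain 2-D Euclidean distance between points (x, y)."""
    return float(np.hypot(q[0] - p[0], q[1] - p[1]))


def iou(a: DetectionInstance, b: DetectionInstance) -> float:
    """Intersection over union in [0, 1]; masks when both present, else boxes."""
    ax0, ay0, ax1, ay1 = a.box
    bx0, by0, bx1, by1 = b.box
    area_a = (ax1 - ax0) * (ay1 - ay0)
    area_b = (bx1 - bx0) * (by1 - by0)
    if area_a <= 0 or area_b <= 0:
        raise ValueError("zero-area instance")
    ix0, iy0 = max(ax0, bx0), max(ay0, by0)
    ix1, iy1 = min(ax1, bx1), min(ay1, by1)
    if ix1 <= ix0 or iy1 <= iy0:
        return 0.0
    if a.mask is not None and b.mask is not None:
        h, w = int(np.ceil(iy1 - iy0)), int(np.ceil(ix1 - ix0))

        def sub(inst: DetectionInstance) -> np.ndarray:
            ox = int(round(ix0 - inst.box[0]))
            oy = int(round(iy0 - inst.box[1]))
            return inst.mask[oy : oy + h, ox : ox + w]

        sa, sb = sub(a), sub(b)
        hh, ww = min(sa.shape[0], sb.shape[0]), min(sa.shape[1], sb.shape[1])
        inter = float(np.logical_and(sa[:hh, :ww], sb[:hh, :ww]).sum())
        union = float(a.mask.sum()) + float(b.mask.sum()) - inter
    else:
        inter = (ix1 - ix0) * (iy1 - iy0)
        union = area_a + area_b - inter
    return inter / union if union > 0 else 0.0


def box_iou(a: Sequence[float], b: Sequence[float]) -> float:
    """IoU of two bare boxes (x0, y0, x1, y1)."""
    return iou(DetectionInstance(box=tuple(a)), DetectionInstance(box=tuple(b)))


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    matches: list[tuple[int, int, float]] = field(default_factory=list)


def match_detections(
    preds: DetectionSet, gts: DetectionSet, iou_threshold: float = 0.5
) -> MatchResult:
    """Greedy matching: predictions by descending score each claim the
    unmatched ground truth with the highest IoU at or above the threshold.
    """
    if preds.frame != gts.frame:
        raise FrameError("predictions and ground truths are in different frames")
    order = sorted(
        range(len(preds.instances)), key=lambda k: (-preds.instances[k].score, k)
    )
    gt_used = [False] * len(gts.instances)
    matches = []
    for k in order:
        best, best_v = -1, -1.0
        for g, gt in enumerate(gts.instances):
            if gt_used[g]:
                continue
            v = iou(preds.instances[k], gt)
            if v >= iou_threshold and v > best_v:
                best, best_v = g, v
        if best >= 0:
            gt_used[best] = True
            matches.append((k, best, best_v))
    tp = len(matches)
    return MatchResult(
        tp=tp,
        fp=len(preds.instances) - tp,
        fn=len(gts.instances) - tp,
        matches=matches,
    )


def precision_recall(m: MatchResult) -> tuple[float, float]:
    """Precision = TP/(TP+FP), recall = TP/(TP+FN); degenerate cases are 0."""
    if m.tp + m.fp == 0:
        warnings.warn("no predictions: precision defined as 0", stacklevel=2)
        precision = 0.0
    else:
        precision = m.tp / (m.tp + m.fp)
    recall = m.tp / (m.tp + m.fn) if (m.tp + m.fn) > 0 else 0.0
    return precision, recall


def _score_ordered_tp_flags(
    preds: DetectionSet, gts: DetectionSet, iou_threshold: float
) -> np.ndarray:
    """TP/FP flags for predictions in descending-score order."""
    order = sorted(
        range(len(preds.instances)), key=lambda k: (-preds.instances[k].score, k)
    )
    gt_used = [False] * len(gts.instances)
    flags = np.zeros(len(order), dtype=bool)
    for pos, k in enumerate(order):
        best, best_iou = -1, -1.0
        for g, gt in enumerate(gts.instances):
            if gt_used[g]:
                continue
            v = iou(preds.instances[k], gt)
            if v >= iou_threshold and v > best_iou:
                best, best_iou = g, v
        if best >= 0:
            gt_used[best] = True
            flags[pos] = True
    return flags


@dataclass
class PRCurve:
    recall: np.ndarray
    precision: np.ndarray


def pr_curve(preds: DetectionSet, gts: DetectionSet, iou_threshold: float = 0.5) -> PRCurve:
    if not gts.instances:
        raise UndefinedMetricError("AP undefined without ground truth")
    flags = _score_ordered_tp_flags(preds, gts, iou_threshold)
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / len(gts.instances)
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1)
    return PRCurve(recall=recall, precision=precision)


def average_precision(
    preds: DetectionSet, gts: DetectionSet, iou_threshold: float = 0.5
) -> float:
    """Area under the PR curve using the all-point precision envelope."""
    curve = pr_curve(preds, gts, iou_threshold)
    r = np.concatenate([[0.0], curve.recall])
    p = np.concatenate([[1.0], curve.precision])
    # right-continuous envelope: p~(r) = max precision at recall >= r
    env = np.maximum.accumulate(p[::-1])[::-1]
    return float(np.sum(np.diff(r) * env[1:]))


def average_recall(
    preds: DetectionSet,
    gts: DetectionSet,
    iou_threshold: Union[float, Sequence[float]] = 0.5,
    max_detections: Optional[int] = None,
) -> float:
    """Recall of the top-scoring predictions at the stated IoU threshold(s).

    With a single threshold this is the recall itself; with a list of
    thresholds it is their unweighted mean.
    """
    if max_detections is not None:
        order = sorted(
            range(len(preds.instances)), key=lambda k: (-preds.instances[k].score, k)
        )[:max_detections]
        preds = DetectionSet([preds.instances[k] for k in order], frame=preds.frame)
    thresholds = (
        [iou_threshold] if np.isscalar(iou_threshold) else list(iou_threshold)
    )
    recalls = []
    for t in thresholds:
        m = match_detections(preds, gts, t)
        recalls.append(m.tp / (m.tp + m.fn) if (m.tp + m.fn) > 0 else 0.0)
    return float(np.mean(recalls))


@dataclass
class RegressionReport:
    r2: float
    rmse: float
    rrmse_percent: float


def regression_metrics(y: Sequence[float], y_hat: Sequence[float]) -> RegressionReport:
    """R², RMSE and relative RMSE (% of the mean measured value)."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("y and y_hat must have equal length")
    if len(y) < 2:
        raise ValueError("need n >= 2")
    ss_res = float(np.sum((y - y_hat) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        if ss_res > 0:
            raise UndefinedMetricError("R² undefined for constant y with residuals")
        r2 = 1.0
    else:
        r2 = 1.0 - ss_res / ss_tot
    rmse = float(np.sqrt(ss_res / len(y)))
    y_bar = float(y.mean())
    if y_bar == 0:
        raise UndefinedMetricError("rRMSE undefined for zero mean")
    return RegressionReport(r2=r2, rmse=rmse, rrmse_percent=100.0 * rmse / y_bar)


@dataclass
class ClassificationReport:
    accuracy: float
    per_class: dict[str, dict[str, float]]  # label -> {precision, recall, f1}
    macro_precision: float
    macro_recall: float
    macro_f1: float


def classification_metrics(
    cm: np.ndarray, labels: Optional[Sequence[str]] = None
) -> ClassificationReport:
    """Accuracy and one-vs-rest precision/recall/F1 from a confusion matrix.

    Rows are true classes, columns predicted classes.
    """
    cm = np.asarray(cm, dtype=float)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.size == 0:
        raise ValueError("confusion matrix must be square and non-empty")
    if (cm < 0).any():
        raise ValueError("confusion matrix counts must be non-negative")
    total = cm.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    k = cm.shape[0]
    labels = list(labels) if labels is not None else [str(i) for i in range(k)]
    accuracy = float(np.trace(cm) / total)
    per_class = {}
    precs, recs, f1s = [], [], []
    for i in range(k):
        tp = cm[i, i]
        fp = cm[:, i].sum() - tp
        fn = cm[i, :].sum() - tp
        prec = tp / (tp + fp) if (tp + fp) > 0 else 0.0
        rec = tp / (tp + fn) if (tp + fn) > 0 else 0.0
        f1 = 2 * prec * rec / (prec + rec) if (prec + rec) > 0 else 0.0
        per_class[labels[i]] = {"precision": prec, "recall": rec, "f1": f1}
        precs.append(prec)
        recs.append(rec)
        f1s.append(f1)
    return ClassificationReport(
        accuracy=accuracy,
        per_class=per_class,
        macro_precision=float(np.mean(precs)),
        macro_recall=float(np.mean(recs)),
        macro_f1=float(np.mean(f1s)),
    )


def relative_improvement(new_value: float, base_value: float) -> float:
    """Percent change of ``new_value`` over ``base_value``."""
    if base_value == 0:
        raise ValueError("base value must be nonzero")
    return 100.0 * (new_value - base_value) / base_value


@dataclass
class StabilityReport:
    mean1: float
    mean2: float
    sd1: float
    sd2: float
    statistic: float
    p_value: float
    pearson_r: float


def sampling_stability(sample1: Sequence[float], sample2: Sequence[float]) -> StabilityReport:
    """Compare two repeated samplings of the same plots.

    Reports means, sample SDs (n-1), a two-sided Wilcoxon rank-sum test
    (normal approximation with tie correction) and Pearson correlation of
    the paired values.
    """
    s1 = np.asarray(sample1, dtype=float)
    s2 = np.asarray(sample2, dtype=float)
    if len(s1) != len(s2) or len(s1) < 3:
        raise ValueError("need two equal-length samples of n >= 3")
    if np.std(s1) == 0 or np.std(s2) == 0:
        raise UndefinedMetricError("correlation undefined for zero-variance sample")
    res = stats.mannwhitneyu(s1, s2, alternative="two-sided", method="asymptotic")
    r, _ = stats.pearsonr(s1, s2)
    return StabilityReport(
        mean1=float(s1.mean()),
        mean2=float(s2.mean()),
        sd1=float(s1.std(ddof=1)),
        sd2=float(s2.std(ddof=1)),
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        pearson_r=float(r),
    )


@dataclass
class GridAgreement:
    distances: np.ndarray
    ious: np.ndarray
    mean_distance: float
    sd_distance: float
    mean_iou: float
    sd_iou: float
    n_paired: int
    n_missing: int


def grid_agreement(
    predicted: Union[PlotGrid, np.ndarray],
    truth_boxes: np.ndarray,
) -> GridAgreement:
    """Per-plot centroid distance and IoU of a predicted grid against truth.

    Plots are paired greedily by nearest centroid (one-to-one); unpaired
    truth plots are counted as missing and excluded from the means.
    """
    if isinstance(predicted, PlotGrid):
        pred_boxes = predicted.boundaries.reshape(-1, 4)
    else:
        pred_boxes = np.asarray(predicted, dtype=float).reshape(-1, 4)
    truth_boxes = np.asarray(truth_boxes, dtype=float).reshape(-1, 4)
    pc = np.column_stack(
        [(pred_boxes[:, 0] + pred_boxes[:, 2]) / 2, (pred_boxes[:, 1] + pred_boxes[:, 3]) / 2]
    )
    tc = np.column_stack(
        [(truth_boxes[:, 0] + truth_boxes[:, 2]) / 2, (truth_boxes[:, 1] + truth_boxes[:, 3]) / 2]
    )
    d = np.linalg.norm(tc[:, None, :] - pc[None, :, :], axis=2)
    pairs = sorted((d[t, p], t, p) for t in range(len(tc)) for p in range(len(pc)))
    t_used: set[int] = set()
    p_used: set[int] = set()
    dists, ious_ = [], []
    for dist, t, p in pairs:
        if t in t_used or p in p_used:
            continue
        t_used.add(t)
        p_used.add(p)
        dists.append(dist)
        ious_.append(box_iou(pred_boxes[p], truth_boxes[t]))
    dists = np.asarray(dists)
    ious_ = np.asarray(ious_)
    sd = lambda a: float(a.std(ddof=1)) if len(a) > 1 else 0.0
    return GridAgreement(
        distances=dists,
        ious=ious_,
        mean_distance=float(dists.mean()) if len(dists) else float("nan"),
        sd_distance=sd(dists),
        mean_iou=float(ious_.mean()) if len(ious_) else float("nan"),
        sd_iou=sd(ious_),
        n_paired=len(dists),
        n_missing=len(tc) - len(dists),
    )
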