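"""Instance-segmentation quality measurement.

Predictions are matched to ground truth by Intersection-over-Union (IoU)
with a threshold strictly greater than 0.5, which guarantees at most one
prediction can match any ground-truth object. Matching runs in three
stages: (1) import both mask sets, (2) iterate predictions — initially all
False Positive — find candidate ground-truth masks by bounding-box
intersection, keep the highest IoU, and promote to True Positive when it
exceeds the threshold; (3) iterate ground-truth masks — initially all False
Negative — and clear the FN label when some prediction exceeds the
threshold. Detection ability is summarized by precision, recall and their
harmonic mean (F1); contour quality by the RMSE of a per-object measurement
(typically the minimal Feret diameter) over true-positive pairs:
RMSE = sqrt((1/n) * sum_i (p_hat_i - p_i)^2), n the number of true positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ConsistencyError, ParameterError, UndefinedInputError
from .imaging import AnnotationSet, LabelImage, polygons_to_labels

__all__ = [
    "MatchParams",
    "MatchTable",
    "EvalResult",
    "iou",
    "match_masks",
    "match_masks_bruteforce",
    "precision_recall_f1",
    "diameter_rmse",
    "threshold_sweep",
]


@dataclass
class MatchParams:
    """IoU threshold for matching; comparison is always strict (IoU > t)."""

    iou_threshold: float = 0.5

    def __post_init__(self) -> None:
        if self.iou_threshold < 0.5:
            raise ParameterError(
                f"iou_threshold must be >= 0.5 to guarantee unique matching, "
                f"got {self.iou_threshold}"
            )


@dataclass
class MatchTable:
    """TP/FP/FN assignment between predicted and ground-truth objects."""

    tp: list[tuple[int, int, float]] = field(default_factory=list)  # (pred, gt, iou)
    fp: list[int] = field(default_factory=list)
    fn: list[int] = field(default_factory=list)

    @property
    def n_tp(self) -> int:
        return len(self.tp)

    @property
    def n_fp(self) -> int:
        return len(self.fp)

    @property
    def n_fn(self) -> int:
        return len(self.fn)


@dataclass
class EvalResult:
    precision: float
    recall: float
    f1: float
    n_tp: int
    n_fp: int
    n_fn: int
    rmse_um: float | None = None


def iou(a: np.ndarray, b: np.ndarray) -> float:
    """Pixel-count IoU of two boolean masks in the same frame."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ConsistencyError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.logical_or(a, b).sum()
    if union == 0:
        raise UndefinedInputError("IoU of two empty masks is undefined")
    return float(np.logical_and(a, b).sum() / union)


def _as_label_image(x, frame_shape=None) -> LabelImage:
    if isinstance(x, LabelImage):
        return x
    if isinstance(x, AnnotationSet):
        if frame_shape is None:
            # infer a frame covering all polygons
            maxx = maxy = 0.0
            for ann in x:
                _, _, mx, my = ann.polygon.bounds
                maxx, maxy = max(maxx, mx), max(maxy, my)
            frame_shape = (int(np.ceil(maxy)), int(np.ceil(maxx)))
        return polygons_to_labels(x, frame_shape)
    raise ConsistencyError(f"expected LabelImage or AnnotationSet, got {type(x).__name__}")


def _common_frame(pred, gt, frame_shape=None) -> tuple[LabelImage, LabelImage]:
    """Rasterize both inputs into one shared full-resolution frame."""
    if frame_shape is None:
        shapes = [x.shape for x in (pred, gt) if isinstance(x, LabelImage)]
        if len(shapes) == 2 and shapes[0] != shapes[1]:
            raise ConsistencyError(
                f"prediction frame {shapes[0]} != ground-truth frame {shapes[1]}"
            )
        if shapes:
            frame_shape = shapes[0]
        else:
            maxx = maxy = 1.0
            for aset in (pred, gt):
                for ann in aset:
                    _, _, mx, my = ann.polygon.bounds
                    maxx, maxy = max(maxx, mx), max(maxy, my)
            frame_shape = (int(np.ceil(maxy)), int(np.ceil(maxx)))
    pred_img = _as_label_image(pred, frame_shape)
    gt_img = _as_label_image(gt, frame_shape)
    if pred_img.shape != gt_img.shape:
        raise ConsistencyError(
            f"prediction frame {pred_img.shape} != ground-truth frame {gt_img.shape}"
        )
    return pred_img, gt_img


def _object_table(img: LabelImage):
    """Labels, bounding boxes and pixel-coordinate sets of all objects."""
    labels = []
    bboxes = []
    slices = ndimage.find_objects(img.labels)
    for lab, sl in enumerate(slices, start=1):
        if sl is None:
            continue
        labels.append(lab)
        bboxes.append((sl[1].start, sl[0].start, sl[1].stop, sl[0].stop))  # x0,y0,x1,y1
    return labels, np.array(bboxes).reshape(-1, 4)


def _pair_iou(pred: np.ndarray, gt: np.ndarray, p_lab: int, g_lab: int) -> float:
    pm = pred == p_lab
    gm = gt == g_lab
    inter = int(np.logical_and(pm, gm).sum())
    union = int(pm.sum()) + int(gm.sum()) - inter
    return inter / union if union else 0.0


def _best_iou_map(pred: LabelImage, gt: LabelImage):
    """Per-pred and per-gt best IoU and argmax via a joint histogram.

    Equivalent to bounding-box gating plus per-pair pixel counting (only
    co-occurring label pairs have non-zero intersection), but in one pass.
    """
    p = pred.labels.ravel()
    g = gt.labels.ravel()
    p_areas = np.bincount(p)
    g_areas = np.bincount(g)
    both = (p > 0) & (g > 0)
    pair_keys, pair_counts = np.unique(
        p[both].astype(np.int64) * (int(g.max()) + 1) + g[both], return_counts=True
    )
    pl = (pair_keys // (int(g.max()) + 1)).astype(int)
    gl = (pair_keys % (int(g.max()) + 1)).astype(int)
    inter = pair_counts.astype(float)
    union = p_areas[pl] + g_areas[gl] - inter
    ious = inter / union
    return pl, gl, ious


def match_masks(pred, gt, p: MatchParams | None = None, frame_shape=None) -> MatchTable:
    """Three-stage IoU matching of predictions against ground truth.

    Accepts label images or polygon sets (polygons are rasterized at full
    resolution first so both paths agree). Stage 2 promotes each prediction
    to TP when its best IoU against bounding-box-intersecting ground-truth
    masks strictly exceeds the threshold; stage 3 clears the FN label of
    each ground-truth mask whose best IoU against predictions exceeds it.
    Ties in the best-IoU candidate are broken toward the lower ground-truth
    label (cannot change TP/FP counts above threshold 0.5).
    """
    p = p or MatchParams()
    pred_img, gt_img = _common_frame(pred, gt, frame_shape)
    pred_labels = [int(v) for v in pred_img.label_values()]
    gt_labels = [int(v) for v in gt_img.label_values()]
    pl, gl, ious = _best_iou_map(pred_img, gt_img)

    # stage 2: per prediction, best IoU among intersecting gt (tie -> lower gt label)
    best_for_pred: dict[int, tuple[float, int]] = {}
    for a, b, v in zip(pl, gl, ious):
        cur = best_for_pred.get(a)
        if cur is None or v > cur[0] or (v == cur[0] and b < cur[1]):
            best_for_pred[a] = (v, b)
    # stage 3: per gt, best IoU among predictions
    best_for_gt: dict[int, float] = {}
    for a, b, v in zip(pl, gl, ious):
        if v > best_for_gt.get(b, -1.0):
            best_for_gt[b] = v

    table = MatchTable()
    for lab in pred_labels:
        best = best_for_pred.get(lab)
        if best is not None and best[0] > p.iou_threshold:
            table.tp.append((int(lab), int(best[1]), float(best[0])))
        else:
            table.fp.append(lab)
    for lab in gt_labels:
        if not best_for_gt.get(lab, 0.0) > p.iou_threshold:
            table.fn.append(lab)
    return table


def match_masks_bruteforce(pred, gt, p: MatchParams | None = None, frame_shape=None) -> MatchTable:
    """All-pairs matcher (no bounding-box gate); the independent cross-check.

    Computes the IoU of every (prediction, ground truth) pair by direct
    pixel counting and applies the same strict-threshold rules.
    """
    p = p or MatchParams()
    pred_img, gt_img = _common_frame(pred, gt, frame_shape)
    pred_labels = [int(v) for v in pred_img.label_values()]
    gt_labels = [int(v) for v in gt_img.label_values()]
    table = MatchTable()
    matched_gt_best: dict[int, float] = {g: 0.0 for g in gt_labels}
    for plab in pred_labels:
        best_v, best_g = 0.0, None
        for glab in gt_labels:  # ascending, so strict > breaks ties toward lower gt label
            v = _pair_iou(pred_img.labels, gt_img.labels, plab, glab)
            matched_gt_best[glab] = max(matched_gt_best[glab], v)
            if v > best_v:
                best_v, best_g = v, glab
        if best_g is not None and best_v > p.iou_threshold:
            table.tp.append((int(plab), int(best_g), float(best_v)))
        else:
            table.fp.append(plab)
    for glab in gt_labels:
        if not matched_gt_best[glab] > p.iou_threshold:
            table.fn.append(glab)
    return table


def precision_recall_f1(m: MatchTable) -> EvalResult:
    """Detection scores from a match table.

    precision = TP/(TP+FP) (how correct the predictions are), recall =
    TP/(TP+FN) (how exhaustive they are), F1 their harmonic mean; all are 0
    when their denominator is 0.
    """
    tp, fp, fn = m.n_tp, m.n_fp, m.n_fn
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvalResult(precision, recall, f1, tp, fp, fn)


def diameter_rmse(
    m: MatchTable, pred_measure: dict[int, float], gt_measure: dict[int, float]
) -> float:
    """RMSE of a per-object measurement over true-positive pairs, in um."""
    if m.n_tp == 0:
        raise UndefinedInputError("RMSE undefined with zero true positives")
    diffs = np.array([pred_measure[pl] - gt_measure[gl] for pl, gl, _ in m.tp])
    return float(np.sqrt(np.mean(diffs**2)))


def threshold_sweep(
    pred,
    gt,
    thresholds,
    pred_measure: dict[int, float] | None = None,
    gt_measure: dict[int, float] | None = None,
    bin_width_um: float = 5.0,
    frame_shape=None,
):
    """Evaluate matching over a grid of IoU thresholds.

    Returns a list of dicts with per-threshold f1, rmse (None when no
    measurements or no TPs) and the count of non-empty ``bin_width_um``
    diameter classes among matched ground-truth objects. F1 is checked to
    be non-increasing in the threshold (it is, analytically, since the TP
    set can only shrink).
    """
    thresholds = sorted(float(t) for t in thresholds)
    if thresholds and thresholds[0] < 0.5:
        raise ParameterError("sweep thresholds must be >= 0.5")
    rows = []
    prev_f1 = None
    for t in thresholds:
        table = match_masks(pred, gt, MatchParams(t), frame_shape=frame_shape)
        scores = precision_recall_f1(table)
        rmse = None
        if pred_measure and gt_measure and table.n_tp:
            rmse = diameter_rmse(table, pred_measure, gt_measure)
        n_classes = 0
        if gt_measure:
            matched_d = [gt_measure[gl] for _, gl, _ in table.tp]
            if matched_d:
                bins = np.floor(np.array(matched_d) / bin_width_um).astype(int)
                n_classes = int(np.unique(bins).size)
        if prev_f1 is not None and scores.f1 > prev_f1 + 1e-12:
            raise AssertionError("F1 increased with the IoU threshold")  # pragma: no cover
        prev_f1 = scores.f1
        rows.append(
            {
                "threshold": t,
                "f1": scores.f1,
                "precision": scores.precision,
                "recall": scores.recall,
                "rmse_um": rmse,
                "n_nonempty_classes": n_classes,
                "n_tp": scores.n_tp,
                "n_fp": scores.n_fp,
                "n_fn": scores.n_fn,
            }
        )
    return rows
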