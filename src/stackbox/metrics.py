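"""COCO-style detection evaluation.

Average precision uses 101-point interpolation (precision envelope
sampled at recalls 0, 0.01, ..., 1.00); the ranged AP averages over the
ten IoU thresholds 0.50:0.05:0.95.  Average recall averages recall over
the same threshold grid after truncating each image to its top-k
highest-confidence detections.  Size-restricted variants (medium: 32² ≤
area < 96², large: ≥ 96²) follow the COCO ignore convention: off-bucket
ground truths are ignored rather than counted, detections matched to
them are neither TP nor FP, and unmatched detections whose own area
falls outside the bucket are excluded from the false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from typing import Sequence

import numpy as np

from .errors import ValidationError
from .geometry import Detection, GroundTruth, boxes_to_array, group_by, iou_matrix

IOU_GRID = tuple(np.linspace(0.50, 0.95, 10))
RECALL_GRID = np.linspace(0.0, 1.0, 101)

MEDIUM = (32.0**2, 96.0**2)
LARGE = (96.0**2, float("inf"))


def match_for_eval(
    gts: Sequence[GroundTruth],
    dets: Sequence[Detection],
    iou_threshold: float,
    area_range: tuple[float, float] | None = None,
    max_dets: int | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Greedy one-to-one TP/FP labelling.

    Detections are processed per image and class in confidence order;
    each matches the unmatched ground truth with the highest IoU ≥
    threshold (ties: first index), and each ground truth is used at most
    once.  Returns ``(scores, labels, n_gt)`` with labels 1 = TP,
    0 = FP, -1 = ignored; ``n_gt`` counts in-bucket ground truths only.
    """

    def gt_ignored(g: GroundTruth) -> bool:
        return area_range is not None and not (area_range[0] <= g.box.area < area_range[1])

    gt_groups = group_by(list(gts), key=lambda g: (g.image_id, g.class_id))
    det_groups = group_by(list(dets), key=lambda d: (d.image_id, d.class_id))
    n_gt = sum(1 for g in gts if not gt_ignored(g))

    scores: list[float] = []
    labels: list[int] = []
    for key, dgroup in det_groups.items():
        order = sorted(range(len(dgroup)), key=lambda i: (-dgroup[i].confidence, i))
        if max_dets is not None:
            order = order[:max_dets]
        ggroup = gt_groups.get(key, [])
        g_ignored = [gt_ignored(g) for g in ggroup]
        taken = [False] * len(ggroup)
        gboxes = boxes_to_array([g.box for g in ggroup]) if ggroup else None
        for i in order:
            d = dgroup[i]
            label = 0
            if ggroup:
                ious = iou_matrix(boxes_to_array([d.box]), gboxes)[0]
                best, best_iou, best_ign = -1, iou_threshold, True
                # prefer a non-ignored match; fall back to an ignored one
                for want_ignored in (False, True):
                    for j in range(len(ggroup)):
                        if taken[j] or g_ignored[j] != want_ignored:
                            continue
                        if ious[j] >= best_iou and (best < 0 or ious[j] > best_iou):
                            best, best_iou, best_ign = j, float(ious[j]), want_ignored
                    if best >= 0:
                        break
                if best >= 0:
                    taken[best] = True
                    label = -1 if best_ign else 1
            if label == 0 and area_range is not None:
                if not (area_range[0] <= d.box.area < area_range[1]):
                    label = -1
            scores.append(d.confidence)
            labels.append(label)
    return np.asarray(scores, dtype=float), np.asarray(labels, dtype=int), n_gt


def average_precision_101(
    scores: np.ndarray, labels: np.ndarray, n_gt: int
) -> float | None:
    """101-point interpolated AP from TP/FP labels; None when n_gt = 0."""
    if n_gt < 0:
        raise ValidationError("n_gt must be non-negative")
    if n_gt == 0:
        return None
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    keep = labels >= 0
    scores, labels = scores[keep], labels[keep]
    if len(scores) == 0:
        return 0.0
    order = np.argsort(-scores, kind="stable")
    tp = np.cumsum(labels[order] == 1)
    fp = np.cumsum(labels[order] == 0)
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1)
    # precision envelope: max precision at any recall >= r
    ap = 0.0
    for r in RECALL_GRID:
        mask = recall >= r - 1e-12
        ap += float(precision[mask].max()) if mask.any() else 0.0
    return ap / len(RECALL_GRID)


def _ap_at(gts, dets, thr, area_range=None) -> float | None:
    scores, labels, n_gt = match_for_eval(gts, dets, thr, area_range=area_range)
    return average_precision_101(scores, labels, n_gt)


def average_recall(
    gts: Sequence[GroundTruth],
    dets: Sequence[Detection],
    max_dets: int,
    area_range: tuple[float, float] | None = None,
    iou_grid: Sequence[float] = IOU_GRID,
) -> float | None:
    """Recall averaged over the IoU grid, keeping at most ``max_dets``
    top-confidence detections per image (and class); None when the
    bucket holds no ground truths."""
    recalls = []
    for thr in iou_grid:
        _, labels, n_gt = match_for_eval(gts, dets, thr, area_range=area_range, max_dets=max_dets)
        if n_gt == 0:
            return None
        recalls.append(np.sum(labels == 1) / n_gt)
    return float(np.mean(recalls))


_METRIC_NAMES = (
    "ap_range",
    "ap_50",
    "ap_75",
    "ap_medium",
    "ap_large",
    "ar_1",
    "ar_10",
    "ar_medium",
    "ar_large",
    "map_50",
)


@dataclass(frozen=True)
class MetricsReport:
    """The ten headline detection metrics; None marks an undefined bucket."""

    ap_range: float | None
    ap_50: float | None
    ap_75: float | None
    ap_medium: float | None
    ap_large: float | None
    ar_1: float | None
    ar_10: float | None
    ar_medium: float | None
    ar_large: float | None
    map_50: float | None

    def as_dict(self) -> dict[str, float | None]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _class_mean(values: list[float | None]) -> float | None:
    defined = [v for v in values if v is not None]
    return float(np.mean(defined)) if defined else None


def evaluate(
    gts: Sequence[GroundTruth],
    dets: Sequence[Detection],
    size_thresholds: tuple[float, float] = (MEDIUM[0], MEDIUM[1]),
    ar_bucket_max_dets: int = 100,
) -> MetricsReport:
    """All ten metrics, class-averaged (a single-class dataset reduces to
    per-class values).  Raises on an empty ground-truth set."""
    if not gts:
        raise ValidationError("evaluate requires a non-empty ground-truth set")
    medium = (size_thresholds[0], size_thresholds[1])
    large = (size_thresholds[1], float("inf"))
    classes = sorted({g.class_id for g in gts})
    per_class: dict[str, list[float | None]] = {m: [] for m in _METRIC_NAMES}
    for c in classes:
        g = [x for x in gts if x.class_id == c]
        d = [x for x in dets if x.class_id == c]
        ap50 = _ap_at(g, d, 0.5)
        per_class["ap_50"].append(ap50)
        per_class["map_50"].append(ap50)
        per_class["ap_75"].append(_ap_at(g, d, 0.75))
        for name, rng in (("ap_range", None), ("ap_medium", medium), ("ap_large", large)):
            vals = [_ap_at(g, d, t, rng) for t in IOU_GRID]
            per_class[name].append(_class_mean(vals) if any(v is not None for v in vals) else None)
        per_class["ar_1"].append(average_recall(g, d, 1))
        per_class["ar_10"].append(average_recall(g, d, 10))
        per_class["ar_medium"].append(average_recall(g, d, ar_bucket_max_dets, medium))
        per_class["ar_large"].append(average_recall(g, d, ar_bucket_max_dets, large))
    return MetricsReport(**{m: _class_mean(per_class[m]) for m in _METRIC_NAMES})


def crossval_summary(reports: Sequence[MetricsReport]) -> dict[str, tuple[float, float] | None]:
    """Per-metric fold mean ± sample SD; requires at least two folds."""
    if len(reports) < 2:
        raise ValidationError("cross-validation summary needs at least 2 folds")
    out: dict[str, tuple[float, float] | None] = {}
    for m in _METRIC_NAMES:
        vals = [getattr(r, m) for r in reports if getattr(r, m) is not None]
        if not vals:
            out[m] = None
        else:
            arr = np.asarray(vals, dtype=float)
            sd = float(arr.std(ddof=1)) if len(arr) > 1 else 0.0
            out[m] = (float(arr.mean()), sd)
    return out
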