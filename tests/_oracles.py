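"""Independent brute-force oracles used to cross-check the package.

Everything here is deliberately written on a separate code path from
``stackbox``: IoU via pixel rasterization or shapely polygons, fusion
via naive O(n²) loops, and PR curves via exact rational arithmetic.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from shapely.geometry import box as shapely_box


def raster_iou(a, b) -> float:
    """IoU of two integer-coordinate boxes by counting unit pixels."""
    x0, y0, x1, y1 = (int(v) for v in a)
    u0, v0, u1, v1 = (int(v) for v in b)
    w = max(x1, u1) + 1
    h = max(y1, v1) + 1
    ga = np.zeros((h, w), dtype=bool)
    gb = np.zeros((h, w), dtype=bool)
    ga[y0:y1, x0:x1] = True
    gb[v0:v1, u0:u1] = True
    union = np.logical_or(ga, gb).sum()
    return float(np.logical_and(ga, gb).sum() / union) if union else 0.0


def shapely_iou(a, b) -> float:
    pa, pb = shapely_box(*a), shapely_box(*b)
    inter = pa.intersection(pb).area
    union = pa.union(pb).area
    return inter / union if union else 0.0


def naive_nms(boxes, scores, thr):
    """Greedy NMS over (n, 4) coords and scores; returns kept indices."""
    order = sorted(range(len(boxes)), key=lambda i: (-scores[i], i))
    kept, removed = [], set()
    for i in order:
        if i in removed:
            continue
        kept.append(i)
        for j in order:
            if j not in removed and j != i and shapely_iou(boxes[i], boxes[j]) > thr:
                removed.add(j)
    return kept


def naive_wbf(boxes, scores, models, thr, n_models, conf_mode="average", rescale=True):
    """Reference weighted-boxes fusion over a flat pooled list.

    Clusters are grown against the running confidence-weighted mean box;
    fused confidence is the member mean (or max), rescaled by the number
    of distinct contributing models over ``n_models``.
    Returns (fused_boxes, fused_confidences) in cluster-creation order.
    """

    def fused_of(members):
        w = np.array([scores[j] for j in members], dtype=float)
        pts = np.array([boxes[j] for j in members], dtype=float)
        return (w[:, None] * pts).sum(axis=0) / w.sum()

    order = sorted(range(len(boxes)), key=lambda i: (-scores[i], i))
    clusters: list[list[int]] = []
    for i in order:
        best, best_iou = None, thr
        for cl in clusters:
            v = shapely_iou(boxes[i], fused_of(cl))
            if v > best_iou:
                best, best_iou = cl, v
        if best is None:
            clusters.append([i])
        else:
            best.append(i)
    out_boxes, out_confs = [], []
    for cl in clusters:
        confs = [scores[j] for j in cl]
        conf = max(confs) if conf_mode == "maximum" else sum(confs) / len(confs)
        if rescale:
            conf *= min(len({models[j] for j in cl}), n_models) / n_models
        out_boxes.append(fused_of(cl))
        out_confs.append(conf)
    return out_boxes, out_confs


# ---------------------------------------------------------------------------
# exact metrics


def naive_match(gt_boxes, det_boxes, det_scores, thr, max_dets=None):
    """Greedy one-to-one matching on a single image; returns TP flags in
    confidence order along with the processed detection order."""
    order = sorted(range(len(det_boxes)), key=lambda i: (-det_scores[i], i))
    if max_dets is not None:
        order = order[:max_dets]
    taken = [False] * len(gt_boxes)
    flags = []
    for i in order:
        best, best_iou = -1, None
        for j in range(len(gt_boxes)):
            if taken[j]:
                continue
            v = shapely_iou(det_boxes[i], gt_boxes[j])
            if v >= thr and (best_iou is None or v > best_iou):
                best, best_iou = j, v
        if best >= 0:
            taken[best] = True
            flags.append(True)
        else:
            flags.append(False)
    return order, flags


def exact_ap_101(instances, thr, max_dets=None) -> Fraction:
    """Exact 101-point interpolated AP over a list of per-image instances.

    ``instances`` is a list of (gt_boxes, det_boxes, det_scores).
    Returns a Fraction; rational arithmetic keeps the precision envelope
    exact at every recall grid point.
    """
    pooled = []  # (score, is_tp)
    n_gt = 0
    for gt_boxes, det_boxes, det_scores in instances:
        n_gt += len(gt_boxes)
        order, flags = naive_match(gt_boxes, det_boxes, det_scores, thr, max_dets)
        for i, tp in zip(order, flags):
            pooled.append((det_scores[i], tp))
    if n_gt == 0:
        return None
    pooled.sort(key=lambda t: -t[0])
    points = []  # (recall, precision) as Fractions
    tp = fp = 0
    for _, is_tp in pooled:
        tp += int(is_tp)
        fp += int(not is_tp)
        points.append((Fraction(tp, n_gt), Fraction(tp, tp + fp)))
    total = Fraction(0)
    for k in range(101):
        r = Fraction(k, 100)
        best = max((p for rec, p in points if rec >= r), default=Fraction(0))
        total += best
    return total / 101


def exact_ar(instances, max_dets, iou_grid) -> Fraction:
    """Exact average recall over the IoU grid with per-image truncation."""
    n_gt = sum(len(g) for g, _, _ in instances)
    if n_gt == 0:
        return None
    total = Fraction(0)
    for thr in iou_grid:
        tp = 0
        for gt_boxes, det_boxes, det_scores in instances:
            _, flags = naive_match(gt_boxes, det_boxes, det_scores, thr, max_dets)
            tp += sum(flags)
        total += Fraction(tp, n_gt)
    return total / len(iou_grid)
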