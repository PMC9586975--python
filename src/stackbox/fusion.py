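"""Box-fusion baselines: NMS, Soft-NMS (gaussian/linear), NMW and WBF.

All entry points accept a flat detection sequence and fuse independently
per ``(image_id, class_id)`` group, so feeding a multi-image pool is
equivalent to fusing each image separately and concatenating.

Tie-breaking everywhere is stable: detections are processed in order of
(confidence descending, roster position, input order), so results are
deterministic for equal scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .geometry import Box, Detection, boxes_to_array, group_by, iou_matrix, with_confidence


@dataclass(frozen=True)
class FusionConfig:
    """Shared knobs for the fusion baselines.

    iou_threshold
        Overlap above which boxes are suppressed (NMS), decayed
        (linear Soft-NMS) or clustered (NMW, WBF).  Default 0.5.
    soft_sigma
        Gaussian decay scale for Soft-NMS: ``s * exp(-iou² / soft_sigma)``.
    soft_score_threshold
        Soft-NMS detections whose decayed score falls below this are removed.
    conf_mode
        WBF fused confidence: "average" of cluster members or "maximum".
    model_weights
        Optional per-model non-negative weights for WBF (default all 1).
    rescale_by_model_count
        WBF: multiply fused confidence by (#distinct contributing models / M).
    """

    iou_threshold: float = 0.5
    soft_sigma: float = 0.5
    soft_score_threshold: float = 0.001
    conf_mode: str = "average"
    model_weights: Mapping[str, float] | None = None
    rescale_by_model_count: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.iou_threshold <= 1.0):
            raise ConfigurationError(f"iou_threshold {self.iou_threshold} outside (0, 1]")
        if self.soft_sigma <= 0:
            raise ConfigurationError("soft_sigma must be positive")
        if self.conf_mode not in ("average", "maximum"):
            raise ConfigurationError(f"unknown conf_mode {self.conf_mode!r}")


@dataclass(frozen=True)
class FusedBox:
    """A fused box with the indices of the detections that produced it."""

    box: Box
    confidence: float
    support: tuple[int, ...]
    image_id: int | str = 0
    class_id: int = 1

    def as_detection(self, model_id: str) -> Detection:
        return Detection(self.box, min(self.confidence, 1.0), model_id, self.image_id, self.class_id)


def _sort_order(dets: Sequence[Detection], roster: Sequence[str] | None = None) -> list[int]:
    """Indices sorted by confidence desc, then roster order, then input order."""
    pos = {m: i for i, m in enumerate(roster)} if roster else {}
    return sorted(
        range(len(dets)),
        key=lambda i: (-dets[i].confidence, pos.get(dets[i].model_id, 0), i),
    )


def _per_group(dets: Sequence[Detection]):
    return group_by(list(dets), key=lambda d: (d.image_id, d.class_id))


def nms(dets: Sequence[Detection], cfg: FusionConfig | None = None) -> list[Detection]:
    """Greedy non-maximum suppression; survivors keep their boxes and scores."""
    cfg = cfg or FusionConfig()
    out: list[Detection] = []
    for group in _per_group(dets).values():
        order = _sort_order(group)
        boxes = boxes_to_array([d.box for d in group])
        suppressed = np.zeros(len(group), dtype=bool)
        for k, i in enumerate(order):
            if suppressed[i]:
                continue
            out.append(group[i])
            rest = [j for j in order[k + 1:] if not suppressed[j]]
            if rest:
                ious = iou_matrix(boxes[i], boxes[rest])[0]
                for j, v in zip(rest, ious):
                    if v > cfg.iou_threshold:
                        suppressed[j] = True
    return out


def soft_nms(
    dets: Sequence[Detection], cfg: FusionConfig | None = None, mode: str = "gaussian"
) -> list[Detection]:
    """Soft-NMS: decay overlapping scores instead of suppressing boxes.

    gaussian: every remaining score is multiplied by ``exp(-iou²/sigma)``.
    linear:   scores are multiplied by ``1 - iou`` only when the overlap
              exceeds ``cfg.iou_threshold``.
    Detections whose score drops below ``cfg.soft_score_threshold`` are
    removed; surviving detections carry their rescored confidence.
    """
    cfg = cfg or FusionConfig()
    if mode not in ("gaussian", "linear"):
        raise ConfigurationError(f"unknown soft-nms mode {mode!r}")
    out: list[Detection] = []
    for group in _per_group(dets).values():
        boxes = boxes_to_array([d.box for d in group])
        scores = np.array([d.confidence for d in group], dtype=float)
        alive = list(range(len(group)))
        while alive:
            k = max(range(len(alive)), key=lambda j: (scores[alive[j]], -alive[j]))
            i = alive.pop(k)
            out.append(with_confidence(group[i], float(scores[i])))
            if not alive:
                break
            ious = iou_matrix(boxes[i], boxes[alive])[0]
            for j, v in zip(list(alive), ious):
                if mode == "gaussian":
                    scores[j] *= np.exp(-(v**2) / cfg.soft_sigma)
                elif v > cfg.iou_threshold:
                    scores[j] *= 1.0 - v
            alive = [j for j in alive if scores[j] >= cfg.soft_score_threshold]
    return out


def nmw(dets: Sequence[Detection], cfg: FusionConfig | None = None) -> list[FusedBox]:
    """Non-maximum weighted fusion.

    Clusters are seeded greedily in score order at ``iou_threshold``; the
    fused box is the mean of member coordinates weighted by
    ``score × IoU(member, seed)``.  Confidences are not changed: the fused
    confidence is the seed's original score.
    """
    cfg = cfg or FusionConfig()
    out: list[FusedBox] = []
    for (image_id, class_id), group in _per_group(dets).items():
        order = _sort_order(group)
        boxes = boxes_to_array([d.box for d in group])
        clusters: list[dict] = []  # {"seed": idx, "members": [idx]}
        for i in order:
            placed = False
            for cl in clusters:
                v = float(iou_matrix(boxes[i], boxes[cl["seed"]])[0, 0])
                if v > cfg.iou_threshold:
                    cl["members"].append(i)
                    placed = True
                    break
            if not placed:
                clusters.append({"seed": i, "members": [i]})
        for cl in clusters:
            seed = cl["seed"]
            members = cl["members"]
            w = np.array(
                [group[j].confidence * float(iou_matrix(boxes[j], boxes[seed])[0, 0]) for j in members]
            )
            coords = (w[:, None] * boxes[members]).sum(axis=0) / w.sum()
            out.append(
                FusedBox(Box(*coords), group[seed].confidence, tuple(members), image_id, class_id)
            )
    return out


def wbf(
    dets_by_model: Mapping[str, Sequence[Detection]],
    cfg: FusionConfig | None = None,
    roster: Sequence[str] | None = None,
) -> list[FusedBox]:
    """Weighted boxes fusion.

    Detections from all models are pooled and clustered incrementally
    against each cluster's *running fused box* at ``iou_threshold``.  The
    fused coordinates are the confidence-weighted mean of the members'
    coordinates; the fused confidence is the member average (or maximum
    for the WBF-max variant, ``conf_mode="maximum"``), optionally rescaled
    by the fraction of models contributing to the cluster.
    """
    cfg = cfg or FusionConfig()
    roster = list(roster) if roster is not None else sorted(dets_by_model)
    if set(dets_by_model) - set(roster):
        raise ConfigurationError(
            f"models {sorted(set(dets_by_model) - set(roster))} not in roster {roster}"
        )
    weights = dict(cfg.model_weights or {})
    if set(weights) - set(roster):
        raise ConfigurationError("model_weights refer to models outside the roster")
    n_models = len(roster)

    pooled: list[Detection] = []
    for m in roster:
        pooled.extend(dets_by_model.get(m, []))

    out: list[FusedBox] = []
    for (image_id, class_id), group in _per_group(pooled).items():
        order = _sort_order(group, roster)
        boxes = boxes_to_array([d.box for d in group])
        # clusters: member indices + running weighted-mean box
        clusters: list[dict] = []
        for i in order:
            w_i = group[i].confidence * weights.get(group[i].model_id, 1.0)
            best, best_iou = None, cfg.iou_threshold
            for cl in clusters:
                running = cl["box"] / cl["wsum"]
                v = float(iou_matrix(boxes[i], np.array([running]))[0, 0])
                if v > best_iou:
                    best, best_iou = cl, v
            if best is None:
                clusters.append({"members": [i], "wsum": w_i, "box": boxes[i] * w_i})
            else:
                best["members"].append(i)
                best["box"] = best["box"] + boxes[i] * w_i
                best["wsum"] += w_i
        for cl in clusters:
            members = cl["members"]
            confs = np.array([group[j].confidence for j in members])
            conf = float(confs.max() if cfg.conf_mode == "maximum" else confs.mean())
            if cfg.rescale_by_model_count:
                contributing = len({group[j].model_id for j in members})
                conf *= min(contributing, n_models) / n_models
            coords = cl["box"] / cl["wsum"]
            out.append(FusedBox(Box(*coords), conf, tuple(members), image_id, class_id))
    return out


_SOFT_MODES = {"soft-nms-gaussian": "gaussian", "soft-nms-linear": "linear"}


def fuse(
    method: str,
    dets_by_model: Mapping[str, Sequence[Detection]],
    cfg: FusionConfig | None = None,
    roster: Sequence[str] | None = None,
) -> list[Detection]:
    """Dispatch a named fusion method over per-model detections.

    Methods: ``nms``, ``soft-nms-gaussian``, ``soft-nms-linear``, ``nmw``,
    ``wbf``, ``wbf-max``.  Output is always a flat detection list tagged
    with the method name as ``model_id``.
    """
    cfg = cfg or FusionConfig()
    roster = list(roster) if roster is not None else sorted(dets_by_model)
    pooled: list[Detection] = []
    for m in roster:
        pooled.extend(dets_by_model.get(m, []))
    if method == "nms":
        return [Detection(d.box, d.confidence, "nms", d.image_id, d.class_id) for d in nms(pooled, cfg)]
    if method in _SOFT_MODES:
        rescored = soft_nms(pooled, cfg, mode=_SOFT_MODES[method])
        return [Detection(d.box, d.confidence, method, d.image_id, d.class_id) for d in rescored]
    if method == "nmw":
        return [fb.as_detection("nmw") for fb in nmw(pooled, cfg)]
    if method in ("wbf", "wbf-max"):
        wcfg = FusionConfig(
            iou_threshold=cfg.iou_threshold,
            soft_sigma=cfg.soft_sigma,
            soft_score_threshold=cfg.soft_score_threshold,
            conf_mode="maximum" if method == "wbf-max" else "average",
            model_weights=cfg.model_weights,
            rescale_by_model_count=cfg.rescale_by_model_count,
        )
        return [fb.as_detection(method) for fb in wbf(dets_by_model, wcfg, roster)]
    raise ConfigurationError(f"unknown fusion method {method!r}")


FUSION_METHODS = ("nms", "soft-nms-gaussian", "soft-nms-linear", "nmw", "wbf", "wbf-max")
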