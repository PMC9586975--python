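"""Test-side stacking pipeline.

At inference there is no ground truth, so each base learner's prediction
is treated as a pseudo-ground-truth in turn: the best-IoU detections of
the remaining models are gathered around it, missing slots are imputed,
duplicated rows (which arise from symmetric anchoring of mutually
best-matching detections) are removed, the fitted per-coordinate
regressors predict one refined box per row, and a final NMS at IoU 0.5
removes redundant output boxes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError
from .fusion import FusionConfig, nms
from .geometry import Box, Detection, boxes_to_array, group_by, iou_matrix
from .train import COORDS, MatchRow, RawMatchRow, StackBoxModel, impute_and_filter

logger = logging.getLogger(__name__)


@dataclass
class PseudoRow:
    """A test row: anchor detection plus M filled slots and the dedup key."""

    anchor: Detection
    slots: tuple[Detection, ...]
    fill_flags: tuple[bool, ...]

    @property
    def dedup_key(self) -> tuple:
        key: list = [self.anchor.image_id, self.anchor.class_id]
        for d in self.slots:
            key.extend(d.box.coords)
        return tuple(key)

    @property
    def confidences(self) -> tuple[float, ...]:
        return tuple(d.confidence for d in self.slots)


def assemble_test_rows(
    dets_by_model: Mapping[str, Sequence[Detection]],
    roster: Sequence[str],
    min_iou: float = 0.0,
) -> list[PseudoRow]:
    """Build pseudo-ground-truth rows from every detection of every model.

    For each anchor detection the best-IoU same-image same-class
    detection of each remaining model fills that model's slot; the anchor
    fills its own.  Anchors with no match in any other model are dropped;
    remaining empty slots are imputed from the row's best match.
    """
    roster = list(roster)
    if set(dets_by_model) - set(roster):
        raise ConfigurationError(
            f"detection models {sorted(set(dets_by_model) - set(roster))} not in roster"
        )
    grouped = {
        m: group_by(list(dets_by_model.get(m, [])), key=lambda d: (d.image_id, d.class_id))
        for m in roster
    }
    raw_rows: list[RawMatchRow] = []
    anchors: list[Detection] = []
    for mi, anchor_model in enumerate(roster):
        for anchor in dets_by_model.get(anchor_model, []):
            a_arr = boxes_to_array([anchor.box])
            slots: list[Detection | None] = []
            ious: list[float] = []
            for kj, m in enumerate(roster):
                if kj == mi:
                    slots.append(anchor)
                    ious.append(1.0)
                    continue
                cand = grouped[m].get((anchor.image_id, anchor.class_id), [])
                if cand:
                    vals = iou_matrix(a_arr, boxes_to_array([d.box for d in cand]))[0]
                    k = int(np.argmax(vals))
                    if vals[k] > min_iou:
                        slots.append(cand[k])
                        ious.append(float(vals[k]))
                        continue
                slots.append(None)
                ious.append(0.0)
            raw_rows.append(
                RawMatchRow(anchor.box, anchor.image_id, anchor.class_id, slots, ious, anchor_slot=mi)
            )
            anchors.append(anchor)
    filled = impute_and_filter(raw_rows, mode="test")
    # impute_and_filter preserves order and only drops rows; realign anchors
    kept: list[PseudoRow] = []
    fi = 0
    raw_avail = [
        any(d is not None for k, d in enumerate(r.slots) if k != r.anchor_slot) for r in raw_rows
    ]
    for anchor, ok in zip(anchors, raw_avail):
        if ok:
            row = filled[fi]
            kept.append(PseudoRow(anchor, row.slots, row.fill_flags))
            fi += 1
    return kept


def deduplicate(rows: Sequence[PseudoRow]) -> list[PseudoRow]:
    """Collapse rows with identical coordinate tuples, keeping first occurrences."""
    seen: set[tuple] = set()
    out: list[PseudoRow] = []
    for row in rows:
        key = row.dedup_key
        if key not in seen:
            seen.add(key)
            out.append(row)
    if len(out) < len(rows):
        logger.info("deduplicate: removed %d duplicated rows", len(rows) - len(out))
    return out


def predict_boxes(
    model: StackBoxModel,
    rows: Sequence[PseudoRow],
    conf_mode: str = "mean",
) -> list[Detection]:
    """Predict one refined box per row with the fitted coordinate regressors.

    The stacked box's confidence is the mean (default) or max of the
    row's slot confidences, imputed slots included.  Predicted boxes that
    come out degenerate (min ≥ max on either axis) are dropped with a
    logged count.
    """
    if conf_mode not in ("mean", "max"):
        raise ConfigurationError(f"unknown conf_mode {conf_mode!r}")
    if not rows:
        return []
    for row in rows:
        if len(row.slots) != len(model.roster):
            raise ConfigurationError(
                f"row has {len(row.slots)} slots but model roster has {len(model.roster)}"
            )
    X_by_coord = {
        c: np.array([[d.box.coords[ci] for d in row.slots] for row in rows], dtype=float)
        for ci, c in enumerate(COORDS)
    }
    coords = model.predict_coords(X_by_coord)
    out: list[Detection] = []
    n_degenerate = 0
    for row, (x0, y0, x1, y1) in zip(rows, coords):
        if not (x0 < x1 and y0 < y1):
            n_degenerate += 1
            continue
        confs = row.confidences
        conf = max(confs) if conf_mode == "max" else float(np.mean(confs))
        out.append(
            Detection(
                Box(x0, y0, x1, y1),
                min(conf, 1.0),
                "stackbox",
                row.anchor.image_id,
                row.anchor.class_id,
            )
        )
    if n_degenerate:
        logger.info("predict_boxes: dropped %d degenerate predictions", n_degenerate)
    return out


def finalize(dets: Sequence[Detection], iou_threshold: float = 0.5) -> list[Detection]:
    """Final per-image per-class NMS at the fixed 0.5 default."""
    return nms(dets, FusionConfig(iou_threshold=iou_threshold))


def predict(
    model: StackBoxModel,
    dets_by_model: Mapping[str, Sequence[Detection]],
    conf_mode: str = "mean",
    min_iou: float = 0.0,
    nms_iou_threshold: float = 0.5,
) -> list[Detection]:
    """Full test-side pipeline: assemble → deduplicate → predict → NMS."""
    rows = assemble_test_rows(dets_by_model, model.roster, min_iou=min_iou)
    rows = deduplicate(rows)
    stacked = predict_boxes(model, rows, conf_mode=conf_mode)
    return finalize(stacked, nms_iou_threshold)
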