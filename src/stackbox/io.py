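"""COCO-format readers/writers, run configuration and the CV harness.

COCO annotation JSON (``images``/``annotations``/``categories``) and the
COCO detection-results JSON (a flat list of ``{image_id, category_id,
bbox, score}``) are the canonical interchange; ``bbox`` is ``[x, y, w,
h]`` and is converted to corner coordinates on read.  A flat CSV dialect
(image_id, class, score, x_min, y_min, x_max, y_max, model) is provided
for small fixtures.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigurationError, ValidationError
from .fusion import FUSION_METHODS, FusionConfig, fuse
from .geometry import Box, Detection, GroundTruth
from .infer import predict
from .metrics import MetricsReport, crossval_summary, evaluate
from .train import fit

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# COCO annotation + results JSON


def read_coco_annotations(path) -> tuple[list[GroundTruth], dict]:
    """Read ground truths from COCO annotation JSON.

    Returns ``(ground_truths, image_table)``; zero-area annotations are
    dropped with a logged count.
    """
    with open(path) as fh:
        data = json.load(fh)
    for key in ("images", "annotations"):
        if key not in data:
            raise ValidationError(f"{path}: missing top-level key {key!r}")
    images = {}
    for rec in data["images"]:
        try:
            images[rec["id"]] = {"width": rec.get("width"), "height": rec.get("height")}
        except (KeyError, TypeError) as exc:
            raise ValidationError(f"{path}: malformed image record {rec!r}") from exc
    gts: list[GroundTruth] = []
    n_dropped = 0
    for rec in data["annotations"]:
        try:
            x, y, w, h = rec["bbox"]
            image_id = rec["image_id"]
            class_id = rec.get("category_id", 1)
        except (KeyError, TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: malformed annotation record {rec!r}") from exc
        if w <= 0 or h <= 0:
            n_dropped += 1
            continue
        gts.append(GroundTruth(Box.from_xywh(x, y, w, h), image_id, class_id))
    if n_dropped:
        logger.info("read_coco_annotations: dropped %d zero-area annotations", n_dropped)
    return gts, images


def write_coco_annotations(path, gts: Sequence[GroundTruth], images: Mapping) -> None:
    data = {
        "images": [
            {"id": i, "width": img.get("width"), "height": img.get("height")}
            for i, img in images.items()
        ],
        "annotations": [
            {
                "id": k + 1,
                "image_id": g.image_id,
                "category_id": g.class_id,
                "bbox": list(g.box.to_xywh()),
                "area": g.box.area,
                "iscrowd": 0,
            }
            for k, g in enumerate(gts)
        ],
        "categories": [{"id": c, "name": str(c)} for c in sorted({g.class_id for g in gts})],
    }
    with open(path, "w") as fh:
        json.dump(data, fh)


def read_detections(path, model_id: str) -> list[Detection]:
    """Read a COCO results JSON and tag every record with ``model_id``."""
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, list):
        raise ValidationError(f"{path}: detection results must be a JSON list")
    dets: list[Detection] = []
    for rec in data:
        try:
            x, y, w, h = rec["bbox"]
            score = rec["score"]
            image_id = rec["image_id"]
            class_id = rec.get("category_id", 1)
        except (KeyError, TypeError, ValueError) as exc:
            raise ValidationError(f"{path}: malformed detection record {rec!r}") from exc
        if not (0.0 <= score <= 1.0):
            raise ValidationError(f"{path}: score {score} outside [0, 1] in record {rec!r}")
        dets.append(Detection(Box.from_xywh(x, y, w, h), score, model_id, image_id, class_id))
    return dets


def write_detections(path, dets: Sequence[Detection]) -> None:
    data = [
        {
            "image_id": d.image_id,
            "category_id": d.class_id,
            "bbox": list(d.box.to_xywh()),
            "score": d.confidence,
        }
        for d in dets
    ]
    with open(path, "w") as fh:
        json.dump(data, fh)


# ---------------------------------------------------------------------------
# flat CSV dialect

_CSV_FIELDS = ("image_id", "class", "score", "x_min", "y_min", "x_max", "y_max", "model")


def write_detections_csv(path, dets: Sequence[Detection]) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(_CSV_FIELDS)
        for d in dets:
            w.writerow(
                [d.image_id, d.class_id, d.confidence, *d.box.coords, d.model_id]
            )


def read_detections_csv(path) -> list[Detection]:
    dets: list[Detection] = []
    with open(path, newline="") as fh:
        for rec in csv.DictReader(fh):
            score = float(rec["score"])
            if not (0.0 <= score <= 1.0):
                raise ValidationError(f"{path}: score {score} outside [0, 1]")
            dets.append(
                Detection(
                    Box(
                        float(rec["x_min"]),
                        float(rec["y_min"]),
                        float(rec["x_max"]),
                        float(rec["y_max"]),
                    ),
                    score,
                    rec["model"],
                    _maybe_int(rec["image_id"]),
                    int(rec["class"]),
                )
            )
    return dets


def _maybe_int(s: str):
    try:
        return int(s)
    except ValueError:
        return s


# ---------------------------------------------------------------------------
# run configuration


@dataclass
class RunConfig:
    """Everything needed to reproduce a run, round-trippable via YAML."""

    roster: list[str] = field(default_factory=list)
    annotations: str | None = None
    detections: dict[str, str] = field(default_factory=dict)  # model -> path
    regressor: str = "lr"
    seed: int = 0
    n_folds: int = 5
    iou_threshold: float = 0.5
    min_match_iou: float = 0.0
    conf_mode: str = "mean"
    preset: str | None = None
    coordinate_dialect: str = "corners"  # corners | xywh
    log_level: str = "INFO"

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def manifest(self) -> dict:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return {"config_sha256": hashlib.sha256(blob).hexdigest(), "seed": self.seed}


# ---------------------------------------------------------------------------
# cross-validation harness


def make_folds(image_ids: Sequence, n_folds: int, seed: int) -> list[list]:
    """Seeded image-disjoint, exhaustive, near-equal partition."""
    ids = list(image_ids)
    if len(ids) < n_folds:
        raise ConfigurationError(f"{len(ids)} images cannot form {n_folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    folds: list[list] = [[] for _ in range(n_folds)]
    for k, idx in enumerate(perm):
        folds[k % n_folds].append(ids[idx])
    return [sorted(f) for f in folds]


def _subset_by_images(items, image_ids: set):
    return [x for x in items if x.image_id in image_ids]


def run_crossval(
    gts: Sequence[GroundTruth],
    dets_by_model: Mapping[str, Sequence[Detection]],
    roster: Sequence[str],
    n_folds: int = 5,
    seed: int = 0,
    regressor: str = "lr",
    fusion_methods: Sequence[str] = FUSION_METHODS,
    iou_threshold: float = 0.5,
    conf_mode: str = "mean",
) -> dict[str, list[MetricsReport]]:
    """Fivefold (by default) cross-validation over images.

    For each fold the stacking model is fitted on the training images
    and evaluated on the held-out images; each base learner and each
    fusion baseline is evaluated on the same held-out images.  Returns
    per-algorithm per-fold reports (use :func:`summarize_crossval` for
    the mean ± SD table).
    """
    roster = list(roster)
    image_ids = sorted({g.image_id for g in gts})
    folds = make_folds(image_ids, n_folds, seed)
    results: dict[str, list[MetricsReport]] = {m: [] for m in roster}
    for fm in fusion_methods:
        results[fm] = []
    results[f"stackbox-{regressor}"] = []
    cfg = FusionConfig(iou_threshold=iou_threshold)
    for k, test_ids in enumerate(folds):
        test_set = set(test_ids)
        train_set = set(image_ids) - test_set
        gts_test = _subset_by_images(gts, test_set)
        if not gts_test:
            raise ConfigurationError(f"fold {k} holds no ground truths")
        dets_test = {m: _subset_by_images(dets_by_model.get(m, []), test_set) for m in roster}
        for m in roster:
            results[m].append(evaluate(gts_test, dets_test[m]))
        for fm in fusion_methods:
            fused = fuse(fm, dets_test, cfg, roster)
            results[fm].append(evaluate(gts_test, fused))
        gts_train = _subset_by_images(gts, train_set)
        dets_train = {m: _subset_by_images(dets_by_model.get(m, []), train_set) for m in roster}
        model = fit(gts_train, dets_train, roster, regressor_kind=regressor, seed=seed)
        stacked = predict(model, dets_test, conf_mode=conf_mode)
        results[f"stackbox-{regressor}"].append(evaluate(gts_test, stacked))
        logger.info("fold %d/%d done (%d test images)", k + 1, n_folds, len(test_ids))
    return results


def summarize_crossval(results: Mapping[str, Sequence[MetricsReport]]) -> pd.DataFrame:
    """Mean ± SD table: one row per algorithm, one column per metric."""
    rows = {}
    for algo, reports in results.items():
        summary = crossval_summary(list(reports))
        rows[algo] = {
            m: (f"{v[0]:.2f} ± {v[1]:.2f}" if v is not None else "—")
            for m, v in summary.items()
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def summary_to_markdown(table: pd.DataFrame) -> str:
    """Render the summary DataFrame as a GitHub-style markdown table."""
    cols = list(table.columns)
    lines = ["| Algorithm | " + " | ".join(cols) + " |"]
    lines.append("|" + "---|" * (len(cols) + 1))
    for algo, row in table.iterrows():
        lines.append("| " + algo + " | " + " | ".join(str(row[c]) for c in cols) + " |")
    return "\n".join(lines)
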