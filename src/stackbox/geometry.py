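"""Axis-aligned boxes, detections and IoU arithmetic.

Coordinate convention: continuous corner coordinates ``(x_min, y_min,
x_max, y_max)`` with the origin at the top-left of the image.  Width is
``x_max - x_min`` exactly (no half-open pixel semantics); COCO-style
``[x, y, w, h]`` records are converted with ``x_max = x + w``.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np

from .errors import InvalidBoxError, ValidationError

logger = logging.getLogger(__name__)

#: COCO-convention area thresholds (pixels²) separating the size buckets.
DEFAULT_AREA_THRESHOLDS = (32.0**2, 96.0**2)


@dataclass(frozen=True, slots=True)
class Box:
    """A valid axis-aligned rectangle in pixel coordinates.

    Raises :class:`InvalidBoxError` on construction if any coordinate is
    non-finite or the box has non-positive extent on either axis.
    """

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        coords = (self.x_min, self.y_min, self.x_max, self.y_max)
        if not all(math.isfinite(c) for c in coords):
            raise InvalidBoxError(f"non-finite coordinates: {coords}")
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise InvalidBoxError(
                f"degenerate box (need x_min < x_max and y_min < y_max): {coords}"
            )

    @property
    def coords(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max, self.y_max)

    @property
    def area(self) -> float:
        return (self.x_max - self.x_min) * (self.y_max - self.y_min)

    @classmethod
    def from_xywh(cls, x: float, y: float, w: float, h: float) -> "Box":
        """Convert a COCO ``[x, y, w, h]`` record to corner form."""
        return cls(x, y, x + w, y + h)

    def to_xywh(self) -> tuple[float, float, float, float]:
        return (self.x_min, self.y_min, self.x_max - self.x_min, self.y_max - self.y_min)


@dataclass(frozen=True, slots=True)
class Detection:
    """One predicted box with its confidence and provenance."""

    box: Box
    confidence: float
    model_id: str
    image_id: int | str
    class_id: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValidationError(
                f"confidence {self.confidence!r} outside [0, 1] "
                f"(model={self.model_id}, image={self.image_id})"
            )


@dataclass(frozen=True, slots=True)
class GroundTruth:
    """One annotated object; ``area_bucket`` follows the COCO size convention."""

    box: Box
    image_id: int | str
    class_id: int = 1
    area_thresholds: tuple[float, float] = field(default=DEFAULT_AREA_THRESHOLDS)

    @property
    def area_bucket(self) -> str:
        lo, hi = self.area_thresholds
        a = self.box.area
        if a >= hi:
            return "large"
        if a >= lo:
            return "medium"
        return "other"


def area(b: Box) -> float:
    """Box area in pixels² (width × height)."""
    return b.area


def iou(a: Box, b: Box) -> float:
    """Intersection over union of two boxes; 0 when disjoint."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    if ix <= 0.0 or iy <= 0.0:
        return 0.0
    inter = ix * iy
    return inter / (a.area + b.area - inter)


def validate_and_clip(
    b: Box | tuple[float, float, float, float],
    image_width: float,
    image_height: float,
    policy: str = "clip",
) -> Box | None:
    """Constrain a box to the image frame.

    ``policy="clip"`` clamps coordinates into ``[0, width] × [0, height]``;
    ``policy="drop"`` additionally discards (returns ``None``) any box that
    is degenerate before or after clipping.  Under "clip" a box that ends
    up with no positive area is also dropped, with a logged warning.
    """
    if image_width <= 0 or image_height <= 0:
        raise ValidationError("image dimensions must be positive")
    if policy not in ("clip", "drop"):
        raise ValidationError(f"unknown clip policy {policy!r}")
    x0, y0, x1, y1 = b.coords if isinstance(b, Box) else b
    x0c = min(max(x0, 0.0), image_width)
    x1c = min(max(x1, 0.0), image_width)
    y0c = min(max(y0, 0.0), image_height)
    y1c = min(max(y1, 0.0), image_height)
    if x0c >= x1c or y0c >= y1c:
        logger.warning("dropping degenerate box %s after clipping", (x0, y0, x1, y1))
        return None
    return Box(x0c, y0c, x1c, y1c)


# ---------------------------------------------------------------------------
# vectorised helpers used by matching, fusion and evaluation


def boxes_to_array(boxes: Iterable[Box]) -> np.ndarray:
    """Stack boxes into an (n, 4) float array (x_min, y_min, x_max, y_max)."""
    arr = np.array([b.coords for b in boxes], dtype=float)
    return arr.reshape(-1, 4)


def iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pairwise IoU between two (n, 4) and (m, 4) corner-coordinate arrays."""
    a = np.asarray(a, dtype=float).reshape(-1, 4)
    b = np.asarray(b, dtype=float).reshape(-1, 4)
    ix = np.minimum(a[:, None, 2], b[None, :, 2]) - np.maximum(a[:, None, 0], b[None, :, 0])
    iy = np.minimum(a[:, None, 3], b[None, :, 3]) - np.maximum(a[:, None, 1], b[None, :, 1])
    inter = np.clip(ix, 0.0, None) * np.clip(iy, 0.0, None)
    area_a = (a[:, 2] - a[:, 0]) * (a[:, 3] - a[:, 1])
    area_b = (b[:, 2] - b[:, 0]) * (b[:, 3] - b[:, 1])
    union = area_a[:, None] + area_b[None, :] - inter
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(union > 0, inter / union, 0.0)
    return out


def group_by(
    items: Sequence, key
) -> dict:
    """Stable grouping preserving input order within each group."""
    groups: dict = {}
    for it in items:
        groups.setdefault(key(it), []).append(it)
    return groups


def with_confidence(det: Detection, confidence: float) -> Detection:
    return replace(det, confidence=confidence)
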