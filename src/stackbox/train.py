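"""Training side of the stacking ensemble.

For every ground truth, each base learner contributes its best-IoU
prediction (per image and class, non-exclusive: one detection may serve
several ground truths).  Ground truths matched by no model are dropped;
the remaining missing slots are imputed with the row's best match
regardless of source model.  Four per-coordinate datasets (x_min, y_min,
x_max, y_max) are then built — predictors are the M base learners'
values of that coordinate, the target is the ground truth's — and one
regressor is fitted per coordinate.
"""

from __future__ import annotations

import base64
import json
import logging
import pickle
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, TrainingError
from .geometry import Box, Detection, GroundTruth, boxes_to_array, group_by, iou_matrix

logger = logging.getLogger(__name__)

COORDS = ("x_min", "y_min", "x_max", "y_max")


# ---------------------------------------------------------------------------
# regressor backends


class OLSRegressor:
    """Closed-form ordinary least squares with intercept.

    Uses the pseudoinverse, so a rank-deficient design (e.g. identical
    base learners) yields the minimum-norm solution and still reproduces
    any target lying in the column space.  Exposes ``coef_``,
    ``intercept_`` and ``standard_errors_`` (NaN when not identifiable).
    """

    def __init__(self, seed: int | None = None):
        self.coef_: np.ndarray | None = None
        self.intercept_: float | None = None
        self.standard_errors_: np.ndarray | None = None

    def fit(self, X: np.ndarray, y: np.ndarray) -> "OLSRegressor":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        A = np.column_stack([np.ones(len(X)), X])
        beta = np.linalg.pinv(A) @ y
        self.intercept_ = float(beta[0])
        self.coef_ = beta[1:]
        resid = y - A @ beta
        dof = len(y) - A.shape[1]
        if dof > 0:
            s2 = float(resid @ resid) / dof
            try:
                cov = s2 * np.linalg.inv(A.T @ A)
                self.standard_errors_ = np.sqrt(np.diag(cov))
            except np.linalg.LinAlgError:
                self.standard_errors_ = np.full(A.shape[1], np.nan)
        else:
            self.standard_errors_ = np.full(A.shape[1], np.nan)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        if self.coef_ is None:
            raise TrainingError("OLSRegressor.predict called before fit")
        return np.asarray(X, dtype=float) @ self.coef_ + self.intercept_


def _sklearn_backend(cls, **fixed) -> Callable[[int], object]:
    def make(seed: int):
        return cls(random_state=seed, **fixed)

    return make


def _xgb_backend(seed: int):
    try:
        from xgboost import XGBRegressor
    except ImportError as exc:  # pragma: no cover - optional dependency
        raise ConfigurationError("regressor 'xgb' requires the xgboost package") from exc
    return XGBRegressor(random_state=seed, n_estimators=100, verbosity=0)


def _registry() -> dict[str, Callable[[int], object]]:
    from sklearn.ensemble import (
        AdaBoostRegressor,
        GradientBoostingRegressor,
        RandomForestRegressor,
    )

    return {
        "lr": lambda seed: OLSRegressor(seed),
        "adaboost": _sklearn_backend(AdaBoostRegressor),
        "rf": _sklearn_backend(RandomForestRegressor, n_estimators=100),
        "gb": _sklearn_backend(GradientBoostingRegressor),
        "xgb": _xgb_backend,
    }


REGRESSOR_KINDS = ("lr", "adaboost", "rf", "gb", "xgb")


def make_regressor(kind: str, seed: int = 0):
    """Instantiate a seeded meta-regressor backend by name."""
    reg = _registry()
    if kind not in reg:
        raise ConfigurationError(f"unknown regressor kind {kind!r}; choose from {REGRESSOR_KINDS}")
    return reg[kind](seed)


# ---------------------------------------------------------------------------
# matching and imputation


@dataclass
class MatchRow:
    """One training row: a target box and M slot detections (imputed where needed)."""

    target_box: Box
    image_id: int | str
    class_id: int
    slots: tuple[Detection, ...]
    ious: tuple[float, ...]
    fill_flags: tuple[bool, ...]


@dataclass
class RawMatchRow:
    """Pre-imputation row: ``slots[k] is None`` when model k produced no match.

    ``anchor_slot`` is set on test-side rows, where one model's own
    prediction plays the part of the ground truth and occupies its slot.
    """

    target_box: Box
    image_id: int | str
    class_id: int
    slots: list[Detection | None]
    ious: list[float]
    anchor_slot: int | None = None


def match_to_ground_truth(
    gts: Sequence[GroundTruth],
    dets_by_model: Mapping[str, Sequence[Detection]],
    roster: Sequence[str],
    min_iou: float = 0.0,
) -> list[RawMatchRow]:
    """Per ground truth and per model, the same-image same-class best-IoU detection.

    A slot stays empty when the model's best IoU does not exceed
    ``min_iou`` (default 0: any positive overlap counts).  Matching is
    non-exclusive — a single detection may be the best match of several
    ground truths.
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
    rows: list[RawMatchRow] = []
    for gt in gts:
        gt_arr = boxes_to_array([gt.box])
        slots: list[Detection | None] = []
        ious: list[float] = []
        for m in roster:
            cand = grouped[m].get((gt.image_id, gt.class_id), [])
            if cand:
                vals = iou_matrix(gt_arr, boxes_to_array([d.box for d in cand]))[0]
                k = int(np.argmax(vals))
                if vals[k] > min_iou:
                    slots.append(cand[k])
                    ious.append(float(vals[k]))
                    continue
            slots.append(None)
            ious.append(0.0)
        rows.append(RawMatchRow(gt.box, gt.image_id, gt.class_id, slots, ious))
    return rows


def impute_and_filter(raw: Sequence[RawMatchRow], mode: str = "train") -> list[MatchRow]:
    """Drop unmatched rows and fill missing slots from the row's best match.

    A row with no matched slot at all is removed.  In each surviving row,
    every empty slot is filled with a copy of the detection whose IoU with
    the target is highest, irrespective of which model produced it (ties:
    earliest roster model).  In "test" mode the anchor model's slot is
    pre-filled by construction and does not count as a match: a row is
    dropped when none of the remaining M−1 models responded, and the
    anchor is never used as the imputation source.
    """
    if mode not in ("train", "test"):
        raise ConfigurationError(f"unknown imputation mode {mode!r}")
    out: list[MatchRow] = []
    n_dropped = n_filled = 0
    for row in raw:
        avail = [
            k
            for k, d in enumerate(row.slots)
            if d is not None and k != row.anchor_slot
        ]
        if not avail:
            n_dropped += 1
            continue
        best = max(avail, key=lambda k: (row.ious[k], -k))
        slots = []
        flags = []
        for k, d in enumerate(row.slots):
            if d is None:
                slots.append(row.slots[best])
                flags.append(True)
                n_filled += 1
            else:
                slots.append(d)
                flags.append(False)
        out.append(
            MatchRow(
                row.target_box,
                row.image_id,
                row.class_id,
                tuple(slots),
                tuple(row.ious),
                tuple(flags),
            )
        )
    if n_dropped or n_filled:
        logger.info(
            "impute_and_filter(%s): dropped %d unmatched rows, filled %d slots",
            mode,
            n_dropped,
            n_filled,
        )
    return out


def build_coordinate_datasets(rows: Sequence[MatchRow]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Four aligned datasets, one per coordinate: (n × M predictors, n targets)."""
    if not rows:
        raise TrainingError("no match rows to build coordinate datasets from")
    datasets: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for ci, cname in enumerate(COORDS):
        X = np.array([[d.box.coords[ci] for d in row.slots] for row in rows], dtype=float)
        y = np.array([row.target_box.coords[ci] for row in rows], dtype=float)
        datasets[cname] = (X, y)
    return datasets


# ---------------------------------------------------------------------------
# the fitted model


@dataclass
class StackBoxModel:
    """Four fitted per-coordinate meta-regressors plus the base-learner roster."""

    roster: tuple[str, ...]
    regressors: dict[str, object]
    regressor_kind: str
    metadata: dict = field(default_factory=dict)

    def predict_coords(self, X_by_coord: Mapping[str, np.ndarray]) -> np.ndarray:
        """Stack the four coordinate predictions into an (n, 4) array."""
        cols = [np.asarray(self.regressors[c].predict(X_by_coord[c])) for c in COORDS]
        return np.column_stack(cols)

    # -- persistence --------------------------------------------------------

    def save(self, path) -> None:
        """Versioned JSON serialization; OLS coefficients stored in clear,
        other backends as a base64 pickle blob."""
        payload = {
            "format": "stackbox-model",
            "version": 1,
            "roster": list(self.roster),
            "regressor_kind": self.regressor_kind,
            "metadata": self.metadata,
            "regressors": {},
        }
        for c, reg in self.regressors.items():
            if isinstance(reg, OLSRegressor):
                payload["regressors"][c] = {
                    "type": "ols",
                    "coef": list(map(float, reg.coef_)),
                    "intercept": reg.intercept_,
                }
            else:
                blob = base64.b64encode(pickle.dumps(reg)).decode("ascii")
                payload["regressors"][c] = {"type": "pickle", "blob": blob}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    @classmethod
    def load(cls, path) -> "StackBoxModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format") != "stackbox-model":
            raise ConfigurationError(f"{path} is not a stackbox model file")
        regressors: dict[str, object] = {}
        for c, spec in payload["regressors"].items():
            if spec["type"] == "ols":
                reg = OLSRegressor()
                reg.coef_ = np.asarray(spec["coef"], dtype=float)
                reg.intercept_ = float(spec["intercept"])
                regressors[c] = reg
            else:
                regressors[c] = pickle.loads(base64.b64decode(spec["blob"]))
        return cls(
            roster=tuple(payload["roster"]),
            regressors=regressors,
            regressor_kind=payload["regressor_kind"],
            metadata=payload.get("metadata", {}),
        )


def fit(
    gts: Sequence[GroundTruth],
    dets_by_model: Mapping[str, Sequence[Detection]],
    roster: Sequence[str] | None = None,
    regressor_kind: str = "lr",
    seed: int = 0,
    min_iou: float = 0.0,
) -> StackBoxModel:
    """Match, impute, build the four coordinate datasets and fit the meta-learners."""
    roster = list(roster) if roster is not None else sorted(dets_by_model)
    if len(roster) < 2:
        raise ConfigurationError(f"stacking needs at least 2 base learners, got {len(roster)}")
    raw = match_to_ground_truth(gts, dets_by_model, roster, min_iou=min_iou)
    rows = impute_and_filter(raw, mode="train")
    if not rows:
        raise TrainingError("no ground truth was matched by any base learner")
    datasets = build_coordinate_datasets(rows)
    regressors: dict[str, object] = {}
    for c in COORDS:
        X, y = datasets[c]
        reg = make_regressor(regressor_kind, seed)
        reg.fit(X, y)
        regressors[c] = reg
    n_filled = sum(sum(r.fill_flags) for r in rows)
    meta = {
        "n_rows": len(rows),
        "n_ground_truths": len(gts),
        "n_filled_slots": int(n_filled),
        "seed": seed,
        "min_iou": min_iou,
    }
    return StackBoxModel(tuple(roster), regressors, regressor_kind, meta)
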