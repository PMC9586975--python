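"""Seeded synthetic detection scenarios.

Stands in for GPU-trained base detectors: ground-truth boxes are sampled
on blank images, and each simulated base learner re-emits them through a
per-model systematic affine distortion of the four corner coordinates
plus Gaussian jitter, with configurable miss and false-positive rates
and a Beta confidence model.  This is exactly the structure a stacking
meta-regression can exploit (a learnable, model-specific coordinate
bias), so the presets double as end-to-end test benches.

Reproducibility: every operation derives independent named substreams
(gt, fp, one per model) from the scenario seed, so adding a model never
perturbs the ground-truth sample.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .errors import GenerationError, StackBoxError
from .geometry import Box, Detection, GroundTruth, iou_matrix, validate_and_clip


def _substream(seed: int, label: str) -> np.random.Generator:
    """Deterministic named substream of the scenario seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed), zlib.crc32(label.encode())]))


@dataclass(frozen=True)
class NoiseProfile:
    """How one simulated base learner distorts the ground truth.

    Each emitted coordinate is ``a_k · c_k + b_k + N(0, jitter_sd²)``,
    clipped to the image.  A ground truth is skipped entirely with
    probability ``miss_rate``; ``fp_rate`` false positives per image are
    added at Poisson-sampled counts, with the same size distribution as
    ground truths.  Confidences are Beta-distributed with the stated
    means (``conf_concentration`` = alpha + beta).
    """

    name: str
    scale: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    offset: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    jitter_sd: float = 0.0
    miss_rate: float = 0.0
    fp_rate: float = 0.0
    tp_conf_mean: float = 0.85
    fp_conf_mean: float = 0.30
    conf_concentration: float = 25.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.miss_rate <= 1.0):
            raise StackBoxError("miss_rate outside [0, 1]")
        if self.jitter_sd < 0 or self.fp_rate < 0:
            raise StackBoxError("jitter_sd and fp_rate must be non-negative")


@dataclass(frozen=True)
class SyntheticScenario:
    """One reproducible benchmark: images, ground truths, base learners.

    Box areas are log-uniform over ``area_range`` (default spans the
    medium and large COCO buckets), aspect ratios uniform in
    ``aspect_range``, placed uniformly with ``margin`` pixels kept clear
    of the frame so that a biased re-emission stays inside the image.
    Boxes within an image are rejection-sampled to pairwise IoU ≤
    ``max_gt_iou``.
    """

    n_images: int
    width: float = 640.0
    height: float = 640.0
    boxes_per_image: tuple[int, int] = (1, 3)
    area_range: tuple[float, float] = (2000.0, 38000.0)
    aspect_range: tuple[float, float] = (0.6, 1.6)
    margin: float = 25.0
    max_gt_iou: float = 0.2
    profiles: tuple[NoiseProfile, ...] = ()
    seed: int = 0

    @property
    def roster(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.profiles)


def _sample_box(rng: np.random.Generator, scenario: SyntheticScenario) -> Box:
    lo, hi = scenario.area_range
    area = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    aspect = float(rng.uniform(*scenario.aspect_range))  # width / height
    h = float(np.sqrt(area / aspect))
    w = area / h
    m = scenario.margin
    max_x = scenario.width - m - w
    max_y = scenario.height - m - h
    if max_x <= m or max_y <= m:
        raise GenerationError(
            f"box of size {w:.0f}x{h:.0f} cannot fit inside "
            f"{scenario.width}x{scenario.height} with margin {m}"
        )
    x0 = float(rng.uniform(m, max_x))
    y0 = float(rng.uniform(m, max_y))
    return Box(x0, y0, x0 + w, y0 + h)


def generate_ground_truth(
    scenario: SyntheticScenario,
) -> tuple[list[GroundTruth], dict]:
    """Sample ground-truth boxes and the image table, reproducibly."""
    rng = _substream(scenario.seed, "gt")
    lo, hi = scenario.boxes_per_image
    if not (1 <= lo <= hi):
        raise GenerationError(f"invalid boxes_per_image range {scenario.boxes_per_image}")
    gts: list[GroundTruth] = []
    images = {
        i: {"width": scenario.width, "height": scenario.height}
        for i in range(scenario.n_images)
    }
    for img in range(scenario.n_images):
        n = int(rng.integers(lo, hi + 1))
        placed: list[Box] = []
        attempts = 0
        while len(placed) < n:
            b = _sample_box(rng, scenario)
            if all(
                iou_matrix(np.array([b.coords]), np.array([p.coords]))[0, 0]
                <= scenario.max_gt_iou
                for p in placed
            ):
                placed.append(b)
            attempts += 1
            if attempts > 200 * n:
                raise GenerationError("cannot place non-overlapping boxes; loosen constraints")
        gts.extend(GroundTruth(b, img) for b in placed)
    return gts, images


def simulate_base_learner(
    gts: Sequence[GroundTruth],
    profile: NoiseProfile,
    scenario: SyntheticScenario,
    seed: int | None = None,
) -> list[Detection]:
    """Emit one simulated detector's output for the given ground truths."""
    seed = scenario.seed if seed is None else seed
    rng = _substream(seed, f"model:{profile.name}")
    fp_rng = _substream(seed, f"fp:{profile.name}")
    a = np.asarray(profile.scale)
    b = np.asarray(profile.offset)
    dets: list[Detection] = []
    for gt in gts:
        if rng.random() < profile.miss_rate:
            continue
        coords = a * np.asarray(gt.box.coords) + b
        if profile.jitter_sd > 0:
            coords = coords + rng.normal(0.0, profile.jitter_sd, size=4)
        box = validate_and_clip(tuple(coords), scenario.width, scenario.height, policy="drop")
        if box is None:
            continue
        conf = _beta(rng, profile.tp_conf_mean, profile.conf_concentration)
        dets.append(Detection(box, conf, profile.name, gt.image_id, gt.class_id))
    # uniformly placed false positives, same size distribution as ground truths
    for img in range(scenario.n_images):
        for _ in range(int(fp_rng.poisson(profile.fp_rate))):
            box = _sample_box(fp_rng, scenario)
            conf = _beta(fp_rng, profile.fp_conf_mean, profile.conf_concentration)
            dets.append(Detection(box, conf, profile.name, img, 1))
    return dets


def _beta(rng: np.random.Generator, mean: float, concentration: float) -> float:
    alpha = mean * concentration
    beta = (1.0 - mean) * concentration
    return float(rng.beta(alpha, beta))


def simulate_all(
    scenario: SyntheticScenario,
) -> tuple[list[GroundTruth], dict, dict[str, list[Detection]]]:
    """Ground truths plus one detection set per configured base learner."""
    gts, images = generate_ground_truth(scenario)
    dets = {p.name: simulate_base_learner(gts, p, scenario) for p in scenario.profiles}
    return gts, images, dets


# ---------------------------------------------------------------------------
# presets

# Three distinct affine coordinate biases: a pure shift, a scale error,
# and an asymmetric inflation.  All three push boxes in the same
# direction, so plain (confidence-weighted) averaging cannot cancel the
# systematic error while a per-coordinate regression can invert it —
# the regime where detectors share a localization weakness and strict-
# threshold precision collapses even though loose-threshold detection
# mostly works.  Offsets and scales keep a biased box inside a 640x640
# frame given the 40 px placement margin, so the affine model holds
# exactly (no clipping).
_BIAS_PROFILES = (
    NoiseProfile(
        "model_shift",
        offset=(12.0, 10.0, 12.0, 10.0),
        jitter_sd=2.0,
        miss_rate=0.1,
        fp_rate=0.5,
    ),
    NoiseProfile(
        "model_scale",
        scale=(1.03, 1.03, 1.03, 1.03),
        offset=(5.0, 6.0, 5.0, 6.0),
        jitter_sd=2.0,
        miss_rate=0.1,
        fp_rate=0.5,
    ),
    NoiseProfile(
        "model_inflate",
        offset=(6.0, 10.0, 24.0, 28.0),
        jitter_sd=2.0,
        miss_rate=0.1,
        fp_rate=0.5,
    ),
)


def preset_scenarios(seed: int = 0) -> dict[str, SyntheticScenario]:
    """Named study conditions used throughout the tests.

    perfect — three noise-free identity learners on 200 images.
    bias    — three learners with distinct affine biases, 2 px jitter,
              10% miss rate and 0.5 false positives per image, 500 images.
    hard    — the bias learners with 6 px jitter, 25% misses and 1 FP/img.
    """
    perfect = SyntheticScenario(
        n_images=200,
        profiles=tuple(NoiseProfile(f"model_{s}") for s in ("a", "b", "c")),
        seed=seed,
    )
    bias = SyntheticScenario(n_images=500, profiles=_BIAS_PROFILES, margin=40.0, seed=seed)
    hard = SyntheticScenario(
        n_images=500,
        profiles=tuple(
            replace(p, jitter_sd=6.0, miss_rate=0.25, fp_rate=1.0) for p in _BIAS_PROFILES
        ),
        margin=40.0,
        seed=seed,
    )
    return {"perfect": perfect, "bias": bias, "hard": hard}


def get_preset(name: str, seed: int = 0) -> SyntheticScenario:
    presets = preset_scenarios(seed)
    try:
        return presets[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; available: {sorted(presets)}") from None
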