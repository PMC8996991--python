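"""TMA core detection on a low-magnification pyramid level.

Two pieces live here.  First, the cascade orchestration contract: a
detector is a sequence of ``eta`` stages, each a (box regressor,
classifier) pair trained against an increasing IoU threshold schedule
``phi_1 < ... < phi_eta``, composed so each stage refines the previous
stage's boxes.  The deep backbones that usually fill those stages are
pluggable; the orchestration (stage composition, per-stage IoU
relabeling, non-maximum suppression) is fixed here.  Second, a classical
CPU detector — foreground threshold, connected components, area and
circularity filters — that finds the roughly circular, well-separated
cores of a TMA without any training and serves as the default backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.ndimage import binary_fill_holes
from skimage.color import rgb2gray
from skimage.filters import gaussian, threshold_otsu
from skimage.measure import label as cc_label, regionprops
from skimage.morphology import disk, opening

from .pyramid import BoundingBox

__all__ = [
    "CoreDetection",
    "CascadeConfig",
    "iou",
    "assign_stage_labels",
    "cascade_refine",
    "nms",
    "detect_cores_classical",
    "ClassicalCoreDetector",
]


@dataclass(frozen=True)
class CoreDetection:
    """A detected core: box at the detection level plus a confidence score."""

    box: BoundingBox
    score: float
    core_id: str = ""

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")


@dataclass
class CascadeConfig:
    """Multi-stage refinement schedule.

    ``iou_thresholds`` must be strictly increasing, one per stage; later
    stages are trained on (and therefore demand) better-localised
    proposals.  ``tradeoff`` is the classification/localisation loss
    weight recorded for backend trainers.
    """

    num_stages: int = 3
    iou_thresholds: tuple[float, ...] = (0.5, 0.6, 0.7)
    tradeoff: float = 1.0
    nms_iou: float = 0.3
    min_score: float = 0.5

    def __post_init__(self) -> None:
        if len(self.iou_thresholds) != self.num_stages:
            raise ValueError("one IoU threshold per stage required")
        for t0, t1 in zip(self.iou_thresholds, self.iou_thresholds[1:]):
            if not (0 < t0 < t1 < 1):
                raise ValueError("thresholds must be strictly increasing in (0, 1)")
        if not 0 < self.iou_thresholds[0] < 1:
            raise ValueError("thresholds must lie in (0, 1)")


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes at the same level."""
    if a.level != b.level:
        raise ValueError("IoU requires boxes at the same pyramid level")
    ix = max(0, min(a.x2, b.x2) - max(a.x, b.x))
    iy = max(0, min(a.y2, b.y2) - max(a.y, b.y))
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def assign_stage_labels(
    proposals: Sequence[BoundingBox],
    truth: Sequence[BoundingBox],
    threshold: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Positive/negative labels for proposals at one cascade stage.

    A proposal is positive (label 1) iff its best IoU with any ground-truth
    box reaches ``threshold``; the index of that box is recorded (-1 for
    negatives).
    """
    if not 0 < threshold < 1:
        raise ValueError("IoU threshold must lie in (0, 1)")
    labels = np.zeros(len(proposals), dtype=int)
    matches = np.full(len(proposals), -1, dtype=int)
    for i, p in enumerate(proposals):
        if not truth:
            continue
        ious = [iou(p, t) for t in truth]
        j = int(np.argmax(ious))
        if ious[j] >= threshold:
            labels[i] = 1
            matches[i] = j
    return labels, matches


def nms(detections: list[CoreDetection], iou_threshold: float = 0.3) -> list[CoreDetection]:
    """Greedy non-maximum suppression, highest score first."""
    order = sorted(detections, key=lambda d: d.score, reverse=True)
    kept: list[CoreDetection] = []
    for det in order:
        if all(iou(det.box, k.box) < iou_threshold for k in kept):
            kept.append(det)
    return kept


Stage = tuple[
    Callable[[np.ndarray, BoundingBox], BoundingBox],  # regressor: refines a box
    Callable[[np.ndarray, BoundingBox], float],  # classifier: scores a box
]


def cascade_refine(
    image_region: np.ndarray,
    initial_boxes: Sequence[BoundingBox],
    stages: Sequence[Stage],
    cfg: CascadeConfig,
    truth: Sequence[BoundingBox] | None = None,
) -> list[CoreDetection]:
    """Run proposals through the full stage cascade.

    Each stage's regressor refines every surviving box; when ground truth
    is supplied the per-stage labels under that stage's IoU threshold are
    recomputed (the resampling signal a trainer would use).  The final
    score comes from the last stage's classifier, then NMS and the score
    floor are applied.
    """
    if len(stages) != cfg.num_stages:
        raise ValueError(
            f"cascade expects {cfg.num_stages} stages, got {len(stages)}"
        )
    boxes = list(initial_boxes)
    for s_idx, ((regressor, _), thr) in enumerate(zip(stages, cfg.iou_thresholds)):
        refined = []
        for b in boxes:
            out = regressor(image_region, b)
            if not isinstance(out, BoundingBox) or out.w <= 0 or out.h <= 0:
                raise ValueError(f"stage {s_idx} returned an invalid box for {b}")
            refined.append(out)
        boxes = refined
        if truth is not None:
            assign_stage_labels(boxes, truth, thr)
    _, final_classifier = stages[-1]
    dets = []
    for i, b in enumerate(boxes):
        score = float(np.clip(final_classifier(image_region, b), 0.0, 1.0))
        dets.append(CoreDetection(box=b, score=score, core_id=f"det_{i:04d}"))
    dets = [d for d in nms(dets, cfg.nms_iou) if d.score >= cfg.min_score]
    return dets


# --------------------------------------------------------------- classical

@dataclass
class ClassicalCoreDetector:
    """Training-free core detector for well-separated circular cores.

    Foreground = pixels darker than the Otsu threshold of the grayscale
    image (stained tissue on a bright glass background).  Connected
    components are filtered by area (relative to the median component, so
    dust specks and merged artifacts drop out) and by circularity
    ``4*pi*A / P**2``; the circularity doubles as the detection score.
    """

    min_area_frac: float = 0.25
    max_area_frac: float = 4.0
    min_circularity: float = 0.6
    smooth_sigma: float = 1.0
    level: int = 0

    def detect(self, image: np.ndarray) -> list[CoreDetection]:
        gray = rgb2gray(image) if image.ndim == 3 else image.astype(float)
        if gray.max() > 1.0:
            gray = gray / 255.0
        if np.ptp(gray) < 1e-6:
            return []
        if self.smooth_sigma > 0:
            gray = gaussian(gray, sigma=self.smooth_sigma)
        fg = gray < threshold_otsu(gray)
        if not fg.any():
            return []
        # texture noise crinkles the threshold boundary, which inflates the
        # perimeter estimate; clean the mask before measuring circularity
        fg = binary_fill_holes(opening(fg, disk(1)))
        lab = cc_label(fg)
        props = regionprops(lab)
        if not props:
            return []
        areas = np.array([p.area for p in props])
        med = np.median(areas)
        dets = []
        for p in props:
            if not (self.min_area_frac * med <= p.area <= self.max_area_frac * med):
                continue
            circ = 4.0 * np.pi * p.area / max(p.perimeter, 1.0) ** 2
            if circ < self.min_circularity:
                continue
            y0, x0, y1, x1 = p.bbox
            dets.append(
                CoreDetection(
                    box=BoundingBox(x0, y0, x1 - x0, y1 - y0, level=self.level),
                    score=float(np.clip(circ, 0.0, 1.0)),
                )
            )
        dets.sort(key=lambda d: (d.box.y, d.box.x))
        return [
            CoreDetection(d.box, d.score, core_id=f"core_{i:04d}")
            for i, d in enumerate(dets)
        ]


def detect_cores_classical(level_image: np.ndarray, level: int = 0) -> list[CoreDetection]:
    """Functional wrapper over :class:`ClassicalCoreDetector`."""
    return ClassicalCoreDetector(level=level).detect(level_image)
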