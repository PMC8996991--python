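"""End-to-end slide processing: detect cores, select tumor tiles, fetch
medium-resolution features, train and evaluate the effect classifier.

This is the glue that the CLI and the experiment scripts drive; every
stage is the corresponding module's public surface with a pluggable
backend, so swapping the classical detector or the color-threshold
segmenter for a learned model changes one argument, not the flow.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_detect import ClassicalCoreDetector, CoreDetection, iou
from .effect_predict import (
    MediumResTile,
    TreatmentEffectClassifier,
    fetch_medium_res_tiles,
    predict_core,
    tile_features,
)
from .pyramid import BoundingBox, PyramidImage, detection_level, extract_region, forward_map
from .synthetic_tma import TmaGroundTruth
from .tumor_select import ColorThresholdSegmenter, Segmenter, select_tumor_tiles

__all__ = [
    "PipelineConfig",
    "CoreRecord",
    "detect_slide",
    "detection_recall",
    "collect_core_tiles",
    "run_effect_experiment",
]


@dataclass
class PipelineConfig:
    alpha: float = 0.05
    tile_size: int = 64          # desk-scale tile grid; 512 for full-scale WSIs
    rho: float = 3.0
    delta: float = 0.5
    agg_mode: str = "mean"
    detection_max_dim: int = 2048
    match_iou: float = 0.5
    train_frac: float = 0.66


@dataclass
class CoreRecord:
    """One detected core ready for classification."""

    core_id: str
    slide_index: int
    box0: BoundingBox
    label: int | None
    tiles: list[MediumResTile]


def detect_slide(
    pyramid: PyramidImage, cfg: PipelineConfig | None = None
) -> tuple[list[CoreDetection], int]:
    """Run the classical detector on the slide's detection level and return
    detections (at that level) plus the level index."""
    cfg = cfg or PipelineConfig()
    xi = detection_level(pyramid, cfg.detection_max_dim)
    dets = ClassicalCoreDetector(level=xi).detect(pyramid.levels[xi])
    return dets, xi


def detection_recall(
    detections0: Sequence[BoundingBox],
    truth_boxes: Sequence[BoundingBox],
    iou_threshold: float = 0.5,
) -> float:
    """Fraction of ground-truth cores matched by some detection at the IoU
    threshold (both box sets at level 0)."""
    if not truth_boxes:
        raise ValueError("no ground-truth boxes")
    hit = 0
    for t in truth_boxes:
        if any(iou(d, t) >= iou_threshold for d in detections0):
            hit += 1
    return hit / len(truth_boxes)


def collect_core_tiles(
    pyramid: PyramidImage,
    truth: TmaGroundTruth | None,
    segmenter: Segmenter | None = None,
    cfg: PipelineConfig | None = None,
    slide_index: int = 0,
) -> tuple[list[CoreRecord], float]:
    """Detect cores on one slide, select tumor tiles per core and fetch
    them at the medium level.

    With ground truth supplied, each detection inherits the label of the
    best-matching truth box (unmatched detections keep ``label=None``)
    and the detection recall is returned alongside; without it the
    recall is NaN.
    """
    cfg = cfg or PipelineConfig()
    segmenter = segmenter or ColorThresholdSegmenter()
    dets, xi = detect_slide(pyramid, cfg)
    boxes0 = [forward_map(d.box, pyramid) for d in dets]
    recall = float("nan")
    labels: list[int | None] = [None] * len(boxes0)
    if truth is not None:
        recall = detection_recall(boxes0, truth.core_boxes, cfg.match_iou)
        for i, b in enumerate(boxes0):
            ious = [iou(b, t) for t in truth.core_boxes]
            if ious and max(ious) >= cfg.match_iou:
                labels[i] = int(truth.core_labels[int(np.argmax(ious))])
    records = []
    for i, (det, b0) in enumerate(zip(dets, boxes0)):
        region = extract_region(pyramid, b0, target_level=0)
        cid = f"s{slide_index}_{det.core_id}"
        selected = select_tumor_tiles(
            region, segmenter, alpha=cfg.alpha, M=cfg.tile_size, core_id=cid
        )
        tiles = fetch_medium_res_tiles(selected, pyramid, b0, rho=cfg.rho)
        records.append(
            CoreRecord(core_id=cid, slide_index=slide_index, box0=b0, label=labels[i], tiles=tiles)
        )
    return records, recall


def run_effect_experiment(
    slides: Sequence[tuple[PyramidImage, TmaGroundTruth]],
    cfg: PipelineConfig | None = None,
    segmenter: Segmenter | None = None,
    seed: int = 0,
) -> dict:
    """Detect, select and classify across a slide corpus.

    Labeled cores are split into train/test (default 66/34, seeded,
    stratified by outcome), the logistic effect classifier is trained on
    the training tiles with the core label propagated to each tile, and
    core-level scores ``beta`` on the test split give ROC AUC, accuracy
    and the confusion-derived metrics.
    """
    from .evaluate import ConfusionCounts, classification_metrics, roc_auc

    cfg = cfg or PipelineConfig()
    all_records: list[CoreRecord] = []
    recalls = []
    for si, (pyr, truth) in enumerate(slides):
        recs, rec = collect_core_tiles(pyr, truth, segmenter, cfg, slide_index=si)
        all_records.extend(recs)
        recalls.append(rec)

    labeled = [r for r in all_records if r.label is not None and r.tiles]
    rng = np.random.default_rng(seed)
    by_class: dict[int, list[CoreRecord]] = {0: [], 1: []}
    for r in labeled:
        by_class[r.label].append(r)
    train, test = [], []
    for cls_records in by_class.values():
        order = rng.permutation(len(cls_records))
        n_train = int(round(cfg.train_frac * len(cls_records)))
        train += [cls_records[i] for i in order[:n_train]]
        test += [cls_records[i] for i in order[n_train:]]

    X = np.stack([tile_features(t) for r in train for t in r.tiles])
    y = np.array([r.label for r in train for _ in r.tiles])
    clf = TreatmentEffectClassifier().fit(X, y)
    backend = clf.tile_backend()

    preds = [
        predict_core(r.tiles, backend, delta=cfg.delta, core_id=r.core_id, agg_mode=cfg.agg_mode)
        for r in test
    ]
    y_true = np.array([r.label for r in test])
    betas = np.array([p.beta for p in preds])
    decisions = np.array([p.decision for p in preds])
    auc, roc = roc_auc(betas, y_true)
    counts = ConfusionCounts.from_predictions(y_true, decisions)
    metrics = classification_metrics(counts)
    return {
        "detection_recall": float(np.nanmean(recalls)),
        "auc": auc,
        "roc": roc,
        "metrics": metrics,
        "counts": counts,
        "n_train_cores": len(train),
        "n_test_cores": len(test),
        "predictions": pd.DataFrame(
            {
                "core_id": [p.core_id for p in preds],
                "beta": betas,
                "decision": decisions,
                "label": y_true,
                "n_tiles_used": [p.n_tiles_used for p in preds],
            }
        ),
    }
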