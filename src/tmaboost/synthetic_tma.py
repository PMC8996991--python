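"""Seeded synthetic tissue-microarray fixtures.

No public TMA dataset with per-core bevacizumab-response labels exists,
so every statistical assumption the pipeline makes is emulated here: a
slide is a bright background carrying a rows x cols grid of circular
stained cores (grid positions jittered, never touching); each core
contains a band-limited "tumor" blob whose DAB-brown staining intensity
is shifted between outcome classes by ``effect_size`` noise standard
deviations; core outcomes are Bernoulli with the observed 57.2%
effective prevalence; and companion generators produce training traces
with a known loss plateau and exponential survival records with a known
hazard ratio.  Everything is bit-reproducible under a fixed seed.

Default geometry is a desk-scale rendering of the study layout: 6 x 10
cores per slide and 12 slides gives the 720-core corpus, with cores
drawn at 128 px diameter rather than the ~4000 px of a 2 mm core at
20x so that full-pipeline runs stay in CPU seconds.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from imageio.v3 import imwrite
from scipy.ndimage import gaussian_filter

from .evaluate import SurvivalRecord
from .model_select import TrainingTrace
from .pyramid import BoundingBox, PyramidImage, build_pyramid

INVALID, EFFECTIVE = 0, 1

__all__ = [
    "TmaSpec",
    "TmaGroundTruth",
    "generate_slide",
    "generate_dataset",
    "generate_trace",
    "generate_survival",
]

# stain palette (RGB): bright glass background, hematoxylin-ish tissue,
# DAB-brown tumor staining
_BACKGROUND = np.array([235.0, 233.0, 236.0])
_TISSUE = np.array([186.0, 166.0, 202.0])
_TUMOR = np.array([155.0, 115.0, 78.0])


@dataclass(frozen=True)
class TmaSpec:
    """Geometry and statistics of a synthetic TMA slide.

    ``effect_size`` is the mean shift of the tumor brown index between
    Effective and Invalid cores, in units of the texture noise SD; 0
    makes appearance and outcome independent.  ``effective_prob`` is the
    marginal probability a core is labelled Effective (default the
    observed 57.2% prevalence).
    """

    rows: int = 6
    cols: int = 10
    core_diameter_px: int = 128
    num_levels: int = 4
    tumor_fraction_range: tuple[float, float] = (0.15, 0.45)
    effect_size: float = 2.0
    effective_prob: float = 0.572
    noise_sd: float = 12.0
    spacing_factor: float = 1.6
    jitter_frac: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows * self.cols < 1:
            raise ValueError("need at least one core")
        if not 0.0 <= self.effective_prob <= 1.0:
            raise ValueError("effective_prob must lie in [0, 1]")
        if self.num_levels < 1:
            raise ValueError("need at least one pyramid level")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")
        lo, hi = self.tumor_fraction_range
        if not 0 <= lo <= hi <= 1:
            raise ValueError("tumor_fraction_range must be an interval within [0, 1]")
        # overlap check: worst-case jitter must keep adjacent cores apart
        if self.spacing * (1 - 2 * self.jitter_frac) < self.core_diameter_px:
            raise ValueError(
                "cores can overlap at the requested geometry: increase "
                "spacing_factor or reduce jitter_frac"
            )

    @property
    def spacing(self) -> int:
        return int(round(self.spacing_factor * self.core_diameter_px))

    @property
    def margin(self) -> int:
        return self.spacing // 2

    @property
    def slide_shape(self) -> tuple[int, int]:
        h = 2 * self.margin + self.spacing * self.rows
        w = 2 * self.margin + self.spacing * self.cols
        return h, w


@dataclass
class TmaGroundTruth:
    """Per-core truth: level-0 boxes, in-box tumor masks, outcome labels."""

    core_boxes: list[BoundingBox]
    tumor_masks: list[np.ndarray]
    core_labels: np.ndarray
    core_ids: list[str]

    def __post_init__(self) -> None:
        n = len(self.core_boxes)
        if not (len(self.tumor_masks) == len(self.core_labels) == len(self.core_ids) == n):
            raise ValueError("one box, mask, label and id per core")

    def write(self, out_dir: str, slide_id: str = "slide") -> None:
        os.makedirs(out_dir, exist_ok=True)
        recs = [
            {"core_id": cid, **box.to_dict(), "outcome": int(lab)}
            for cid, box, lab in zip(self.core_ids, self.core_boxes, self.core_labels)
        ]
        with open(os.path.join(out_dir, "ground_truth.json"), "w") as fh:
            json.dump(recs, fh, indent=1)
        pd.DataFrame(
            {
                "core_id": self.core_ids,
                "slide_id": slide_id,
                "outcome": self.core_labels.astype(int),
            }
        ).to_csv(os.path.join(out_dir, "labels.csv"), index=False)
        mask_dir = os.path.join(out_dir, "masks")
        os.makedirs(mask_dir, exist_ok=True)
        for cid, m in zip(self.core_ids, self.tumor_masks):
            imwrite(os.path.join(mask_dir, f"{cid}.png"), (m * 255).astype(np.uint8))


def _band_limited_noise(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Gaussian-filtered white noise, renormalised to unit SD."""
    field_ = gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    sd = field_.std()
    return field_ / sd if sd > 0 else field_


def generate_slide(spec: TmaSpec) -> tuple[PyramidImage, TmaGroundTruth]:
    """Render one synthetic TMA slide and its ground truth.

    Cores sit on a jittered grid; each carries a tumor blob covering a
    fraction drawn from ``tumor_fraction_range`` whose brown staining
    mean encodes the core outcome at ``effect_size`` noise SDs.  The
    same seed always reproduces the same bytes.
    """
    rng = np.random.default_rng(spec.seed)
    H, W = spec.slide_shape
    d = spec.core_diameter_px
    r = d / 2.0

    img = np.empty((H, W, 3), dtype=np.float64)
    img[:] = _BACKGROUND
    img += rng.normal(0.0, 2.0, size=(H, W, 1))

    boxes, masks, labels, ids = [], [], [], []
    yy, xx = np.mgrid[0:d, 0:d]
    idx = 0
    for row in range(spec.rows):
        for col in range(spec.cols):
            cy = spec.margin + spec.spacing * (row + 0.5)
            cx = spec.margin + spec.spacing * (col + 0.5)
            jmax = spec.jitter_frac * spec.spacing
            cy += rng.uniform(-jmax, jmax)
            cx += rng.uniform(-jmax, jmax)
            x0 = int(round(cx - r))
            y0 = int(round(cy - r))
            label = EFFECTIVE if rng.random() < spec.effective_prob else INVALID
            frac = rng.uniform(*spec.tumor_fraction_range)

            disc = (yy - (d - 1) / 2.0) ** 2 + (xx - (d - 1) / 2.0) ** 2 <= r ** 2
            blob_field = _band_limited_noise(rng, (d, d), sigma=d / 8.0)
            inside = blob_field[disc]
            if frac <= 0:
                tumor = np.zeros((d, d), dtype=bool)
            else:
                thr = np.quantile(inside, 1.0 - frac)
                tumor = disc & (blob_field >= thr)

            texture = gaussian_filter(
                rng.normal(0.0, 1.0, size=(d, d, 3)), sigma=(1.5, 1.5, 0)
            )
            texture *= spec.noise_sd / max(texture.std(), 1e-9)
            patch = np.where(tumor[..., None], _TUMOR, _TISSUE) + texture
            # outcome shifts the brown (DAB) index of tumor pixels:
            # +delta/2 on R and G, -delta/2 on B, i.e. a brown-index shift
            # of effect_size * noise_sd between the two classes
            if label == EFFECTIVE:
                delta = spec.effect_size * spec.noise_sd
                patch[tumor] += np.array([delta / 2.0, delta / 2.0, -delta / 2.0])

            region = img[y0 : y0 + d, x0 : x0 + d]
            region[disc] = patch[disc]

            boxes.append(BoundingBox(x0, y0, d, d, level=0))
            masks.append(tumor)
            labels.append(label)
            ids.append(f"core_{idx:04d}")
            idx += 1

    level0 = np.clip(img, 0, 255).astype(np.uint8)
    pyramid = build_pyramid(level0, spec.num_levels)
    truth = TmaGroundTruth(boxes, masks, np.array(labels, dtype=int), ids)
    return pyramid, truth


def generate_dataset(
    spec: TmaSpec, num_slides: int = 12
) -> list[tuple[PyramidImage, TmaGroundTruth]]:
    """Generate a multi-slide corpus; slide i uses seed ``spec.seed + i``.

    The default 12 slides of 60 cores reproduce the 720-core study
    layout.
    """
    out = []
    for i in range(num_slides):
        s = TmaSpec(**{**spec.__dict__, "seed": spec.seed + i})
        out.append(generate_slide(s))
    return out


def generate_trace(
    num_iters: int,
    plateau_start: int,
    noise_sd: float = 0.0,
    seed: int = 0,
    eval_period: int = 1000,
    loss_base: float = 0.1,
    loss_amp: float = 2.0,
    f_max: float = 0.9,
    f_amp: float = 0.6,
) -> TrainingTrace:
    """Synthetic training trace with a known plateau location.

    Loss decays exponentially (time constant ``plateau_start / 5``) and
    is exactly flat from ``plateau_start`` on; the F-measure rises with
    the matching plateau.  Gaussian evaluation noise of SD ``noise_sd``
    is added to both, seeded.
    """
    if plateau_start >= num_iters:
        raise ValueError("plateau_start must precede num_iters")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    its = np.arange(eval_period, num_iters + 1, eval_period)
    lam = max(plateau_start / 5.0, 1.0)
    k_eff = np.minimum(its, plateau_start)
    loss = loss_base + loss_amp * np.exp(-k_eff / lam)
    fmeas = f_max - f_amp * np.exp(-k_eff / lam)
    if noise_sd > 0:
        loss = loss + rng.normal(0.0, noise_sd, size=its.shape)
        fmeas = fmeas + rng.normal(0.0, noise_sd, size=its.shape)
    return TrainingTrace(its, np.clip(loss, 0.0, None), np.clip(fmeas, 0.0, 1.0))


def generate_survival(
    n_per_group: int,
    hazard_ratio: float = 0.18,
    seed: int = 0,
    baseline_hazard: float = math.log(2) / 12.0,
    censor_time: float | None = None,
) -> list[SurvivalRecord]:
    """Exponential two-group survival records.

    Group 0 (predicted invalid) has the baseline hazard (default median
    PFS 12 months); group 1's hazard is ``hazard_ratio`` times that —
    the default 0.18 mirrors a strongly protective prediction.  With
    ``censor_time`` set, censoring times are uniform on (0,
    censor_time).
    """
    if n_per_group < 2:
        raise ValueError("need at least 2 subjects per group")
    if hazard_ratio <= 0:
        raise ValueError("hazard_ratio must be positive")
    rng = np.random.default_rng(seed)
    records = []
    for group, hz in ((0, baseline_hazard), (1, baseline_hazard * hazard_ratio)):
        times = rng.exponential(1.0 / hz, size=n_per_group)
        times = np.maximum(times, 1e-9)
        if censor_time is not None:
            cens = rng.uniform(0.0, censor_time, size=n_per_group)
            cens = np.maximum(cens, 1e-9)
            event = (times <= cens).astype(int)
            times = np.minimum(times, cens)
        else:
            event = np.ones(n_per_group, dtype=int)
        for i, (t, e) in enumerate(zip(times, event)):
            records.append(
                SurvivalRecord(
                    subject_id=f"g{group}_{i:04d}", time=float(t), event=int(e), group=group
                )
            )
    return records
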