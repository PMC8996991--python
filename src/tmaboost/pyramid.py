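"""Multiresolution image pyramids and cross-level coordinate mapping.

Whole-slide scanners store gigapixel images as a pyramid of rasters
``levels[0] .. levels[M-1]``, where level 0 is the full-magnification scan
and every subsequent level halves both dimensions.  Detection runs on a
low-magnification level, segmentation on level 0, and core-level
classification on a "medium" level chosen from the physical footprint of a
core; this module owns the data model and the three coordinate mappings
between those levels.
"""

from __future__ import annotations

import json
import math
import os
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import tifffile
from imageio.v3 import imread, imwrite

__all__ = [
    "BoundingBox",
    "PyramidImage",
    "forward_map",
    "backward_level",
    "detection_level",
    "extract_region",
    "build_pyramid",
    "downsample2x",
]


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned box ``[x, x+w) x [y, y+h)`` at a pyramid level.

    Coordinates are 0-based with the origin at the top-left corner of the
    raster, matching image conventions.
    """

    x: int
    y: int
    w: int
    h: int
    level: int = 0

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"degenerate box: w={self.w}, h={self.h}")

    @property
    def area(self) -> int:
        return self.w * self.h

    @property
    def x2(self) -> int:
        return self.x + self.w

    @property
    def y2(self) -> int:
        return self.y + self.h

    def to_dict(self) -> dict:
        return {"level": self.level, "x": self.x, "y": self.y, "w": self.w, "h": self.h}


class PyramidImage:
    """Ordered list of rasters, level 0 at highest magnification.

    Each level's dimensions must equal ``ceil(previous / 2)``; this is the
    invariant the coordinate mappings below rely on.
    """

    def __init__(self, levels: Sequence[np.ndarray]):
        if len(levels) < 1:
            raise ValueError("a pyramid needs at least one level")
        for m in range(1, len(levels)):
            prev, cur = levels[m - 1], levels[m]
            want = (math.ceil(prev.shape[0] / 2), math.ceil(prev.shape[1] / 2))
            if cur.shape[:2] != want:
                raise ValueError(
                    f"level {m} has shape {cur.shape[:2]}, expected {want} "
                    f"(ceil of level {m - 1} halved)"
                )
        self.levels = list(levels)

    @property
    def num_levels(self) -> int:
        return len(self.levels)

    def shape(self, level: int) -> tuple[int, int]:
        return self.levels[level].shape[:2]

    # ------------------------------------------------------------------ I/O
    def write(self, path: str) -> None:
        """Write as a multi-page TIFF (``.tif``/``.tiff``) or a directory of
        ``level_0.png .. level_{M-1}.png``."""
        if path.endswith((".tif", ".tiff")):
            with tifffile.TiffWriter(path) as tw:
                for lv in self.levels:
                    tw.write(lv)
        else:
            os.makedirs(path, exist_ok=True)
            for m, lv in enumerate(self.levels):
                imwrite(os.path.join(path, f"level_{m}.png"), lv)

    @classmethod
    def read(cls, path: str) -> "PyramidImage":
        if os.path.isdir(path):
            names = sorted(
                (f for f in os.listdir(path) if f.startswith("level_")),
                key=lambda f: int(f.split("_")[1].split(".")[0]),
            )
            if not names:
                raise FileNotFoundError(f"no level_*.png files under {path}")
            return cls([imread(os.path.join(path, f)) for f in names])
        with tifffile.TiffFile(path) as tf:
            return cls([p.asarray() for p in tf.pages])


def downsample2x(img: np.ndarray) -> np.ndarray:
    """Factor-2 downsample by 2x2 block averaging, odd edges padded by
    replication so the output has ceil(n/2) samples per axis."""
    h, w = img.shape[:2]
    ph, pw = h % 2, w % 2
    if ph or pw:
        pad = [(0, ph), (0, pw)] + [(0, 0)] * (img.ndim - 2)
        img = np.pad(img, pad, mode="edge")
    a = img.astype(np.float64)
    out = (a[0::2, 0::2] + a[1::2, 0::2] + a[0::2, 1::2] + a[1::2, 1::2]) / 4.0
    if np.issubdtype(np.asarray(img).dtype, np.integer):
        return np.round(out).astype(img.dtype)
    return out.astype(img.dtype)


def build_pyramid(level0: np.ndarray, num_levels: int) -> PyramidImage:
    """Build a pyramid from a full-resolution raster by repeated halving."""
    levels = [level0]
    for _ in range(num_levels - 1):
        levels.append(downsample2x(levels[-1]))
    return PyramidImage(levels)


def forward_map(box: BoundingBox, pyramid: PyramidImage | None = None) -> BoundingBox:
    """Map a box detected at level xi onto level 0.

    All four components are scaled by ``2**xi``; with a pyramid given the
    result is clipped to the level-0 bounds.
    """
    xi = box.level
    if xi < 0 or (pyramid is not None and xi >= pyramid.num_levels):
        raise ValueError(f"level {xi} outside pyramid range")
    s = 2 ** xi
    x, y, w, h = box.x * s, box.y * s, box.w * s, box.h * s
    if pyramid is not None:
        H, W = pyramid.shape(0)
        x2, y2 = min(x + w, W), min(y + h, H)
        x, y = max(x, 0), max(y, 0)
        w, h = x2 - x, y2 - y
    return BoundingBox(x, y, w, h, level=0)


def backward_level(
    w0: float, h0: float, rho: float = 3.0, num_levels: int | None = None
) -> int:
    """Medium-magnification level for a core of level-0 footprint w0 x h0.

    ``l = log2(w0 * h0 * 10**(-2*rho)) / 2`` rounded to the nearest integer
    and clamped to ``[0, num_levels - 1]``.  With the default rho = 3 a
    1000 x 1000 px core stays at level 0 and a 4000 x 4000 px core (a 2 mm
    core scanned at 20x) maps to level 2.
    """
    if w0 <= 0 or h0 <= 0:
        raise ValueError("core dimensions must be positive")
    raw = math.log2(w0 * h0 * 10 ** (-2.0 * rho)) / 2.0
    lvl = int(round(raw))
    lvl = max(lvl, 0)
    if num_levels is not None:
        lvl = min(lvl, num_levels - 1)
    return lvl


def detection_level(pyramid: PyramidImage, max_dim: int = 2048) -> int:
    """Lowest-magnification working level for core detection: the smallest
    level whose longest side still fits in ``max_dim`` pixels (top level if
    none does)."""
    for m in range(pyramid.num_levels):
        if max(pyramid.shape(m)) <= max_dim:
            return m
    return pyramid.num_levels - 1


def extract_region(
    pyr: PyramidImage, box: BoundingBox, target_level: int = 0
) -> np.ndarray:
    """Pixels of a level-0 box footprint at ``target_level``.

    The footprint is divided by ``2**target_level`` rounding outward, so the
    region always covers the full footprint.
    """
    if box.level != 0:
        raise ValueError("extract_region expects a level-0 box")
    if not 0 <= target_level < pyr.num_levels:
        raise ValueError(f"target level {target_level} out of range")
    s = 2 ** target_level
    x0, y0 = box.x // s, box.y // s
    x1 = math.ceil(box.x2 / s)
    y1 = math.ceil(box.y2 / s)
    H, W = pyr.shape(target_level)
    x0c, y0c = max(x0, 0), max(y0, 0)
    x1c, y1c = min(x1, W), min(y1, H)
    if x1c <= x0c or y1c <= y0c:
        raise ValueError("box does not intersect the image")
    return pyr.levels[target_level][y0c:y1c, x0c:x1c]


def boxes_to_json(boxes: Sequence[BoundingBox], ids: Sequence[str], path: str) -> None:
    recs = [{"core_id": i, **b.to_dict()} for i, b in zip(ids, boxes)]
    with open(path, "w") as fh:
        json.dump(recs, fh, indent=1)


def boxes_from_json(path: str) -> tuple[list[BoundingBox], list[str]]:
    with open(path) as fh:
        recs = json.load(fh)
    boxes = [BoundingBox(r["x"], r["y"], r["w"], r["h"], r["level"]) for r in recs]
    return boxes, [r["core_id"] for r in recs]
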