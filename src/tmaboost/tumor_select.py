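"""Tumor-like tile selection inside a detected core.

A high-resolution core region is cut into an M x M tile grid, each tile
is pushed through a pluggable 3-class segmenter (background / other
tissue / tumor-like), the per-pixel argmax gives a class map, non-tumor
pixels are suppressed, and only tiles whose tumor fraction clears a
threshold alpha survive into the downstream classifier.  Two reference
segmenter backends are shipped: an oracle driven by ground-truth masks
(for testing) and a color-threshold segmenter that keys on the brown DAB
chromogen for CPU end-to-end runs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Protocol

import numpy as np

BACKGROUND, OTHERS, TUMORLIKE = 0, 1, 2

__all__ = [
    "Tile",
    "SelectedTile",
    "tile_core",
    "class_map",
    "suppress_non_tumor",
    "qualify_tile",
    "select_tumor_tiles",
    "Segmenter",
    "OracleSegmenter",
    "ColorThresholdSegmenter",
]


@dataclass
class Tile:
    """One M x M patch of a core region at level 0.

    ``origin`` is the (x, y) offset of the tile within the region (add the
    core box offset for absolute slide coordinates).  Edge tiles are
    padded to the full M x M with ``pad_value``; ``valid`` masks the
    unpadded footprint.
    """

    core_id: str
    tile_index: int
    origin: tuple[int, int]
    pixels: np.ndarray
    valid: np.ndarray

    @property
    def size(self) -> int:
        return self.pixels.shape[0]


@dataclass
class SelectedTile:
    """A qualified tile after suppression: pixels with non-tumor set to the
    null value, plus the boolean tumor mask so downstream code can tell
    suppressed pixels from genuinely dark tissue."""

    tile: Tile
    kappa: np.ndarray
    tumor_mask: np.ndarray
    tumor_fraction: float


def tile_core(region: np.ndarray, M: int = 512, core_id: str = "", pad_value=0) -> list[Tile]:
    """Non-overlapping M x M grid over a region, row-major order; right and
    bottom edge tiles are padded with ``pad_value``."""
    if region.size == 0:
        raise ValueError("empty core region")
    h, w = region.shape[:2]
    tiles = []
    idx = 0
    for ty in range(0, h, M):
        for tx in range(0, w, M):
            patch = region[ty : ty + M, tx : tx + M]
            ph, pw = patch.shape[:2]
            valid = np.zeros((M, M), dtype=bool)
            valid[:ph, :pw] = True
            if (ph, pw) != (M, M):
                pad = [(0, M - ph), (0, M - pw)] + [(0, 0)] * (patch.ndim - 2)
                patch = np.pad(patch, pad, mode="constant", constant_values=pad_value)
            tiles.append(Tile(core_id, idx, (tx, ty), patch, valid))
            idx += 1
    return tiles


def class_map(p: np.ndarray, atol: float = 1e-6) -> np.ndarray:
    """Per-pixel argmax over the (H, W, 3) class-probability stack.

    Ties break toward the lowest class index (numpy argmax order).
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 3 or p.shape[2] < 2:
        raise ValueError("expected an (H, W, C) probability stack")
    sums = p.sum(axis=2)
    if np.any(p < -atol) or np.any(np.abs(sums - 1.0) > max(atol, 1e-6)):
        raise ValueError("class probabilities must be >= 0 and sum to 1 per pixel")
    return np.argmax(p, axis=2).astype(np.uint8)


def suppress_non_tumor(tile: Tile, kappa: np.ndarray, null_value=0) -> tuple[np.ndarray, np.ndarray]:
    """Zero out non-tumor pixels of a tile.

    Returns (masked pixels, tumor mask); pixels with ``kappa > OTHERS``
    (i.e. tumor-like) are kept, all others set to ``null_value``.
    Idempotent: re-suppressing a masked tile is a no-op.
    """
    if kappa.shape != tile.pixels.shape[:2]:
        raise ValueError(
            f"class map {kappa.shape} does not match tile {tile.pixels.shape[:2]}"
        )
    keep = kappa > OTHERS
    out = tile.pixels.copy()
    out[~keep] = null_value
    return out, keep


def qualify_tile(kappa: np.ndarray, alpha: float = 0.05, mode: str = "fraction",
                 valid: np.ndarray | None = None) -> bool:
    """Decide whether a tile carries enough tumor-like tissue.

    ``fraction`` mode (default): qualified iff the fraction of pixels
    labelled tumor-like strictly exceeds ``alpha``.  ``literal`` mode:
    qualified iff the mean class code ``sum(kappa)/N`` strictly exceeds
    ``alpha`` — a variant that weights class codes rather than counting
    tumor pixels, kept selectable because the two differ whenever "other
    tissue" pixels are present.
    """
    if not 0 <= alpha < 1:
        raise ValueError("alpha must lie in [0, 1)")
    if valid is not None:
        kappa = kappa[valid]
    n = kappa.size
    if n == 0:
        return False
    if mode == "fraction":
        stat = float(np.count_nonzero(kappa > OTHERS)) / n
    elif mode == "literal":
        stat = float(kappa.sum()) / n
    else:
        raise ValueError(f"unknown qualification mode {mode!r}")
    return stat > alpha


class Segmenter(Protocol):
    """Backend contract: map a tile's pixels to an (H, W, 3) probability
    stack over {background, others, tumorlike}."""

    def predict_proba(self, tile: Tile) -> np.ndarray: ...


@dataclass
class OracleSegmenter:
    """Ground-truth-driven segmenter for tests and calibration.

    ``tumor_mask`` and ``tissue_mask`` are region-sized boolean arrays
    (tile origins index into them); probabilities are one-hot.
    """

    tumor_mask: np.ndarray
    tissue_mask: np.ndarray | None = None

    def predict_proba(self, tile: Tile) -> np.ndarray:
        M = tile.size
        tx, ty = tile.origin
        p = np.zeros((M, M, 3), dtype=float)
        sub = np.zeros((M, M), dtype=bool)
        reg = self.tumor_mask[ty : ty + M, tx : tx + M]
        sub[: reg.shape[0], : reg.shape[1]] = reg
        if self.tissue_mask is not None:
            tis = np.zeros((M, M), dtype=bool)
            reg_t = self.tissue_mask[ty : ty + M, tx : tx + M]
            tis[: reg_t.shape[0], : reg_t.shape[1]] = reg_t
        else:
            tis = np.ones((M, M), dtype=bool)
        p[..., TUMORLIKE] = sub
        p[..., OTHERS] = (~sub) & tis & tile.valid
        p[..., BACKGROUND] = 1.0 - p[..., TUMORLIKE] - p[..., OTHERS]
        return p


@dataclass
class ColorThresholdSegmenter:
    """Heuristic DAB-brown segmenter.

    Background: bright, low-saturation pixels (glass).  Tumor-like:
    tissue pixels whose brown index (mean of R and G minus B) exceeds
    ``brown_threshold`` — DAB deposits absorb blue.  Everything else is
    "other tissue".  Soft probabilities come from logistic ramps around
    the two thresholds so the argmax matches the hard rules exactly.
    """

    background_luma: float = 210.0
    brown_threshold: float = 16.0
    softness: float = 8.0

    def predict_proba(self, tile: Tile) -> np.ndarray:
        px = tile.pixels.astype(float)
        if px.ndim == 2:
            px = np.stack([px] * 3, axis=-1)
        luma = px.mean(axis=2)
        brown = (px[..., 0] + px[..., 1]) / 2.0 - px[..., 2]
        s = max(self.softness, 1e-6)
        p_bg = 1.0 / (1.0 + np.exp(-(luma - self.background_luma) / s))
        p_tumor_given_tissue = 1.0 / (1.0 + np.exp(-(brown - self.brown_threshold) / s))
        p = np.empty(px.shape[:2] + (3,), dtype=float)
        p[..., BACKGROUND] = p_bg
        p[..., TUMORLIKE] = (1.0 - p_bg) * p_tumor_given_tissue
        p[..., OTHERS] = (1.0 - p_bg) * (1.0 - p_tumor_given_tissue)
        p[~tile.valid] = (1.0, 0.0, 0.0)
        return p


def select_tumor_tiles(
    core_region: np.ndarray,
    segmenter: Segmenter,
    alpha: float = 0.05,
    M: int = 512,
    mode: str = "fraction",
    core_id: str = "",
) -> list[SelectedTile]:
    """Full per-core selection: tile, segment, argmax, suppress, qualify.

    Returns the qualified tiles in tile-index order; a core with no
    tumor-like tissue yields an empty list.
    """
    out = []
    for tile in tile_core(core_region, M=M, core_id=core_id):
        try:
            proba = segmenter.predict_proba(tile)
            kappa = class_map(proba)
        except Exception as exc:  # surface which tile broke the contract
            raise RuntimeError(
                f"segmenter failed on tile_index={tile.tile_index} of core {core_id!r}"
            ) from exc
        kappa[~tile.valid] = BACKGROUND
        # padding counts as background: the qualification denominator is the
        # full M x M tile cardinality
        if not qualify_tile(kappa, alpha=alpha, mode=mode):
            continue
        masked, tumor = suppress_non_tumor(tile, kappa)
        frac = float(np.count_nonzero(kappa > OTHERS)) / kappa.size
        out.append(
            SelectedTile(
                tile=Tile(tile.core_id, tile.tile_index, tile.origin, masked, tile.valid),
                kappa=kappa,
                tumor_mask=tumor,
                tumor_fraction=frac,
            )
        )
    return out
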