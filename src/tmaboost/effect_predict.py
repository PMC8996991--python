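"""Core-level treatment-effectiveness prediction.

The qualified tumor tiles of a core are fetched at a medium pyramid
level chosen from the core's physical footprint, scored by a pluggable
probabilistic classifier (probability that the treatment was effective),
aggregated into a single core score ``beta``, and thresholded at
``delta`` (default 0.5) into the Effective / Invalid decision.

The reference classifier backend is a logistic model over color and
stain-intensity summaries of the masked tumor pixels — the intensity of
the DAB chromogen is the signal carrier — wrapped as a scikit-learn
estimator so it drops into sklearn model selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.utils.validation import check_is_fitted

from .pyramid import BoundingBox, PyramidImage, backward_level
from .tumor_select import SelectedTile

INVALID, EFFECTIVE = 0, 1

__all__ = [
    "CorePrediction",
    "MediumResTile",
    "fetch_medium_res_tiles",
    "aggregate_beta",
    "predict_core",
    "tile_features",
    "TreatmentEffectClassifier",
]


@dataclass
class CorePrediction:
    core_id: str
    beta: float
    decision: int  # 0 Invalid, 1 Effective
    n_tiles_used: int
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta {self.beta} outside [0, 1]")


@dataclass
class MediumResTile:
    """A selected tumor tile resampled to the medium-magnification level.

    ``tumor_weight`` is the per-pixel tumor coverage in [0, 1] obtained by
    block-averaging the level-0 suppression mask, so the tumor-area
    fraction is conserved across the resampling.
    """

    core_id: str
    tile_index: int
    level: int
    pixels: np.ndarray
    tumor_weight: np.ndarray

    @property
    def tumor_fraction(self) -> float:
        return float(self.tumor_weight.mean())


def _block_average(mask: np.ndarray, factor: int) -> np.ndarray:
    """Average a 2-D array over factor x factor blocks (zero-padded)."""
    if factor == 1:
        return mask.astype(float)
    h, w = mask.shape
    ph, pw = (-h) % factor, (-w) % factor
    a = np.pad(mask.astype(float), ((0, ph), (0, pw)))
    H, W = a.shape
    return a.reshape(H // factor, factor, W // factor, factor).mean(axis=(1, 3))


def fetch_medium_res_tiles(
    selected: Sequence[SelectedTile],
    pyramid: PyramidImage,
    core_box: BoundingBox,
    rho: float = 3.0,
) -> list[MediumResTile]:
    """Backward-map each selected tile to the medium level for its core.

    The level comes from the core's level-0 footprint; each tile's pixel
    footprint is fetched from that pyramid level and its tumor mask is
    block-averaged down by the same factor.
    """
    if core_box.level != 0:
        raise ValueError("core box must be at level 0")
    lvl = backward_level(core_box.w, core_box.h, rho=rho, num_levels=pyramid.num_levels)
    f = 2 ** lvl
    out = []
    H, W = pyramid.shape(lvl)
    for st in selected:
        tx, ty = st.tile.origin
        x0 = (core_box.x + tx) // f
        y0 = (core_box.y + ty) // f
        M = st.tile.size
        m = -(-M // f)  # ceil
        x0, y0 = min(max(x0, 0), max(W - m, 0)), min(max(y0, 0), max(H - m, 0))
        px = pyramid.levels[lvl][y0 : y0 + m, x0 : x0 + m]
        wmask = _block_average(st.tumor_mask, f)[: px.shape[0], : px.shape[1]]
        out.append(
            MediumResTile(
                core_id=st.tile.core_id,
                tile_index=st.tile.tile_index,
                level=lvl,
                pixels=px,
                tumor_weight=wmask,
            )
        )
    return out


def aggregate_beta(tile_probs: Sequence[float], mode: str = "mean") -> float:
    """Reduce per-tile effectiveness probabilities to the core score.

    The mean is the default (smooth and order-free); median and max are
    selectable.
    """
    probs = np.asarray(tile_probs, dtype=float)
    if probs.size == 0:
        raise ValueError("aggregate_beta needs at least one tile probability")
    if np.any((probs < 0) | (probs > 1)):
        raise ValueError("tile probabilities must lie in [0, 1]")
    if mode == "mean":
        return float(probs.mean())
    if mode == "median":
        return float(np.median(probs))
    if mode == "max":
        return float(probs.max())
    raise ValueError(f"unknown aggregation mode {mode!r}")


def predict_core(
    tiles: Sequence[MediumResTile],
    backend: "Callable[[MediumResTile], float]",
    delta: float = 0.5,
    core_id: str = "",
    agg_mode: str = "mean",
) -> CorePrediction:
    """Score a core: per-tile probabilities -> beta -> threshold at delta.

    A core with no qualified tumor tiles cannot be scored; it is reported
    Invalid with beta 0 and the ``no_tumor_tiles`` flag rather than
    failing, so whole-slide runs complete.
    """
    if not tiles:
        return CorePrediction(core_id, 0.0, INVALID, 0, flags=("no_tumor_tiles",))
    probs = []
    for t in tiles:
        p = float(backend(t))
        if not 0.0 <= p <= 1.0:
            raise ValueError(
                f"backend returned probability {p} outside [0, 1] "
                f"for tile {t.tile_index} of core {core_id!r}"
            )
        probs.append(p)
    beta = aggregate_beta(probs, mode=agg_mode)
    decision = EFFECTIVE if beta >= delta else INVALID
    return CorePrediction(core_id or tiles[0].core_id, beta, decision, len(tiles))


# ---------------------------------------------------------------- features

def tile_features(t: MediumResTile) -> np.ndarray:
    """Color / stain-intensity summary of a medium-resolution tumor tile.

    Tumor-weighted means and SDs of the RGB channels plus the brown
    (DAB) index ``(R+G)/2 - B`` and the tumor-area fraction; all-zero
    weights fall back to unweighted stats over the tile.
    """
    px = t.pixels.astype(float)
    if px.ndim == 2:
        px = np.stack([px] * 3, axis=-1)
    w = t.tumor_weight.astype(float)
    tot = w.sum()
    if tot <= 0:
        w = np.ones_like(w)
        tot = w.sum()
    flat_w = w.ravel() / tot
    chans = px.reshape(-1, px.shape[2])
    means = flat_w @ chans
    var = flat_w @ (chans - means) ** 2
    brown = (px[..., 0] + px[..., 1]) / 2.0 - px[..., 2]
    bm = float(flat_w @ brown.ravel())
    bv = float(flat_w @ (brown.ravel() - bm) ** 2)
    return np.concatenate(
        [means, np.sqrt(var), [bm, np.sqrt(bv), t.tumor_fraction]]
    )


class TreatmentEffectClassifier(BaseEstimator, ClassifierMixin):
    """Logistic tile classifier over stain-summary features.

    ``fit`` takes tiles (or precomputed feature rows) with the weak
    core-level outcome propagated to every tile of the core; ``predict``
    and ``predict_proba`` score tiles.  Use :func:`predict_core` to
    aggregate tile probabilities into the core decision.
    """

    def __init__(self, C: float = 1.0, max_iter: int = 1000):
        self.C = C
        self.max_iter = max_iter

    @staticmethod
    def _as_matrix(X) -> np.ndarray:
        if len(X) and isinstance(X[0], MediumResTile):
            return np.stack([tile_features(t) for t in X])
        return np.asarray(X, dtype=float)

    def fit(self, X, y):
        Xm = self._as_matrix(X)
        y = np.asarray(y)
        self.pipeline_ = make_pipeline(
            StandardScaler(), LogisticRegression(C=self.C, max_iter=self.max_iter)
        )
        self.pipeline_.fit(Xm, y)
        self.classes_ = self.pipeline_[-1].classes_
        self.n_features_in_ = Xm.shape[1]
        return self

    def predict_proba(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict_proba(self._as_matrix(X))

    def predict(self, X):
        check_is_fitted(self, "pipeline_")
        return self.pipeline_.predict(self._as_matrix(X))

    def tile_backend(self) -> "Callable[[MediumResTile], float]":
        """Adapter giving the per-tile probability-of-Effective callable
        that :func:`predict_core` expects."""
        check_is_fitted(self, "pipeline_")
        pos = int(np.where(self.classes_ == EFFECTIVE)[0][0])

        def _score(t: MediumResTile) -> float:
            return float(self.predict_proba([t])[0, pos])

        return _score
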