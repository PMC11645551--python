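"""Histology feature backbones.

A backbone maps each 224x224x3 tile of the rescaled H&E image to a 14x14 grid
of F-dimensional feature vectors, one per 16x16 pixel patch (i.e. one per
8x8 µm superpixel at 0.5 µm/px). Any extractor satisfying this contract can be
plugged in — pretrained pathology vision transformers in production use — and
the package ships :class:`FallbackBackbone`, a deterministic, training-free
extractor built from per-patch image statistics, so the full pipeline runs
and is testable without model downloads.
"""

from __future__ import annotations

from typing import Protocol, runtime_checkable

import numpy as np

__all__ = ["HistologyBackbone", "FallbackBackbone"]

PATCH_PX = 16
TILE_PX = 224
PATCHES_PER_SIDE = TILE_PX // PATCH_PX  # 14


@runtime_checkable
class HistologyBackbone(Protocol):
    """Contract for tile-level feature extractors.

    Attributes
    ----------
    patch_px : int
        Patch side in pixels (16).
    tile_px : int
        Tile side in pixels (224).
    feature_dim : int
        Output feature dimension F.
    """

    patch_px: int
    tile_px: int
    feature_dim: int

    def apply(self, tile: np.ndarray) -> np.ndarray:
        """Map a (224, 224, 3) tile to a (14, 14, F) feature block.

        Must be deterministic: the same tile yields bitwise-identical output.
        """
        ...


class FallbackBackbone:
    """Training-free per-patch statistics extractor with a seeded projection.

    For every 16x16 patch the extractor computes channel means and standard
    deviations plus an 8-bin histogram of grayscale gradient magnitudes (a
    crude texture signature), then expands the resulting descriptor to
    ``feature_dim`` channels through a fixed, seed-determined random linear
    map. Strictly patch-local: changing one patch changes only that patch's
    feature vector.
    """

    _N_GRAD_BINS = 8
    _DESC_DIM = 3 + 3 + _N_GRAD_BINS

    def __init__(self, feature_dim: int = 32, seed: int = 0):
        self.patch_px = PATCH_PX
        self.tile_px = TILE_PX
        self.feature_dim = int(feature_dim)
        self.seed = int(seed)
        rng = np.random.default_rng(seed)
        self.projection = rng.standard_normal(
            (self._DESC_DIM, self.feature_dim)
        ) / np.sqrt(self._DESC_DIM)
        # fixed gradient-magnitude bin edges on [0, 1]-scaled images
        self._edges = np.linspace(0.0, 0.5, self._N_GRAD_BINS + 1)
        self._edges[-1] = np.inf

    def _descriptors(self, tile: np.ndarray) -> np.ndarray:
        p = PATCHES_PER_SIDE
        # (p, 16, p, 16, 3) -> (p, p, 16, 16, 3)
        patches = tile.reshape(p, PATCH_PX, p, PATCH_PX, 3).transpose(0, 2, 1, 3, 4)
        means = patches.mean(axis=(2, 3))
        stds = patches.std(axis=(2, 3))
        gray = patches.mean(axis=4)  # (p, p, 16, 16)
        # gradients strictly inside each patch so features stay patch-local
        gx = np.abs(np.diff(gray, axis=3))
        gy = np.abs(np.diff(gray, axis=2))
        grad = np.concatenate(
            [gx.reshape(p, p, -1), gy.reshape(p, p, -1)], axis=2
        )
        idx = np.clip(
            np.searchsorted(self._edges, grad, side="right") - 1, 0, self._N_GRAD_BINS - 1
        )
        hist = np.zeros((p, p, self._N_GRAD_BINS))
        np.add.at(
            hist,
            (
                np.arange(p)[:, None, None],
                np.arange(p)[None, :, None],
                idx,
            ),
            1.0,
        )
        hist /= grad.shape[2]
        return np.concatenate([means, stds, hist], axis=2)

    def apply(self, tile: np.ndarray) -> np.ndarray:
        tile = np.asarray(tile, dtype=float)
        if tile.shape != (TILE_PX, TILE_PX, 3):
            raise ValueError(
                f"expected a ({TILE_PX}, {TILE_PX}, 3) tile, got {tile.shape}"
            )
        if tile.max() > 1.0 + 1e-9:  # accept uint8-scaled input
            tile = tile / 255.0
        return self._descriptors(tile) @ self.projection
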