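"""Multimodal feature-map construction from a histology image.

The image is rescaled to a common physical resolution (0.5 µm/px), padded so
both sides divide the 224-px tile size, and tiled. A backbone turns every tile
into 14x14 per-patch feature vectors; stacking the reassembled histology
feature map with two normalized positional channels and three 16x-average-
pooled RGB channels yields one C = F + 5 channel descriptor per 8x8 µm
superpixel. A per-superpixel tissue mask is detected from the pooled image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.transform import resize

from .backbone import PATCH_PX, TILE_PX, HistologyBackbone
from .grid import SuperpixelGrid

__all__ = [
    "PreparedImage",
    "MultimodalFeatureMap",
    "prepare_image",
    "tile_image",
    "extract_histology_features",
    "positional_feature_map",
    "rgb_feature_map",
    "tissue_mask",
    "stack_feature_maps",
    "build_feature_map",
]


@dataclass(frozen=True)
class PreparedImage:
    """RGB image rescaled to the target pixel size and padded to tile multiples.

    ``pixels`` is float in [0, 1], with shape (rows_px, cols_px, 3), both
    spatial dims divisible by the tile size. ``pad`` records (top, bottom,
    left, right) pixels added so outputs can be cropped back; ``unpadded_px``
    is the pre-padding size after rescaling.
    """

    pixels: np.ndarray
    pad: tuple[int, int, int, int]
    source_pixel_size_um: float
    pixel_size_um: float = 0.5
    unpadded_px: tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels, dtype=float)
        object.__setattr__(self, "pixels", px)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ValueError("pixels must be (rows, cols, 3) RGB")
        if px.shape[0] % TILE_PX or px.shape[1] % TILE_PX:
            raise ValueError(f"image dims {px.shape[:2]} must divide {TILE_PX}")

    @property
    def shape_px(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @property
    def n_superpixel_rows(self) -> int:
        return self.pixels.shape[0] // PATCH_PX

    @property
    def n_superpixel_cols(self) -> int:
        return self.pixels.shape[1] // PATCH_PX


@dataclass(frozen=True)
class MultimodalFeatureMap:
    """Channel-stacked per-superpixel descriptors.

    ``channels`` is (C, n_rows, n_cols) with C = F + 5; ``channel_roles`` tags
    each channel as one of hist / pos_y / pos_x / rgb_r / rgb_g / rgb_b; ``mask``
    is the per-superpixel tissue-foreground flag.
    """

    channels: np.ndarray
    channel_roles: tuple[str, ...]
    grid: SuperpixelGrid
    mask: np.ndarray

    def __post_init__(self) -> None:
        ch = np.asarray(self.channels, dtype=float)
        mask = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "channels", ch)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "channel_roles", tuple(self.channel_roles))
        if ch.ndim != 3:
            raise ValueError("channels must be (C, rows, cols)")
        if len(self.channel_roles) != ch.shape[0]:
            raise ValueError("one role per channel required")
        if ch.shape[1:] != (self.grid.n_rows, self.grid.n_cols):
            raise ValueError("channel spatial dims must match the grid")
        if mask.shape != ch.shape[1:]:
            raise ValueError("mask shape must match the grid")

    @property
    def n_channels(self) -> int:
        return self.channels.shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.channels.shape[1:]

    def by_role(self, prefix: str) -> np.ndarray:
        """Channels whose role starts with ``prefix`` (e.g. 'hist', 'rgb')."""
        idx = [i for i, r in enumerate(self.channel_roles) if r.startswith(prefix)]
        return self.channels[idx]

    def crop(self, n_rows: int, n_cols: int) -> "MultimodalFeatureMap":
        """Top-left crop, used to drop padding superpixels."""
        if n_rows > self.grid.n_rows or n_cols > self.grid.n_cols:
            raise ValueError("crop size exceeds the current grid")
        grid = SuperpixelGrid(
            n_rows=n_rows,
            n_cols=n_cols,
            superpixel_um=self.grid.superpixel_um,
            pixel_size_um=self.grid.pixel_size_um,
            origin_um=self.grid.origin_um,
        )
        return MultimodalFeatureMap(
            channels=self.channels[:, :n_rows, :n_cols],
            channel_roles=self.channel_roles,
            grid=grid,
            mask=self.mask[:n_rows, :n_cols],
        )


def prepare_image(
    image: np.ndarray,
    source_pixel_size_um: float,
    target_pixel_size_um: float = 0.5,
    tile_px: int = TILE_PX,
    pad_value: float = 0.0,
) -> PreparedImage:
    """Rescale an RGB image to the target pixel size and pad to tile multiples.

    Bilinear rescaling by ``source/target``; zero-padding (configurable value)
    is appended on the right and bottom only, and recorded so downstream maps
    can be cropped back to the tissue extent.
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB (rows, cols, 3) image, got {image.shape}")
    if source_pixel_size_um <= 0 or target_pixel_size_um <= 0:
        raise ValueError("pixel sizes must be positive")
    img = image.astype(float)
    if image.dtype == np.uint8:
        img = img / 255.0
    factor = source_pixel_size_um / target_pixel_size_um
    if abs(factor - 1.0) > 1e-12:
        out_shape = (
            int(round(img.shape[0] * factor)),
            int(round(img.shape[1] * factor)),
        )
        img = resize(
            img, out_shape, order=1, mode="edge", anti_aliasing=False,
            preserve_range=True,
        )
    h, w = img.shape[:2]
    pad_b = (-h) % tile_px
    pad_r = (-w) % tile_px
    if pad_b or pad_r:
        img = np.pad(
            img,
            ((0, pad_b), (0, pad_r), (0, 0)),
            mode="constant",
            constant_values=pad_value,
        )
    return PreparedImage(
        pixels=img,
        pad=(0, pad_b, 0, pad_r),
        source_pixel_size_um=float(source_pixel_size_um),
        pixel_size_um=float(target_pixel_size_um),
        unpadded_px=(h, w),
    )


def tile_image(img: PreparedImage, tile_px: int = TILE_PX) -> np.ndarray:
    """Partition into non-overlapping tiles: (n_ty, n_tx, tile, tile, 3)."""
    h, w = img.shape_px
    nty, ntx = h // tile_px, w // tile_px
    return (
        img.pixels.reshape(nty, tile_px, ntx, tile_px, 3).transpose(0, 2, 1, 3, 4)
    )


def extract_histology_features(
    img: PreparedImage, backbone: HistologyBackbone
) -> np.ndarray:
    """Run the backbone on every tile and assemble a seamless (F, R, C) map.

    Each 224-px tile yields a 14x14 block of feature vectors — one per 16x16
    patch, i.e. one per 8x8 µm superpixel at 0.5 µm/px.
    """
    tiles = tile_image(img, backbone.tile_px)
    nty, ntx = tiles.shape[:2]
    pps = backbone.tile_px // backbone.patch_px
    out = np.empty(
        (backbone.feature_dim, nty * pps, ntx * pps), dtype=float
    )
    for a in range(nty):
        for b in range(ntx):
            block = np.asarray(backbone.apply(tiles[a, b]))
            if block.shape != (pps, pps, backbone.feature_dim):
                raise ValueError(
                    f"backbone returned shape {block.shape}, expected "
                    f"({pps}, {pps}, {backbone.feature_dim})"
                )
            out[:, a * pps : (a + 1) * pps, b * pps : (b + 1) * pps] = (
                block.transpose(2, 0, 1)
            )
    return out


def positional_feature_map(
    n_rows: int, n_cols: int, alpha: float = 1.0
) -> np.ndarray:
    """Two normalized coordinate channels: alpha*i/n_rows and alpha*j/n_cols."""
    i = np.arange(n_rows, dtype=float)[:, None] / n_rows
    j = np.arange(n_cols, dtype=float)[None, :] / n_cols
    out = np.empty((2, n_rows, n_cols))
    out[0] = alpha * np.broadcast_to(i, (n_rows, n_cols))
    out[1] = alpha * np.broadcast_to(j, (n_rows, n_cols))
    return out


def rgb_feature_map(img: PreparedImage) -> np.ndarray:
    """Per-channel 16x16 average pooling of the image, values in [0, 1]."""
    h, w = img.shape_px
    r, c = h // PATCH_PX, w // PATCH_PX
    pooled = img.pixels.reshape(r, PATCH_PX, c, PATCH_PX, 3).mean(axis=(1, 3))
    return pooled.transpose(2, 0, 1)


def tissue_mask(
    img: PreparedImage,
    closing_size: int = 3,
    min_component_frac: float = 0.001,
) -> np.ndarray:
    """Per-superpixel tissue-foreground mask.

    Assumes stained tissue is darker than the (white) background: the pooled
    grayscale image is thresholded with Otsu's method keeping the dark class,
    closed with a ``closing_size`` square element, and connected components
    smaller than ``min_component_frac`` of the grid area are dropped. Padded
    border superpixels are forced to background.
    """
    gray = rgb_feature_map(img).mean(axis=0)
    r, c = gray.shape
    valid_r = -((-img.unpadded_px[0]) // PATCH_PX) if img.unpadded_px[0] else r
    valid_c = -((-img.unpadded_px[1]) // PATCH_PX) if img.unpadded_px[1] else c
    if gray.max() - gray.min() < 1e-9:
        warnings.warn("image is uniform; tissue mask is empty", stacklevel=2)
        return np.zeros((r, c), dtype=bool)
    thr = threshold_otsu(gray)
    mask = gray < thr
    mask = ndimage.binary_closing(
        mask, structure=np.ones((closing_size, closing_size), dtype=bool)
    )
    labels, n = ndimage.label(mask)
    if n:
        sizes = ndimage.sum_labels(mask, labels, index=np.arange(1, n + 1))
        keep = np.flatnonzero(sizes >= min_component_frac * r * c) + 1
        mask = np.isin(labels, keep)
    mask[valid_r:, :] = False
    mask[:, valid_c:] = False
    if not mask.any():
        warnings.warn("no tissue foreground detected", stacklevel=2)
    return mask


def stack_feature_maps(
    hist: np.ndarray,
    pos: np.ndarray,
    rgb: np.ndarray,
    grid: SuperpixelGrid | None = None,
    mask: np.ndarray | None = None,
    standardize_hist: bool = True,
) -> MultimodalFeatureMap:
    """Stack histology, positional and RGB maps into (C, R, C) with C = F + 5.

    Histology channels are standardized (zero mean, unit variance over masked
    superpixels) by default so the large histology block does not drown the
    five positional/RGB channels; switchable off for raw-feature fidelity.
    """
    hist = np.asarray(hist, dtype=float)
    pos = np.asarray(pos, dtype=float)
    rgb = np.asarray(rgb, dtype=float)
    if not (hist.shape[1:] == pos.shape[1:] == rgb.shape[1:]):
        raise ValueError(
            f"spatial dims differ: hist {hist.shape[1:]}, pos {pos.shape[1:]}, "
            f"rgb {rgb.shape[1:]}"
        )
    if pos.shape[0] != 2 or rgb.shape[0] != 3:
        raise ValueError("pos must have 2 channels and rgb 3")
    n_rows, n_cols = hist.shape[1:]
    if mask is None:
        mask = np.ones((n_rows, n_cols), dtype=bool)
    if standardize_hist and mask.any():
        sub = hist[:, mask]
        mu = sub.mean(axis=1)
        sd = sub.std(axis=1)
        sd[sd < 1e-12] = 1.0
        hist = (hist - mu[:, None, None]) / sd[:, None, None]
    if grid is None:
        grid = SuperpixelGrid(n_rows=n_rows, n_cols=n_cols)
    roles = (
        ("hist",) * hist.shape[0]
        + ("pos_y", "pos_x")
        + ("rgb_r", "rgb_g", "rgb_b")
    )
    return MultimodalFeatureMap(
        channels=np.concatenate([hist, pos, rgb], axis=0),
        channel_roles=roles,
        grid=grid,
        mask=np.asarray(mask, dtype=bool),
    )


def build_feature_map(
    image: np.ndarray,
    source_pixel_size_um: float,
    backbone: HistologyBackbone,
    alpha: float = 1.0,
    standardize_hist: bool = True,
    crop_to_image: bool = True,
) -> MultimodalFeatureMap:
    """End-to-end pipeline: prepare, featurize, stack and mask one image.

    With ``crop_to_image`` the map is cropped back to the superpixels covered
    by the unpadded image, aligning it with grids defined on the original
    tissue extent.
    """
    pimg = prepare_image(image, source_pixel_size_um)
    hist = extract_histology_features(pimg, backbone)
    mask = tissue_mask(pimg)
    n_rows, n_cols = hist.shape[1:]
    pos = positional_feature_map(n_rows, n_cols, alpha=alpha)
    rgb = rgb_feature_map(pimg)
    grid = SuperpixelGrid(
        n_rows=n_rows,
        n_cols=n_cols,
        superpixel_um=PATCH_PX * pimg.pixel_size_um,
        pixel_size_um=pimg.pixel_size_um,
    )
    fmap = stack_feature_maps(
        hist, pos, rgb, grid=grid, mask=mask, standardize_hist=standardize_hist
    )
    if crop_to_image:
        vr = -((-pimg.unpadded_px[0]) // PATCH_PX)
        vc = -((-pimg.unpadded_px[1]) // PATCH_PX)
        fmap = fmap.crop(vr, vc)
    return fmap
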