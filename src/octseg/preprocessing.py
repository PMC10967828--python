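"""Image conditioning for OCT B-scans.

The chain is: strip all-black margins and resize to a fixed shape →
grayscale → Gaussian smoothing (speckle variance reduction) → CLAHE
(contrast-limited adaptive histogram equalization).  Masks follow the same
geometry with nearest-neighbour resampling and are never smoothed or
equalized.

CLAHE is implemented directly (per-tile clipped 256-bin histogram
equalization with bilinear blending between tile mappings): with a single
tile and a large clip limit it reduces exactly to global histogram
equalization, which the tests pin against a brute-force oracle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from skimage.transform import resize as _sk_resize

from .exceptions import ArgumentError, DataError

BLACK_THRESHOLD = 1.0 / 255.0   # robust to 8-bit quantization noise


@dataclass(frozen=True)
class PreprocessConfig:
    target_shape: tuple = (512, 256)       # (rows, cols) = (depth, lateral)
    gaussian_sigma: float = 1.0
    clahe_clip_limit: float = 2.0
    clahe_tile_grid: tuple = (8, 8)
    border_mode: str = "reflect"

    def validate(self) -> None:
        if any(int(s) <= 0 for s in self.target_shape):
            raise ArgumentError(f"target_shape must be positive, got {self.target_shape}")
        if self.gaussian_sigma < 0:
            raise ArgumentError(f"gaussian_sigma must be >= 0, got {self.gaussian_sigma}")
        if self.clahe_clip_limit <= 0:
            raise ArgumentError(f"clahe_clip_limit must be > 0, got {self.clahe_clip_limit}")
        if any(int(t) <= 0 for t in self.clahe_tile_grid):
            raise ArgumentError(f"clahe_tile_grid must be positive, got {self.clahe_tile_grid}")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Channel-mean luminance for (H, W, C) input; identity for 2D."""
    if image.ndim == 3:
        return image.mean(axis=2)
    if image.ndim != 2:
        raise DataError(f"expected 2D or 3D image, got shape {image.shape}")
    return np.asarray(image, dtype=float)


def _black_margin_box(image: np.ndarray) -> tuple[int, int, int, int]:
    keep_rows = np.where((image >= BLACK_THRESHOLD).any(axis=1))[0]
    keep_cols = np.where((image >= BLACK_THRESHOLD).any(axis=0))[0]
    if keep_rows.size == 0 or keep_cols.size == 0:
        raise DataError("image is entirely black; nothing to crop to")
    return keep_rows[0], keep_rows[-1] + 1, keep_cols[0], keep_cols[-1] + 1


def crop_resize(image: np.ndarray, config: PreprocessConfig | None = None) -> np.ndarray:
    """Remove all-black margin rows/cols, then bilinear-resize to target_shape."""
    config = config or PreprocessConfig()
    config.validate()
    if image.size == 0:
        raise DataError("empty image")
    r0, r1, c0, c1 = _black_margin_box(image)
    crop = image[r0:r1, c0:c1]
    if crop.shape == tuple(config.target_shape):
        return crop.astype(float, copy=True)
    out = _sk_resize(crop, config.target_shape, order=1, mode="reflect",
                     anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def crop_resize_pair(image: np.ndarray, mask: np.ndarray,
                     config: PreprocessConfig | None = None):
    """Crop/resize an image with its label mask (nearest-neighbour labels)."""
    config = config or PreprocessConfig()
    config.validate()
    if image.shape != mask.shape:
        raise DataError(f"image shape {image.shape} != mask shape {mask.shape}")
    r0, r1, c0, c1 = _black_margin_box(image)
    img = crop_resize(image, config)
    mcrop = mask[r0:r1, c0:c1]
    if mcrop.shape == tuple(config.target_shape):
        return img, mcrop.copy()
    m = _sk_resize(mcrop.astype(float), config.target_shape, order=0,
                   mode="edge", anti_aliasing=False, preserve_range=True)
    return img, np.rint(m).astype(mask.dtype)


def gaussian_smooth(image: np.ndarray, sigma: float,
                    border_mode: str = "reflect") -> np.ndarray:
    if sigma < 0:
        raise ArgumentError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return np.asarray(image, dtype=float).copy()
    return gaussian_filter(np.asarray(image, dtype=float), sigma=sigma,
                           mode=border_mode)


def clahe_enhance(image: np.ndarray, clip_limit: float = 2.0,
                  tile_grid: tuple = (8, 8), nbins: int = 256) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization on a [0, 1] image.

    clip_limit is the usual multiple of the uniform histogram height at which
    per-tile histograms are clipped (excess redistributed uniformly).
    """
    if clip_limit <= 0:
        raise ArgumentError(f"clip_limit must be > 0, got {clip_limit}")
    tr, tc = int(tile_grid[0]), int(tile_grid[1])
    h, w = image.shape
    if tr > h or tc > w:
        raise ArgumentError(
            f"tile grid {tile_grid} larger than image of shape {image.shape}")
    levels = np.clip(np.rint(np.asarray(image, dtype=float) * (nbins - 1)),
                     0, nbins - 1).astype(np.int32)

    th, tw = -(-h // tr), -(-w // tc)        # ceil division
    pad_r, pad_c = tr * th - h, tc * tw - w
    lv = np.pad(levels, ((0, pad_r), (0, pad_c)), mode="reflect")

    tiles = lv.reshape(tr, th, tc, tw).transpose(0, 2, 1, 3).reshape(tr, tc, th * tw)
    npix = th * tw
    luts = np.empty((tr, tc, nbins))
    clip = max(clip_limit * npix / nbins, 1.0)
    for i in range(tr):
        for j in range(tc):
            hist = np.bincount(tiles[i, j], minlength=nbins).astype(float)
            excess = np.maximum(hist - clip, 0.0).sum()
            hist = np.minimum(hist, clip) + excess / nbins
            luts[i, j] = np.cumsum(hist) / npix * (nbins - 1)

    # bilinear interpolation between the four surrounding tile mappings
    rows = np.arange(h, dtype=float)
    cols = np.arange(w, dtype=float)
    fy = rows / th - 0.5
    fx = cols / tw - 0.5
    i0 = np.clip(np.floor(fy).astype(int), 0, tr - 1)
    i1 = np.clip(i0 + 1, 0, tr - 1)
    ay = np.clip(fy - np.floor(fy), 0.0, 1.0)
    ay[fy < 0] = 0.0
    ay[fy > tr - 1] = 0.0
    j0 = np.clip(np.floor(fx).astype(int), 0, tc - 1)
    j1 = np.clip(j0 + 1, 0, tc - 1)
    ax = np.clip(fx - np.floor(fx), 0.0, 1.0)
    ax[fx < 0] = 0.0
    ax[fx > tc - 1] = 0.0

    i0g = i0[:, None]
    i1g = i1[:, None]
    j0g = j0[None, :]
    j1g = j1[None, :]
    v = levels[:h, :w]
    out = ((1 - ay)[:, None] * (1 - ax)[None, :] * luts[i0g, j0g, v]
           + (1 - ay)[:, None] * ax[None, :] * luts[i0g, j1g, v]
           + ay[:, None] * (1 - ax)[None, :] * luts[i1g, j0g, v]
           + ay[:, None] * ax[None, :] * luts[i1g, j1g, v])
    return np.clip(out / (nbins - 1), 0.0, 1.0)


def preprocess_pipeline(image: np.ndarray,
                        config: PreprocessConfig | None = None) -> np.ndarray:
    """Grayscale -> crop/resize -> Gaussian smoothing -> CLAHE."""
    config = config or PreprocessConfig()
    config.validate()
    gray = to_grayscale(image)
    out = crop_resize(gray, config)
    out = gaussian_smooth(out, config.gaussian_sigma, config.border_mode)
    return clahe_enhance(out, config.clahe_clip_limit, config.clahe_tile_grid)
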