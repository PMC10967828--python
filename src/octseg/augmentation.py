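"""The nine-transform augmentation set.

Two geometric transforms (vertical/horizontal flip) are applied to image and
mask alike; the seven photometric transforms (random snow, CLAHE, blur,
invert, coarse dropout, downscale, equalize) alter the image only and return
the mask untouched.  Expanding a dataset keeps each original and adds its
nine variants, a x10 expansion.

Parameter defaults follow the Albumentations dialect for these transform
names (snow threshold/brightness, blur limit 3-7, 8 dropout holes of 8x8
filled with 0, downscale factor 0.25, CLAHE clip 1-4 on an 8x8 grid),
adapted to single-channel float images; all are overridable per transform.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import uniform_filter, zoom

from .exceptions import ArgumentError, DataError
from .preprocessing import clahe_enhance

TRANSFORM_NAMES = (
    "vertical_flip", "horizontal_flip", "random_snow", "clahe", "blur",
    "invert", "coarse_dropout", "downscale", "equalize",
)
GEOMETRIC_TRANSFORMS = frozenset({"vertical_flip", "horizontal_flip"})


@dataclass(frozen=True)
class AugmentationSet:
    transforms: tuple = TRANSFORM_NAMES
    params: dict = field(default_factory=dict)
    seed: int = 0

    def validate(self) -> None:
        if sorted(self.transforms) != sorted(TRANSFORM_NAMES):
            raise ArgumentError(
                "AugmentationSet must contain exactly the nine transforms "
                f"{TRANSFORM_NAMES}, got {self.transforms}")


# ---------------------------------------------------------------------------
# individual transforms: (image, mask, rng, params) -> (image, mask)
# ---------------------------------------------------------------------------

def _vertical_flip(img, mask, rng, p):
    return np.flip(img, axis=0).copy(), np.flip(mask, axis=0).copy()


def _horizontal_flip(img, mask, rng, p):
    return np.flip(img, axis=1).copy(), np.flip(mask, axis=1).copy()


def _random_snow(img, mask, rng, p):
    lo, hi = p.get("snow_point", (0.1, 0.3))
    coeff = p.get("brightness_coeff", 2.5)
    snow_point = rng.uniform(lo, hi)
    thresh = snow_point * 0.5 + 85.0 / 255.0
    out = np.where(img < thresh, img * coeff, img)
    return np.clip(out, 0.0, 1.0), mask


def _clahe(img, mask, rng, p):
    lo, hi = p.get("clip_limit", (1.0, 4.0))
    grid = p.get("tile_grid", (8, 8))
    clip = rng.uniform(lo, hi)
    return clahe_enhance(img, clip_limit=clip, tile_grid=grid), mask


def _blur(img, mask, rng, p):
    lo, hi = p.get("blur_limit", (3, 7))
    k = int(rng.integers(lo // 2, hi // 2 + 1)) * 2 + 1   # odd in [lo, hi]
    return uniform_filter(img, size=k, mode="reflect"), mask


def _invert(img, mask, rng, p):
    return 1.0 - img, mask


def _coarse_dropout(img, mask, rng, p):
    n_holes = p.get("max_holes", 8)
    hh = p.get("max_height", 8)
    hw = p.get("max_width", 8)
    fill = p.get("fill_value", 0.0)
    out = img.copy()
    h, w = img.shape
    for _ in range(n_holes):
        r = int(rng.integers(0, max(h - hh, 1)))
        c = int(rng.integers(0, max(w - hw, 1)))
        out[r:r + hh, c:c + hw] = fill
    return out, mask


def _downscale(img, mask, rng, p):
    scale = p.get("scale", 0.25)
    h, w = img.shape
    small = zoom(img, scale, order=0)
    back = zoom(small, (h / small.shape[0], w / small.shape[1]), order=0)
    return np.clip(back[:h, :w], 0.0, 1.0), mask


def _equalize(img, mask, rng, p):
    nbins = p.get("nbins", 256)
    levels = np.clip(np.rint(img * (nbins - 1)), 0, nbins - 1).astype(np.int32)
    hist = np.bincount(levels.ravel(), minlength=nbins).astype(float)
    cdf = np.cumsum(hist) / levels.size
    return cdf[levels], mask


_REGISTRY = {
    "vertical_flip": _vertical_flip,
    "horizontal_flip": _horizontal_flip,
    "random_snow": _random_snow,
    "clahe": _clahe,
    "blur": _blur,
    "invert": _invert,
    "coarse_dropout": _coarse_dropout,
    "downscale": _downscale,
    "equalize": _equalize,
}


def apply_transform(name: str, image: np.ndarray, mask: np.ndarray,
                    seed: int = 0, params: dict | None = None):
    """Apply one named transform; stochastic choices are deterministic in seed."""
    if name not in _REGISTRY:
        raise ArgumentError(f"unknown transform {name!r}; valid: {TRANSFORM_NAMES}")
    if image.shape != mask.shape:
        raise DataError(f"image shape {image.shape} != mask shape {mask.shape}")
    rng = np.random.default_rng(
        np.random.SeedSequence([int(seed), TRANSFORM_NAMES.index(name)]))
    img, msk = _REGISTRY[name](np.asarray(image, dtype=float), mask, rng,
                               (params or {}).get(name, params or {}))
    return img, msk


def expand_dataset(pairs: list, augset: AugmentationSet | None = None):
    """x10 expansion: each original pair plus its nine transformed variants.

    Returns ``(expanded_pairs, provenance)`` where provenance[i] is
    ``(source_index, transform_name)`` with ``"original"`` for the retained
    inputs.
    """
    augset = augset or AugmentationSet()
    augset.validate()
    if not pairs:
        raise DataError("expand_dataset needs a non-empty input list")
    out, provenance = [], []
    for i, (img, msk) in enumerate(pairs):
        if img.shape != msk.shape:
            raise DataError(f"pair {i}: image shape {img.shape} != mask shape {msk.shape}")
        out.append((np.asarray(img, dtype=float), msk))
        provenance.append((i, "original"))
        for name in augset.transforms:
            seed = np.random.SeedSequence(
                [int(augset.seed), i, TRANSFORM_NAMES.index(name)]).generate_state(1)[0]
            aug = apply_transform(name, img, msk, seed=int(seed) % (2 ** 31),
                                  params=augset.params)
            out.append(aug)
            provenance.append((i, name))
    return out, provenance
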