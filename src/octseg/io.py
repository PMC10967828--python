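"""Dataset readers/writers: 8-bit grayscale PNG/TIFF images, indexed-PNG
label masks with a fixed 5-entry palette, JSON manifests."""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .exceptions import DataError

#: Fixed palette for mask classes 0-4 (background/dark through bright).
MASK_PALETTE = [
    (0, 0, 0),
    (60, 80, 200),
    (60, 200, 80),
    (230, 170, 40),
    (200, 200, 200),
]

IMAGE_SUFFIXES = (".png", ".tif", ".tiff")


@dataclass(frozen=True)
class DatasetLayout:
    images_dir: Path
    masks_dir: Path
    manifest: Path | None = None
    n_classes: int = 5


def save_image(image: np.ndarray, path) -> None:
    """Write a [0, 1] float image as 8-bit grayscale PNG."""
    arr = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    Image.fromarray(np.rint(arr * 255).astype(np.uint8), mode="L").save(path)


def load_image(path) -> np.ndarray:
    """Read PNG/TIFF as float in [0, 1]; multi-channel stays (H, W, C)."""
    with Image.open(path) as im:
        arr = np.asarray(im)
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    return np.clip(arr.astype(float), 0.0, 1.0)


def save_mask(mask: np.ndarray, path) -> None:
    """Write an integer label mask as indexed PNG with the fixed palette."""
    mask = np.asarray(mask)
    im = Image.fromarray(mask.astype(np.uint8), mode="P")
    palette = []
    for rgb in MASK_PALETTE:
        palette.extend(rgb)
    palette.extend([0] * (768 - len(palette)))
    im.putpalette(palette)
    im.save(path)


def load_mask(path, n_classes: int = 5) -> np.ndarray:
    with Image.open(path) as im:
        if im.mode not in ("P", "L", "I", "I;16"):
            raise DataError(f"{path}: mask must be indexed or grayscale PNG, "
                            f"got mode {im.mode}")
        arr = np.asarray(im).astype(np.int64)
    if arr.min() < 0 or arr.max() >= n_classes:
        raise DataError(f"{path}: mask labels outside [0, {n_classes})")
    return arr.astype(np.uint8)


def save_dataset(pairs: list, out_dir, manifest: dict | None = None) -> None:
    """Write pairs as images/NNNN.png + masks/NNNN.png plus manifest.json."""
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    for i, (img, msk) in enumerate(pairs):
        save_image(img, out / "images" / f"{i:04d}.png")
        save_mask(msk, out / "masks" / f"{i:04d}.png")
    if manifest is not None:
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)


def load_dataset(layout: DatasetLayout) -> list:
    """Load (image, mask) pairs in deterministic lexicographic stem order."""
    images_dir = Path(layout.images_dir)
    masks_dir = Path(layout.masks_dir)
    if not images_dir.is_dir():
        raise DataError(f"images directory not found: {images_dir}")
    if not masks_dir.is_dir():
        raise DataError(f"masks directory not found: {masks_dir}")
    image_files = sorted(p for p in images_dir.iterdir()
                         if p.suffix.lower() in IMAGE_SUFFIXES)
    mask_files = {p.stem: p for p in masks_dir.iterdir()
                  if p.suffix.lower() == ".png"}
    if not image_files:
        raise DataError(f"no images found in {images_dir}")
    pairs = []
    for img_path in image_files:
        if img_path.stem not in mask_files:
            raise DataError(f"image without mask: {img_path}")
        img = load_image(img_path)
        msk = load_mask(mask_files[img_path.stem], layout.n_classes)
        if img.shape[:2] != msk.shape:
            raise DataError(
                f"dimension mismatch between {img_path} {img.shape[:2]} and "
                f"its mask {msk.shape}")
        pairs.append((img, msk))
    orphan_masks = set(mask_files) - {p.stem for p in image_files}
    if orphan_masks:
        raise DataError(f"masks without images: {sorted(orphan_masks)[:5]}")
    return pairs
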