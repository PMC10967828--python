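"""Synthetic OCT-like B-scans with layered ground truth.

Real macular OCT B-scans show a stack of tissue bands of differing
reflectivity separated by smooth, non-crossing boundaries, corrupted by
multiplicative speckle.  This module generates images with exactly that
structure — five ordered regions by default (vitreous above the ILM, inner
retina down to IPL/INL, outer retina down to the RPE, the thin RPE–BM
complex, and the choroid under BM) — so the whole segmentation pipeline can
be exercised without any dataset download.

Every image/mask pair is a pure function of ``(config.seed, index)``.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import gaussian_filter1d

from .exceptions import ArgumentError, ConfigurationError

#: Default mean reflectivity per class, dark vitreous -> bright inner retina
#: -> medium outer retina -> hyperreflective RPE complex -> dim choroid.
DEFAULT_BAND_INTENSITIES = (0.05, 0.65, 0.45, 0.85, 0.25)

CLASS_NAMES = ("Above ILM", "ILM-IPL/INL", "IPL/INL-RPE", "RPE-BM", "Under BM")


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the layered-phantom generator.

    boundary_rows optionally pins the column-averaged depth of each of the
    ``n_classes - 1`` boundaries (useful for exactly reproducible fixtures);
    when None the depths are drawn per image.
    """

    height: int = 128
    width: int = 64
    n_classes: int = 5
    boundary_smoothness: float = 4.0
    band_intensities: tuple = DEFAULT_BAND_INTENSITIES
    speckle_sigma: float = 0.10
    fluid_probability: float = 0.2
    seed: int = 0
    boundary_rows: tuple | None = None

    def validate(self) -> None:
        if self.n_classes < 2:
            raise ConfigurationError(f"n_classes must be >= 2, got {self.n_classes}")
        if self.height < 16 or self.width < 16:
            raise ConfigurationError(
                f"height and width must be >= 16, got {(self.height, self.width)}")
        if len(self.band_intensities) != self.n_classes:
            raise ConfigurationError(
                f"band_intensities needs {self.n_classes} entries, "
                f"got {len(self.band_intensities)}")
        if any(not (0.0 <= v <= 1.0) for v in self.band_intensities):
            raise ConfigurationError("band_intensities entries must lie in [0, 1]")
        if self.speckle_sigma < 0:
            raise ConfigurationError(f"speckle_sigma must be >= 0, got {self.speckle_sigma}")
        if self.boundary_smoothness < 0:
            raise ConfigurationError(
                f"boundary_smoothness must be >= 0, got {self.boundary_smoothness}")
        if not (0.0 <= self.fluid_probability <= 1.0):
            raise ConfigurationError(
                f"fluid_probability must lie in [0, 1], got {self.fluid_probability}")
        if self.boundary_rows is not None and len(self.boundary_rows) != self.n_classes - 1:
            raise ConfigurationError(
                f"boundary_rows needs {self.n_classes - 1} entries, "
                f"got {len(self.boundary_rows)}")


def _boundaries(cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """(n_classes-1, width) float boundary depths, strictly increasing per column."""
    nb = cfg.n_classes - 1
    if cfg.boundary_rows is not None:
        base = np.asarray(cfg.boundary_rows, dtype=float)
    else:
        # cumulative positive gaps scaled into the canvas, margins ~10%
        gaps = rng.uniform(0.5, 1.5, size=nb + 1)
        frac = np.cumsum(gaps)[:-1] / gaps.sum()
        base = cfg.height * (0.1 + 0.8 * frac)
    curves = np.repeat(base[:, None], cfg.width, axis=1)
    if cfg.boundary_smoothness > 0:
        noise = rng.normal(0.0, 1.0, size=(nb, cfg.width))
        noise = gaussian_filter1d(noise, sigma=max(cfg.width / 16.0, 1.0),
                                  axis=1, mode="reflect")
        sd = noise.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        curves = curves + cfg.boundary_smoothness * noise / sd
    # clamp into the canvas and enforce strict ordering down each column
    curves = np.clip(curves, 1, cfg.height - nb)
    for i in range(1, nb):
        curves[i] = np.maximum(curves[i], curves[i - 1] + 1.0)
    return curves


def _rng_for(cfg: SyntheticConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(cfg.seed), int(index)]))


def generate_bscan(config: SyntheticConfig, index: int = 0):
    """Generate one (image, mask) pair, deterministic in (config.seed, index).

    Returns ``(image, mask)`` where image is float64 in [0, 1] and mask is
    uint8 with values in {0, ..., n_classes-1}; shape (height, width), axis 0
    is depth.
    """
    config.validate()
    rng = _rng_for(config, index)
    curves = _boundaries(config, rng)

    rows = np.arange(config.height, dtype=float)[:, None]
    mask = (rows >= curves[:, None, :]).sum(axis=0).astype(np.uint8)

    intensities = np.asarray(config.band_intensities, dtype=float)
    image = intensities[mask]

    if config.fluid_probability > 0 and rng.random() < config.fluid_probability:
        # dark elliptical pocket inside the retina; an intensity anomaly only,
        # the labels keep the enclosing band's class
        cy = rng.uniform(curves[0].mean(), curves[-1].mean())
        cx = rng.uniform(0.2 * config.width, 0.8 * config.width)
        ry = rng.uniform(0.03, 0.10) * config.height
        rx = rng.uniform(0.05, 0.20) * config.width
        yy = np.arange(config.height)[:, None]
        xx = np.arange(config.width)[None, :]
        inside = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
        image = np.where(inside, image * 0.25, image)

    if config.speckle_sigma > 0:
        speckle = rng.normal(0.0, config.speckle_sigma, size=image.shape)
        image = image * (1.0 + speckle)

    return np.clip(image, 0.0, 1.0), mask


def generate_dataset(config: SyntheticConfig, n: int):
    """Generate ``n`` pairs plus a manifest sufficient to regenerate them."""
    if n < 1:
        raise ArgumentError(f"n must be >= 1, got {n}")
    config.validate()
    pairs = [generate_bscan(config, i) for i in range(n)]
    manifest = {
        "config": _config_dict(config),
        "items": [{"index": i, "seed": int(config.seed)} for i in range(n)],
    }
    return pairs, manifest


def dataset_from_manifest(manifest: dict):
    """Regenerate the exact dataset a manifest describes."""
    cfg = config_from_dict(manifest["config"])
    return [generate_bscan(cfg, item["index"]) for item in manifest["items"]]


def _config_dict(config: SyntheticConfig) -> dict:
    d = asdict(config)
    d["band_intensities"] = list(config.band_intensities)
    if config.boundary_rows is not None:
        d["boundary_rows"] = list(config.boundary_rows)
    return d


def config_from_dict(d: dict) -> SyntheticConfig:
    d = dict(d)
    d["band_intensities"] = tuple(d["band_intensities"])
    if d.get("boundary_rows") is not None:
        d["boundary_rows"] = tuple(d["boundary_rows"])
    return SyntheticConfig(**d)
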