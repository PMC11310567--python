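"""Photometric and geometric augmentation operators.

The policy mirrors common detection-training augmentation: multiplicative
brightness in [0.8, 1.8], mean-anchored contrast in [0.6, 1.8],
luminance-anchored saturation in [0.8, 1.4], rotation in [-90, 90] degrees and
a vertical flip with probability 0.4.  Operators are deterministic; a seeded
sampler draws per-image parameter specs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import rotate as _sk_rotate


@dataclass(frozen=True)
class AugmentationConfig:
    brightness_range: tuple[float, float] = (0.8, 1.8)
    contrast_range: tuple[float, float] = (0.6, 1.8)
    saturation_range: tuple[float, float] = (0.8, 1.4)
    rotation_range_deg: tuple[float, float] = (-90.0, 90.0)
    vflip_prob: float = 0.4
    rng_seed: int = 0

    def validate(self) -> None:
        for name in ("brightness_range", "contrast_range", "saturation_range",
                     "rotation_range_deg"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} empty: {(lo, hi)}")
        if not 0.0 <= self.vflip_prob <= 1.0:
            raise ValueError("vflip_prob must be in [0, 1]")


@dataclass(frozen=True)
class AugmentationSpec:
    brightness_factor: float
    contrast_factor: float
    saturation_factor: float
    rotation_deg: float
    vflip: bool


def _luma(rgb: np.ndarray) -> np.ndarray:
    return 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]


def _finish(arr: np.ndarray) -> np.ndarray:
    return np.clip(np.round(arr), 0, 255).astype(np.uint8)


def adjust_brightness(image: np.ndarray, factor: float) -> np.ndarray:
    """v -> clip(round(v * factor)); factor 1 is a no-op."""
    if factor <= 0:
        raise ValueError("brightness factor must be positive")
    if factor == 1.0:
        return np.array(image, dtype=np.uint8)
    return _finish(np.asarray(image, float) * factor)


def adjust_contrast(image: np.ndarray, factor: float) -> np.ndarray:
    """v -> clip(round(mu + factor*(v - mu))), mu = image mean luminance."""
    if factor <= 0:
        raise ValueError("contrast factor must be positive")
    if factor == 1.0:
        return np.array(image, dtype=np.uint8)
    arr = np.asarray(image, float)
    mu = float(_luma(arr).mean())
    return _finish(mu + factor * (arr - mu))


def adjust_saturation(image: np.ndarray, factor: float) -> np.ndarray:
    """Per-pixel blend with the BT.601 luminance; factor 0 gives greyscale."""
    if factor < 0:
        raise ValueError("saturation factor must be non-negative")
    if factor == 1.0:
        return np.array(image, dtype=np.uint8)
    arr = np.asarray(image, float)
    y = _luma(arr)[..., None]
    return _finish(y + factor * (arr - y))


def rotate(image: np.ndarray, mask: np.ndarray, angle_deg: float,
           fill_color: tuple[int, int, int] = (0, 0, 0),
           ) -> tuple[np.ndarray, np.ndarray]:
    """Rotate about the canvas center; positive angle is counter-clockwise.

    The canvas keeps its size; pixels rotated in from outside are filled with
    ``fill_color`` (the crop's background variant).  Image uses bilinear,
    mask nearest-neighbor so it stays binary.
    """
    if not -180.0 <= angle_deg <= 180.0:
        raise ValueError("angle must be within [-180, 180] degrees")
    if angle_deg == 0.0:
        return np.array(image, dtype=np.uint8), np.asarray(mask, bool).copy()
    if angle_deg in (90.0, 180.0, -90.0, -180.0) and image.shape[0] == image.shape[1]:
        k = int(angle_deg // 90) % 4
        return (np.rot90(np.asarray(image, np.uint8), k).copy(),
                np.rot90(np.asarray(mask, bool), k).copy())
    arr = np.asarray(image, float)
    out = np.empty_like(arr)
    for c in range(3):
        out[..., c] = _sk_rotate(arr[..., c], angle_deg, resize=False, order=1,
                                 cval=float(fill_color[c]), preserve_range=True)
    rot_mask = _sk_rotate(np.asarray(mask, float), angle_deg, resize=False,
                          order=0, cval=0.0, preserve_range=True) > 0.5
    return _finish(out), rot_mask


def vflip(image: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Reverse row order of both rasters (an involution)."""
    return (np.asarray(image)[::-1].copy(),
            np.asarray(mask)[::-1].copy())


def sample_spec(config: AugmentationConfig, draw_index: int) -> AugmentationSpec:
    """Deterministic per-draw spec from the stream (rng_seed, draw_index)."""
    config.validate()
    rng = np.random.default_rng(
        np.random.SeedSequence([config.rng_seed & 0x7FFFFFFF, draw_index]))
    return AugmentationSpec(
        brightness_factor=float(rng.uniform(*config.brightness_range)),
        contrast_factor=float(rng.uniform(*config.contrast_range)),
        saturation_factor=float(rng.uniform(*config.saturation_range)),
        rotation_deg=float(rng.uniform(*config.rotation_range_deg)),
        vflip=bool(rng.random() < config.vflip_prob),
    )


def apply_spec(image: np.ndarray, mask: np.ndarray, spec: AugmentationSpec,
               fill_color: tuple[int, int, int] = (0, 0, 0),
               ) -> tuple[np.ndarray, np.ndarray]:
    """Apply one sampled spec: photometric ops, then rotation, then flip."""
    out = adjust_brightness(image, spec.brightness_factor)
    out = adjust_contrast(out, spec.contrast_factor)
    out = adjust_saturation(out, spec.saturation_factor)
    out, m = rotate(out, mask, spec.rotation_deg, fill_color)
    if spec.vflip:
        out, m = vflip(out, m)
    return out, m
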