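"""Scene preprocessing: YUV background separation and per-seed crops.

Seeds photographed on a blue background are separated in YUV space: the U
(blue - luma) channel is strongly positive on the background and near zero or
negative on the brown/cream seeds, so thresholding U (Otsu by default)
recovers the seed foreground.  Connected components become individual seeds,
each standardized to a 170 x 170 crop on a selectable background (black, blue
or white) for the detector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu
from skimage.measure import label, regionprops
from skimage.transform import resize

BACKGROUND_VARIANTS = ("black", "blue", "white")
CROP_SIZE = 170


class NoSeedsFoundError(RuntimeError):
    pass


@dataclass
class SeedCrop:
    """A single seed standardized to 170x170 pixels."""

    image: np.ndarray       # uint8 RGB, CROP_SIZE x CROP_SIZE
    seed_mask: np.ndarray   # bool, same shape
    source_bbox: tuple[int, int, int, int]  # (x, y, w, h) in scene coords
    background_variant: str
    scale_factor: float     # scene pixels per crop pixel

    def __post_init__(self):
        assert self.image.shape[:2] == (CROP_SIZE, CROP_SIZE)
        assert self.scale_factor > 0


def rgb_to_yuv(image: np.ndarray) -> np.ndarray:
    """BT.601 RGB -> YUV, unquantized floats.

    Y = 0.299 R + 0.587 G + 0.114 B; U = 0.492 (B - Y); V = 0.877 (R - Y).
    """
    rgb = np.asarray(image, dtype=float)
    y = 0.299 * rgb[..., 0] + 0.587 * rgb[..., 1] + 0.114 * rgb[..., 2]
    u = 0.492 * (rgb[..., 2] - y)
    v = 0.877 * (rgb[..., 0] - y)
    return np.stack([y, u, v], axis=-1)


def segment_foreground(image: np.ndarray, u_threshold: float | None = None,
                       min_area_px: int = 32,
                       permissive: bool = False) -> np.ndarray:
    """Seed foreground mask: pixels whose U falls below ``u_threshold``.

    The threshold defaults to Otsu's method on the U channel (the background
    is bluer, i.e. higher U, than any seed pixel).  Holes are filled and
    components below ``min_area_px`` removed.  An empty result raises
    :class:`NoSeedsFoundError` unless ``permissive``.
    """
    u = rgb_to_yuv(image)[..., 1]
    if u_threshold is None:
        # Otsu gives the optimal split bin; refine to the midpoint of the two
        # class means so the cut falls between the clusters rather than on a
        # histogram-bin center inside one of them
        t0 = float(threshold_otsu(u))
        lo, hi = u[u < t0], u[u >= t0]
        if lo.size and hi.size:
            u_threshold = float((lo.mean() + hi.mean()) / 2.0)
        else:
            u_threshold = t0
    fg = u < u_threshold
    if fg.any():
        fg = ndimage.binary_fill_holes(fg)
        lab, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=int))
        if n:
            counts = np.bincount(lab.ravel())
            keep = np.flatnonzero(counts >= min_area_px)
            keep = keep[keep != 0]
            fg = np.isin(lab, keep)
    if not fg.any() and not permissive:
        raise NoSeedsFoundError(
            f"no foreground components >= {min_area_px} px below U threshold "
            f"{u_threshold:.2f}")
    return fg


def extract_seed_instances(image: np.ndarray, fg: np.ndarray,
                           min_area_px: int = 32,
                           ) -> list[tuple[np.ndarray, tuple[int, int, int, int]]]:
    """8-connected components of the foreground, ordered by (bbox y, then x).

    Returns one (mask, tight bbox) pair per seed; components smaller than
    ``min_area_px`` are dropped.  Coordinates are 0-based half-open (x, y, w, h).
    """
    lab = label(fg, connectivity=2)
    out = []
    for region in regionprops(lab):
        if region.area < min_area_px:
            continue
        y0, x0, y1, x1 = region.bbox
        mask = lab == region.label
        out.append((mask, (int(x0), int(y0), int(x1 - x0), int(y1 - y0))))
    out.sort(key=lambda t: (t[1][1], t[1][0]))
    return out


def standardize_crop(image: np.ndarray, seed_mask: np.ndarray,
                     bbox: tuple[int, int, int, int],
                     background_variant: str = "blue",
                     background_color: tuple[int, int, int] = (30, 60, 160),
                     margin: float = 0.05) -> SeedCrop:
    """Extract one seed as a 170x170 crop on a uniform background.

    The bbox is expanded by ``margin`` (fraction of its size, clipped to the
    scene), non-seed pixels are replaced by the variant color (black, the
    configured blue, or white), the crop is padded to a square preserving
    aspect ratio, and resized with bilinear interpolation (nearest for the
    mask).  ``scale_factor`` records scene pixels per crop pixel.
    """
    if background_variant not in BACKGROUND_VARIANTS:
        raise ValueError(f"unknown background variant {background_variant!r}")
    x, y, w, h = bbox
    if w <= 0 or h <= 0:
        raise ValueError(f"degenerate bbox {bbox}")
    H, W = image.shape[:2]
    mx, my = int(round(w * margin)), int(round(h * margin))
    x0, y0 = max(x - mx, 0), max(y - my, 0)
    x1, y1 = min(x + w + mx, W), min(y + h + my, H)

    color = {"black": (0, 0, 0), "white": (255, 255, 255),
             "blue": tuple(background_color)}[background_variant]
    sub_img = np.array(image[y0:y1, x0:x1], dtype=np.uint8)
    sub_mask = np.asarray(seed_mask[y0:y1, x0:x1], dtype=bool)
    sub_img[~sub_mask] = color

    side = max(sub_img.shape[:2])
    sq = np.empty((side, side, 3), dtype=np.uint8)
    sq[:] = color
    sqm = np.zeros((side, side), dtype=bool)
    oy = (side - sub_img.shape[0]) // 2
    ox = (side - sub_img.shape[1]) // 2
    sq[oy:oy + sub_img.shape[0], ox:ox + sub_img.shape[1]] = sub_img
    sqm[oy:oy + sub_img.shape[0], ox:ox + sub_img.shape[1]] = sub_mask

    if side == CROP_SIZE:
        out_img, out_mask = sq, sqm
    else:
        out_img = resize(sq, (CROP_SIZE, CROP_SIZE), order=1,
                         preserve_range=True, anti_aliasing=False)
        out_img = np.clip(np.round(out_img), 0, 255).astype(np.uint8)
        out_mask = resize(sqm.astype(float), (CROP_SIZE, CROP_SIZE), order=0,
                          preserve_range=True, anti_aliasing=False) > 0.5
        # keep the variant background exact outside the seed
        out_img[~out_mask] = color
    return SeedCrop(image=out_img, seed_mask=out_mask,
                    source_bbox=(x0, y0, x1 - x0, y1 - y0),
                    background_variant=background_variant,
                    scale_factor=side / CROP_SIZE)


def crops_from_scene(image: np.ndarray, background_variant: str = "blue",
                     background_color: tuple[int, int, int] = (30, 60, 160),
                     min_area_px: int = 32) -> list[SeedCrop]:
    """Full preprocessing of one scene: segment, split into seeds, standardize."""
    fg = segment_foreground(image, min_area_px=min_area_px, permissive=True)
    return [standardize_crop(image, m, b, background_variant, background_color)
            for m, b in extract_seed_instances(image, fg, min_area_px)]
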