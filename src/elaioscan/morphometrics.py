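"""Seed morphometrics: the 10 per-seed traits and their per-line statistics.

Traits follow the conventions of standard particle-analysis tools:

- area: pixel count x s^2, s = mm per pixel (1 when unscaled)
- perimeter: length of the outer boundary polygon (pixel-corner trace,
  Douglas-Peucker simplified at 2.0 px to remove rasterization staircase;
  exact for axis-aligned rectangles, near-unbiased and rotation-stable on
  smooth shapes)
- major/minor axis: full axis lengths of the ellipse with the same second
  central moments as the mask
- aspect ratio: major / minor
- circularity: 4 pi area / perimeter^2 (1 for a disk)
- roundness: 4 area / (pi major^2)
- solidity: area / convex hull area
- elaiosome area and elaiosome area % of seed area

Per-line summaries average ~100 seeds of one germplasm line; descriptive
statistics over lines report mean, max, min and the n-1 standard deviation.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from shapely.geometry import Polygon
from skimage.measure import label, regionprops

from .coco_io import mask_to_polygon

PERIMETER_SIMPLIFY_PX = 2.0

TRAIT_NAMES = ("area", "perimeter", "major_axis", "minor_axis", "aspect_ratio",
               "circularity", "roundness", "solidity", "elaiosome_area",
               "elaiosome_area_pct")


@dataclass(frozen=True)
class TraitRecord:
    area: float
    perimeter: float
    major_axis: float
    minor_axis: float
    aspect_ratio: float
    circularity: float
    roundness: float
    solidity: float
    elaiosome_area: float
    elaiosome_area_pct: float


@dataclass(frozen=True)
class LineSummary:
    line_id: str
    n_seeds: int
    means: dict  # trait -> mean


def fit_ellipse(mask: np.ndarray) -> tuple[float, float, float]:
    """Equivalent-moment ellipse of a mask.

    Returns (major, minor, orientation_deg): full axis lengths of the ellipse
    with the same normalized second central moments, orientation in degrees
    counter-clockwise from the x axis.
    """
    mask = np.asarray(mask, bool)
    if mask.sum() < 5:
        raise ValueError("mask too small for ellipse fit (< 5 px)")
    lab = (mask).astype(np.uint8)
    props = regionprops(lab)[0]
    major = float(props.axis_major_length)
    minor = float(props.axis_minor_length)
    if minor <= 0:
        raise ValueError("degenerate (collinear) mask")
    # regionprops orientation: angle of major axis vs row axis; convert
    orient = float(np.degrees(props.orientation))
    return major, minor, orient


def outer_perimeter(mask: np.ndarray,
                    simplify_px: float = PERIMETER_SIMPLIFY_PX) -> float:
    """Length of the simplified outer boundary polygon, in pixels."""
    rings = mask_to_polygon(mask)
    outer = max(rings, key=len)
    poly = Polygon(np.asarray(outer, float).reshape(-1, 2))
    if simplify_px > 0:
        poly = poly.simplify(simplify_px)
    return float(poly.length)


def seed_traits(seed_mask: np.ndarray, elaiosome_mask: np.ndarray | None,
                mm_per_px: float | None = None) -> TraitRecord:
    """Compute the 10-trait record for one seed.

    ``elaiosome_mask`` may be None (no detection: elaiosome traits are 0);
    pixels outside the seed are clipped off the elaiosome with a warning.
    Lengths scale by ``mm_per_px`` and areas by its square when given.
    """
    seed_mask = np.asarray(seed_mask, bool)
    if not seed_mask.any():
        raise ValueError("empty seed mask")
    s = 1.0 if mm_per_px is None else float(mm_per_px)
    if s <= 0:
        raise ValueError("mm_per_px must be positive")

    npx = int(seed_mask.sum())
    area = npx * s * s
    perim = outer_perimeter(seed_mask) * s
    major, minor, _ = fit_ellipse(seed_mask)
    major *= s
    minor *= s

    props = regionprops(seed_mask.astype(np.uint8))[0]
    solidity = float(props.solidity)

    if elaiosome_mask is None:
        elai_px = 0
    else:
        elai = np.asarray(elaiosome_mask, bool)
        if elai.shape != seed_mask.shape:
            raise ValueError("elaiosome/seed mask shapes differ")
        outside = elai & ~seed_mask
        if outside.any():
            import warnings
            warnings.warn(
                f"elaiosome mask has {int(outside.sum())} px outside the "
                "seed; clipping", stacklevel=2)
        elai_px = int((elai & seed_mask).sum())
    elai_area = elai_px * s * s

    return TraitRecord(
        area=area,
        perimeter=perim,
        major_axis=major,
        minor_axis=minor,
        aspect_ratio=major / minor,
        circularity=4.0 * np.pi * area / perim ** 2,
        roundness=4.0 * area / (np.pi * major ** 2),
        solidity=solidity,
        elaiosome_area=elai_area,
        elaiosome_area_pct=100.0 * elai_area / area,
    )


def line_summary(records: list[TraitRecord], line_id: str) -> LineSummary:
    """Unweighted per-trait mean over the seeds of one line."""
    if not records:
        raise ValueError("no trait records for line")
    df = pd.DataFrame([asdict(r) for r in records])
    return LineSummary(line_id=line_id, n_seeds=len(records),
                       means={t: float(df[t].mean()) for t in TRAIT_NAMES})


def descriptive_stats(summaries: list[LineSummary]) -> pd.DataFrame:
    """Average / Max. / Min. / Stdev. of per-line means, one trait per column.

    The standard deviation uses the n-1 denominator over lines, so at least
    two lines are required.
    """
    if not summaries:
        raise ValueError("no line summaries")
    if len(summaries) < 2:
        raise ValueError("descriptive Stdev. needs at least 2 lines")
    df = pd.DataFrame([s.means for s in summaries], columns=list(TRAIT_NAMES))
    return pd.DataFrame({
        "Average": df.mean(),
        "Max.": df.max(),
        "Min.": df.min(),
        "Stdev.": df.std(ddof=1),
    }).T


def records_to_frame(records: list[TraitRecord], **extra) -> pd.DataFrame:
    """One row per seed; extra keyword columns (line, seed index) prepended."""
    df = pd.DataFrame([asdict(r) for r in records])
    for k, v in reversed(list(extra.items())):
        df.insert(0, k, v)
    return df
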