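"""Detector contract and the trainable color-model baseline.

The self-training loop only requires a detector exposing ``fit`` (labeled
crops in, parameters out) and ``predict`` (crop in, scored detections out).
A deep instance-segmentation network can plug in behind this contract; the
included baseline is a two-class Gaussian color model in YUV space over
seed-interior pixels, followed by morphological cleanup.  It is weak enough
to benefit from more training data and strong enough to beat raw color
thresholding on striped seeds, which is exactly what the protocol needs.

External deep models can also exchange detections offline: one JSON line per
crop with fields {"crop": str, "bbox": [x, y, w, h], "score": float,
"segmentation": [[x1, y1, ...]]}, i.e. COCO-with-scores per line.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.morphology import disk

from .preprocess import SeedCrop, rgb_to_yuv


@dataclass
class Detection:
    bbox: tuple[float, float, float, float]
    mask: np.ndarray            # bool, crop-sized
    score: float
    category_id: int = 1


@dataclass
class ColorModelParams:
    """Gaussian class-conditional color model in YUV.

    One mean/covariance per class (elaiosome vs non-elaiosome seed interior),
    class priors, and the morphology settings used at prediction time.
    """

    mean: dict = field(default_factory=dict)       # class -> (3,) array
    cov: dict = field(default_factory=dict)        # class -> (3,3) array
    prior: dict = field(default_factory=dict)      # class -> float
    opening_radius: int = 7
    min_component_px: int = 24
    score_threshold: float = 0.5

    CLASSES = ("elaiosome", "coat")

    def to_json(self, path) -> None:
        doc = {
            "mean": {k: v.tolist() for k, v in self.mean.items()},
            "cov": {k: v.tolist() for k, v in self.cov.items()},
            "prior": self.prior,
            "opening_radius": self.opening_radius,
            "min_component_px": self.min_component_px,
            "score_threshold": self.score_threshold,
        }
        Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1))

    @classmethod
    def from_json(cls, path) -> "ColorModelParams":
        doc = json.loads(Path(path).read_text())
        return cls(
            mean={k: np.asarray(v, float) for k, v in doc["mean"].items()},
            cov={k: np.asarray(v, float) for k, v in doc["cov"].items()},
            prior=doc["prior"],
            opening_radius=doc["opening_radius"],
            min_component_px=doc["min_component_px"],
            score_threshold=doc["score_threshold"],
        )


class InsufficientLabelsError(ValueError):
    pass


def fit(crops: list[tuple[SeedCrop, np.ndarray]],
        opening_radius: int = 2, min_component_px: int = 24,
        score_threshold: float = 0.5) -> ColorModelParams:
    """Maximum-likelihood Gaussian per class over seed-interior pixels.

    ``crops`` pairs each seed crop with its elaiosome label mask; background
    pixels are excluded, coat = seed interior minus elaiosome.  Priors are the
    class pixel frequencies; covariances are regularized with eps*I where eps
    is 1e-3 of the mean variance.  Fewer than 10 pixels in either class raises
    :class:`InsufficientLabelsError`.
    """
    if not crops:
        raise InsufficientLabelsError("no labeled crops")
    buckets = {"elaiosome": [], "coat": []}
    for crop, elai_mask in crops:
        yuv = rgb_to_yuv(crop.image)
        elai = np.asarray(elai_mask, bool) & crop.seed_mask
        coat = crop.seed_mask & ~elai
        buckets["elaiosome"].append(yuv[elai])
        buckets["coat"].append(yuv[coat])

    params = ColorModelParams(opening_radius=opening_radius,
                              min_component_px=min_component_px,
                              score_threshold=score_threshold)
    counts = {}
    for cls, chunks in buckets.items():
        px = np.concatenate(chunks, axis=0) if chunks else np.empty((0, 3))
        if px.shape[0] < 10:
            raise InsufficientLabelsError(
                f"insufficient labeled pixels for class {cls!r}: {px.shape[0]}")
        mu = px.mean(axis=0)
        cov = np.cov(px.T, bias=True)
        eps = 1e-3 * float(np.trace(cov)) / 3.0
        params.mean[cls] = mu
        params.cov[cls] = cov + max(eps, 1e-9) * np.eye(3)
        counts[cls] = px.shape[0]
    total = sum(counts.values())
    params.prior = {cls: counts[cls] / total for cls in counts}
    return params


def _log_gauss(px: np.ndarray, mu: np.ndarray, cov: np.ndarray) -> np.ndarray:
    sign, logdet = np.linalg.slogdet(cov)
    inv = np.linalg.inv(cov)
    d = px - mu
    return -0.5 * (np.einsum("ij,jk,ik->i", d, inv, d) + logdet
                   + 3 * np.log(2 * np.pi))


def posterior_elaiosome(params: ColorModelParams, crop: SeedCrop) -> np.ndarray:
    """Per-pixel P(elaiosome | color) over the seed interior (0 elsewhere)."""
    yuv = rgb_to_yuv(crop.image)
    interior = crop.seed_mask
    px = yuv[interior]
    if px.shape[0] == 0:
        return np.zeros(crop.seed_mask.shape)
    ll = np.stack([
        _log_gauss(px, params.mean[c], params.cov[c])
        + np.log(max(params.prior[c], 1e-12))
        for c in params.CLASSES
    ])
    ll -= ll.max(axis=0, keepdims=True)
    w = np.exp(ll)
    post = np.zeros(crop.seed_mask.shape)
    post[interior] = w[0] / w.sum(axis=0)
    return post


def _bounded_reconstruct(marker: np.ndarray, cand: np.ndarray,
                         radius: int) -> np.ndarray:
    """Grow ``marker`` by dilation restricted to ``cand`` until stable.

    Growth is additionally bounded to within ``radius`` pixels of the marker,
    so the boundary ring eroded by a prior opening is recovered while a long
    thin structure (a coat stripe touching the lobe through a few blend
    pixels) cannot be re-entered.
    """
    if radius > 0:
        cand = cand & ndimage.binary_dilation(marker, structure=disk(radius))
    struct = np.ones((3, 3), bool)
    m = marker
    while True:
        grown = ndimage.binary_dilation(m, structure=struct) & cand
        if (grown == m).all():
            return m
        m = grown


def predict(params: ColorModelParams, crop: SeedCrop) -> list[Detection]:
    """At most one elaiosome detection per crop.

    Posterior threshold at 0.5, morphological opening (removes thin stripe
    responses), keep the largest surviving connected component of at least
    ``min_component_px`` pixels, then reconstruct it within the thresholded
    candidate region, bounded by the opening radius, so the lobe boundary
    eroded by the opening is recovered without re-absorbing stripes.  The
    score is the mean posterior over the kept pixels.
    """
    post = posterior_elaiosome(params, crop)
    cand = post > 0.5
    opened = cand
    if params.opening_radius > 0:
        opened = ndimage.binary_opening(cand, structure=disk(params.opening_radius))
    if not opened.any():
        return []
    lab, n = ndimage.label(opened, structure=np.ones((3, 3), int))
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    best = int(sizes.argmax())
    if sizes[best] < params.min_component_px:
        return []
    mask = _bounded_reconstruct(lab == best, cand, params.opening_radius)
    ys, xs = np.nonzero(mask)
    x0, y0 = float(xs.min()), float(ys.min())
    bbox = (x0, y0, float(xs.max()) + 1 - x0, float(ys.max()) + 1 - y0)
    score = float(post[mask].mean())
    return [Detection(bbox=bbox, mask=mask, score=score)]
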