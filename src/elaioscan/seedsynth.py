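"""Synthetic seed-scene generator.

Emulates top-down photographs of milk-thistle seeds spread on a uniform blue
background without contact: each seed is an ellipse-like dark blob carrying a
cream elaiosome lobe at one apex, and (with some probability) a thin bright
coat stripe whose color is deliberately close to the elaiosome color.  The
stripe is the confounder that defeats pure color thresholding, which is the
failure mode the detection pipeline exists to overcome.

Every scene comes with exact per-seed ground truth (seed mask, elaiosome mask,
tight bounding box), so downstream segmentation, training and evaluation can
be tested without any real image.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_PALETTE = {
    "background": (30, 60, 160),   # saturated blue, B channel dominant
    "coat": (72, 46, 26),          # dark brown seed coat
    "stripe": (235, 222, 186),     # bright cream, deliberately near elaiosome
    "elaiosome": (224, 208, 168),  # cream elaiosome lobe
}


class PlacementError(RuntimeError):
    """Raised when seeds cannot be placed without contact (scene too dense)."""


@dataclass(frozen=True)
class SceneParams:
    """Parameters of one synthetic seed scene.

    Lengths are pixels; color triples are 8-bit RGB.  ``elaiosome_fraction_range``
    is the target elaiosome area as a fraction of total seed area, matching the
    per-seed "elaiosome area %" trait (divided by 100).
    """

    image_width_px: int = 1024
    image_height_px: int = 1024
    n_seeds: int = 100
    seed_major_px_range: tuple[float, float] = (42.0, 62.0)
    seed_minor_px_range: tuple[float, float] = (20.0, 30.0)
    elaiosome_fraction_range: tuple[float, float] = (0.06, 0.14)
    stripe_prob: float = 0.7
    palette: dict = field(default_factory=lambda: dict(DEFAULT_PALETTE))
    noise_sigma: float = 4.0
    rng_seed: int = 0

    def validate(self) -> None:
        if self.image_width_px <= 0 or self.image_height_px <= 0:
            raise ValueError("image dimensions must be positive")
        if self.n_seeds < 0:
            raise ValueError("n_seeds must be non-negative")
        for name in ("seed_major_px_range", "seed_minor_px_range",
                     "elaiosome_fraction_range"):
            lo, hi = getattr(self, name)
            if not lo <= hi:
                raise ValueError(f"{name} is empty: {(lo, hi)}")
        if not (self.seed_minor_px_range[1] <= self.seed_major_px_range[1]):
            raise ValueError("minor axis range must not exceed major axis range")
        lo, hi = self.elaiosome_fraction_range
        if not (0.0 < lo and hi < 0.3):
            raise ValueError("elaiosome_fraction_range must lie inside (0, 0.3)")
        if not 0.0 <= self.stripe_prob <= 1.0:
            raise ValueError("stripe_prob must be in [0, 1]")
        colors = [tuple(self.palette[k]) for k in
                  ("background", "coat", "stripe", "elaiosome")]
        if len(set(colors)) != 4:
            raise ValueError("palette colors must be distinct")
        r, g, b = self.palette["background"]
        if not (b > r and b > g):
            raise ValueError("background blue channel must be strictly dominant")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be non-negative")


@dataclass
class SeedTruth:
    """Ground truth for one placed seed (scene coordinates)."""

    seed_mask: np.ndarray        # bool, full scene shape
    elaiosome_mask: np.ndarray   # bool, subset of seed_mask
    bbox: tuple[int, int, int, int]  # (x, y, w, h), 0-based, half-open
    true_elaiosome_fraction: float
    true_major_px: float
    true_minor_px: float
    has_stripe: bool


@dataclass
class SceneTruth:
    seeds: list[SeedTruth]

    def __len__(self) -> int:
        return len(self.seeds)

    def union_seed_mask(self, shape: tuple[int, int] | None = None) -> np.ndarray:
        if not self.seeds:
            if shape is None:
                raise ValueError("shape required for empty truth")
            return np.zeros(shape, dtype=bool)
        out = np.zeros_like(self.seeds[0].seed_mask)
        for s in self.seeds:
            out |= s.seed_mask
        return out


def _tight_bbox(mask: np.ndarray) -> tuple[int, int, int, int]:
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("empty mask has no bounding box")
    x0, x1 = int(xs.min()), int(xs.max()) + 1
    y0, y1 = int(ys.min()), int(ys.max()) + 1
    return (x0, y0, x1 - x0, y1 - y0)


def _seed_blob(rng: np.random.Generator, a: float, b: float,
               theta: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Rasterize one perturbed ellipse in a local patch.

    Returns (patch mask, local x grid, local y grid) where the grids are the
    seed-frame coordinates of every patch pixel (used for lobe/stripe drawing).
    The boundary is an ellipse whose polar radius is modulated by a two-term
    Fourier series with relative amplitudes <= 8%, giving a convex-hull
    deficit so solidity < 1 like real seeds.
    """
    amp2 = rng.uniform(0.01, 0.05)
    amp3 = rng.uniform(0.01, 0.03)
    ph2, ph3 = rng.uniform(0, 2 * np.pi, size=2)

    pad = int(np.ceil(a * 1.15)) + 2
    yy, xx = np.mgrid[-pad:pad + 1, -pad:pad + 1].astype(float)
    # rotate scene coords into the seed frame
    c, s = np.cos(theta), np.sin(theta)
    u = c * xx + s * yy
    v = -s * xx + c * yy
    phi = np.arctan2(v / b, u / a)  # elliptical anomaly
    r_ell = np.hypot(a * np.cos(phi), b * np.sin(phi))
    mod = 1.0 + amp2 * np.cos(2 * phi + ph2) + amp3 * np.cos(3 * phi + ph3)
    inside = np.hypot(u, v) <= r_ell * mod
    return inside, u, v


def _elaiosome_lobe(seed: np.ndarray, u: np.ndarray, v: np.ndarray,
                    a: float, b: float, target_fraction: float) -> np.ndarray:
    """Half-ellipse lobe capping the +u apex, area tuned by bisection.

    The lobe is the intersection of the seed with an ellipse of semi-axes
    (L, 0.75 b) centered at the apex; the captured seed area grows
    monotonically with L, so bisection on L converges to the target fraction
    up to discretization.
    """
    seed_area = int(seed.sum())
    target = target_fraction * seed_area
    wb = 0.75 * b

    def lobe(L: float) -> np.ndarray:
        du = (u - a) / max(L, 1e-6)
        dv = v / wb
        return seed & (du * du + dv * dv <= 1.0)

    lo, hi = 0.05 * a, 2.2 * a
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if lobe(mid).sum() < target:
            lo = mid
        else:
            hi = mid
    return lobe(0.5 * (lo + hi))


def _stripe_band(rng: np.random.Generator, seed: np.ndarray,
                 u: np.ndarray, v: np.ndarray, a: float, b: float,
                 elaiosome: np.ndarray) -> np.ndarray:
    """Thin curved band along the coat: a quadratic Bezier spine dilated to a
    2-4 px width, restricted to coat pixels (never the elaiosome)."""
    side = rng.choice([-1.0, 1.0])
    # spine from mid-body toward the non-elaiosome apex, bowed sideways
    p0 = np.array([-0.85 * a, side * 0.15 * b])
    p1 = np.array([rng.uniform(-0.3, 0.2) * a, side * rng.uniform(0.5, 0.85) * b])
    p2 = np.array([rng.uniform(0.45, 0.7) * a, side * rng.uniform(0.0, 0.4) * b])
    t = np.linspace(0.0, 1.0, 160)[:, None]
    spine = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t ** 2 * p2

    width = rng.uniform(2.0, 4.0)
    pts = np.stack([u.ravel(), v.ravel()], axis=1)
    # min distance from every patch pixel to the sampled spine
    d2 = np.min(
        (pts[:, None, 0] - spine[None, :, 0]) ** 2
        + (pts[:, None, 1] - spine[None, :, 1]) ** 2,
        axis=1,
    )
    band = (d2 <= (width / 2.0) ** 2).reshape(u.shape)
    return band & seed & ~elaiosome


def generate_scene(params: SceneParams) -> tuple[np.ndarray, SceneTruth]:
    """Generate one labeled scene.

    Seeds are placed by rejection sampling with a minimum 2 px gap between
    masks (dilated-overlap test); after 200 * n_seeds failed placements a
    :class:`PlacementError` names the density limit.  Gaussian pixel noise is
    applied last and clipped to [0, 255].

    Returns the RGB uint8 image and the per-seed :class:`SceneTruth`.
    """
    params.validate()
    rng = np.random.default_rng(np.random.SeedSequence([params.rng_seed & 0x7FFFFFFF]))
    H, W = params.image_height_px, params.image_width_px
    img = np.empty((H, W, 3), dtype=float)
    img[:] = params.palette["background"]

    occupied = np.zeros((H, W), dtype=bool)  # union of seeds dilated by the gap
    seeds: list[SeedTruth] = []
    attempts_left = max(200 * params.n_seeds, 200)

    while len(seeds) < params.n_seeds:
        if attempts_left <= 0:
            raise PlacementError(
                f"could not place {params.n_seeds} seeds of major axis up to "
                f"{params.seed_major_px_range[1]:.0f} px in a {W}x{H} scene "
                f"with a 2 px gap; reduce n_seeds or seed size"
            )
        attempts_left -= 1

        a = rng.uniform(*params.seed_major_px_range) / 2.0
        b = rng.uniform(*params.seed_minor_px_range) / 2.0
        b = min(b, a)
        theta = rng.uniform(0, np.pi)
        patch, u, v = _seed_blob(rng, a, b, theta)
        ph = patch.shape[0]
        pad = ph // 2
        cx = rng.integers(pad, W - pad) if W > 2 * pad else None
        cy = rng.integers(pad, H - pad) if H > 2 * pad else None
        if cx is None or cy is None:
            raise PlacementError("scene smaller than a single seed patch")

        ys, xs = slice(cy - pad, cy + pad + 1), slice(cx - pad, cx + pad + 1)
        # 2 px gap: test the patch dilated by 2 px against occupancy
        from scipy.ndimage import binary_dilation
        grown = binary_dilation(patch, iterations=2)
        if (occupied[ys, xs] & grown).any():
            continue

        frac = rng.uniform(*params.elaiosome_fraction_range)
        elai = _elaiosome_lobe(patch, u, v, a, b, frac)
        has_stripe = bool(rng.random() < params.stripe_prob)
        stripe = (_stripe_band(rng, patch, u, v, a, b, elai)
                  if has_stripe else np.zeros_like(patch))

        occupied[ys, xs] |= grown
        coat = patch & ~elai & ~stripe
        region = img[ys, xs]
        region[coat] = params.palette["coat"]
        region[elai] = params.palette["elaiosome"]
        if has_stripe:
            jitter = rng.uniform(-5, 5, size=3)
            region[stripe] = np.clip(np.asarray(params.palette["stripe"], float)
                                     + jitter, 0, 255)

        seed_mask = np.zeros((H, W), dtype=bool)
        seed_mask[ys, xs] = patch
        elai_mask = np.zeros((H, W), dtype=bool)
        elai_mask[ys, xs] = elai
        seeds.append(SeedTruth(
            seed_mask=seed_mask,
            elaiosome_mask=elai_mask,
            bbox=_tight_bbox(seed_mask),
            true_elaiosome_fraction=float(elai.sum() / patch.sum()),
            true_major_px=2 * a,
            true_minor_px=2 * b,
            has_stripe=has_stripe,
        ))

    if params.noise_sigma > 0:
        img = img + rng.normal(0.0, params.noise_sigma, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)
    # seeds are sorted like downstream instance extraction: bbox y, then x
    seeds.sort(key=lambda s: (s.bbox[1], s.bbox[0]))
    return img, SceneTruth(seeds=seeds)


def naive_elaiosome_threshold(image: np.ndarray, palette: dict) -> np.ndarray:
    """Pure color thresholding for the elaiosome: nearest-palette classification.

    Each pixel is assigned to the nearest of the background, coat and elaiosome
    palette colors (squared RGB distance); the predicted elaiosome mask is the
    set of pixels nearest the elaiosome color.  On scenes with a coat stripe
    this picks up the stripe as well — the classic failure of color-only
    segmentation that motivates the learned detector.
    """
    classes = np.asarray(
        [palette["background"], palette["coat"], palette["elaiosome"]], float)
    d = ((image[..., None, :].astype(float) - classes) ** 2).sum(axis=-1)
    return d.argmin(axis=-1) == 2


def generate_dataset(n_scenes: int, params: SceneParams,
                     out_dir=None) -> tuple[list[np.ndarray], "object"]:
    """Generate ``n_scenes`` scenes and a COCO dataset of elaiosome annotations.

    Scene ``i`` uses an RNG stream derived from ``(rng_seed, i)`` so scenes are
    order-independent.  The dataset holds one "elaiosome" category and one
    annotation per seed (elaiosome polygon + tight elaiosome bbox).  When
    ``out_dir`` is given, scenes are written there as PNG alongside
    ``instances.json``.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    from . import coco_io

    images, truths = [], []
    for i in range(n_scenes):
        import dataclasses
        derived = int(np.random.SeedSequence(
            [params.rng_seed & 0x7FFFFFFF, i]).generate_state(1)[0] & 0x7FFFFFFF)
        p_i = dataclasses.replace(params, rng_seed=derived)
        img, truth = generate_scene(p_i)
        images.append(img)
        truths.append(truth)

    dataset = coco_io.dataset_from_truths(
        truths, widths=[im.shape[1] for im in images],
        heights=[im.shape[0] for im in images])

    if out_dir is not None:
        import pathlib
        from PIL import Image
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, im in enumerate(images):
            Image.fromarray(im).save(out / f"scene_{i:04d}.png")
        coco_io.write_coco(dataset, out / "instances.json")
    return images, dataset
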