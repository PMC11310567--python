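"""COCO-format annotation handling.

Reads and writes single-category ("elaiosome") instance annotations as COCO
JSON, converts binary masks to pixel-corner polygons and back, and performs
the image-level 8:1:1 train/validation/test split.

Polygons are traced on pixel edges (vertices at integer pixel corners), so a
filled rectangle round-trips exactly; rasterization uses even-odd scanline
fill.  Uncompressed COCO run-length encodings are accepted on read.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

ELAIOSOME_CATEGORY = {"id": 1, "name": "elaiosome"}


@dataclass
class InstanceAnnotation:
    id: int
    image_id: int
    category_id: int
    bbox: tuple[float, float, float, float]  # (x, y, w, h), 0-based
    segmentation: list[list[float]]          # list of flat [x1,y1,x2,y2,...]
    area: float                              # rasterized mask pixel count
    score: float | None = None               # predictions only


@dataclass
class CocoDataset:
    images: list[dict] = field(default_factory=list)
    annotations: list[InstanceAnnotation] = field(default_factory=list)
    categories: list[dict] = field(default_factory=lambda: [dict(ELAIOSOME_CATEGORY)])

    def image_ids(self) -> list[int]:
        return [im["id"] for im in self.images]

    def annotations_for(self, image_id: int) -> list[InstanceAnnotation]:
        return [a for a in self.annotations if a.image_id == image_id]

    def validate(self) -> None:
        ids = [im["id"] for im in self.images]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate image ids")
        ann_ids = [a.id for a in self.annotations]
        if len(set(ann_ids)) != len(ann_ids):
            raise ValueError("duplicate annotation ids")
        known = set(ids)
        for a in self.annotations:
            if a.image_id not in known:
                raise ValueError(
                    f"annotation {a.id} references unknown image {a.image_id}")


# ---------------------------------------------------------------------------
# mask <-> polygon
# ---------------------------------------------------------------------------

# outgoing directed boundary edges per exposed side, consistent orientation
_SIDES = (
    ((-1, 0), (0, 0), (1, 0)),   # top exposed:    (x, y)   -> (x+1, y)
    ((0, 1), (1, 0), (1, 1)),    # right exposed:  (x+1, y) -> (x+1, y+1)
    ((1, 0), (1, 1), (0, 1)),    # bottom exposed: (x+1, y+1) -> (x, y+1)
    ((0, -1), (0, 1), (0, 0)),   # left exposed:   (x, y+1) -> (x, y)
)


def mask_to_polygon(mask: np.ndarray) -> list[list[float]]:
    """Trace the boundary of ``mask`` as closed pixel-corner polygons.

    Returns COCO-style flat coordinate lists, one per closed contour (outer
    boundaries and holes alike; even-odd fill reconstructs the mask).
    Consecutive collinear vertices are merged, so a filled ``h x w`` rectangle
    yields a single 4-vertex polygon.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("cannot trace an empty mask")
    H, W = mask.shape
    padded = np.zeros((H + 2, W + 2), dtype=bool)
    padded[1:-1, 1:-1] = mask

    edges: dict[tuple[int, int], list[tuple[int, int]]] = {}

    def add(p, q):
        edges.setdefault(p, []).append(q)

    ys, xs = np.nonzero(mask)
    for i, j in zip(ys.tolist(), xs.tolist()):
        if not padded[i, j + 1]:          # top neighbor off
            add((j, i), (j + 1, i))
        if not padded[i + 1, j + 2]:      # right
            add((j + 1, i), (j + 1, i + 1))
        if not padded[i + 2, j + 1]:      # bottom
            add((j + 1, i + 1), (j, i + 1))
        if not padded[i + 1, j]:          # left
            add((j, i + 1), (j, i))

    polygons: list[list[float]] = []
    while edges:
        start = min(edges)  # deterministic loop order
        ring = [start]
        cur = start
        prev_dir = None
        while True:
            outs = edges[cur]
            if len(outs) == 1 or prev_dir is None:
                nxt = outs[0]
            else:
                # checkerboard corner: prefer the sharpest right turn so the
                # trace hugs the component it entered on
                dx, dy = prev_dir
                right = (-dy, dx)
                pref = sorted(
                    outs,
                    key=lambda q: (
                        0 if (q[0] - cur[0], q[1] - cur[1]) == right else 1,
                        q,
                    ),
                )
                nxt = pref[0]
            outs.remove(nxt)
            if not outs:
                del edges[cur]
            prev_dir = (nxt[0] - cur[0], nxt[1] - cur[1])
            cur = nxt
            if cur == start:
                break
            ring.append(cur)
        # merge collinear runs
        out = []
        n = len(ring)
        for k in range(n):
            p0, p1, p2 = ring[k - 1], ring[k], ring[(k + 1) % n]
            if (p1[0] - p0[0]) * (p2[1] - p1[1]) != (p1[1] - p0[1]) * (p2[0] - p1[0]):
                out.append(p1)
        flat: list[float] = []
        for x, y in out:
            flat.extend((float(x), float(y)))
        polygons.append(flat)
    return polygons


def polygon_to_mask(polygons: list[list[float]], height: int, width: int) -> np.ndarray:
    """Rasterize polygons with even-odd scanline fill.

    A pixel (row i, col j) is inside when its center (j+0.5, i+0.5) is covered
    an odd number of times by the union of rings; exact for the pixel-corner
    polygons :func:`mask_to_polygon` produces.
    """
    mask = np.zeros((height, width), dtype=bool)
    segs = []
    for flat in polygons:
        pts = np.asarray(flat, dtype=float).reshape(-1, 2)
        if len(pts) < 3:
            continue
        nxt = np.roll(pts, -1, axis=0)
        segs.append(np.hstack([pts, nxt]))
    if not segs:
        return mask
    e = np.vstack(segs)  # columns: x1 y1 x2 y2
    x1, y1, x2, y2 = e[:, 0], e[:, 1], e[:, 2], e[:, 3]
    for i in range(height):
        yc = i + 0.5
        hit = ((y1 <= yc) & (yc < y2)) | ((y2 <= yc) & (yc < y1))
        if not hit.any():
            continue
        xc = x1[hit] + (yc - y1[hit]) * (x2[hit] - x1[hit]) / (y2[hit] - y1[hit])
        xc.sort()
        for a, b in zip(xc[0::2], xc[1::2]):
            j0 = max(int(np.ceil(a - 0.5)), 0)
            j1 = min(int(np.floor(b - 0.5)), width - 1)
            if j1 >= j0:
                mask[i, j0:j1 + 1] ^= True
    return mask


def _decode_rle(rle: dict) -> np.ndarray:
    """Decode an uncompressed COCO RLE (column-major run lengths)."""
    h, w = rle["size"]
    counts = rle["counts"]
    flat = np.zeros(h * w, dtype=bool)
    pos, val = 0, False
    for c in counts:
        if val:
            flat[pos:pos + c] = True
        pos += c
        val = not val
    return flat.reshape((w, h)).T


def segmentation_to_mask(segmentation, height: int, width: int) -> np.ndarray:
    if isinstance(segmentation, dict):
        return _decode_rle(segmentation)
    return polygon_to_mask(segmentation, height, width)


def annotation_from_mask(mask: np.ndarray, ann_id: int, image_id: int,
                         category_id: int = 1,
                         score: float | None = None) -> InstanceAnnotation:
    """Build an annotation (polygon, tight bbox, pixel area) from a mask."""
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        raise ValueError("cannot annotate an empty mask")
    x0, y0 = float(xs.min()), float(ys.min())
    bbox = (x0, y0, float(xs.max()) + 1 - x0, float(ys.max()) + 1 - y0)
    return InstanceAnnotation(
        id=ann_id, image_id=image_id, category_id=category_id,
        bbox=bbox, segmentation=mask_to_polygon(mask),
        area=float(mask.sum()), score=score)


def dataset_from_truths(truths, widths, heights) -> CocoDataset:
    """Assemble a CocoDataset of elaiosome annotations from scene truths."""
    ds = CocoDataset()
    ann_id = 1
    for i, truth in enumerate(truths):
        img_id = i + 1
        ds.images.append({"id": img_id, "file_name": f"scene_{i:04d}.png",
                          "width": int(widths[i]), "height": int(heights[i])})
        for seed in truth.seeds:
            ds.annotations.append(annotation_from_mask(
                seed.elaiosome_mask, ann_id, img_id))
            ann_id += 1
    return ds


# ---------------------------------------------------------------------------
# JSON round-trip
# ---------------------------------------------------------------------------

def _canonical(obj):
    if isinstance(obj, float):
        r = round(obj, 4)
        return int(r) if r == int(r) and abs(r) < 1e15 else r
    if isinstance(obj, (np.floating,)):
        return _canonical(float(obj))
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, dict):
        return {k: _canonical(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    return obj


def write_coco(dataset: CocoDataset, path) -> None:
    """Write canonical COCO JSON (sorted keys, 4-decimal floats)."""
    dataset.validate()
    anns = []
    for a in dataset.annotations:
        d = {"id": a.id, "image_id": a.image_id, "category_id": a.category_id,
             "bbox": list(a.bbox), "segmentation": a.segmentation,
             "area": a.area, "iscrowd": 0}
        if a.score is not None:
            d["score"] = a.score
        anns.append(d)
    doc = _canonical({"images": dataset.images, "annotations": anns,
                      "categories": dataset.categories})
    Path(path).write_text(json.dumps(doc, sort_keys=True, indent=1) + "\n")


def read_coco(path, validate: bool = True) -> CocoDataset:
    """Read COCO JSON; checks bbox/area consistency against the rasterized
    segmentation (bbox within 1 px, area equal to the pixel count)."""
    doc = json.loads(Path(path).read_text())
    for key in ("images", "annotations", "categories"):
        if key not in doc:
            raise ValueError(f"COCO file missing '{key}'")
    sizes = {im["id"]: (im["height"], im["width"]) for im in doc["images"]}
    ds = CocoDataset(images=doc["images"], annotations=[],
                     categories=doc["categories"])
    for d in doc["annotations"]:
        try:
            ann = InstanceAnnotation(
                id=d["id"], image_id=d["image_id"],
                category_id=d["category_id"], bbox=tuple(d["bbox"]),
                segmentation=d["segmentation"], area=d["area"],
                score=d.get("score"))
        except KeyError as e:
            raise ValueError(f"annotation record missing field {e}: {d.get('id')}")
        if validate:
            h, w = sizes[ann.image_id]
            m = segmentation_to_mask(ann.segmentation, h, w)
            ys, xs = np.nonzero(m)
            if ys.size == 0:
                raise ValueError(f"annotation {ann.id}: empty segmentation")
            x0, y0 = xs.min(), ys.min()
            tight = (x0, y0, xs.max() + 1 - x0, ys.max() + 1 - y0)
            if max(abs(t - b) for t, b in zip(tight, ann.bbox)) > 1.0:
                raise ValueError(
                    f"annotation {ann.id}: bbox {ann.bbox} inconsistent with "
                    f"segmentation tight box {tight}")
            if abs(m.sum() - ann.area) > max(1.0, 0.01 * m.sum()):
                raise ValueError(
                    f"annotation {ann.id}: area {ann.area} != mask pixel "
                    f"count {int(m.sum())}")
        ds.annotations.append(ann)
    ds.validate()
    return ds


# ---------------------------------------------------------------------------
# 8:1:1 split
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    ratios: tuple[int, int, int] = (8, 1, 1)
    rng_seed: int = 0


def split_dataset(dataset: CocoDataset,
                  spec: SplitSpec = SplitSpec()) -> tuple[CocoDataset, ...]:
    """Image-level split after a seeded shuffle; largest-remainder allocation
    keeps the part sizes exact (1000 images at 8:1:1 -> 800/100/100)."""
    if any(r <= 0 for r in spec.ratios):
        raise ValueError("ratios must be positive")
    ids = dataset.image_ids()
    if len(ids) < len(spec.ratios):
        raise ValueError(
            f"need at least {len(spec.ratios)} images, got {len(ids)}")
    rng = np.random.default_rng(np.random.SeedSequence([spec.rng_seed & 0x7FFFFFFF]))
    order = [ids[i] for i in rng.permutation(len(ids))]

    total = len(ids)
    quota = [total * r / sum(spec.ratios) for r in spec.ratios]
    sizes = [int(np.floor(q)) for q in quota]
    rem = total - sum(sizes)
    frac_order = sorted(range(len(quota)),
                        key=lambda k: (quota[k] - sizes[k], -k), reverse=True)
    for k in frac_order[:rem]:
        sizes[k] += 1

    parts = []
    start = 0
    for size in sizes:
        part_ids = set(order[start:start + size])
        start += size
        parts.append(CocoDataset(
            images=[im for im in dataset.images if im["id"] in part_ids],
            annotations=[a for a in dataset.annotations if a.image_id in part_ids],
            categories=[dict(c) for c in dataset.categories]))
    return tuple(parts)
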