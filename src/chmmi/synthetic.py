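"""Synthetic powdered-herb micrograph generator.

Real microscopic slides of powdered medicinal herbs (e.g. *Scutellaria
baicalensis*, *Magnolia officinalis*) show a handful of diagnostic "feature
cells" — fibers, stone cells, cork cells, vessels, starch granules — that are
small, unevenly scattered, often cut off at the frame edge by the field of
view, and frequently out of focus.  Their class frequencies are heavily
imbalanced: a few cell types dominate while others appear in only a dozen
images.

This module emulates that structure with textured, rotated ellipses on a
noisy pale background: each class has its own colour, elongation and texture
signature; cells may be truncated at the border and the whole frame may be
Gaussian-blurred.  Every visible cell yields exactly one tight bounding box
measured from its rendered pixel mask, so the labels are exact by
construction.  Generation is a pure function of (seed, image index), which
makes datasets reproducible and order-independent.
"""

from __future__ import annotations

import colorsys
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .boxes import BBox
from .labels import DatasetIndex, write_yolo_labels

# Per-class profile of a two-herb, nine-cell-type annotation corpus
# (fibers dominate; two classes are nearly absent).  The box-count profile,
# normalized, is the default class-weight vector of the 9-class generator.
IMBALANCED_9CLASS_IMAGE_COUNTS = (7555, 1662, 576, 304, 156, 550, 229, 13, 15)
IMBALANCED_9CLASS_BOX_COUNTS = (9080, 1726, 644, 353, 171, 580, 257, 13, 16)

DEFAULT_CLASS_NAMES_9 = (
    "mo_fibers", "mo_stone_cells", "mo_oil_cells",
    "sb_phloem_fibers", "sb_stone_cells", "sb_cork_cells",
    "sb_vessels", "sb_xylary_fibers", "sb_starch_granules",
)


def table1_class_weights() -> np.ndarray:
    """Default 9-class weight vector: the normalized box-count profile above."""
    c = np.asarray(IMBALANCED_9CLASS_BOX_COUNTS, dtype=float)
    return c / c.sum()


class SlideSpecError(ValueError):
    """Invalid generator configuration; the message names the offending field."""


@dataclass(frozen=True)
class SlideSpec:
    """Study conditions for one synthetic dataset.

    Parameters
    ----------
    n_classes : number of feature-cell classes.
    image_size : (H, W); both must be >= 32 and divisible by 32 (the
        detector's coarsest stride).
    cells_per_image : inclusive (lo, hi) range of cells per frame.
    class_weights : sampling probabilities per class (sums to 1).
    blur_sigma : (lo, hi) range of the whole-frame Gaussian blur, pixels.
    edge_truncation_prob : probability that a cell is deliberately placed
        across the frame border so only part of it is visible.
    cell_size : (lo, hi) range of cell major diameter as a fraction of the
        short image side.
    seed : root seed; image i uses the stream seeded with seed + i.
    """

    n_classes: int = 9
    image_size: tuple[int, int] = (320, 320)
    cells_per_image: tuple[int, int] = (0, 5)
    class_weights: tuple[float, ...] | None = None
    blur_sigma: tuple[float, float] = (0.0, 1.5)
    edge_truncation_prob: float = 0.25
    cell_size: tuple[float, float] = (0.10, 0.35)
    seed: int = 0

    def resolved_weights(self) -> np.ndarray:
        if self.class_weights is None:
            if self.n_classes == 9:
                return table1_class_weights()
            return np.full(self.n_classes, 1.0 / self.n_classes)
        return np.asarray(self.class_weights, dtype=float)

    def validate(self) -> None:
        if self.n_classes < 1:
            raise SlideSpecError(f"n_classes: must be >= 1, got {self.n_classes}")
        h, w = self.image_size
        if h < 32 or w < 32 or h % 32 or w % 32:
            raise SlideSpecError(
                f"image_size: H and W must be >= 32 and divisible by 32, got {self.image_size}"
            )
        lo, hi = self.cells_per_image
        if lo < 0 or hi < lo:
            raise SlideSpecError(f"cells_per_image: empty range {self.cells_per_image}")
        wts = self.resolved_weights()
        if len(wts) != self.n_classes:
            raise SlideSpecError(
                f"class_weights: length {len(wts)} != n_classes {self.n_classes}"
            )
        if np.any(wts < 0) or abs(wts.sum() - 1.0) > 1e-9:
            raise SlideSpecError("class_weights: must be non-negative and sum to 1")
        if self.blur_sigma[1] < self.blur_sigma[0] or self.blur_sigma[0] < 0:
            raise SlideSpecError(f"blur_sigma: empty range {self.blur_sigma}")
        if not (0.0 <= self.edge_truncation_prob <= 1.0):
            raise SlideSpecError(
                f"edge_truncation_prob: {self.edge_truncation_prob} outside [0,1]"
            )
        if not (0.0 < self.cell_size[0] <= self.cell_size[1] <= 1.0):
            raise SlideSpecError(f"cell_size: invalid range {self.cell_size}")
        if self.seed < 0:
            raise SlideSpecError(f"seed: must be >= 0, got {self.seed}")


@dataclass
class AnnotatedImage:
    """An RGB raster plus its normalized box labels."""

    pixels: np.ndarray  # H x W x 3, uint8
    boxes: list[BBox]
    image_id: str = ""

    def __post_init__(self) -> None:
        px = self.pixels
        if px.ndim != 3 or px.shape[2] != 3 or px.dtype != np.uint8:
            raise ValueError(f"pixels must be HxWx3 uint8, got {px.shape} {px.dtype}")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def class_style(class_id: int, n_classes: int) -> dict:
    """Deterministic per-class rendering style.

    Alternates rounded (stone-cell / granule-like) and elongated (fiber /
    vessel-like) morphologies around a hue wheel.
    """
    hue = (class_id * 0.41) % 1.0  # low-discrepancy hue spacing
    r, g, b = colorsys.hsv_to_rgb(hue, 0.55, 0.55)
    elongated = class_id % 2 == 1
    return {
        "color": np.array([r, g, b]),
        "aspect": (3.0 + (class_id % 3)) if elongated else (1.0 + 0.3 * (class_id % 2 + 1)),
        "tex_freq": 2.0 + (class_id % 4) * 2.0,  # texture stripes across the cell
        "wall_dark": 0.45 + 0.1 * (class_id % 3),
    }


def _render_cell(canvas: np.ndarray, rng: np.random.Generator, class_id: int,
                 n_classes: int, spec: SlideSpec, truncate: bool) -> np.ndarray | None:
    """Draw one cell on ``canvas`` in place; return its boolean visible mask."""
    H, W = canvas.shape[:2]
    style = class_style(class_id, n_classes)
    short = min(H, W)
    diam = rng.uniform(*spec.cell_size) * short
    a = diam / 2.0  # major semi-axis, px
    b = max(2.0, a / style["aspect"])
    theta = rng.uniform(0.0, np.pi)
    ct, st = np.cos(theta), np.sin(theta)
    # support radii of the rotated ellipse along x and y
    rx = float(np.hypot(a * ct, b * st))
    ry = float(np.hypot(a * st, b * ct))

    if truncate:
        side = rng.integers(4)
        d = rng.uniform(0.1, 0.6)  # fraction of the support radius kept inside
        if side == 0:
            cx, cy = d * rx, rng.uniform(ry, H - ry) if H > 2 * ry else H / 2
        elif side == 1:
            cx, cy = W - d * rx, rng.uniform(ry, H - ry) if H > 2 * ry else H / 2
        elif side == 2:
            cx, cy = rng.uniform(rx, W - rx) if W > 2 * rx else W / 2, d * ry
        else:
            cx, cy = rng.uniform(rx, W - rx) if W > 2 * rx else W / 2, H - d * ry
    else:
        cx = rng.uniform(rx, max(rx + 1, W - rx))
        cy = rng.uniform(ry, max(ry + 1, H - ry))

    x0, x1 = int(max(0, np.floor(cx - rx - 1))), int(min(W, np.ceil(cx + rx + 2)))
    y0, y1 = int(max(0, np.floor(cy - ry - 1))), int(min(H, np.ceil(cy + ry + 2)))
    if x1 <= x0 or y1 <= y0:
        return None
    ys, xs = np.mgrid[y0:y1, x0:x1]
    u = (xs - cx) * ct + (ys - cy) * st   # along the major axis
    v = -(xs - cx) * st + (ys - cy) * ct
    q = (u / a) ** 2 + (v / b) ** 2
    mask = q <= 1.0
    if mask.sum() < 16:  # too little visible to annotate meaningfully
        return None

    color = style["color"] * rng.uniform(0.85, 1.15)
    tex = 1.0 + 0.25 * np.sin(style["tex_freq"] * np.pi * u / max(a, 1e-6))
    wall = np.where(q > 0.72, style["wall_dark"], 1.0)  # darker cell wall rim
    shade = (tex * wall)[..., None] * color[None, None, :]
    patch = canvas[y0:y1, x0:x1]
    patch[mask] = np.clip(shade[mask], 0.0, 1.0)

    full = np.zeros((H, W), dtype=bool)
    full[y0:y1, x0:x1] = mask
    return full


def bbox_from_mask(mask: np.ndarray, class_id: int) -> BBox | None:
    """Tight normalized box around the True pixels of ``mask``."""
    ys, xs = np.nonzero(mask)
    if ys.size == 0:
        return None
    H, W = mask.shape
    x1, x2 = xs.min() / W, (xs.max() + 1) / W
    y1, y2 = ys.min() / H, (ys.max() + 1) / H
    if x2 - x1 < 2.0 / W or y2 - y1 < 2.0 / H:
        return None
    return BBox.from_corners(class_id, x1, y1, x2, y2)


def generate_slide(spec: SlideSpec, image_index: int,
                   return_masks: bool = False):
    """Render one synthetic slide.  Deterministic in (spec.seed, image_index).

    Returns an :class:`AnnotatedImage`; with ``return_masks=True`` also
    returns the per-cell boolean masks (aligned with the boxes) so tests can
    re-measure the labels independently.
    """
    spec.validate()
    if image_index < 0:
        raise SlideSpecError(f"image_index: must be >= 0, got {image_index}")
    rng = np.random.default_rng(spec.seed + image_index)
    H, W = spec.image_size
    weights = spec.resolved_weights()

    # pale noisy background with a gentle illumination gradient
    base = rng.uniform(0.78, 0.88)
    canvas = np.full((H, W, 3), base, dtype=float)
    gy, gx = np.mgrid[0:H, 0:W]
    grad = 0.04 * (gx / W - 0.5) * rng.uniform(-1, 1) + 0.04 * (gy / H - 0.5) * rng.uniform(-1, 1)
    canvas += grad[..., None]
    canvas += rng.normal(0.0, 0.02, size=(H, W, 3))

    n_cells = int(rng.integers(spec.cells_per_image[0], spec.cells_per_image[1] + 1))
    boxes: list[BBox] = []
    masks: list[np.ndarray] = []
    for _ in range(n_cells):
        cid = int(rng.choice(spec.n_classes, p=weights))
        truncate = bool(rng.random() < spec.edge_truncation_prob)
        mask = _render_cell(canvas, rng, cid, spec.n_classes, spec, truncate)
        if mask is None:
            continue
        box = bbox_from_mask(mask, cid)
        if box is None:
            continue
        boxes.append(box)
        masks.append(mask)

    sigma = rng.uniform(*spec.blur_sigma)
    if sigma > 1e-3:
        for ch in range(3):
            canvas[..., ch] = gaussian_filter(canvas[..., ch], sigma)

    pixels = (np.clip(canvas, 0.0, 1.0) * 255).round().astype(np.uint8)
    img = AnnotatedImage(pixels=pixels, boxes=boxes, image_id=f"img_{image_index:05d}")
    if return_masks:
        return img, masks
    return img


def generate_dataset(spec: SlideSpec, n_images: int,
                     out_dir: str | Path,
                     class_names: list[str] | None = None) -> DatasetIndex:
    """Write ``n_images`` slides as PNG + YOLO labels under ``out_dir``.

    Layout: ``images/img_#####.png``, ``labels/img_#####.txt``,
    ``dataset.yaml``.  Returns the populated :class:`DatasetIndex`.
    """
    spec.validate()
    if n_images < 1:
        raise SlideSpecError(f"n_images: must be >= 1, got {n_images}")
    out = Path(out_dir)
    img_dir, lbl_dir = out / "images", out / "labels"
    img_dir.mkdir(parents=True, exist_ok=True)
    lbl_dir.mkdir(parents=True, exist_ok=True)
    if class_names is None:
        class_names = (
            list(DEFAULT_CLASS_NAMES_9) if spec.n_classes == 9
            else [f"class_{i}" for i in range(spec.n_classes)]
        )

    image_paths, label_paths = [], []
    counts = {c: 0 for c in range(spec.n_classes)}
    for i in range(n_images):
        ann = generate_slide(spec, i)
        ip = img_dir / f"{ann.image_id}.png"
        lp = lbl_dir / f"{ann.image_id}.txt"
        Image.fromarray(ann.pixels).save(ip)
        write_yolo_labels(ann.boxes, lp)
        for b in ann.boxes:
            counts[b.class_id] += 1
        image_paths.append(ip)
        label_paths.append(lp)

    index = DatasetIndex(
        root=out,
        image_paths=image_paths,
        label_paths=label_paths,
        n_classes=spec.n_classes,
        class_names=class_names,
        class_box_counts=counts,
    )
    index.save_yaml()
    return index
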