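"""Segmentation-combination ("cut and recombine") data augmentation.

Two slides are each cut into a left and a right half; the four mixed-source
recombinations of those halves form four new annotated images.  Because
powdered-herb micrographs routinely contain cells that are only partially
visible, boxes crossing the cut are clipped (not dropped) as long as a
minimum fraction of their area survives.  Classic geometric ops (mirror,
translate, rotate by multiples of 90 degrees) and a class-balancing driver
that grows minority classes toward a target box-count ratio complete the
module.  All label remapping is exact affine/crop arithmetic, so a box can
always be re-projected onto its source with IoU 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image

from .boxes import BBox, clip_box
from .labels import DatasetIndex, read_yolo_labels, write_yolo_labels
from .synthetic import AnnotatedImage


@dataclass(frozen=True)
class AugmentationPolicy:
    """Knobs of the augmentation driver.

    ``clip_keep_fraction``: minimum surviving-area fraction for a box that is
    cut or pushed out of frame.  ``balance_ratio``: target minority/majority
    box-count ratio for :func:`balance_dataset`.
    """

    clip_keep_fraction: float = 0.2
    balance_ratio: float = 0.5
    geometric_ops: tuple[str, ...] = ("mirror", "translate", "rotate")
    max_new_images: int = 2000
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.clip_keep_fraction <= 1.0):
            raise ValueError(f"clip_keep_fraction {self.clip_keep_fraction} outside (0,1]")
        if not (0.0 < self.balance_ratio <= 1.0):
            raise ValueError(f"balance_ratio {self.balance_ratio} outside (0,1]")


@dataclass
class ImageHalf:
    """One half of a cut slide, with boxes in the half's own frame."""

    pixels: np.ndarray          # H x W' x 3 uint8
    boxes: list[BBox]
    origin: tuple[str, str]     # (source tag, "left"|"right")

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


def split_image(img: AnnotatedImage,
                clip_keep_fraction: float = 0.2,
                source: str = "a") -> tuple[ImageHalf, ImageHalf]:
    """Cut vertically at floor(W/2) into a left and a right half.

    The two halves' pixels concatenate back to the source exactly.  Boxes
    are clipped to each half and kept where at least ``clip_keep_fraction``
    of their area survives, then re-normalized to half-frame coordinates.
    """
    W = img.width
    if W < 2:
        raise ValueError("image too narrow to split")
    mid = W // 2
    fm = mid / W  # cut position in normalized coordinates
    left_boxes, right_boxes = [], []
    for b in img.boxes:
        lb = clip_box(b, 0.0, 0.0, fm, 1.0, clip_keep_fraction)
        if lb is not None:
            left_boxes.append(lb)
        rb = clip_box(b, fm, 0.0, 1.0, 1.0, clip_keep_fraction)
        if rb is not None:
            right_boxes.append(rb)
    left = ImageHalf(img.pixels[:, :mid].copy(), left_boxes, (source, "left"))
    right = ImageHalf(img.pixels[:, mid:].copy(), right_boxes, (source, "right"))
    return left, right


def recombine(first: ImageHalf, second: ImageHalf,
              image_id: str = "") -> AnnotatedImage:
    """Stitch ``first`` (left slot) and ``second`` (right slot) into one image."""
    if first.height != second.height:
        raise ValueError(
            f"half heights differ: {first.height} vs {second.height}"
        )
    wl, wr = first.width, second.width
    W = wl + wr
    pixels = np.concatenate([first.pixels, second.pixels], axis=1)
    boxes: list[BBox] = []
    for b in first.boxes:
        x1, y1, x2, y2 = b.corners()
        boxes.append(BBox.from_corners(b.class_id, x1 * wl / W, y1, x2 * wl / W, y2))
    for b in second.boxes:
        x1, y1, x2, y2 = b.corners()
        boxes.append(
            BBox.from_corners(b.class_id, (wl + x1 * wr) / W, y1, (wl + x2 * wr) / W, y2)
        )
    return AnnotatedImage(pixels=pixels, boxes=boxes, image_id=image_id)


def mida_pair(img_a: AnnotatedImage, img_b: AnnotatedImage,
              clip_keep_fraction: float = 0.2) -> list[AnnotatedImage]:
    """The four mixed-source recombinations of two distinct slides.

    Ordered output: (aL,bR), (bL,aR), (aR,bL), (bR,aL).  Same-source pairs
    are excluded so every product differs from both inputs; identical inputs
    are rejected because then no recombination could differ.
    """
    if img_a.pixels.shape != img_b.pixels.shape:
        raise ValueError("source images must share dimensions")
    if np.array_equal(img_a.pixels, img_b.pixels):
        raise ValueError("source images are pixel-identical; recombination "
                         "cannot differ from the originals")
    aL, aR = split_image(img_a, clip_keep_fraction, source="a")
    bL, bR = split_image(img_b, clip_keep_fraction, source="b")
    combos = [(aL, bR), (bL, aR), (aR, bL), (bR, aL)]
    out = []
    for i, (lhs, rhs) in enumerate(combos, start=1):
        out.append(recombine(lhs, rhs, image_id=f"mida_{i}"))
    return out


def geometric_augment(img: AnnotatedImage, op: str,
                      params: dict | None = None,
                      clip_keep_fraction: float = 0.2) -> AnnotatedImage:
    """Mirror, translate, or rotate (multiples of 90 degrees) with exact
    box remapping.

    mirror: horizontal flip, cx -> 1-cx.
    translate: shift by (dx, dy) fractions of the image size; vacated pixels
    are zero-filled and boxes pushed out of frame are clipped/dropped by the
    keep rule.
    rotate: clockwise by ``angle`` in {90, 180, 270}; (cx, cy) -> (1-cy, cx)
    per quarter turn, with w and h swapped.
    """
    params = params or {}
    px = img.pixels
    if op == "mirror":
        new_px = px[:, ::-1].copy()
        new_boxes = [BBox(b.class_id, 1.0 - b.cx, b.cy, b.w, b.h) for b in img.boxes]
    elif op == "translate":
        dx, dy = params.get("dx", 0.0), params.get("dy", 0.0)
        H, W = px.shape[:2]
        sx, sy = int(round(dx * W)), int(round(dy * H))
        new_px = np.zeros_like(px)
        src_x = slice(max(0, -sx), min(W, W - sx))
        src_y = slice(max(0, -sy), min(H, H - sy))
        dst_x = slice(max(0, sx), min(W, W + sx))
        dst_y = slice(max(0, sy), min(H, H + sy))
        new_px[dst_y, dst_x] = px[src_y, src_x]
        fdx, fdy = sx / W, sy / H  # realized pixel-exact shift
        new_boxes = []
        for b in img.boxes:
            x1, y1, x2, y2 = b.corners()
            x1, x2, y1, y2 = x1 + fdx, x2 + fdx, y1 + fdy, y2 + fdy
            # clip the shifted corners to the frame under the keep rule
            kx1, ky1 = max(x1, 0.0), max(y1, 0.0)
            kx2, ky2 = min(x2, 1.0), min(y2, 1.0)
            if kx2 <= kx1 or ky2 <= ky1:
                continue
            kept = (kx2 - kx1) * (ky2 - ky1) / b.area()
            if kept < clip_keep_fraction:
                continue
            new_boxes.append(BBox.from_corners(b.class_id, kx1, ky1, kx2, ky2))
    elif op == "rotate":
        angle = int(params.get("angle", 90))
        if angle % 90 != 0:
            raise ValueError(f"rotation angle must be a multiple of 90, got {angle}")
        k = (angle // 90) % 4
        new_px = px
        new_boxes = list(img.boxes)
        for _ in range(k):
            new_px = np.rot90(new_px, k=-1, axes=(0, 1)).copy()  # clockwise
            new_boxes = [
                BBox(b.class_id, 1.0 - b.cy, b.cx, b.h, b.w) for b in new_boxes
            ]
    else:
        raise ValueError(f"unsupported augmentation op {op!r}")
    return AnnotatedImage(pixels=np.ascontiguousarray(new_px), boxes=new_boxes,
                          image_id=f"{img.image_id}_{op}")


def _load_annotated(index: DatasetIndex, i: int) -> AnnotatedImage:
    px = np.asarray(Image.open(index.image_paths[i]).convert("RGB"))
    return AnnotatedImage(pixels=px, boxes=index.boxes_for(i),
                          image_id=index.image_paths[i].stem)


def balance_dataset(index: DatasetIndex, policy: AugmentationPolicy,
                    out_dir: str | Path | None = None,
                    pair_sources: dict | None = None) -> DatasetIndex:
    """Grow minority classes by repeated cut-and-recombine augmentation.

    Samples image pairs biased toward images containing minority-class boxes,
    applies :func:`mida_pair` plus one random geometric op per product, and
    appends the outputs until every class's box count reaches
    ``policy.balance_ratio`` times the majority class's count, or the
    ``max_new_images`` budget runs out (then the returned index carries a
    warning instead of raising).  Deterministic under ``policy.seed``.

    ``pair_sources``, when given a dict, is filled with
    ``new_image_id -> (source_id_1, source_id_2)`` so callers can keep
    augmented images inside their sources' data split.
    """
    if len(index) < 2:
        raise ValueError("need at least 2 images to augment")
    counts = dict(index.recount())
    if sum(counts.values()) == 0:
        raise ValueError("dataset has no boxes to balance")

    out = Path(out_dir) if out_dir is not None else index.root
    img_dir, lbl_dir = out / "images", out / "labels"
    img_dir.mkdir(parents=True, exist_ok=True)
    lbl_dir.mkdir(parents=True, exist_ok=True)
    if out != index.root:
        for ip, lp in zip(index.image_paths, index.label_paths):
            tgt_i, tgt_l = img_dir / ip.name, lbl_dir / lp.name
            if not tgt_i.exists():
                tgt_i.write_bytes(ip.read_bytes())
            if not tgt_l.exists():
                tgt_l.write_bytes(lp.read_bytes())

    rng = np.random.default_rng(policy.seed)
    image_paths = [img_dir / p.name for p in index.image_paths]
    label_paths = [lbl_dir / p.name for p in index.label_paths]
    per_image_boxes = [read_yolo_labels(lp) for lp in label_paths]
    n_orig = len(image_paths)  # pairs are drawn from originals only, so every
    # augmented image traces back to exactly two source slides

    present = {c for c, n in counts.items() if n > 0}

    def deficit_classes():
        mx = max(counts.values())
        return [c for c in present if counts[c] < policy.balance_ratio * mx]

    warning = None
    n_new = 0
    if deficit_classes():
        while n_new < policy.max_new_images:
            deficits = deficit_classes()
            if not deficits:
                break
            target = min(deficits, key=lambda c: counts[c])
            holders = [i for i, bs in enumerate(per_image_boxes[:n_orig])
                       if any(b.class_id == target for b in bs)]
            if not holders:
                warning = f"class {target} has no source boxes to amplify"
                break
            i = int(rng.choice(holders))
            # pairing two minority holders grows the deficit class fastest
            partner_pool = [j for j in holders if j != i] or \
                [j for j in range(n_orig) if j != i]
            j = int(rng.choice(partner_pool))
            img_i, img_j = _load_annotated_from(image_paths, per_image_boxes, i), \
                _load_annotated_from(image_paths, per_image_boxes, j)
            if np.array_equal(img_i.pixels, img_j.pixels):
                continue
            products = mida_pair(img_i, img_j, policy.clip_keep_fraction)
            products = [p for p in products
                        if any(b.class_id == target for b in p.boxes)]
            for prod in products:
                if policy.geometric_ops and rng.random() < 0.5:
                    op = str(rng.choice(list(policy.geometric_ops)))
                    params = {}
                    if op == "translate":
                        params = {"dx": float(rng.uniform(-0.2, 0.2)),
                                  "dy": float(rng.uniform(-0.2, 0.2))}
                    elif op == "rotate":
                        if prod.height == prod.width:
                            params = {"angle": int(rng.choice([90, 180, 270]))}
                        else:
                            params = {"angle": 180}
                    prod = geometric_augment(prod, op, params,
                                             policy.clip_keep_fraction)
                new_id = f"aug_{n_new:05d}"
                ip, lp = img_dir / f"{new_id}.png", lbl_dir / f"{new_id}.txt"
                Image.fromarray(prod.pixels).save(ip)
                write_yolo_labels(prod.boxes, lp)
                image_paths.append(ip)
                label_paths.append(lp)
                per_image_boxes.append(prod.boxes)
                for b in prod.boxes:
                    counts[b.class_id] = counts.get(b.class_id, 0) + 1
                if pair_sources is not None:
                    pair_sources[new_id] = (image_paths[i].stem, image_paths[j].stem)
                n_new += 1
                if n_new >= policy.max_new_images:
                    break
        if deficit_classes() and warning is None:
            warning = (
                f"augmentation budget ({policy.max_new_images}) exhausted before "
                f"reaching balance ratio {policy.balance_ratio}"
            )

    result = DatasetIndex(
        root=out,
        image_paths=image_paths,
        label_paths=label_paths,
        n_classes=index.n_classes,
        class_names=index.class_names,
        class_box_counts=counts,
        warning=warning,
    )
    result.save_yaml()
    return result


def _load_annotated_from(image_paths, per_image_boxes, i) -> AnnotatedImage:
    px = np.asarray(Image.open(image_paths[i]).convert("RGB"))
    return AnnotatedImage(pixels=px, boxes=per_image_boxes[i],
                          image_id=image_paths[i].stem)
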