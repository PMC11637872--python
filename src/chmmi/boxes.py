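"""Axis-aligned bounding boxes in normalized center format.

A box is stored as (class_id, cx, cy, w, h) with all coordinates expressed
as fractions of the image dimensions, the convention of YOLO-style label
files.  Corner format (x1, y1, x2, y2) is used internally for geometry
(overlap, clipping) and conversion between the two is part of this module's
contract.
"""

from __future__ import annotations

import math
from dataclasses import dataclass


@dataclass(frozen=True)
class BBox:
    """A class-labelled box in normalized center coordinates.

    ``cx``, ``cy`` are the box center and ``w``, ``h`` its extent, all as
    fractions of the image width/height.  The visible part of the box
    (its intersection with the unit square) must be non-empty.
    """

    class_id: int
    cx: float
    cy: float
    w: float
    h: float

    def __post_init__(self) -> None:
        if self.class_id < 0:
            raise ValueError(f"class_id must be >= 0, got {self.class_id}")
        if not (0.0 <= self.cx <= 1.0 and 0.0 <= self.cy <= 1.0):
            raise ValueError(f"box center ({self.cx}, {self.cy}) outside [0,1]^2")
        if not (0.0 < self.w <= 1.0 and 0.0 < self.h <= 1.0):
            raise ValueError(f"box extent ({self.w}, {self.h}) outside (0,1]")
        x1, y1, x2, y2 = self.corners()
        if min(x2, 1.0) - max(x1, 0.0) <= 0 or min(y2, 1.0) - max(y1, 0.0) <= 0:
            raise ValueError("box does not intersect the image frame")

    def corners(self) -> tuple[float, float, float, float]:
        """(x1, y1, x2, y2) corner coordinates, still normalized."""
        return (
            self.cx - self.w / 2.0,
            self.cy - self.h / 2.0,
            self.cx + self.w / 2.0,
            self.cy + self.h / 2.0,
        )

    @staticmethod
    def from_corners(class_id: int, x1: float, y1: float, x2: float, y2: float) -> "BBox":
        if not (x1 < x2 and y1 < y2):
            raise ValueError(f"degenerate corner box ({x1},{y1},{x2},{y2})")
        return BBox(class_id, (x1 + x2) / 2.0, (y1 + y2) / 2.0, x2 - x1, y2 - y1)

    def area(self) -> float:
        return self.w * self.h


def iou_corners(a, b) -> float:
    """Intersection over union of two corner-format boxes (x1, y1, x2, y2).

    Degenerate (zero-area) boxes yield 0.
    """
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    area_a = max(0.0, ax2 - ax1) * max(0.0, ay2 - ay1)
    area_b = max(0.0, bx2 - bx1) * max(0.0, by2 - by1)
    if area_a <= 0.0 or area_b <= 0.0:
        return 0.0
    iw = min(ax2, bx2) - max(ax1, bx1)
    ih = min(ay2, by2) - max(ay1, by1)
    if iw <= 0.0 or ih <= 0.0:
        return 0.0
    inter = iw * ih
    return inter / (area_a + area_b - inter)


def ciou_corners(a, b) -> float:
    """Complete IoU: IoU minus center-distance and aspect-ratio penalties.

    ciou = IoU - rho^2 / c^2 - alpha * v  where rho is the center distance,
    c the diagonal of the smallest enclosing box,
    v = (4/pi^2) (arctan(w_a/h_a) - arctan(w_b/h_b))^2 and
    alpha = v / (1 - IoU + v).  Equals plain IoU when the boxes share center
    and aspect ratio; always <= IoU.
    """
    ax1, ay1, ax2, ay2 = a
    bx1, by1, bx2, by2 = b
    i = iou_corners(a, b)
    if (ax2 - ax1) <= 0 or (ay2 - ay1) <= 0 or (bx2 - bx1) <= 0 or (by2 - by1) <= 0:
        return 0.0
    # squared center distance and enclosing-box diagonal
    rho2 = ((ax1 + ax2) / 2 - (bx1 + bx2) / 2) ** 2 + ((ay1 + ay2) / 2 - (by1 + by2) / 2) ** 2
    cw = max(ax2, bx2) - min(ax1, bx1)
    ch = max(ay2, by2) - min(ay1, by1)
    c2 = cw * cw + ch * ch
    v = (4.0 / math.pi**2) * (
        math.atan((ax2 - ax1) / (ay2 - ay1)) - math.atan((bx2 - bx1) / (by2 - by1))
    ) ** 2
    alpha = 0.0 if v == 0.0 else v / (1.0 - i + v)
    return i - (rho2 / c2 if c2 > 0 else 0.0) - alpha * v


def iou(a: BBox, b: BBox) -> float:
    return iou_corners(a.corners(), b.corners())


def ciou(a: BBox, b: BBox) -> float:
    return ciou_corners(a.corners(), b.corners())


def clip_box(box: BBox, x1: float, y1: float, x2: float, y2: float,
             keep_fraction: float) -> BBox | None:
    """Clip ``box`` to the window [x1,x2]x[y1,y2] (normalized coords of the
    source frame) and re-normalize to the window's own frame.

    Returns None when the retained area fraction falls below
    ``keep_fraction`` (or the intersection is empty).
    """
    bx1, by1, bx2, by2 = box.corners()
    cx1, cy1 = max(bx1, x1), max(by1, y1)
    cx2, cy2 = min(bx2, x2), min(by2, y2)
    if cx2 <= cx1 or cy2 <= cy1:
        return None
    kept = (cx2 - cx1) * (cy2 - cy1) / box.area()
    if kept < keep_fraction:
        return None
    ww, wh = x2 - x1, y2 - y1
    return BBox.from_corners(
        box.class_id,
        (cx1 - x1) / ww, (cy1 - y1) / wh,
        (cx2 - x1) / ww, (cy2 - y1) / wh,
    )
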