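"""Axis-aligned bounding boxes and intersection-over-union primitives.

Two IOU flavours are used throughout the package:

* :func:`iou_wh` — the *shape* IOU between two width/height pairs placed at
  a common centre.  This is the distance underlying anchor clustering, where
  only box dimensions matter and position is ignored.
* :func:`iou_corners` — the ordinary positional IOU between two placed
  boxes, used for non-maximum suppression and true-positive matching.

Boxes live either in continuous pixel coordinates (origin at the top-left
corner, x rightward, y downward) or in normalized coordinates in [0, 1].
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

__all__ = [
    "Frame",
    "BoundingBox",
    "PredictionBox",
    "WHPair",
    "iou_wh",
    "iou_corners",
    "to_corners",
    "to_center",
]


class Frame(str, enum.Enum):
    """Coordinate frame of a box: raw pixels or unit-normalized."""

    PIXEL = "pixel"
    NORMALIZED = "normalized"


@dataclass(frozen=True)
class BoundingBox:
    """A centre/width/height box.

    Parameters
    ----------
    cx, cy : float
        Horizontal and vertical centre.
    w, h : float
        Width and height; must be strictly positive.
    frame : Frame
        ``Frame.PIXEL`` (default) or ``Frame.NORMALIZED``.
    """

    cx: float
    cy: float
    w: float
    h: float
    frame: Frame = Frame.PIXEL

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"box dimensions must be positive, got w={self.w}, h={self.h}")
        if self.frame == Frame.NORMALIZED:
            for name in ("cx", "cy", "w", "h"):
                v = getattr(self, name)
                if not 0.0 <= v <= 1.0:
                    raise ValueError(f"normalized coordinate {name}={v} outside [0, 1]")

    @property
    def area(self) -> float:
        return self.w * self.h

    def corners(self) -> tuple[float, float, float, float]:
        return to_corners(self)


@dataclass(frozen=True)
class PredictionBox:
    """A scored, class-labelled predicted box.

    ``c`` is the detection confidence (objectness times class probability),
    constrained to [0, 1].
    """

    box: BoundingBox
    c: float
    class_id: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.c <= 1.0:
            raise ValueError(f"confidence must lie in [0, 1], got {self.c}")
        if self.class_id < 0:
            raise ValueError(f"class_id must be non-negative, got {self.class_id}")


@dataclass(frozen=True)
class WHPair:
    """A width/height pair — the clustering currency for anchor boxes."""

    w: float
    h: float

    def __post_init__(self) -> None:
        if self.w <= 0 or self.h <= 0:
            raise ValueError(f"dimensions must be positive, got w={self.w}, h={self.h}")

    @property
    def area(self) -> float:
        return self.w * self.h


def iou_wh(a: WHPair, b: WHPair) -> float:
    """Shape IOU of two width/height pairs placed at a common centre.

    The intersection of two co-centred rectangles is
    ``min(w_a, w_b) * min(h_a, h_b)``; the union follows by
    inclusion-exclusion.  Symmetric, bounded in [0, 1], and 1 exactly when
    the pairs coincide.
    """
    if a.w <= 0 or a.h <= 0 or b.w <= 0 or b.h <= 0:
        raise ValueError("iou_wh requires positive dimensions")
    inter = min(a.w, b.w) * min(a.h, b.h)
    union = a.w * a.h + b.w * b.h - inter
    return inter / union


def iou_corners(a: BoundingBox, b: BoundingBox) -> float:
    """Positional IOU of two placed boxes; 0 when they are disjoint."""
    if a.frame != b.frame:
        raise ValueError(f"cannot compare boxes across frames ({a.frame} vs {b.frame})")
    ax0, ay0, ax1, ay1 = to_corners(a)
    bx0, by0, bx1, by1 = to_corners(b)
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = a.area + b.area - inter
    return inter / union


def to_corners(b: BoundingBox) -> tuple[float, float, float, float]:
    """Centre box -> ``(xmin, ymin, xmax, ymax)``."""
    hw, hh = b.w / 2.0, b.h / 2.0
    return (b.cx - hw, b.cy - hh, b.cx + hw, b.cy + hh)


def to_center(
    corners: tuple[float, float, float, float], frame: Frame = Frame.PIXEL
) -> BoundingBox:
    """``(xmin, ymin, xmax, ymax)`` -> centre box; inverse of :func:`to_corners`."""
    xmin, ymin, xmax, ymax = corners
    if xmax <= xmin or ymax <= ymin:
        raise ValueError(f"degenerate corner box {corners}")
    return BoundingBox(
        cx=(xmin + xmax) / 2.0,
        cy=(ymin + ymax) / 2.0,
        w=xmax - xmin,
        h=ymax - ymin,
        frame=frame,
    )
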