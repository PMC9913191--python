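"""Image preprocessing: letterbox resize, region masking, augmentation.

Surveillance frames (2560x1440) must be brought to the square network
input (416x416 by default) without stretching the animals: the frame is
scaled by the smaller axis ratio ``s = min(w1/w2, h1/h2)`` and the
remainder padded with mid-gray RGB (128, 128, 128).  The same affine map
``x -> x*s + dw, y -> y*s + dh`` carries the annotations.

Masking blanks out regions of the barn where mounting cannot occur
(aisles, walls outside the shaded pen) so the detector neither wastes
computation nor fires on them.

Images are numpy ``uint8`` arrays of shape (H, W, 3); Pillow is used for
resampling, polygon rasterisation and file I/O.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from PIL import Image, ImageDraw

from .geometry import BoundingBox, Frame

__all__ = [
    "GRAY_FILL",
    "LetterboxParams",
    "MaskSpec",
    "letterbox_params",
    "apply_letterbox",
    "forward_boxes",
    "inverse_boxes",
    "apply_mask",
    "augment",
    "AUGMENT_OPS",
]

#: Letterbox padding colour.
GRAY_FILL: tuple[int, int, int] = (128, 128, 128)

#: Supported augmentation operations.
AUGMENT_OPS = ("hflip", "shift_x", "shift_y", "brighten", "darken")

#: Minimum fraction of a box's area that must remain visible after a shift.
MIN_VISIBLE_FRACTION = 0.25


@dataclass(frozen=True)
class LetterboxParams:
    """Record of an aspect-preserving resize.

    ``(w2, h2)`` source -> content scaled to ``(w3, h3)`` -> centred on a
    ``(w1, h1)`` canvas with pad offsets ``(dw, dh)``.
    """

    w1: int
    h1: int
    w2: int
    h2: int
    w3: int
    h3: int
    dw: int
    dh: int

    @property
    def scale(self) -> float:
        return min(self.w1 / self.w2, self.h1 / self.h2)


@dataclass(frozen=True)
class MaskSpec:
    """Keep-region polygon in source pixel coordinates; the rest is filled."""

    polygon: tuple[tuple[float, float], ...]
    fill: tuple[int, int, int] = (0, 0, 0)

    def __post_init__(self) -> None:
        if len(self.polygon) < 3:
            raise ValueError("mask polygon needs at least 3 vertices")


def letterbox_params(src: tuple[int, int], dst: tuple[int, int]) -> LetterboxParams:
    """Compute the aspect-preserving resize from ``src=(w2,h2)`` to ``dst=(w1,h1)``.

    The content size is the source scaled by ``min(w1/w2, h1/h2)`` and
    rounded to the nearest pixel; odd pad remainders go to the
    right/bottom edge (floor-divided symmetric padding).
    """
    w2, h2 = src
    w1, h1 = dst
    if min(w1, h1, w2, h2) <= 0:
        raise ValueError(f"dimensions must be positive, got src={src}, dst={dst}")
    s = min(w1 / w2, h1 / h2)
    w3 = round(w2 * s)
    h3 = round(h2 * s)
    dw = (w1 - w3) // 2
    dh = (h1 - h3) // 2
    return LetterboxParams(w1=w1, h1=h1, w2=w2, h2=h2, w3=w3, h3=h3, dw=dw, dh=dh)


def _check_image(image: np.ndarray) -> np.ndarray:
    img = np.asarray(image)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) image, got shape {img.shape}")
    return img


def apply_letterbox(image: np.ndarray, params: LetterboxParams) -> np.ndarray:
    """Resize to the content size and centre on the gray canvas."""
    img = _check_image(image)
    h, w = img.shape[:2]
    if (w, h) != (params.w2, params.h2):
        raise ValueError(
            f"image size {(w, h)} does not match params source {(params.w2, params.h2)}"
        )
    content = Image.fromarray(img).resize((params.w3, params.h3), Image.BILINEAR)
    canvas = np.empty((params.h1, params.w1, 3), dtype=np.uint8)
    canvas[:] = GRAY_FILL
    canvas[
        params.dh : params.dh + params.h3, params.dw : params.dw + params.w3
    ] = np.asarray(content)
    return canvas


def forward_boxes(
    boxes: Sequence[BoundingBox], params: LetterboxParams
) -> list[BoundingBox]:
    """Map source-frame boxes into the letterboxed frame."""
    s = params.scale
    return [
        BoundingBox(cx=b.cx * s + params.dw, cy=b.cy * s + params.dh,
                    w=b.w * s, h=b.h * s, frame=Frame.PIXEL)
        for b in boxes
    ]


def inverse_boxes(
    boxes: Sequence[BoundingBox], params: LetterboxParams
) -> list[BoundingBox]:
    """Map letterboxed-frame boxes back to the source frame."""
    s = params.scale
    return [
        BoundingBox(cx=(b.cx - params.dw) / s, cy=(b.cy - params.dh) / s,
                    w=b.w / s, h=b.h / s, frame=Frame.PIXEL)
        for b in boxes
    ]


def apply_mask(image: np.ndarray, mask: MaskSpec) -> np.ndarray:
    """Fill every pixel outside the kept polygon; pixels inside are unchanged."""
    img = _check_image(image)
    h, w = img.shape[:2]
    xs = [p[0] for p in mask.polygon]
    ys = [p[1] for p in mask.polygon]
    if max(xs) - min(xs) <= 0 or max(ys) - min(ys) <= 0:
        raise ValueError("degenerate mask polygon (zero extent)")
    stencil = Image.new("L", (w, h), 0)
    ImageDraw.Draw(stencil).polygon([tuple(p) for p in mask.polygon], fill=255)
    keep = np.asarray(stencil, dtype=bool)
    out = np.empty_like(img)
    out[:] = mask.fill
    out[keep] = img[keep]
    return out


def normalized_label_dimensions(
    annotations: Sequence,
    input_size: int = 416,
) -> np.ndarray:
    """Collect (w, h) of every annotated box, letterboxed and normalized.

    Each annotation supplies its source resolution; boxes are carried
    through the letterbox map to ``input_size`` and divided by it, giving
    the unit-square samples that anchor clustering consumes.
    """
    samples: list[tuple[float, float]] = []
    for ann in annotations:
        params = letterbox_params(ann.image_size, (input_size, input_size))
        for b in forward_boxes(ann.boxes(), params):
            samples.append((b.w / input_size, b.h / input_size))
    if not samples:
        raise ValueError("no annotated boxes found")
    return np.asarray(samples, dtype=float)


def _shift(
    img: np.ndarray,
    boxes: Sequence[BoundingBox],
    dx: int,
    dy: int,
    fill: tuple[int, int, int] = GRAY_FILL,
) -> tuple[np.ndarray, list[BoundingBox]]:
    h, w = img.shape[:2]
    out = np.empty_like(img)
    out[:] = fill
    src_x0, src_x1 = max(0, -dx), min(w, w - dx)
    src_y0, src_y1 = max(0, -dy), min(h, h - dy)
    if src_x1 > src_x0 and src_y1 > src_y0:
        out[src_y0 + dy : src_y1 + dy, src_x0 + dx : src_x1 + dx] = img[
            src_y0:src_y1, src_x0:src_x1
        ]
    kept: list[BoundingBox] = []
    for b in boxes:
        x0, y0, x1, y1 = b.corners()
        x0, x1 = x0 + dx, x1 + dx
        y0, y1 = y0 + dy, y1 + dy
        cx0, cy0 = max(x0, 0.0), max(y0, 0.0)
        cx1, cy1 = min(x1, float(w)), min(y1, float(h))
        if cx1 <= cx0 or cy1 <= cy0:
            continue
        visible = (cx1 - cx0) * (cy1 - cy0)
        if visible / b.area < MIN_VISIBLE_FRACTION:
            continue
        kept.append(
            BoundingBox(cx=(cx0 + cx1) / 2, cy=(cy0 + cy1) / 2,
                        w=cx1 - cx0, h=cy1 - cy0)
        )
    return out, kept


def augment(
    image: np.ndarray,
    boxes: Sequence[BoundingBox],
    op: str,
    magnitude: float | None = None,
    seed: int | None = None,
) -> tuple[np.ndarray, list[BoundingBox]]:
    """Apply one augmentation and transform the boxes consistently.

    Operations
    ----------
    hflip
        Mirror left-right; box centres map ``cx -> W - cx``.
    shift_x, shift_y
        Translate by ``magnitude`` (fraction of the frame, default drawn
        uniformly from [-0.1, 0.1]); boxes are clipped and dropped when
        less than 25% of their area stays visible.
    brighten, darken
        Scale intensities by ``magnitude`` (defaults drawn from
        U(1.1, 1.4) and U(0.6, 0.9) respectively) with clamping to
        [0, 255]; boxes are returned unchanged.
    """
    img = _check_image(image)
    if op not in AUGMENT_OPS:
        raise ValueError(f"unknown augmentation {op!r}; choose from {AUGMENT_OPS}")
    rng = np.random.default_rng(seed)
    h, w = img.shape[:2]

    if op == "hflip":
        out = img[:, ::-1].copy()
        new_boxes = [
            BoundingBox(cx=w - b.cx, cy=b.cy, w=b.w, h=b.h, frame=b.frame)
            for b in boxes
        ]
        return out, new_boxes

    if op in ("shift_x", "shift_y"):
        if magnitude is None:
            magnitude = float(rng.uniform(-0.1, 0.1))
        if not -1.0 <= magnitude <= 1.0:
            raise ValueError(f"shift magnitude {magnitude} outside [-1, 1]")
        if op == "shift_x":
            return _shift(img, boxes, dx=round(magnitude * w), dy=0)
        return _shift(img, boxes, dx=0, dy=round(magnitude * h))

    # brightness ops
    if magnitude is None:
        magnitude = float(rng.uniform(1.1, 1.4) if op == "brighten" else rng.uniform(0.6, 0.9))
    if op == "brighten" and not 1.0 <= magnitude <= 3.0:
        raise ValueError(f"brighten factor {magnitude} outside [1, 3]")
    if op == "darken" and not 0.0 < magnitude <= 1.0:
        raise ValueError(f"darken factor {magnitude} outside (0, 1]")
    out = np.clip(img.astype(np.float32) * magnitude, 0, 255).astype(np.uint8)
    return out, list(boxes)
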