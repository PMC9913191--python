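"""The four-detection-layer network and its prediction machinery.

The detector is a YOLO-v3-style one-stage network with a Darknet-53-style
backbone whose five residual stages hold (1, 2, 8, 8, 6) units, and —
beyond the usual 13/26/52 pyramid — an extra stride-4 head on a 104x104
grid (at 416 input) that specialises on the small images of distant
animals.  Each head predicts, per grid cell and per anchor, the five
quantities (x, y, w, h, c) plus per-class scores, so a 416-input model
emits 3 * (13^2 + 26^2 + 52^2 + 104^2) = 43,095 candidate boxes per image.

The modules here cover the full train/infer path: architecture
construction, box decoding, ground-truth target assignment, the composite
loss (summed over the four heads), and greedy non-maximum suppression.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from . import nn
from .anchors import AnchorSet, mounting_anchor_set
from .geometry import BoundingBox, PredictionBox, WHPair, iou_corners, iou_wh

__all__ = [
    "ArchitectureSpec",
    "LossWeights",
    "FourScaleDetector",
    "build_model",
    "count_predictions",
    "decode",
    "assign_targets",
    "loss",
    "nms",
]

STRIDES = (4, 8, 16, 32)  # finest to coarsest head


@dataclass(frozen=True)
class ArchitectureSpec:
    """Hyperparameters that define one concrete network.

    ``stage_widths`` are the output channels of the five backbone stages;
    the head pyramid widths follow the usual halving pattern.  The anchor
    set is expressed at ``anchors.input_size`` and rescaled automatically
    when the spec uses a different input resolution.
    """

    input_size: int = 416
    residual_counts: tuple[int, int, int, int, int] = (1, 2, 8, 8, 6)
    stage_widths: tuple[int, int, int, int, int] = (64, 128, 256, 512, 1024)
    num_classes: int = 1
    anchors: AnchorSet = field(default_factory=mounting_anchor_set)

    def __post_init__(self) -> None:
        if self.input_size % 32 != 0:
            raise ValueError(f"input_size must be divisible by 32, got {self.input_size}")
        if len(self.residual_counts) != 5 or len(self.stage_widths) != 5:
            raise ValueError("residual_counts and stage_widths must have 5 entries")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")

    @property
    def head_scales(self) -> tuple[int, ...]:
        """Grid sizes of the four heads, finest first."""
        return tuple(self.input_size // s for s in STRIDES)

    @property
    def anchor_set(self) -> AnchorSet:
        return self.anchors.rescaled(self.input_size)

    @classmethod
    def tiny(cls, input_size: int = 64, anchors: AnchorSet | None = None,
             num_classes: int = 1) -> "ArchitectureSpec":
        """A narrow configuration for desk-scale experiments and tests.

        Same topology (four heads, (1,2,8,8,6) residual stages), reduced
        channel widths and input resolution.
        """
        spec = cls(
            input_size=input_size,
            stage_widths=(8, 16, 32, 64, 128),
            num_classes=num_classes,
        )
        if anchors is not None:
            spec = replace(spec, anchors=anchors)
        return spec


@dataclass(frozen=True)
class LossWeights:
    """Relative weights of the loss components.

    ``coord`` scales the sum-squared coordinate error on the positive
    cells; objectness uses binary cross-entropy with weight 1 on positive
    and ``noobj`` on negative cells; anchors overlapping a ground truth
    above ``ignore_iou`` without being its best match contribute nothing.
    """

    coord: float = 5.0
    obj: float = 1.0
    noobj: float = 0.5
    cls: float = 1.0
    ignore_iou: float = 0.5


def _five_conv_block(c_in: int, c: int, rng: np.random.Generator) -> nn.Sequential:
    return nn.Sequential(
        nn.ConvBNLeaky(c_in, c, 1, 1, rng),
        nn.ConvBNLeaky(c, 2 * c, 3, 1, rng),
        nn.ConvBNLeaky(2 * c, c, 1, 1, rng),
        nn.ConvBNLeaky(c, 2 * c, 3, 1, rng),
        nn.ConvBNLeaky(2 * c, c, 1, 1, rng),
    )


def _head_bias(n_anchors: int, m: int, obj_prior_logit: float) -> np.ndarray:
    """Bias init for the prediction conv: objectness starts at a low prior."""
    bias = np.zeros(n_anchors * (5 + m), dtype=np.float32)
    for a in range(n_anchors):
        bias[a * (5 + m) + 4] = obj_prior_logit
    return bias


class FourScaleDetector(nn.Module):
    """The network itself.  ``forward`` maps an (N, 3, H, W) batch in [0, 1]
    to raw head tensors ``{grid_size: (N, 3*(5+M), S, S)}``, finest first."""

    def __init__(self, spec: ArchitectureSpec, seed: int | None = 0):
        super().__init__()
        self.spec = spec
        rng = np.random.default_rng(seed)
        w1, w2, w3, w4, w5 = spec.stage_widths
        m = spec.num_classes
        out_ch = 3 * (5 + m)

        stem_w = max(4, w1 // 2)
        self.stem = nn.ConvBNLeaky(3, stem_w, 3, 1, rng)

        def stage(c_in: int, c_out: int, n_res: int) -> nn.Sequential:
            mods: list[nn.Module] = [nn.ConvBNLeaky(c_in, c_out, 3, 2, rng)]
            mods += [nn.Residual(c_out, rng) for _ in range(n_res)]
            return nn.Sequential(*mods)

        r = spec.residual_counts
        self.stage1 = stage(stem_w, w1, r[0])   # stride 2
        self.stage2 = stage(w1, w2, r[1])       # stride 4   -> C2 (104 grid)
        self.stage3 = stage(w2, w3, r[2])       # stride 8   -> C3 (52)
        self.stage4 = stage(w3, w4, r[3])       # stride 16  -> C4 (26)
        self.stage5 = stage(w4, w5, r[4])       # stride 32  -> C5 (13)

        b5, b4, b3 = w5 // 2, w4 // 2, w3 // 2
        b2 = w3 // 2  # the 104 path keeps the 52-path block width
        self.block5 = _five_conv_block(w5, b5, rng)
        self.head5_conv = nn.ConvBNLeaky(b5, 2 * b5, 3, 1, rng)
        self.head5 = nn.ConvLinear(2 * b5, out_ch, rng, _head_bias(3, m, -4.0))

        self.route4 = nn.ConvBNLeaky(b5, b4, 1, 1, rng)
        self.block4 = _five_conv_block(b4 + w4, b4, rng)
        self.head4_conv = nn.ConvBNLeaky(b4, 2 * b4, 3, 1, rng)
        self.head4 = nn.ConvLinear(2 * b4, out_ch, rng, _head_bias(3, m, -4.0))

        self.route3 = nn.ConvBNLeaky(b4, b3, 1, 1, rng)
        self.block3 = _five_conv_block(b3 + w3, b3, rng)
        self.head3_conv = nn.ConvBNLeaky(b3, 2 * b3, 3, 1, rng)
        self.head3 = nn.ConvLinear(2 * b3, out_ch, rng, _head_bias(3, m, -4.0))

        # Extra stride-4 path: conv + upsample on the 52-scale pre-head
        # feature, concatenated with the stride-4 backbone output.
        self.route2 = nn.ConvBNLeaky(2 * b3, b2, 1, 1, rng)
        self.block2 = _five_conv_block(b2 + w2, b2, rng)
        self.head2_conv = nn.ConvBNLeaky(b2, 2 * b2, 3, 1, rng)
        self.head2 = nn.ConvLinear(2 * b2, out_ch, rng, _head_bias(3, m, -4.0))

        self.up = nn.Upsample2x()

    def forward(self, x: np.ndarray | nn.Tensor) -> dict[int, nn.Tensor]:
        if not isinstance(x, nn.Tensor):
            x = nn.Tensor(np.asarray(x, dtype=np.float32))
        n, c, h, w = x.shape
        if c != 3 or h != self.spec.input_size or w != self.spec.input_size:
            raise ValueError(
                f"expected (N, 3, {self.spec.input_size}, {self.spec.input_size}), got {x.shape}"
            )
        c1 = self.stage1(self.stem(x))
        c2 = self.stage2(c1)
        c3 = self.stage3(c2)
        c4 = self.stage4(c3)
        c5 = self.stage5(c4)

        f5 = self.block5(c5)
        out5 = self.head5(self.head5_conv(f5))

        f4 = self.block4(nn.concat([self.up(self.route4(f5)), c4]))
        out4 = self.head4(self.head4_conv(f4))

        f3 = self.block3(nn.concat([self.up(self.route3(f4)), c3]))
        pre3 = self.head3_conv(f3)
        out3 = self.head3(pre3)

        f2 = self.block2(nn.concat([self.up(self.route2(pre3)), c2]))
        out2 = self.head2(self.head2_conv(f2))

        s104, s52, s26, s13 = self.spec.head_scales
        return {s104: out2, s52: out3, s26: out4, s13: out5}


def build_model(spec: ArchitectureSpec, seed: int | None = 0) -> FourScaleDetector:
    """Construct a randomly initialised detector for the given spec."""
    return FourScaleDetector(spec, seed=seed)


def count_predictions(spec: ArchitectureSpec, head_scales: Sequence[int] | None = None) -> int:
    """Number of candidate boxes per image: 3 anchors per cell over all heads.

    The four-head 416 model yields 43,095; the classic three-head pyramid
    (13, 26, 52) yields 10,647.
    """
    scales = tuple(head_scales) if head_scales is not None else spec.head_scales
    return int(3 * sum(s * s for s in scales))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-np.clip(x, -60.0, 60.0)))


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _ordered_anchors(anchor_set: AnchorSet, head_scales: Sequence[int]) -> dict[int, np.ndarray]:
    """Per-scale (3, 2) anchor arrays keyed by grid size."""
    out: dict[int, np.ndarray] = {}
    for s in head_scales:
        if s not in anchor_set.layer_map:
            raise ValueError(
                f"anchor set (scales {tuple(anchor_set.layer_map)}) does not cover head {s}"
            )
        out[s] = np.asarray(anchor_set.layer_map[s], dtype=float)
    return out


def decode(
    outputs: Mapping[int, "nn.Tensor | np.ndarray"],
    spec: ArchitectureSpec,
    conf_threshold: float = 0.5,
) -> list[list[PredictionBox]]:
    """Raw head tensors -> scored boxes in the letterboxed pixel frame.

    Per cell and anchor: centre ``(sigma(tx) + cell) * stride``, size
    ``anchor * exp(tw)``, confidence ``sigma(obj) * max_c sigma(cls_c)``.
    Boxes below ``conf_threshold`` are discarded.
    """
    m = spec.num_classes
    anchors = _ordered_anchors(spec.anchor_set, spec.head_scales)
    batch: list[list[PredictionBox]] | None = None
    for s in spec.head_scales:
        raw = outputs[s]
        data = raw.data if isinstance(raw, nn.Tensor) else np.asarray(raw, dtype=np.float32)
        n = data.shape[0]
        if data.shape[1:] != (3 * (5 + m), s, s):
            raise ValueError(
                f"head {s}: expected shape (N, {3 * (5 + m)}, {s}, {s}), got {data.shape}"
            )
        if batch is None:
            batch = [[] for _ in range(n)]
        stride = spec.input_size / s
        r = data.reshape(n, 3, 5 + m, s, s)
        cy_grid, cx_grid = np.meshgrid(np.arange(s), np.arange(s), indexing="ij")
        bx = (_sigmoid(r[:, :, 0]) + cx_grid) * stride
        by = (_sigmoid(r[:, :, 1]) + cy_grid) * stride
        bw = anchors[s][None, :, 0, None, None] * np.exp(np.clip(r[:, :, 2], -20, 10))
        bh = anchors[s][None, :, 1, None, None] * np.exp(np.clip(r[:, :, 3], -20, 10))
        obj = _sigmoid(r[:, :, 4])
        cls = _sigmoid(r[:, :, 5:])
        conf = obj * cls.max(axis=2)
        cls_id = cls.argmax(axis=2)
        keep = conf >= conf_threshold
        for i in range(n):
            for a, gy, gx in zip(*np.nonzero(keep[i])):
                batch[i].append(
                    PredictionBox(
                        box=BoundingBox(
                            cx=float(bx[i, a, gy, gx]),
                            cy=float(by[i, a, gy, gx]),
                            w=float(bw[i, a, gy, gx]),
                            h=float(bh[i, a, gy, gx]),
                        ),
                        c=float(conf[i, a, gy, gx]),
                        class_id=int(cls_id[i, a, gy, gx]),
                    )
                )
    assert batch is not None
    return batch


def assign_targets(
    gt: Sequence[Sequence[BoundingBox]],
    spec: ArchitectureSpec,
    class_ids: Sequence[Sequence[int]] | None = None,
) -> dict[int, dict[str, np.ndarray]]:
    """Build training targets: each ground truth goes to its best-IOU anchor.

    For every ground-truth box the shape IOU against all 12 anchors picks
    one responsible (head, anchor) pair, and the cell containing the box
    centre at that head's stride becomes the positive cell.  (Near-miss
    predictions are exempted from the negative set dynamically inside
    :func:`loss`, based on their decoded overlap with the ground truth.)

    Returns, per grid size: ``t_box`` (N,3,S,S,4) with (tx, ty, tw, th)
    regression targets, ``obj`` and ``noobj`` masks (N,3,S,S), and ``cls``
    one-hot targets (N,3,S,S,M).
    """
    n = len(gt)
    m = spec.num_classes
    anchors = _ordered_anchors(spec.anchor_set, spec.head_scales)
    flat: list[tuple[int, int, float, float]] = []  # (scale, local idx, w, h)
    for s in spec.head_scales:
        for j, (aw, ah) in enumerate(anchors[s]):
            flat.append((s, j, float(aw), float(ah)))

    tgt = {
        s: {
            "t_box": np.zeros((n, 3, s, s, 4), dtype=np.float32),
            "obj": np.zeros((n, 3, s, s), dtype=np.float32),
            "noobj": np.ones((n, 3, s, s), dtype=np.float32),
            "cls": np.zeros((n, 3, s, s, m), dtype=np.float32),
        }
        for s in spec.head_scales
    }

    size = float(spec.input_size)
    for i, boxes in enumerate(gt):
        ids = class_ids[i] if class_ids is not None else [0] * len(boxes)
        for b, cid in zip(boxes, ids):
            if not (0 <= b.cx <= size and 0 <= b.cy <= size):
                raise ValueError(f"ground-truth centre ({b.cx}, {b.cy}) outside the frame")
            gt_wh = WHPair(b.w, b.h)
            ious = [iou_wh(gt_wh, WHPair(aw, ah)) for (_, _, aw, ah) in flat]
            best = int(np.argmax(ious))
            best_scale, best_local, aw, ah = flat[best]
            stride = size / best_scale
            gx = min(int(b.cx / stride), best_scale - 1)
            gy = min(int(b.cy / stride), best_scale - 1)
            t = tgt[best_scale]
            t["obj"][i, best_local, gy, gx] = 1.0
            t["noobj"][i, best_local, gy, gx] = 0.0
            t["t_box"][i, best_local, gy, gx] = (
                b.cx / stride - gx,
                b.cy / stride - gy,
                np.log(b.w / aw),
                np.log(b.h / ah),
            )
            t["cls"][i, best_local, gy, gx, int(cid)] = 1.0
    return tgt


def _decoded_best_gt_iou(
    r: np.ndarray, anchors: np.ndarray, stride: float,
    gt_boxes: Sequence[np.ndarray], s: int,
) -> np.ndarray:
    """Best IOU of every decoded prediction against its image's ground
    truths, shape (N, 3, S, S).  Used for the dynamic ignore region."""
    n = r.shape[0]
    cy_grid, cx_grid = np.meshgrid(np.arange(s), np.arange(s), indexing="ij")
    bx = (_sigmoid(r[:, :, 0]) + cx_grid) * stride
    by = (_sigmoid(r[:, :, 1]) + cy_grid) * stride
    bw = anchors[None, :, 0, None, None] * np.exp(np.clip(r[:, :, 2], -20, 10))
    bh = anchors[None, :, 1, None, None] * np.exp(np.clip(r[:, :, 3], -20, 10))
    best = np.zeros((n, 3, s, s), dtype=np.float32)
    for i in range(n):
        g = np.asarray(gt_boxes[i], dtype=np.float32)
        if g.size == 0:
            continue
        px0, py0 = bx[i] - bw[i] / 2, by[i] - bh[i] / 2
        px1, py1 = bx[i] + bw[i] / 2, by[i] + bh[i] / 2
        for gx0, gy0, gx1, gy1, garea in zip(
            g[:, 0] - g[:, 2] / 2, g[:, 1] - g[:, 3] / 2,
            g[:, 0] + g[:, 2] / 2, g[:, 1] + g[:, 3] / 2,
            g[:, 2] * g[:, 3],
        ):
            iw = np.minimum(px1, gx1) - np.maximum(px0, gx0)
            ih = np.minimum(py1, gy1) - np.maximum(py0, gy0)
            inter = np.clip(iw, 0, None) * np.clip(ih, 0, None)
            union = bw[i] * bh[i] + garea - inter
            best[i] = np.maximum(best[i], inter / union)
    return best


def loss(
    outputs: Mapping[int, nn.Tensor],
    targets: Mapping[int, Mapping[str, np.ndarray]],
    spec: ArchitectureSpec,
    weights: LossWeights = LossWeights(),
    gt_boxes: Sequence[np.ndarray] | None = None,
) -> tuple[nn.Tensor, dict[str, float]]:
    """Composite detection loss, summed over the four heads.

    Sum-squared error on the (x, y, w, h) offsets of positive cells
    (weight ``weights.coord``), binary cross-entropy with logits on
    objectness (positives weight 1, negatives ``weights.noobj``) and on
    the per-class scores of positive cells.  When ``gt_boxes`` (per-image
    (G, 4) arrays of cx/cy/w/h in the letterboxed frame) are supplied,
    non-responsible predictions whose decoded box overlaps a ground truth
    above ``weights.ignore_iou`` are exempted from the negative term, so
    near-misses are neither rewarded nor punished.  The scalar is the
    mean per image; gradients are computed analytically.
    """
    m = spec.num_classes
    total = 0.0
    comp = {"coord": 0.0, "obj": 0.0, "cls": 0.0}
    parents: list[nn.Tensor] = []
    grads: list[np.ndarray] = []
    anchors_by_scale = _ordered_anchors(spec.anchor_set, spec.head_scales)

    for s in spec.head_scales:
        raw = outputs[s]
        t = targets[s]
        n = raw.data.shape[0]
        r = raw.data.reshape(n, 3, 5 + m, s, s)
        obj_mask = t["obj"]          # (N,3,S,S)
        noobj_mask = t["noobj"]
        if gt_boxes is not None:
            best_iou = _decoded_best_gt_iou(
                r, anchors_by_scale[s], spec.input_size / s, gt_boxes, s
            )
            noobj_mask = noobj_mask * (best_iou <= weights.ignore_iou)
        t_box = t["t_box"]           # (N,3,S,S,4)
        t_cls = t["cls"]             # (N,3,S,S,M)

        txy = r[:, :, 0:2]
        twh = r[:, :, 2:4]
        o = r[:, :, 4]
        c = r[:, :, 5:]

        sxy = _sigmoid(txy)
        so = _sigmoid(o)
        sc = _sigmoid(c)

        mask4 = obj_mask[:, :, None]  # broadcast over the channel axis
        # coordinates (positives only)
        exy = (sxy - np.moveaxis(t_box[..., 0:2], -1, 2)) * mask4
        ewh = (twh - np.moveaxis(t_box[..., 2:4], -1, 2)) * mask4
        l_coord = weights.coord * float((exy**2).sum() + (ewh**2).sum())
        # objectness BCE with logits
        l_obj = float(
            weights.obj * (obj_mask * _softplus(-o)).sum()
            + weights.noobj * (noobj_mask * _softplus(o)).sum()
        )
        # class BCE (positives only)
        tc = np.moveaxis(t_cls, -1, 2)
        l_cls = weights.cls * float(
            (mask4 * (_softplus(c) - tc * c)).sum()
        )

        comp["coord"] += l_coord / n
        comp["obj"] += l_obj / n
        comp["cls"] += l_cls / n
        total += (l_coord + l_obj + l_cls) / n

        g = np.zeros_like(r)
        g[:, :, 0:2] = 2.0 * weights.coord * exy * sxy * (1 - sxy) * mask4
        g[:, :, 2:4] = 2.0 * weights.coord * ewh * mask4
        g[:, :, 4] = weights.obj * obj_mask * (so - 1.0) + weights.noobj * noobj_mask * so
        g[:, :, 5:] = weights.cls * mask4 * (sc - tc)
        parents.append(raw)
        grads.append((g / n).reshape(raw.data.shape))

    def _backward(gout: np.ndarray) -> None:
        scale = float(gout)
        for p, g in zip(parents, grads):
            if p.requires_grad:
                p.accumulate(scale * g)

    out = nn.Tensor(np.float32(total), parents=tuple(parents), backward=_backward)
    return out, comp


def nms(boxes: Sequence[PredictionBox], iou_threshold: float = 0.45) -> list[PredictionBox]:
    """Greedy per-class non-maximum suppression by descending confidence."""
    remaining = sorted(boxes, key=lambda p: -p.c)
    kept: list[PredictionBox] = []
    while remaining:
        best = remaining.pop(0)
        kept.append(best)
        remaining = [
            p
            for p in remaining
            if p.class_id != best.class_id
            or iou_corners(p.box, best.box) <= iou_threshold
        ]
    return kept
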