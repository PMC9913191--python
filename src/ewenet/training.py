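"""Training loop: SGD regimen, per-epoch checkpointing, metric logging.

The reference regimen is SGD with momentum 0.9, initial learning rate
1e-3 (held constant), weight decay 5e-4, batch size 10, 100 epochs, with
one checkpoint written per epoch.  After training, the working model is
selected post hoc from the per-epoch validation metrics: highest F1, ties
broken by mAP, then by the later epoch.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import nn
from .anchors import AnchorSet
from .evaluation import evaluate
from .geometry import BoundingBox, PredictionBox
from .imaging import apply_letterbox, forward_boxes, inverse_boxes, letterbox_params
from .model import ArchitectureSpec, FourScaleDetector, LossWeights, assign_targets, decode, loss, nms

__all__ = ["TrainConfig", "TrainLog", "Sample", "train", "select_best_checkpoint",
           "predict_images", "save_checkpoint", "load_checkpoint",
           "load_model_checkpoint"]


@dataclass(frozen=True)
class Sample:
    """One training/validation example: an RGB image (H, W, 3, uint8) in the
    source frame plus its ground-truth boxes and class ids."""

    image: np.ndarray
    boxes: tuple[BoundingBox, ...]
    class_ids: tuple[int, ...] = ()

    def ids(self) -> tuple[int, ...]:
        return self.class_ids if self.class_ids else tuple(0 for _ in self.boxes)


@dataclass(frozen=True)
class TrainConfig:
    """The training regimen; defaults follow the reference setup."""

    batch_size: int = 10
    initial_lr: float = 0.001
    weight_decay: float = 0.0005
    momentum: float = 0.9
    epochs: int = 100
    seed: int = 0
    conf_threshold: float = 0.5  # working point for the per-epoch P/R/F1
    nms_iou: float = 0.45
    match_iou: float = 0.5
    eval_every: int = 1
    early_stop_map: float | None = None  # stop once training/val mAP reaches this
    loss_weights: LossWeights = field(default_factory=LossWeights)

    def __post_init__(self) -> None:
        if min(self.batch_size, self.epochs) < 1 or self.initial_lr <= 0:
            raise ValueError("batch_size, epochs and initial_lr must be positive")


@dataclass
class TrainLog:
    """Per-epoch records; convertible to a DataFrame/CSV."""

    rows: list[dict] = field(default_factory=list)
    checkpoints: list[Path] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


def _prepare(samples: Sequence[Sample], input_size: int):
    """Letterbox every sample once; returns (chw float images, boxes, ids)."""
    images, boxes, ids = [], [], []
    for s in samples:
        h, w = s.image.shape[:2]
        params = letterbox_params((w, h), (input_size, input_size))
        img = apply_letterbox(s.image, params)
        images.append(np.ascontiguousarray(img.transpose(2, 0, 1), dtype=np.float32) / 255.0)
        boxes.append(forward_boxes(s.boxes, params))
        ids.append(list(s.ids()))
    return images, boxes, ids


def predict_images(
    model: FourScaleDetector,
    images: Sequence[np.ndarray],
    conf_threshold: float = 0.5,
    nms_iou: float = 0.45,
    batch_size: int = 8,
) -> list[list[PredictionBox]]:
    """Inference on source-frame images; detections mapped back to that frame."""
    spec = model.spec
    model.eval()
    out: list[list[PredictionBox]] = []
    metas = []
    letterboxed = []
    for img in images:
        h, w = img.shape[:2]
        params = letterbox_params((w, h), (spec.input_size, spec.input_size))
        metas.append(params)
        lb = apply_letterbox(img, params)
        letterboxed.append(np.ascontiguousarray(lb.transpose(2, 0, 1), dtype=np.float32) / 255.0)
    for lo in range(0, len(letterboxed), batch_size):
        batch = np.stack(letterboxed[lo : lo + batch_size])
        raw = model(batch)
        decoded = decode(raw, spec, conf_threshold=conf_threshold)
        for k, preds in enumerate(decoded):
            kept = nms(preds, iou_threshold=nms_iou)
            params = metas[lo + k]
            mapped = inverse_boxes([p.box for p in kept], params)
            out.append(
                [PredictionBox(box=b, c=p.c, class_id=p.class_id)
                 for b, p in zip(mapped, kept)]
            )
    return out


def _spec_to_json(spec: ArchitectureSpec) -> str:
    return json.dumps(
        {
            "input_size": spec.input_size,
            "residual_counts": list(spec.residual_counts),
            "stage_widths": list(spec.stage_widths),
            "num_classes": spec.num_classes,
            "anchors": {
                "anchors": [list(a) for a in spec.anchors.anchors],
                "layer_map": {str(k): [list(a) for a in v]
                              for k, v in spec.anchors.layer_map.items()},
                "input_size": spec.anchors.input_size,
            },
        }
    )


def _spec_from_json(blob: str) -> ArchitectureSpec:
    d = json.loads(blob)
    a = d["anchors"]
    anchors = AnchorSet(
        anchors=tuple(tuple(x) for x in a["anchors"]),
        layer_map={int(k): tuple(tuple(x) for x in v)
                   for k, v in a["layer_map"].items()},
        input_size=a["input_size"],
    )
    return ArchitectureSpec(
        input_size=d["input_size"],
        residual_counts=tuple(d["residual_counts"]),
        stage_widths=tuple(d["stage_widths"]),
        num_classes=d["num_classes"],
        anchors=anchors,
    )


def save_checkpoint(model: FourScaleDetector, path: str | Path, epoch: int) -> None:
    """Weights + buffers + the architecture spec, as an .npz archive."""
    state = model.state_dict()
    np.savez(
        path,
        __epoch__=np.asarray(epoch),
        __spec__=np.frombuffer(_spec_to_json(model.spec).encode(), dtype=np.uint8),
        **state,
    )


def load_checkpoint(model: FourScaleDetector, path: str | Path) -> int:
    """Load weights into an existing model of matching architecture."""
    with np.load(path) as data:
        state = {k: data[k] for k in data.files if not k.startswith("__")}
        epoch = int(data["__epoch__"])
    model.load_state_dict(state)
    return epoch


def load_model_checkpoint(path: str | Path) -> tuple[FourScaleDetector, int]:
    """Rebuild the model recorded in a checkpoint and load its weights."""
    with np.load(path) as data:
        if "__spec__" not in data.files:
            raise ValueError(f"{path} has no embedded architecture spec")
        spec = _spec_from_json(bytes(data["__spec__"]).decode())
    model = FourScaleDetector(spec, seed=0)
    epoch = load_checkpoint(model, path)
    return model, epoch


def _epoch_metrics(
    model: FourScaleDetector,
    images: list[np.ndarray],
    boxes: list[list[BoundingBox]],
    config: TrainConfig,
) -> dict:
    """P/R/F1 at the working threshold and mAP from the full ranking."""
    spec = model.spec
    model.eval()
    preds_all: list[list[PredictionBox]] = []
    for lo in range(0, len(images), max(1, config.batch_size)):
        batch = np.stack(images[lo : lo + config.batch_size])
        decoded = decode(model(batch), spec, conf_threshold=0.01)
        preds_all.extend(nms(p, iou_threshold=config.nms_iou) for p in decoded)
    model.train()
    report = evaluate(
        preds_all, boxes,
        conf_threshold=config.conf_threshold,
        iou_threshold=config.match_iou,
        sweep_grid=[0.0],
    )
    return {"precision": report.precision, "recall": report.recall,
            "f1": report.f1, "map": report.map}


def train(
    model: FourScaleDetector,
    train_samples: Sequence[Sample],
    config: TrainConfig = TrainConfig(),
    val_samples: Sequence[Sample] | None = None,
    checkpoint_dir: str | Path | None = None,
    verbose: bool = False,
) -> TrainLog:
    """Run the SGD loop; one checkpoint and one log row per epoch.

    Validation metrics (P/R/F1 at the working confidence, mAP over the
    full ranking) are computed every ``eval_every`` epochs on
    ``val_samples`` if given, else on the training set.  Training stops
    early only when ``early_stop_map`` is set and reached.
    """
    if not train_samples:
        raise ValueError("empty training set")
    spec = model.spec
    rng = np.random.default_rng(config.seed)
    images, boxes, ids = _prepare(train_samples, spec.input_size)
    if val_samples is not None:
        v_images, v_boxes, _ = _prepare(val_samples, spec.input_size)
    else:
        v_images, v_boxes = images, boxes

    targets_all = [
        assign_targets([b], spec, class_ids=[i]) for b, i in zip(boxes, ids)
    ]
    gt_arrays = [
        np.asarray([[b.cx, b.cy, b.w, b.h] for b in img_boxes], dtype=np.float32)
        for img_boxes in boxes
    ]

    params = list(model.parameters())
    decay_mask = [p.data.ndim == 4 for p in params]  # conv kernels only
    opt = nn.SGD(params, lr=config.initial_lr, momentum=config.momentum,
                 weight_decay=config.weight_decay, decay_mask=decay_mask)

    ckpt_dir = Path(checkpoint_dir) if checkpoint_dir is not None else None
    if ckpt_dir is not None:
        ckpt_dir.mkdir(parents=True, exist_ok=True)

    log = TrainLog()
    n = len(images)
    model.train()
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        epoch_loss = 0.0
        comp_sum = {"coord": 0.0, "obj": 0.0, "cls": 0.0}
        n_batches = 0
        t0 = time.time()
        for lo in range(0, n, config.batch_size):
            idx = order[lo : lo + config.batch_size]
            x = np.stack([images[i] for i in idx])
            tgt = _stack_targets([targets_all[i] for i in idx], spec)
            raw = model(x)
            l, comps = loss(raw, tgt, spec, weights=config.loss_weights,
                            gt_boxes=[gt_arrays[i] for i in idx])
            opt.zero_grad()
            l.backward()
            opt.step()
            epoch_loss += float(l.data)
            for k in comp_sum:
                comp_sum[k] += comps[k]
            n_batches += 1
        row = {
            "epoch": epoch,
            "loss": epoch_loss / n_batches,
            **{f"loss_{k}": v / n_batches for k, v in comp_sum.items()},
            "seconds": time.time() - t0,
        }
        if epoch % config.eval_every == 0 or epoch == config.epochs:
            row.update(_epoch_metrics(model, v_images, v_boxes, config))
        log.rows.append(row)
        if ckpt_dir is not None:
            path = ckpt_dir / f"epoch_{epoch:04d}.npz"
            save_checkpoint(model, path, epoch)
            log.checkpoints.append(path)
        if verbose:
            print(f"[epoch {epoch}] " + " ".join(f"{k}={v:.4g}" for k, v in row.items()
                                                 if k != "epoch"))
        if (
            config.early_stop_map is not None
            and row.get("map", 0.0) >= config.early_stop_map
        ):
            break
    return log


def _stack_targets(per_image: list[dict], spec: ArchitectureSpec) -> dict:
    out = {}
    for s in spec.head_scales:
        out[s] = {
            key: np.concatenate([t[s][key] for t in per_image], axis=0)
            for key in ("t_box", "obj", "noobj", "cls")
        }
    return out


def select_best_checkpoint(log: TrainLog | pd.DataFrame) -> int:
    """Epoch with the highest validation F1; ties broken by mAP, then by
    the later epoch.  Returns the 1-based epoch index."""
    frame = log.to_frame() if isinstance(log, TrainLog) else log
    frame = frame.dropna(subset=["f1"]) if "f1" in frame else frame
    if frame.empty or "f1" not in frame:
        raise ValueError("no evaluated epochs in the log")
    ranked = frame.sort_values(["f1", "map", "epoch"], ascending=False, kind="stable")
    return int(ranked.iloc[0]["epoch"])
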