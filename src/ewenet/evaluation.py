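"""Detection matching and the precision/recall/F1/AP metric stack.

With TP the correctly detected mounting events, FP the spurious
detections and FN the missed events:

    P  = TP / (TP + FP)
    R  = TP / (TP + FN)
    F1 = 2 P R / (P + R)

AP is the area under the precision–recall curve traced by sweeping the
confidence ranking (all-point interpolation of the precision envelope),
and mAP is its mean over classes — with a single behaviour class AP and
mAP coincide.

Matching is greedy and one-to-one: predictions are visited in descending
confidence and claim the best still-unmatched ground truth with IOU at or
above the matching threshold (0.5, the PASCAL convention, by default);
duplicate detections of one animal count as false positives.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .geometry import BoundingBox, PredictionBox, iou_corners

__all__ = [
    "MatchResult",
    "EvalReport",
    "match",
    "precision_recall_f1",
    "average_precision",
    "mean_average_precision",
    "threshold_sweep",
    "evaluate",
]


@dataclass
class MatchResult:
    """TP/FP/FN tallies plus the matched (prediction, gt, IOU) pairs."""

    tp: int
    fp: int
    fn: int
    pairs: list[tuple[int, int, float]] = field(default_factory=list)


def match(
    predictions: Sequence[PredictionBox],
    ground_truth: Sequence[BoundingBox],
    iou_threshold: float = 0.5,
    gt_class_ids: Sequence[int] | None = None,
) -> MatchResult:
    """Greedy one-to-one matching by descending confidence."""
    gt_ids = list(gt_class_ids) if gt_class_ids is not None else [0] * len(ground_truth)
    order = sorted(range(len(predictions)), key=lambda i: -predictions[i].c)
    matched_gt: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for pi in order:
        pred = predictions[pi]
        best_j, best_iou = -1, 0.0
        for j, g in enumerate(ground_truth):
            if j in matched_gt or gt_ids[j] != pred.class_id:
                continue
            iou = iou_corners(pred.box, g)
            if iou > best_iou:
                best_j, best_iou = j, iou
        if best_j >= 0 and best_iou >= iou_threshold:
            matched_gt.add(best_j)
            pairs.append((pi, best_j, best_iou))
    tp = len(pairs)
    return MatchResult(
        tp=tp, fp=len(predictions) - tp, fn=len(ground_truth) - tp, pairs=pairs
    )


def precision_recall_f1(m: MatchResult) -> tuple[float, float, float]:
    """(P, R, F1) with the zero-denominator conventions P=R=F1=0."""
    p = m.tp / (m.tp + m.fp) if m.tp + m.fp > 0 else 0.0
    r = m.tp / (m.tp + m.fn) if m.tp + m.fn > 0 else 0.0
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return p, r, f1


def _tp_flags(
    predictions: Sequence[Sequence[PredictionBox]],
    ground_truth: Sequence[Sequence[BoundingBox]],
    iou_threshold: float,
    class_id: int,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Confidence-sorted TP/FP flags over a whole dataset, one class."""
    confs: list[float] = []
    keys: list[tuple[int, int]] = []  # (image, prediction index)
    for i, preds in enumerate(predictions):
        for j, p in enumerate(preds):
            if p.class_id == class_id:
                confs.append(p.c)
                keys.append((i, j))
    n_gt = sum(1 for gts in ground_truth for _ in gts)
    order = np.argsort(-np.asarray(confs)) if confs else np.array([], dtype=int)
    matched: list[set[int]] = [set() for _ in ground_truth]
    flags = np.zeros(len(order), dtype=bool)
    for rank, oi in enumerate(order):
        img, j = keys[oi]
        pred = predictions[img][j]
        best_g, best_iou = -1, 0.0
        for g, gt_box in enumerate(ground_truth[img]):
            if g in matched[img]:
                continue
            iou = iou_corners(pred.box, gt_box)
            if iou > best_iou:
                best_g, best_iou = g, iou
        if best_g >= 0 and best_iou >= iou_threshold:
            matched[img].add(best_g)
            flags[rank] = True
    sorted_conf = np.asarray([confs[i] for i in order])
    return flags, sorted_conf, n_gt


def average_precision(
    predictions: Sequence[Sequence[PredictionBox]],
    ground_truth: Sequence[Sequence[BoundingBox]],
    iou_threshold: float = 0.5,
    class_id: int = 0,
) -> float:
    """Area under the precision envelope of the P–R curve.

    Predictions are ranked by confidence across the whole dataset; at
    every cut the cumulative precision and recall give one curve point,
    and the integral uses all-point interpolation (the running maximum of
    precision to the right).
    """
    if not any(len(g) for g in ground_truth):
        raise ValueError("average precision is undefined without ground-truth boxes")
    flags, _, n_gt = _tp_flags(predictions, ground_truth, iou_threshold, class_id)
    if flags.size == 0:
        return 0.0
    tp_cum = np.cumsum(flags)
    fp_cum = np.cumsum(~flags)
    recall = tp_cum / n_gt
    precision = tp_cum / (tp_cum + fp_cum)
    # precision envelope, then sum rectangle areas between recall steps
    env = np.maximum.accumulate(precision[::-1])[::-1]
    prev_r = 0.0
    ap = 0.0
    for r, p in zip(recall, env):
        ap += (r - prev_r) * p
        prev_r = r
    return float(ap)


def mean_average_precision(
    predictions: Sequence[Sequence[PredictionBox]],
    ground_truth: Sequence[Sequence[BoundingBox]],
    iou_threshold: float = 0.5,
    class_ids: Sequence[int] = (0,),
    gt_class_ids: Sequence[Sequence[int]] | None = None,
) -> float:
    """Mean AP over classes; equals AP when there is a single class."""
    aps = []
    for cid in class_ids:
        if gt_class_ids is None:
            gts = ground_truth
        else:
            gts = [
                [g for g, gc in zip(gimg, cimg) if gc == cid]
                for gimg, cimg in zip(ground_truth, gt_class_ids)
            ]
        aps.append(average_precision(predictions, gts, iou_threshold, cid))
    return float(np.mean(aps))


@dataclass
class EvalReport:
    """Headline metrics at one confidence threshold plus the sweep table."""

    precision: float
    recall: float
    f1: float
    ap: float
    map: float
    conf_threshold: float
    iou_threshold: float
    sweep: list[tuple[float, float, float, float]] = field(default_factory=list)
    # each row: (threshold, P, R, F1)

    def as_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "ap": self.ap,
            "map": self.map,
            "conf_threshold": self.conf_threshold,
            "iou_threshold": self.iou_threshold,
            "sweep": [list(row) for row in self.sweep],
        }


def threshold_sweep(
    predictions: Sequence[Sequence[PredictionBox]],
    ground_truth: Sequence[Sequence[BoundingBox]],
    thresholds: Sequence[float],
    iou_threshold: float = 0.5,
) -> list[tuple[float, float, float, float]]:
    """(threshold, P, R, F1) rows over an ascending confidence grid.

    On a fixed prediction set, raising the confidence threshold discards
    low-confidence detections, so precision is non-decreasing and recall
    non-increasing along the sweep.
    """
    if list(thresholds) != sorted(thresholds):
        raise ValueError("thresholds must be ascending")
    rows = []
    for thr in thresholds:
        tp = fp = fn = 0
        for preds, gts in zip(predictions, ground_truth):
            keep = [p for p in preds if p.c >= thr]
            m = match(keep, gts, iou_threshold)
            tp += m.tp
            fp += m.fp
            fn += m.fn
        p, r, f1 = precision_recall_f1(MatchResult(tp=tp, fp=fp, fn=fn))
        rows.append((float(thr), p, r, f1))
    return rows


def evaluate(
    predictions: Sequence[Sequence[PredictionBox]],
    ground_truth: Sequence[Sequence[BoundingBox]],
    conf_threshold: float = 0.5,
    iou_threshold: float = 0.5,
    sweep_grid: Sequence[float] | None = None,
) -> EvalReport:
    """Full report: P/R/F1 at the working threshold, AP/mAP, sweep table."""
    if sweep_grid is None:
        sweep_grid = [round(0.05 * i, 2) for i in range(21)]
    tp = fp = fn = 0
    for preds, gts in zip(predictions, ground_truth):
        keep = [p for p in preds if p.c >= conf_threshold]
        m = match(keep, gts, iou_threshold)
        tp += m.tp
        fp += m.fp
        fn += m.fn
    p, r, f1 = precision_recall_f1(MatchResult(tp=tp, fp=fp, fn=fn))
    ap = average_precision(predictions, ground_truth, iou_threshold)
    return EvalReport(
        precision=p,
        recall=r,
        f1=f1,
        ap=ap,
        map=ap,  # single behaviour class
        conf_threshold=conf_threshold,
        iou_threshold=iou_threshold,
        sweep=threshold_sweep(predictions, ground_truth, sweep_grid, iou_threshold),
    )
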