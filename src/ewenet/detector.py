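"""A scikit-learn-style front door to the whole pipeline.

:class:`MountingDetector` bundles anchor clustering, letterboxing, the
four-head network, the SGD loop and decoding behind the familiar
``fit`` / ``predict`` / ``score`` protocol so the detector composes with
sklearn model selection.  ``X`` is a sequence of RGB uint8 images (any
consistent source resolution); ``y`` is a sequence of per-image box lists.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .anchors import AnchorSet, IoUKMeans, mounting_anchor_set
from .geometry import BoundingBox, PredictionBox
from .imaging import forward_boxes, letterbox_params
from .model import ArchitectureSpec, LossWeights, build_model
from .training import Sample, TrainConfig, predict_images, train
from .evaluation import mean_average_precision

__all__ = ["MountingDetector"]


class MountingDetector(BaseEstimator):
    """Four-scale mounting-behaviour detector with a fit/predict surface.

    Parameters mirror :class:`ArchitectureSpec` and :class:`TrainConfig`.
    When ``anchors`` is None and the training labels supply at least 12
    distinct shapes, a fresh 12-anchor set is clustered from them with
    :class:`IoUKMeans`; otherwise the surveillance anchor set is rescaled
    to the input resolution.

    Attributes (set by ``fit``)
    ---------------------------
    spec_ : ArchitectureSpec
    model_ : FourScaleDetector
    anchors_ : AnchorSet
    log_ : TrainLog
    """

    def __init__(
        self,
        input_size: int = 416,
        stage_widths: tuple = (64, 128, 256, 512, 1024),
        residual_counts: tuple = (1, 2, 8, 8, 6),
        num_classes: int = 1,
        anchors: AnchorSet | None = None,
        epochs: int = 100,
        batch_size: int = 10,
        initial_lr: float = 0.001,
        momentum: float = 0.9,
        weight_decay: float = 0.0005,
        conf_threshold: float = 0.5,
        nms_iou: float = 0.45,
        coord_weight: float = 5.0,
        early_stop_map: float | None = None,
        eval_every: int = 1,
        seed: int = 0,
    ):
        self.input_size = input_size
        self.stage_widths = stage_widths
        self.residual_counts = residual_counts
        self.num_classes = num_classes
        self.anchors = anchors
        self.epochs = epochs
        self.batch_size = batch_size
        self.initial_lr = initial_lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.conf_threshold = conf_threshold
        self.nms_iou = nms_iou
        self.coord_weight = coord_weight
        self.early_stop_map = early_stop_map
        self.eval_every = eval_every
        self.seed = seed

    def _cluster_anchors(self, X, y) -> AnchorSet:
        samples = []
        for img, boxes in zip(X, y):
            h, w = np.asarray(img).shape[:2]
            params = letterbox_params((w, h), (self.input_size, self.input_size))
            for b in forward_boxes(boxes, params):
                samples.append((b.w / self.input_size, b.h / self.input_size))
        arr = np.asarray(samples)
        if np.unique(arr, axis=0).shape[0] >= 12:
            km = IoUKMeans(n_clusters=12, random_state=self.seed).fit(arr)
            return km.anchor_set(input_size=self.input_size)
        return mounting_anchor_set().rescaled(self.input_size)

    def fit(self, X: Sequence[np.ndarray], y: Sequence[Sequence[BoundingBox]],
            X_val=None, y_val=None, checkpoint_dir=None, verbose: bool = False):
        if len(X) != len(y):
            raise ValueError(f"X and y lengths differ: {len(X)} vs {len(y)}")
        anchors = self.anchors if self.anchors is not None else self._cluster_anchors(X, y)
        self.anchors_ = anchors.rescaled(self.input_size)
        self.spec_ = ArchitectureSpec(
            input_size=self.input_size,
            residual_counts=tuple(self.residual_counts),
            stage_widths=tuple(self.stage_widths),
            num_classes=self.num_classes,
            anchors=self.anchors_,
        )
        self.model_ = build_model(self.spec_, seed=self.seed)
        config = TrainConfig(
            batch_size=self.batch_size,
            initial_lr=self.initial_lr,
            weight_decay=self.weight_decay,
            momentum=self.momentum,
            epochs=self.epochs,
            seed=self.seed,
            conf_threshold=self.conf_threshold,
            nms_iou=self.nms_iou,
            eval_every=self.eval_every,
            early_stop_map=self.early_stop_map,
            loss_weights=LossWeights(coord=self.coord_weight),
        )
        train_samples = [
            Sample(image=np.asarray(img), boxes=tuple(b)) for img, b in zip(X, y)
        ]
        val_samples = None
        if X_val is not None and y_val is not None:
            val_samples = [
                Sample(image=np.asarray(img), boxes=tuple(b))
                for img, b in zip(X_val, y_val)
            ]
        self.log_ = train(self.model_, train_samples, config,
                          val_samples=val_samples, checkpoint_dir=checkpoint_dir,
                          verbose=verbose)
        return self

    def predict(
        self, X: Sequence[np.ndarray], conf_threshold: float | None = None
    ) -> list[list[PredictionBox]]:
        """Detections per image, in the source pixel frame, NMS applied."""
        check_is_fitted(self, "model_")
        thr = self.conf_threshold if conf_threshold is None else conf_threshold
        return predict_images(
            self.model_, [np.asarray(x) for x in X],
            conf_threshold=thr, nms_iou=self.nms_iou,
            batch_size=max(1, self.batch_size),
        )

    def score(self, X, y) -> float:
        """Mean average precision at IOU 0.5 (identical to AP: one class)."""
        preds = self.predict(X, conf_threshold=0.01)
        return mean_average_precision(preds, [list(b) for b in y])
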