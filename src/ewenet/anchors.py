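"""Anchor-box clustering under the 1 - IOU distance.

One-stage detectors predict offsets against a fixed set of prior
width/height pairs ("anchor boxes").  Priors tuned to a generic benchmark
match barn-surveillance mounting boxes poorly, so the anchor set is
re-derived by K-means++ clustering of the label-box dimensions, with the
shape IOU (co-centred width/height overlap) as similarity: the distance
between a label box ``q`` and a cluster centre ``p`` is ``1 - IOU(q, p)``
and the clustering objective is

    f = sum_q (1 - max_p IOU(q, p))

minimised over centre sets.  Twelve anchors are used, three per detection
scale; the finest 104x104 grid receives the smallest triple so the heads
specialise from distant (small) to near (large) animals.

:class:`IoUKMeans` follows the scikit-learn estimator protocol
(``fit`` / ``predict``, ``cluster_centers_``, ``inertia_``) so it can sit
in sklearn pipelines; the module-level functions are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_is_fitted

from .geometry import WHPair

__all__ = [
    "IoUKMeans",
    "ClusterState",
    "AnchorSet",
    "kmeanspp_init",
    "cluster",
    "objective",
    "avg_iou",
    "k_sweep",
    "scale_and_round",
    "assign_to_layers",
    "MOUNTING_CLUSTER_CENTERS",
    "MOUNTING_ANCHORS_416",
    "MOUNTING_LAYER_MAP",
    "HEAD_SCALES",
]

#: Output grid sizes of the four detection heads at 416x416 input, finest first.
HEAD_SCALES: tuple[int, ...] = (104, 52, 26, 13)

#: Normalized cluster-centre coordinates obtained on the ewe-mounting
#: label boxes (k = 12), in the published order.
MOUNTING_CLUSTER_CENTERS: tuple[tuple[float, float], ...] = (
    (0.045313, 0.081250),
    (0.046094, 0.140972),
    (0.074219, 0.118056),
    (0.095313, 0.140972),
    (0.068359, 0.195139),
    (0.122656, 0.194444),
    (0.074414, 0.282639),
    (0.098437, 0.283333),
    (0.148437, 0.247222),
    (0.127734, 0.314583),
    (0.173828, 0.336805),
    (0.221094, 0.294444),
)

#: The 12 anchors above scaled to a 416-pixel input and rounded.
MOUNTING_ANCHORS_416: tuple[tuple[int, int], ...] = (
    (19, 34), (19, 59), (31, 49),
    (40, 59), (28, 81), (51, 81),
    (31, 118), (41, 118), (62, 103),
    (53, 131), (72, 140), (92, 122),
)

#: Published triple-per-scale assignment (finest grid gets the smallest boxes).
MOUNTING_LAYER_MAP: dict[int, tuple[tuple[int, int], ...]] = {
    104: ((19, 34), (19, 59), (31, 49)),
    52: ((40, 59), (28, 81), (51, 81)),
    26: ((31, 118), (41, 118), (62, 103)),
    13: ((53, 131), (72, 140), (92, 122)),
}


def _as_array(samples: Sequence[WHPair] | np.ndarray) -> np.ndarray:
    if isinstance(samples, np.ndarray):
        arr = np.asarray(samples, dtype=float)
    else:
        arr = np.array([[s.w, s.h] for s in samples], dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ValueError(f"expected an (n, 2) array of width/height pairs, got {arr.shape}")
    if arr.size == 0:
        raise ValueError("empty sample set")
    if np.any(arr <= 0):
        raise ValueError("width/height samples must be positive")
    return arr


def _iou_matrix(samples: np.ndarray, centers: np.ndarray) -> np.ndarray:
    """Pairwise shape IOU, shape (n_samples, n_centers)."""
    inter = np.minimum(samples[:, None, 0], centers[None, :, 0]) * np.minimum(
        samples[:, None, 1], centers[None, :, 1]
    )
    union = (samples[:, 0] * samples[:, 1])[:, None] + (
        centers[:, 0] * centers[:, 1]
    )[None, :] - inter
    return inter / union


@dataclass
class ClusterState:
    """Result of one clustering run: centres, assignments, objective value."""

    centers: np.ndarray  # (k, 2)
    labels: np.ndarray  # (n,)
    objective: float
    n_iter: int
    objective_history: list[float]

    def as_whpairs(self) -> list[WHPair]:
        return [WHPair(float(w), float(h)) for w, h in self.centers]


@dataclass(frozen=True)
class AnchorSet:
    """Twelve pixel anchors with their per-scale assignment.

    ``layer_map`` maps each head grid size (at the reference input) to an
    ordered triple of ``(w, h)`` anchors.  ``input_size`` records the input
    resolution at which the pixel dimensions are expressed so the set can
    be rescaled for other input sizes.
    """

    anchors: tuple[tuple[int, int], ...]
    layer_map: dict[int, tuple[tuple[int, int], ...]]
    input_size: int = 416

    def __post_init__(self) -> None:
        if len(self.anchors) != 12:
            raise ValueError(f"an AnchorSet holds exactly 12 anchors, got {len(self.anchors)}")
        for scale, triple in self.layer_map.items():
            if len(triple) != 3:
                raise ValueError(f"scale {scale} must receive exactly 3 anchors")
        for w, h in self.anchors:
            if w <= 0 or h <= 0:
                raise ValueError("anchor dimensions must be positive")

    @property
    def scales(self) -> tuple[int, ...]:
        return tuple(self.layer_map.keys())

    def ordered_anchors(self) -> list[tuple[float, float]]:
        """Anchors flattened in layer order (finest head first)."""
        return [wh for scale in self.layer_map for wh in self.layer_map[scale]]

    def rescaled(self, input_size: int) -> "AnchorSet":
        """Express the same relative anchors at a different input resolution."""
        if input_size == self.input_size:
            return self
        f = input_size / self.input_size

        def _s(wh: tuple[int, int]) -> tuple[int, int]:
            return (max(1, round(wh[0] * f)), max(1, round(wh[1] * f)))

        new_map = {
            max(1, round(k * f)): tuple(_s(wh) for wh in v)
            for k, v in self.layer_map.items()
        }
        return AnchorSet(
            anchors=tuple(_s(wh) for wh in self.anchors),
            layer_map=new_map,
            input_size=input_size,
        )


#: The published anchor assignment as a ready-made AnchorSet.
def mounting_anchor_set() -> AnchorSet:
    return AnchorSet(anchors=MOUNTING_ANCHORS_416, layer_map=dict(MOUNTING_LAYER_MAP))


class IoUKMeans(ClusterMixin, BaseEstimator):
    """K-means++ clustering of box dimensions under the 1 - IOU distance.

    Parameters
    ----------
    n_clusters : int, default=12
        Number of anchor centres ``k``.
    n_init : int, default=10
        Independent K-means++ restarts; the run with the lowest objective
        is kept, which tames the seeding sensitivity of K-means.
    max_iter : int, default=300
        Iteration cap per restart.
    tol : float, default=1e-6
        Stop when the objective improves by less than this between
        iterations (assignment fixed-points also stop the run).
    random_state : int or None
        Seed for centre initialisation.

    Attributes
    ----------
    cluster_centers_ : ndarray of shape (n_clusters, 2)
        Width/height centres, sorted by ascending area (ties by width).
    labels_ : ndarray of shape (n_samples,)
        Index of the closest centre for each training sample.
    inertia_ : float
        Final value of the objective sum_q (1 - max_p IOU).
    avg_iou_ : float
        Mean best IOU of the training samples, ``1 - inertia_ / n``.
    n_iter_ : int
        Iterations used by the winning restart.
    """

    def __init__(
        self,
        n_clusters: int = 12,
        n_init: int = 10,
        max_iter: int = 300,
        tol: float = 1e-6,
        random_state: int | None = None,
    ):
        self.n_clusters = n_clusters
        self.n_init = n_init
        self.max_iter = max_iter
        self.tol = tol
        self.random_state = random_state

    def fit(self, X, y=None) -> "IoUKMeans":
        X = _as_array(X)
        n_distinct = np.unique(X, axis=0).shape[0]
        if self.n_clusters > n_distinct:
            raise ValueError(
                f"n_clusters={self.n_clusters} exceeds the {n_distinct} distinct samples"
            )
        rng = np.random.default_rng(self.random_state)
        best: ClusterState | None = None
        for _ in range(self.n_init):
            state = _cluster_once(X, self.n_clusters, rng, self.max_iter, self.tol)
            if best is None or state.objective < best.objective:
                best = state
        assert best is not None
        order = np.lexsort((best.centers[:, 0], best.centers[:, 0] * best.centers[:, 1]))
        remap = np.empty(self.n_clusters, dtype=int)
        remap[order] = np.arange(self.n_clusters)
        self.cluster_centers_ = best.centers[order]
        self.labels_ = remap[best.labels]
        self.inertia_ = best.objective
        self.avg_iou_ = 1.0 - best.objective / X.shape[0]
        self.n_iter_ = best.n_iter
        self.objective_history_ = best.objective_history
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "cluster_centers_")
        X = _as_array(X)
        return np.argmax(_iou_matrix(X, self.cluster_centers_), axis=1)

    def transform(self, X) -> np.ndarray:
        """Distance matrix 1 - IOU to each fitted centre."""
        check_is_fitted(self, "cluster_centers_")
        X = _as_array(X)
        return 1.0 - _iou_matrix(X, self.cluster_centers_)

    def anchor_set(self, input_size: int = 416) -> AnchorSet:
        """Scale the fitted centres to pixels and assign them to the four heads."""
        check_is_fitted(self, "cluster_centers_")
        if self.n_clusters != 12:
            raise ValueError("an AnchorSet needs exactly 12 clusters")
        pairs = [
            scale_and_round(WHPair(float(w), float(h)), input_size)
            for w, h in self.cluster_centers_
        ]
        return assign_to_layers([(p.w, p.h) for p in pairs], input_size=input_size)


def _kmeanspp_seed(X: np.ndarray, k: int, rng: np.random.Generator) -> np.ndarray:
    """K-means++ seeding: first centre uniform, then d(x)^2-proportional."""
    n = X.shape[0]
    centers = np.empty((k, 2), dtype=float)
    centers[0] = X[rng.integers(n)]
    if k == 1:
        return centers
    best_iou = _iou_matrix(X, centers[:1])[:, 0]
    for j in range(1, k):
        d2 = (1.0 - best_iou) ** 2
        total = d2.sum()
        if total <= 0:  # all samples coincide with a chosen centre
            idx = rng.integers(n)
        else:
            idx = rng.choice(n, p=d2 / total)
        centers[j] = X[idx]
        best_iou = np.maximum(best_iou, _iou_matrix(X, centers[j : j + 1])[:, 0])
    return centers


def _cluster_once(
    X: np.ndarray, k: int, rng: np.random.Generator, max_iter: int, tol: float
) -> ClusterState:
    centers = _kmeanspp_seed(X, k, rng)
    labels = np.argmax(_iou_matrix(X, centers), axis=1)
    history: list[float] = []
    prev_obj = np.inf
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        # update: per-cluster arithmetic mean of member dimensions, with a
        # monotone safeguard — the mean minimises squared distance, not
        # 1-IOU, so it is accepted only when it does not raise the
        # within-cluster cost (keeps the objective non-increasing)
        for j in range(k):
            members = X[labels == j]
            if members.shape[0]:
                cand = members.mean(axis=0)
                old_cost = np.sum(1.0 - _iou_matrix(members, centers[j : j + 1]))
                new_cost = np.sum(1.0 - _iou_matrix(members, cand[None, :]))
                if new_cost <= old_cost:
                    centers[j] = cand
        iou = _iou_matrix(X, centers)
        new_labels = np.argmax(iou, axis=1)
        obj = float(np.sum(1.0 - iou.max(axis=1)))
        history.append(obj)
        converged = np.array_equal(new_labels, labels) or prev_obj - obj < tol
        labels = new_labels
        prev_obj = obj
        if converged:
            break
    obj = float(np.sum(1.0 - _iou_matrix(X, centers).max(axis=1)))
    return ClusterState(centers=centers, labels=labels, objective=obj,
                        n_iter=n_iter, objective_history=history)


# ---------------------------------------------------------------------------
# functional wrappers


def kmeanspp_init(
    samples: Sequence[WHPair] | np.ndarray, k: int, seed: int | None = None
) -> list[WHPair]:
    """Draw k initial centres with the K-means++ rule (deterministic per seed)."""
    X = _as_array(samples)
    if k > np.unique(X, axis=0).shape[0]:
        raise ValueError(f"k={k} exceeds the number of distinct samples")
    centers = _kmeanspp_seed(X, k, np.random.default_rng(seed))
    return [WHPair(float(w), float(h)) for w, h in centers]


def cluster(
    samples: Sequence[WHPair] | np.ndarray,
    k: int,
    seed: int | None = None,
    max_iter: int = 300,
    tol: float = 1e-6,
    n_init: int = 10,
) -> ClusterState:
    """Cluster width/height samples; returns the best of ``n_init`` restarts."""
    X = _as_array(samples)
    est = IoUKMeans(n_clusters=k, n_init=n_init, max_iter=max_iter, tol=tol,
                    random_state=seed).fit(X)
    return ClusterState(
        centers=est.cluster_centers_,
        labels=est.labels_,
        objective=est.inertia_,
        n_iter=est.n_iter_,
        objective_history=est.objective_history_,
    )


def objective(
    samples: Sequence[WHPair] | np.ndarray, centers: Sequence[WHPair] | np.ndarray
) -> float:
    """f = sum over samples of (1 - best IOU to any centre)."""
    X = _as_array(samples)
    C = _as_array(centers)
    return float(np.sum(1.0 - _iou_matrix(X, C).max(axis=1)))


def avg_iou(
    samples: Sequence[WHPair] | np.ndarray, centers: Sequence[WHPair] | np.ndarray
) -> float:
    """Mean best IOU over samples; equals ``1 - objective/n``."""
    X = _as_array(samples)
    C = _as_array(centers)
    return float(np.mean(_iou_matrix(X, C).max(axis=1)))


def k_sweep(
    samples: Sequence[WHPair] | np.ndarray,
    k_values: Sequence[int],
    seed: int | None = None,
    n_init: int = 10,
) -> list[tuple[int, float]]:
    """Average best-IOU as a function of k, for choosing the anchor count.

    The curve rises with k and flattens once extra centres stop adding
    shape diversity; the operating point is taken where it levels off.
    """
    if list(k_values) != sorted(k_values):
        raise ValueError("k_values must be sorted ascending")
    X = _as_array(samples)
    out = []
    for k in k_values:
        state = cluster(X, k, seed=seed, n_init=n_init)
        out.append((k, 1.0 - state.objective / X.shape[0]))
    return out


def scale_and_round(center: WHPair, input_size: int) -> WHPair:
    """Normalized cluster centre -> integer pixel anchor at the given input size."""
    if not (0 < center.w <= 1 and 0 < center.h <= 1):
        raise ValueError("scale_and_round expects a normalized centre in (0, 1]")
    return WHPair(float(round(center.w * input_size)), float(round(center.h * input_size)))


def assign_to_layers(
    anchors: Sequence[tuple[float, float]] | Sequence[WHPair],
    input_size: int = 416,
) -> AnchorSet:
    """Sort 12 anchors by ascending area (ties by width) and hand triples to
    the heads, finest grid first.

    The finest (stride-4) grid resolves the smallest, most distant animals,
    so it receives the smallest anchor triple.
    """
    pairs = [
        (float(a.w), float(a.h)) if isinstance(a, WHPair) else (float(a[0]), float(a[1]))
        for a in anchors
    ]
    if len(pairs) != 12:
        raise ValueError(f"expected 12 anchors, got {len(pairs)}")
    ordered = sorted(pairs, key=lambda wh: (wh[0] * wh[1], wh[0]))
    as_int = [(round(w), round(h)) for w, h in ordered]
    stride_scales = [input_size // s for s in (4, 8, 16, 32)]
    layer_map = {
        scale: tuple(as_int[3 * i : 3 * i + 3]) for i, scale in enumerate(stride_scales)
    }
    return AnchorSet(anchors=tuple(as_int), layer_map=layer_map, input_size=input_size)
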