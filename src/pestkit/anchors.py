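"""Anchor-box optimization by K-means clustering of label dimensions.

Single-stage detectors predict offsets from prior (width, height)
anchor boxes; anchors matched to the dataset's actual box-size
distribution improve both localization and speed.  This module
clusters the (w, h) pairs of every labeled box with Lloyd's algorithm
and k-means++ seeding, under either of two metrics:

* ``"1-iou"`` (default, the YOLO-family convention): the distance
  between two (w, h) boxes co-anchored at the origin is 1 minus their
  IoU, making the clustering scale-aware in the way detector matching
  is.
* ``"euclidean"``: plain squared-distance K-means for comparison.

The nine fitted anchors are sorted by area and grouped into three
triplets, one per detection scale (small, medium, large objects).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .dataset import AnnotatedImage, ImageAnnotation

__all__ = [
    "AnchorSet",
    "KMeansConfig",
    "collect_box_dims",
    "fit_anchors",
    "group_anchors",
]


@dataclass(frozen=True)
class AnchorSet:
    """Nine (w, h) anchors grouped into three ascending-area triplets."""

    anchors: tuple[tuple[float, float], ...]
    groups: tuple[tuple[tuple[float, float], ...], ...]

    def __post_init__(self) -> None:
        if len(self.anchors) != 9 or tuple(len(g) for g in self.groups) != (3, 3, 3):
            raise ValueError("an AnchorSet holds exactly 9 anchors in 3 triplets")


@dataclass(frozen=True)
class KMeansConfig:
    k: int = 9
    metric: str = "1-iou"
    max_iter: int = 300
    tol: float = 1e-6
    n_init: int = 10  # k-means++ restarts; best final objective wins
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError(f"k must be >= 1, got {self.k}")
        if self.tol <= 0:
            raise ValueError(f"tol must be positive, got {self.tol}")
        if self.n_init < 1:
            raise ValueError(f"n_init must be >= 1, got {self.n_init}")
        if self.metric not in ("1-iou", "euclidean"):
            raise ValueError(f"metric must be '1-iou' or 'euclidean', got {self.metric!r}")


def collect_box_dims(
    dataset: Iterable[AnnotatedImage | ImageAnnotation],
) -> list[tuple[float, float]]:
    """One (width, height) pair per labeled box, in stable order.

    Raises ``ValueError`` on a dataset with no images.
    """
    dims: list[tuple[float, float]] = []
    n_images = 0
    for ann in dataset:
        n_images += 1
        for lb in ann.labels:
            dims.append((lb.box.width, lb.box.height))
    if n_images == 0:
        raise ValueError("empty dataset: no annotated images")
    return dims


def _pairwise_distance(dims: np.ndarray, centers: np.ndarray, metric: str) -> np.ndarray:
    """Distance matrix (n_points, n_centers)."""
    if metric == "euclidean":
        diff = dims[:, None, :] - centers[None, :, :]
        return np.sqrt((diff**2).sum(axis=2))
    # 1 - IoU of origin-anchored boxes
    inter = np.minimum(dims[:, None, 0], centers[None, :, 0]) * np.minimum(
        dims[:, None, 1], centers[None, :, 1]
    )
    union = dims[:, 0:1] * dims[:, 1:2] + (centers[:, 0] * centers[:, 1])[None, :] - inter
    return 1.0 - inter / union


def _kmeans_pp_init(
    dims: np.ndarray, k: int, metric: str, rng: np.random.Generator
) -> np.ndarray:
    """k-means++ seeding: spread initial centers by squared distance."""
    n = dims.shape[0]
    centers = [dims[rng.integers(n)]]
    for _ in range(1, k):
        d2 = _pairwise_distance(dims, np.array(centers), metric).min(axis=1) ** 2
        total = d2.sum()
        if total <= 0:
            centers.append(dims[rng.integers(n)])
            continue
        centers.append(dims[rng.choice(n, p=d2 / total)])
    return np.array(centers, dtype=float)


def fit_anchors(
    dims: Sequence[tuple[float, float]],
    cfg: KMeansConfig = KMeansConfig(),
    return_history: bool = False,
):
    """Cluster box dimensions with Lloyd's algorithm.

    Runs ``cfg.n_init`` k-means++ seedings and keeps the run with the
    lowest final objective (the usual guard against poor local
    optima).  Returns a 9-anchor :class:`AnchorSet` when
    ``cfg.k == 9``, else the raw (k, 2) center array sorted by area.
    With ``return_history=True`` also returns the best run's objective
    trace (mean squared euclidean distance, or mean 1-IoU distance,
    recorded after each assignment step).  Deterministic given
    (dims, cfg); empty clusters are re-seeded to the farthest point.
    """
    dims_arr = np.asarray(dims, dtype=float)
    if dims_arr.ndim != 2 or dims_arr.shape[1] != 2:
        raise ValueError(f"dims must be a sequence of (w, h) pairs, got {dims_arr.shape}")
    n = dims_arr.shape[0]
    if n < cfg.k:
        raise ValueError(f"need at least k={cfg.k} boxes, got {n}")

    rng = np.random.default_rng(cfg.seed)
    best_centers, best_history = None, None
    for _ in range(cfg.n_init):
        centers, history = _lloyd(dims_arr, cfg, rng)
        if best_history is None or history[-1] < best_history[-1]:
            best_centers, best_history = centers, history

    order = np.argsort(best_centers[:, 0] * best_centers[:, 1], kind="stable")
    centers = best_centers[order]
    result = group_anchors([tuple(c) for c in centers]) if cfg.k == 9 else centers
    if return_history:
        return result, best_history
    return result


def _lloyd(
    dims_arr: np.ndarray, cfg: KMeansConfig, rng: np.random.Generator
) -> tuple[np.ndarray, list[float]]:
    centers = _kmeans_pp_init(dims_arr, cfg.k, cfg.metric, rng)
    history: list[float] = []
    prev_centers = centers
    for _ in range(cfg.max_iter):
        dist = _pairwise_distance(dims_arr, centers, cfg.metric)
        nearest = dist.min(axis=1)
        # Lloyd objective: squared distance for euclidean, plain 1-IoU otherwise
        obj = float((nearest**2 if cfg.metric == "euclidean" else nearest).mean())
        if history and obj > history[-1] + 1e-12:
            # mean updates minimize the squared-euclidean objective only;
            # under 1-IoU the objective can rise — revert and stop there
            centers = prev_centers
            break
        history.append(obj)
        assign = dist.argmin(axis=1)
        new_centers = centers.copy()
        for j in range(cfg.k):
            members = dims_arr[assign == j]
            if len(members):
                new_centers[j] = members.mean(axis=0)
            else:
                new_centers[j] = dims_arr[nearest.argmax()]
        shift = np.abs(new_centers - centers).max()
        prev_centers = centers
        centers = new_centers
        if shift < cfg.tol:
            break
    return centers, history


def group_anchors(anchors: Sequence[tuple[float, float]]) -> AnchorSet:
    """Sort nine anchors by area and chunk into three scale triplets."""
    if len(anchors) != 9:
        raise ValueError(f"expected exactly 9 anchors, got {len(anchors)}")
    ordered = tuple(
        sorted(((float(w), float(h)) for w, h in anchors), key=lambda a: a[0] * a[1])
    )
    groups = (ordered[0:3], ordered[3:6], ordered[6:9])
    return AnchorSet(anchors=ordered, groups=groups)
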