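"""Anchor estimation by k-means++ over training-set box dimensions.

Anchor-based detectors are sensitive to the prior (w, h) pairs their heads
regress against; for small objects the stock priors are far too large, so
anchors are re-estimated from the data.  Boxes are clustered in (w, h)
space under the ``1 - IoU`` distance between a box and a centroid placed
at a common centre (the standard choice for anchor estimation, since it is
the quantity the assignment rule cares about); squared Euclidean distance
is available as an alternative.  Seeding follows k-means++ and refinement
is plain Lloyd iteration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AnchorSet", "cluster_anchors", "assign_to_heads", "anchor_iou_distance"]


@dataclass(frozen=True)
class AnchorSet:
    """k (w, h) anchors in input pixels, sorted by area ascending."""

    wh: tuple[tuple[float, float], ...]

    def __post_init__(self):
        for w, h in self.wh:
            if not (w > 0 and h > 0):
                raise ValueError("anchors must have positive dimensions")

    def __len__(self) -> int:
        return len(self.wh)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.wh, dtype=float)


def anchor_iou_distance(boxes: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    """(N, K) matrix of 1 - IoU between centre-aligned boxes and anchors."""
    b = np.asarray(boxes, dtype=float)[:, None, :]
    a = np.asarray(anchors, dtype=float)[None, :, :]
    inter = np.minimum(b[..., 0], a[..., 0]) * np.minimum(b[..., 1], a[..., 1])
    union = b[..., 0] * b[..., 1] + a[..., 0] * a[..., 1] - inter
    return 1.0 - inter / np.maximum(union, 1e-12)


def _euclidean_distance(boxes: np.ndarray, anchors: np.ndarray) -> np.ndarray:
    d = np.asarray(boxes)[:, None, :] - np.asarray(anchors)[None, :, :]
    return (d ** 2).sum(axis=-1)


def cluster_anchors(boxes, k: int = 9, seed: int = 0, *,
                    metric: str = "iou", max_iter: int = 300) -> AnchorSet:
    """Estimate ``k`` anchors from (w, h) box dimensions.

    Parameters
    ----------
    boxes : array-like of shape (N, 2)
        Box widths and heights, already rescaled to the training input size.
    k : number of anchors (three heads take three each, so 9 by default).
    seed : drives only the k-means++ sampling; the Lloyd refinement is
        deterministic given the seeding.
    metric : "iou" (1 - IoU at common centre, default) or "euclidean".
    """
    wh = np.asarray(boxes, dtype=float).reshape(-1, 2)
    if wh.shape[0] < k:
        raise ValueError(f"need at least {k} boxes to fit {k} anchors, got {wh.shape[0]}")
    if np.any(wh <= 0):
        raise ValueError("box dimensions must be positive")
    dist_fn = anchor_iou_distance if metric == "iou" else _euclidean_distance
    if metric not in ("iou", "euclidean"):
        raise ValueError("metric must be 'iou' or 'euclidean'")

    rng = np.random.default_rng(seed)

    # k-means++ seeding: first centre uniform, then proportional to the
    # squared distance (for the IoU metric, the distance itself is already
    # the natural weight and is used squared for stronger spreading).
    centers = np.empty((k, 2))
    centers[0] = wh[rng.integers(wh.shape[0])]
    closest = dist_fn(wh, centers[:1]).ravel()
    for i in range(1, k):
        weights = closest ** 2
        total = weights.sum()
        if total <= 0:
            centers[i:] = centers[0]
            break
        centers[i] = wh[rng.choice(wh.shape[0], p=weights / total)]
        closest = np.minimum(closest, dist_fn(wh, centers[i:i + 1]).ravel())

    # Lloyd refinement: assign, re-centre, stop when assignments freeze.
    assign = np.full(wh.shape[0], -1)
    for _ in range(max_iter):
        d = dist_fn(wh, centers)
        new_assign = d.argmin(axis=1)
        if np.array_equal(new_assign, assign):
            break
        assign = new_assign
        for j in range(k):
            members = wh[assign == j]
            if members.size:
                centers[j] = members.mean(axis=0)

    order = np.argsort(centers[:, 0] * centers[:, 1], kind="stable")
    return AnchorSet(tuple((float(w), float(h)) for w, h in centers[order]))


def assign_to_heads(anchors: AnchorSet, num_heads: int = 3) -> tuple:
    """Group anchors into per-head triplets, smallest areas to the finest head.

    The nine anchors are sorted by area ascending (stable, so equal-area
    anchors keep input order) and split 3/3/3: indices 0-2 to the stride-4
    head, 3-5 to stride 8, 6-8 to stride 16.
    """
    arr = anchors.as_array()
    if len(arr) != 3 * num_heads:
        raise ValueError(f"expected {3 * num_heads} anchors, got {len(arr)}")
    order = np.argsort(arr[:, 0] * arr[:, 1], kind="stable")
    arr = arr[order]
    return tuple(tuple((float(w), float(h)) for w, h in arr[3 * i:3 * i + 3])
                 for i in range(num_heads))
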