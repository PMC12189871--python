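"""Axis-aligned bounding boxes and box geometry.

Boxes travel through the package in two interchangeable forms: the
:class:`BBox` dataclass for single annotated boxes, and ``(..., 4)`` float
arrays in ``(cx, cy, w, h)`` pixel order for vectorised geometry.  All
losses and metrics are built on the conversions and IoU kernels here.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "InvalidBoxError", "BBox", "Detection",
    "cxcywh_to_xyxy", "xyxy_to_cxcywh", "validate_boxes",
    "box_iou_aligned", "box_iou_matrix",
    "boxes_to_array", "detections_to_arrays",
]

EPS = 1e-7


class InvalidBoxError(ValueError):
    """A box with non-positive width or height."""


@dataclass(frozen=True)
class BBox:
    """Axis-aligned box: centre (cx, cy) and size (w, h) in pixels."""

    cx: float
    cy: float
    w: float
    h: float
    class_id: int | None = None

    def __post_init__(self):
        if not (self.w > 0 and self.h > 0):
            raise InvalidBoxError(f"non-positive box size {self.w}x{self.h}")

    @property
    def x1(self) -> float:
        return self.cx - self.w / 2

    @property
    def y1(self) -> float:
        return self.cy - self.h / 2

    @property
    def x2(self) -> float:
        return self.cx + self.w / 2

    @property
    def y2(self) -> float:
        return self.cy + self.h / 2

    @property
    def area(self) -> float:
        return self.w * self.h

    def to_array(self) -> np.ndarray:
        return np.array([self.cx, self.cy, self.w, self.h], dtype=float)

    @classmethod
    def from_xyxy(cls, x1: float, y1: float, x2: float, y2: float,
                  class_id: int | None = None) -> "BBox":
        return cls((x1 + x2) / 2, (y1 + y2) / 2, x2 - x1, y2 - y1, class_id)

    def shift(self, dx: float, dy: float) -> "BBox":
        return BBox(self.cx + dx, self.cy + dy, self.w, self.h, self.class_id)


@dataclass(frozen=True)
class Detection:
    """A predicted box with class and confidence, in frame coordinates."""

    box: BBox
    class_id: int
    confidence: float

    def shift(self, dx: float, dy: float) -> "Detection":
        return Detection(self.box.shift(dx, dy), self.class_id, self.confidence)


# ---------------------------------------------------------------------------
# array form
# ---------------------------------------------------------------------------

def boxes_to_array(boxes: Sequence[BBox]) -> np.ndarray:
    """Stack BBoxes into an (N, 5) array of (cx, cy, w, h, class_id)."""
    if not boxes:
        return np.zeros((0, 5), dtype=float)
    return np.array([[b.cx, b.cy, b.w, b.h,
                      -1 if b.class_id is None else b.class_id]
                     for b in boxes], dtype=float)


def detections_to_arrays(dets: Sequence[Detection]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Split detections into (N,4) cxcywh boxes, class ids and confidences."""
    if not dets:
        return (np.zeros((0, 4)), np.zeros(0, dtype=int), np.zeros(0))
    boxes = np.array([[d.box.cx, d.box.cy, d.box.w, d.box.h] for d in dets])
    cls = np.array([d.class_id for d in dets], dtype=int)
    conf = np.array([d.confidence for d in dets], dtype=float)
    return boxes, cls, conf


def validate_boxes(boxes: np.ndarray) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=float)
    if boxes.shape[-1] < 4:
        raise InvalidBoxError("boxes must have at least 4 components (cx,cy,w,h)")
    if boxes.size and not np.all(boxes[..., 2:4] > 0):
        raise InvalidBoxError("boxes with non-positive width or height")
    return boxes


def cxcywh_to_xyxy(boxes: np.ndarray) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=float)
    half = boxes[..., 2:4] / 2
    return np.concatenate([boxes[..., :2] - half, boxes[..., :2] + half], axis=-1)


def xyxy_to_cxcywh(boxes: np.ndarray) -> np.ndarray:
    boxes = np.asarray(boxes, dtype=float)
    wh = boxes[..., 2:4] - boxes[..., :2]
    return np.concatenate([(boxes[..., :2] + boxes[..., 2:4]) / 2, wh], axis=-1)


def box_iou_aligned(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Elementwise IoU of two broadcastable (..., 4) cxcywh box arrays."""
    a, b = validate_boxes(a), validate_boxes(b)
    ax, bx = cxcywh_to_xyxy(a), cxcywh_to_xyxy(b)
    iw = np.clip(np.minimum(ax[..., 2], bx[..., 2]) - np.maximum(ax[..., 0], bx[..., 0]), 0, None)
    ih = np.clip(np.minimum(ax[..., 3], bx[..., 3]) - np.maximum(ax[..., 1], bx[..., 1]), 0, None)
    inter = iw * ih
    union = a[..., 2] * a[..., 3] + b[..., 2] * b[..., 3] - inter
    return inter / np.maximum(union, EPS)


def box_iou_matrix(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """(N, M) IoU matrix between two cxcywh box sets."""
    a = np.asarray(a, dtype=float).reshape(-1, 4)
    b = np.asarray(b, dtype=float).reshape(-1, 4)
    if a.shape[0] == 0 or b.shape[0] == 0:
        return np.zeros((a.shape[0], b.shape[0]))
    return box_iou_aligned(a[:, None, :], b[None, :, :])
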