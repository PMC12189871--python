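"""Decoding raw head outputs into detections.

Standard anchor-based YOLO decoding: each head cell predicts, per anchor,
a box offset, an objectness logit and per-class logits.  With sigmoid
activations s(.), the box centre is ``(2 s(t_xy) - 0.5 + cell) * stride``
and the size ``(2 s(t_wh))^2 * anchor``, so a zero logit decodes to the
cell centre at anchor size.  Scores are objectness times class probability;
greedy per-class NMS removes duplicates.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .boxes import BBox, Detection, box_iou_matrix
from .nn import Tensor

__all__ = ["decode_head", "nms", "decode_predictions"]


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def decode_head(output: np.ndarray, anchors: Sequence[tuple[float, float]],
                stride: int, num_classes: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Decode one head's raw output for a batch.

    Returns (boxes, obj, cls): boxes ``(N, na, H, W, 4)`` in input pixels
    (cxcywh), objectness ``(N, na, H, W)`` and class probabilities
    ``(N, na, H, W, nc)``, all after sigmoid.
    """
    out = output.data if isinstance(output, Tensor) else np.asarray(output)
    n, c, h, w = out.shape
    na = len(anchors)
    no = 5 + num_classes
    if c != na * no:
        raise ValueError(f"head channels {c} != {na}x{no}")
    out = out.reshape(n, na, no, h, w).transpose(0, 1, 3, 4, 2)  # N,na,H,W,no
    sig = _sigmoid(out)
    gy, gx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    anc = np.asarray(anchors, dtype=float).reshape(1, na, 1, 1, 2)
    cx = (2.0 * sig[..., 0] - 0.5 + gx) * stride
    cy = (2.0 * sig[..., 1] - 0.5 + gy) * stride
    wh = np.maximum((2.0 * sig[..., 2:4]) ** 2 * anc, 1e-6)
    boxes = np.stack([cx, cy, wh[..., 0], wh[..., 1]], axis=-1)
    return boxes, sig[..., 4], sig[..., 5:]


def nms(boxes: np.ndarray, scores: np.ndarray, iou_thresh: float) -> np.ndarray:
    """Greedy non-maximum suppression; returns kept indices, best first."""
    order = np.argsort(-scores, kind="stable")
    keep: list[int] = []
    while order.size:
        i = order[0]
        keep.append(int(i))
        if order.size == 1:
            break
        rest = order[1:]
        ious = box_iou_matrix(boxes[i:i + 1], boxes[rest])[0]
        order = rest[ious <= iou_thresh]
    return np.array(keep, dtype=int)


def decode_predictions(outputs: Sequence, anchors: Sequence, strides: Sequence[int],
                       num_classes: int, conf_thresh: float = 0.25,
                       nms_iou: float = 0.45, max_det: int = 3000) -> list[list[Detection]]:
    """Turn raw head outputs into per-image detection lists.

    ``outputs`` is one tensor/array per head; ``anchors`` and ``strides``
    are aligned with it.  The detection score is objectness times class
    probability, thresholded at ``conf_thresh`` before per-class NMS at
    ``nms_iou``.
    """
    if len(outputs) != len(strides) or len(outputs) != len(anchors):
        raise ValueError("outputs, anchors and strides must align")
    if not outputs:
        return []
    n = (outputs[0].data if isinstance(outputs[0], Tensor) else outputs[0]).shape[0]
    all_boxes = [[] for _ in range(n)]
    all_scores = [[] for _ in range(n)]
    all_cls = [[] for _ in range(n)]
    for out, anc, stride in zip(outputs, anchors, strides):
        boxes, obj, cls = decode_head(out, anc, stride, num_classes)
        scores = obj[..., None] * cls                      # N,na,H,W,nc
        best_cls = scores.argmax(axis=-1)
        best_score = np.take_along_axis(scores, best_cls[..., None], axis=-1)[..., 0]
        for img in range(n):
            mask = best_score[img] > conf_thresh
            if not mask.any():
                continue
            all_boxes[img].append(boxes[img][mask])
            all_scores[img].append(best_score[img][mask])
            all_cls[img].append(best_cls[img][mask])

    results: list[list[Detection]] = []
    for img in range(n):
        if not all_boxes[img]:
            results.append([])
            continue
        bx = np.concatenate(all_boxes[img])
        sc = np.concatenate(all_scores[img])
        cl = np.concatenate(all_cls[img])
        if bx.shape[0] > max_det:
            top = np.argsort(-sc, kind="stable")[:max_det]
            bx, sc, cl = bx[top], sc[top], cl[top]
        dets: list[Detection] = []
        for c in np.unique(cl):
            sel = cl == c
            keep = nms(bx[sel], sc[sel], nms_iou)
            for i in keep:
                b = bx[sel][i]
                dets.append(Detection(BBox(*b), int(c), float(sc[sel][i])))
        dets.sort(key=lambda d: -d.confidence)
        results.append(dets)
    return results
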