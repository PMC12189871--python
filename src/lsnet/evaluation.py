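"""Detection metrics: per-class AP@0.5, mAP, precision/recall/F1 curves.

The protocol is the familiar VOC one.  Detections are matched to ground
truth greedily in descending confidence; a detection is a true positive if
it overlaps an unmatched same-class ground-truth box with IoU >= the
threshold (ties broken by higher IoU), otherwise a false positive; each
ground-truth box absorbs at most one detection.  Average precision is the
area under the precision-recall curve with all-point interpolation
(the VOC-2010 / COCO convention; 11-point interpolation is available for
comparison).  F1 is reported at the confidence threshold maximising it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .boxes import BBox, Detection, box_iou_matrix, boxes_to_array, detections_to_arrays

__all__ = ["MatchResult", "match_detections", "average_precision",
           "precision_recall_curve", "f1_curve", "summary_metrics",
           "plot_curves", "evaluate"]


@dataclass
class MatchResult:
    """Match flags for a set of detections against ground truth.

    ``tp``, ``confidence`` and ``class_id`` are aligned per detection (in
    the caller's order); ``num_gt`` counts ground-truth boxes per class.
    """

    tp: np.ndarray
    confidence: np.ndarray
    class_id: np.ndarray
    num_gt: dict[int, int] = field(default_factory=dict)

    def merged_with(self, other: "MatchResult") -> "MatchResult":
        num_gt = dict(self.num_gt)
        for c, n in other.num_gt.items():
            num_gt[c] = num_gt.get(c, 0) + n
        return MatchResult(
            np.concatenate([self.tp, other.tp]),
            np.concatenate([self.confidence, other.confidence]),
            np.concatenate([self.class_id, other.class_id]),
            num_gt,
        )


def match_detections(dets: list[Detection], gts: list[BBox],
                     iou_thresh: float = 0.5) -> MatchResult:
    """Greedy one-to-one matching for a single image.

    Detections are visited in descending confidence (stable order for
    ties); each claims the unmatched same-class ground-truth box of
    highest IoU, provided that IoU >= ``iou_thresh`` (boundary inclusive).
    """
    boxes, cls, conf = detections_to_arrays(dets)
    gt_arr = boxes_to_array(gts)
    tp = np.zeros(len(dets), dtype=bool)
    num_gt: dict[int, int] = {}
    for b in gts:
        c = -1 if b.class_id is None else int(b.class_id)
        num_gt[c] = num_gt.get(c, 0) + 1

    if len(dets) and len(gts):
        iou = box_iou_matrix(boxes, gt_arr[:, :4])
        gt_cls = gt_arr[:, 4].astype(int)
        taken = np.zeros(len(gts), dtype=bool)
        for i in np.argsort(-conf, kind="stable"):
            cand = (gt_cls == cls[i]) & ~taken & (iou[i] >= iou_thresh)
            if cand.any():
                j = np.flatnonzero(cand)[np.argmax(iou[i][cand])]
                taken[j] = True
                tp[i] = True
    return MatchResult(tp, conf, cls, num_gt)


def _pr_points(match: MatchResult, class_id: int):
    sel = match.class_id == class_id
    order = np.argsort(-match.confidence[sel], kind="stable")
    tp = match.tp[sel][order].astype(float)
    conf = match.confidence[sel][order]
    n_gt = match.num_gt.get(class_id, 0)
    tp_cum = np.cumsum(tp)
    fp_cum = np.cumsum(1.0 - tp)
    recall = tp_cum / n_gt if n_gt else np.zeros_like(tp_cum)
    precision = tp_cum / np.maximum(tp_cum + fp_cum, 1e-12)
    return recall, precision, conf, n_gt


def precision_recall_curve(match: MatchResult, class_id: int):
    """(recall, precision) points in descending-confidence order."""
    recall, precision, _, _ = _pr_points(match, class_id)
    return recall, precision


def average_precision(match: MatchResult, class_id: int,
                      interpolation: str = "all_points") -> float:
    """Area under the precision-recall curve for one class.

    ``all_points`` integrates the precision envelope over every recall
    step; ``eleven_point`` averages the envelope at recalls 0, 0.1, ... 1.
    Returns NaN (with a warning) when the class has no ground truth.
    """
    recall, precision, _, n_gt = _pr_points(match, class_id)
    if n_gt == 0:
        warnings.warn(f"class {class_id} has no ground-truth boxes; AP undefined")
        return float("nan")
    if recall.size == 0:
        return 0.0
    r = np.concatenate([[0.0], recall, [recall[-1]]])
    p = np.concatenate([[1.0], precision, [0.0]])
    # precision envelope: monotone non-increasing from the right
    p = np.maximum.accumulate(p[::-1])[::-1]
    if interpolation == "all_points":
        idx = np.flatnonzero(r[1:] != r[:-1]) + 1
        return float(np.sum((r[idx] - r[idx - 1]) * p[idx]))
    if interpolation == "eleven_point":
        pts = []
        for t in np.linspace(0, 1, 11):
            mask = r >= t
            pts.append(p[mask].max() if mask.any() else 0.0)
        return float(np.mean(pts))
    raise ValueError("interpolation must be 'all_points' or 'eleven_point'")


def f1_curve(match: MatchResult, class_id: int):
    """F1 versus confidence threshold (evaluated at each detection score)."""
    recall, precision, conf, n_gt = _pr_points(match, class_id)
    if recall.size == 0 or n_gt == 0:
        return np.zeros(0), np.zeros(0)
    f1 = 2 * precision * recall / np.maximum(precision + recall, 1e-12)
    return conf, f1


def summary_metrics(match: MatchResult, class_ids: list[int],
                    interpolation: str = "all_points") -> dict:
    """Per-class AP/P/R/F1 (at the best-F1 threshold) and their mAP summary."""
    per_class: dict[int, dict] = {}
    aps = []
    for c in class_ids:
        ap = average_precision(match, c, interpolation)
        recall, precision, conf, n_gt = _pr_points(match, c)
        if recall.size and n_gt:
            f1 = 2 * precision * recall / np.maximum(precision + recall, 1e-12)
            best = int(np.argmax(f1))
            entry = {
                "ap": ap, "f1": float(f1[best]),
                "precision": float(precision[best]),
                "recall": float(recall[best]),
                "confidence": float(conf[best]), "num_gt": n_gt,
            }
        else:
            entry = {"ap": ap, "f1": 0.0, "precision": 0.0, "recall": 0.0,
                     "confidence": float("nan"), "num_gt": n_gt}
        per_class[c] = entry
        if not np.isnan(ap):
            aps.append(ap)
    return {
        "per_class": per_class,
        "map": float(np.mean(aps)) if aps else float("nan"),
    }


def plot_curves(match: MatchResult, class_ids: list[int], out_dir,
                class_names: dict[int, str] | None = None) -> list:
    """Write PR and F1-vs-threshold curve figures; returns the file paths."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from pathlib import Path

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    names = class_names or {}
    paths = []
    fig, (ax_pr, ax_f1) = plt.subplots(1, 2, figsize=(10, 4))
    for c in class_ids:
        label = names.get(c, f"class {c}")
        recall, precision = precision_recall_curve(match, c)
        if recall.size:
            ax_pr.plot(recall, precision, label=label)
        conf, f1 = f1_curve(match, c)
        if conf.size:
            order = np.argsort(conf)
            ax_f1.plot(conf[order], f1[order], label=label)
    ax_pr.set_xlabel("recall"), ax_pr.set_ylabel("precision")
    ax_pr.set_title("precision-recall"), ax_pr.legend()
    ax_f1.set_xlabel("confidence threshold"), ax_f1.set_ylabel("F1")
    ax_f1.set_title("F1 vs threshold"), ax_f1.legend()
    fig.tight_layout()
    path = out_dir / "curves.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    paths.append(path)
    return paths


def evaluate(per_image_dets: list[list[Detection]],
             per_image_gts: list[list[BBox]],
             iou_thresh: float = 0.5, class_ids: list[int] | None = None,
             interpolation: str = "all_points") -> dict:
    """Match every image and summarise over the dataset."""
    if len(per_image_dets) != len(per_image_gts):
        raise ValueError("detection and ground-truth lists must align")
    total = MatchResult(np.zeros(0, dtype=bool), np.zeros(0), np.zeros(0, dtype=int))
    for dets, gts in zip(per_image_dets, per_image_gts):
        total = total.merged_with(match_detections(dets, gts, iou_thresh))
    if class_ids is None:
        class_ids = sorted(total.num_gt)
    result = summary_metrics(total, class_ids, interpolation)
    result["match"] = total
    return result
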