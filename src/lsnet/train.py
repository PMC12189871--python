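"""Training: schedule, target assignment, loss assembly and the SGD loop.

The optimisation recipe follows the published protocol: SGD with momentum
0.937 and weight decay 4e-5, cosine-annealed learning rate from 0.01 down
to 1e-4 over the epoch horizon, and the box-regression term selectable
between CIoU and Wise-IoU v1/v3.  Anchor-target assignment uses the
mainstream size-ratio gate (an anchor matches a target when neither side
ratio exceeds 4) with the centre cell plus its two nearest neighbour cells
— a simplification of the full dynamic assignment used by modern YOLO
trainers, adequate at the scales trained here and documented as such.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np

from . import losses as L
from . import nn
from .boxes import BBox, Detection
from .decode import decode_predictions
from .evaluation import evaluate
from .model import GraphNet
from .nn import Tensor
from .nn import functional as F

__all__ = ["TrainConfig", "lr_schedule", "build_targets", "assemble_loss",
           "load_yolo_split", "train_detector", "evaluate_model",
           "recalibrate_batchnorm", "save_checkpoint", "load_checkpoint"]


@dataclass
class TrainConfig:
    """Optimisation hyper-parameters (defaults follow the published recipe)."""

    epochs: int = 300
    lr_init: float = 0.01
    lr_min: float = 0.0001
    momentum: float = 0.937
    weight_decay: float = 4e-5
    batch_size: int = 8
    input_size: int = 640
    box_loss: str = "wiou_v3"
    focusing: L.FocusingConfig = dataclass_field(default_factory=L.FocusingConfig)
    warmup_steps: int = 0
    lambda_box: float = 0.05
    lambda_obj: float = 1.0
    lambda_cls: float = 0.5
    anchor_ratio_thresh: float = 4.0
    assign_mode: str = "ratio"
    neighbor_cells: bool = True
    balanced_obj: bool = False
    obj_target: str = "iou"  # "iou" (IoU-aware) or "one" (hard positives)
    obj_focal_gamma: float = 0.0  # >0 focuses the negative term on hard cells
    flip_augment: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be positive")
        if self.box_loss not in ("ciou", "wiou_v1", "wiou_v3"):
            raise ValueError("box_loss must be ciou, wiou_v1 or wiou_v3")
        if self.assign_mode not in ("ratio", "best"):
            raise ValueError("assign_mode must be 'ratio' or 'best'")
        if self.obj_target not in ("iou", "one"):
            raise ValueError("obj_target must be 'iou' or 'one'")


def lr_schedule(epoch: int, cfg: TrainConfig) -> float:
    """Cosine annealing: lr_min + (lr_init - lr_min) (1 + cos(pi e/E)) / 2."""
    if not 0 <= epoch <= cfg.epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.epochs}]")
    return cfg.lr_min + 0.5 * (cfg.lr_init - cfg.lr_min) * (
        1.0 + math.cos(math.pi * epoch / cfg.epochs))


# ---------------------------------------------------------------------------
# target assignment
# ---------------------------------------------------------------------------

def build_targets(targets: np.ndarray, model: GraphNet,
                  grids: list[tuple[int, int]],
                  ratio_thresh: float = 4.0, assign_mode: str = "ratio",
                  neighbor_cells: bool = True) -> list[dict]:
    """Assign targets to (head, anchor, cell) triples.

    ``targets`` is (M, 6): image index, class, cx, cy, w, h in input
    pixels.  With ``assign_mode="ratio"`` (the mainstream rule) an anchor
    is eligible when max(wh/anchor, anchor/wh) < ``ratio_thresh``, giving
    each target several positives; ``"best"`` assigns only the single
    anchor (over all heads) of highest centred IoU, giving one clean
    positive per target.  ``neighbor_cells`` adds the two nearest
    neighbour cells to the centre cell.
    """
    from .anchors import anchor_iou_distance

    out = []
    targets = np.asarray(targets, dtype=float).reshape(-1, 6)
    if assign_mode == "best" and targets.shape[0]:
        flat = np.concatenate([np.asarray(a, dtype=float) for a in model.anchors])
        best = anchor_iou_distance(targets[:, 4:6], flat).argmin(axis=1)
    for head, (anchors, stride, (gh, gw)) in enumerate(
            zip(model.anchors, model.strides, grids)):
        anc = np.asarray(anchors, dtype=float)          # (na, 2) input px
        if targets.shape[0] == 0:
            out.append({"img": np.zeros(0, int), "anchor": np.zeros(0, int),
                        "gj": np.zeros(0, int), "gi": np.zeros(0, int),
                        "box": np.zeros((0, 4)), "cls": np.zeros(0, int),
                        "anchor_wh": np.zeros((0, 2))})
            continue
        if assign_mode == "best":
            sel = best // len(anc) == head
            t_idx = np.flatnonzero(sel)
            a_idx = best[sel] % len(anc)
        else:
            ratio = targets[:, None, 4:6] / anc[None, :, :]
            gate = np.maximum(ratio, 1.0 / ratio).max(axis=2) < ratio_thresh
            t_idx, a_idx = np.nonzero(gate)
        gx = targets[t_idx, 2] / stride
        gy = targets[t_idx, 3] / stride
        # centre cell plus the two nearest neighbours (left/right, up/down)
        cells_i, cells_j, keep_t, keep_a = [], [], [], []
        fx, fy = gx % 1.0, gy % 1.0
        ox = np.where(fx < 0.5, -1, 1)
        oy = np.where(fy < 0.5, -1, 1)
        offsets = ((0, 0), (1, 0), (0, 1)) if neighbor_cells else ((0, 0),)
        for di, dj in offsets:
            ci = np.floor(gx).astype(int) + (ox if di else 0)
            cj = np.floor(gy).astype(int) + (oy if dj else 0)
            ok = (ci >= 0) & (ci < gw) & (cj >= 0) & (cj < gh)
            cells_i.append(ci[ok])
            cells_j.append(cj[ok])
            keep_t.append(t_idx[ok])
            keep_a.append(a_idx[ok])
        gi = np.concatenate(cells_i)
        gj = np.concatenate(cells_j)
        tt = np.concatenate(keep_t)
        aa = np.concatenate(keep_a)
        # deduplicate (img, anchor, cell) collisions, first assignment wins
        img = targets[tt, 0].astype(int)
        key = ((img * len(anc) + aa) * gh + gj) * gw + gi
        _, first = np.unique(key, return_index=True)
        first.sort()
        out.append({"img": img[first], "anchor": aa[first],
                    "gj": gj[first], "gi": gi[first],
                    "box": targets[tt[first], 2:6],
                    "cls": targets[tt[first], 1].astype(int),
                    "anchor_wh": anc[aa[first]]})
    return out


# ---------------------------------------------------------------------------
# loss assembly
# ---------------------------------------------------------------------------

def _box_term(pred_boxes: Tensor, gt_boxes: np.ndarray, cfg: TrainConfig,
              state: L.RunningIoUState):
    if cfg.box_loss == "ciou":
        return L.ciou_loss(pred_boxes, gt_boxes)
    if cfg.box_loss == "wiou_v1":
        return L.wiou_v1_loss(pred_boxes, gt_boxes)
    return L.wiou_v3_loss(pred_boxes, gt_boxes, state, cfg.focusing)


def assemble_loss(head_outputs: list[Tensor], targets: np.ndarray,
                  model: GraphNet, cfg: TrainConfig,
                  state: L.RunningIoUState | None = None) -> dict:
    """Compose box + objectness + classification losses for one batch.

    Returns a dict with differentiable ``total`` plus the detached
    components and the batch-mean IoU loss (for the running-mean update).
    The objectness target at a matched cell is the detached IoU of the
    decoded prediction with its target box (zero elsewhere).
    """
    state = state or L.RunningIoUState()
    nc = model.num_classes
    no = 5 + nc
    grids = [(o.shape[2], o.shape[3]) for o in head_outputs]
    assigned = build_targets(targets, model, grids, cfg.anchor_ratio_thresh,
                             cfg.assign_mode, cfg.neighbor_cells)

    box_losses, cls_losses, obj_losses, lious = [], [], [], []
    for out, asg, anchors, stride in zip(head_outputs, assigned,
                                         model.anchors, model.strides):
        n, c, gh, gw = out.shape
        na = len(anchors)
        x = out.reshape(n, na, no, gh, gw).transpose(0, 1, 3, 4, 2)  # N,na,H,W,no
        obj_target = np.zeros((n, na, gh, gw), dtype=np.float32)
        m = asg["img"].size
        if m:
            sel = (asg["img"], asg["anchor"], asg["gj"], asg["gi"])
            p = x[sel]                                   # (m, no)
            sxy = p[:, 0:2].sigmoid()
            swh = p[:, 2:4].sigmoid()
            cell = np.stack([asg["gi"], asg["gj"]], axis=1).astype(np.float32)
            pxy = (sxy * 2.0 - 0.5 + cell) * float(stride)
            pwh = (swh * 2.0).square() * asg["anchor_wh"].astype(np.float32)
            pred_boxes = nn.concat([pxy, pwh], axis=1)
            per_pair = _box_term(pred_boxes, asg["box"], cfg, state)
            box_losses.append(per_pair.mean())
            liou = L.iou_loss(pred_boxes.detach().numpy(), asg["box"])
            lious.append(liou)
            obj_target[sel] = (1.0 if cfg.obj_target == "one"
                               else np.clip(1.0 - liou, 0.0, None))
            if nc > 1:
                onehot = np.zeros((m, nc), dtype=np.float32)
                onehot[np.arange(m), asg["cls"]] = 1.0
                cls_losses.append(F.binary_cross_entropy_with_logits(
                    p[:, 5:], onehot))
        obj_logits = x[..., 4]
        if cfg.balanced_obj and m:
            # average positive and negative cells separately so the sparse
            # positives are not drowned by the background; optionally focus
            # the negative average on hard (confidently wrong) cells
            pos = np.zeros((n, na, gh, gw), dtype=bool)
            pos[sel] = True
            el = F.binary_cross_entropy_with_logits(obj_logits, obj_target,
                                                    reduction="none")
            neg = el[~pos]
            if cfg.obj_focal_gamma > 0:
                w = (1.0 / (1.0 + np.exp(-obj_logits.data[~pos])))                     ** cfg.obj_focal_gamma
                w = np.maximum(w, 1e-6)
                neg_term = (neg * w).sum() * (1.0 / float(w.sum()))
            else:
                neg_term = neg.mean()
            obj_losses.append((el[pos].mean() + neg_term) * 0.5)
        else:
            obj_losses.append(F.binary_cross_entropy_with_logits(
                obj_logits, obj_target))

    zero = Tensor(np.float32(0.0))
    box = sum(box_losses) * (1.0 / len(box_losses)) if box_losses else zero
    obj = sum(obj_losses) * (1.0 / len(obj_losses))
    cls = sum(cls_losses) * (1.0 / len(cls_losses)) if cls_losses else zero
    total = cfg.lambda_box * box + cfg.lambda_obj * obj + cfg.lambda_cls * cls
    mean_liou = float(np.concatenate(lious).mean()) if lious else None
    return {"total": total, "box": float(box.data), "obj": float(obj.data),
            "cls": float(cls.data), "mean_liou": mean_liou}


# ---------------------------------------------------------------------------
# data loading
# ---------------------------------------------------------------------------

def load_yolo_split(root: str | Path, split: str, input_size: int
                    ) -> list[tuple[np.ndarray, np.ndarray]]:
    """Load a dataset split into memory as (CHW float image, (M,5) targets).

    Images are stretch-resized to ``input_size``; targets are
    (class, cx, cy, w, h) in resized pixels.
    """
    from PIL import Image

    from .data import list_image_label_pairs, read_yolo_labels

    root = Path(root)
    pairs = list_image_label_pairs(root / "images" / split, root / "labels" / split)
    samples = []
    for img_path, label_path in pairs:
        with Image.open(img_path) as im:
            im = im.convert("RGB")
            w0, h0 = im.size
            if (w0, h0) != (input_size, input_size):
                im = im.resize((input_size, input_size), Image.BILINEAR)
            arr = np.asarray(im, dtype=np.float32) / 255.0
        boxes = read_yolo_labels(label_path, input_size, input_size)
        t = np.array([[b.class_id, b.cx, b.cy, b.w, b.h] for b in boxes],
                     dtype=float).reshape(-1, 5)
        samples.append((arr.transpose(2, 0, 1), t))
    return samples


def _flip_sample(img: np.ndarray, t: np.ndarray, rng: np.random.Generator,
                 size: int) -> tuple[np.ndarray, np.ndarray]:
    t = t.copy()
    if rng.random() < 0.5:
        img = img[:, :, ::-1]
        if t.size:
            t[:, 1] = size - t[:, 1]
    if rng.random() < 0.5:
        img = img[:, ::-1, :]
        if t.size:
            t[:, 2] = size - t[:, 2]
    return np.ascontiguousarray(img), t


# ---------------------------------------------------------------------------
# checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(path: str | Path, model: GraphNet, epoch: int = 0,
                    extra: dict | None = None) -> None:
    state = {f"param:{k}": v for k, v in model.state_dict().items()}
    state["meta:epoch"] = np.array(epoch)
    for k, v in (extra or {}).items():
        state[f"extra:{k}"] = np.asarray(v)
    np.savez_compressed(path, **state)


def load_checkpoint(path: str | Path, model: GraphNet) -> dict:
    with np.load(path) as data:
        model.load_state_dict({k[len("param:"):]: data[k]
                               for k in data.files if k.startswith("param:")})
        meta = {"epoch": int(data["meta:epoch"])}
        meta.update({k[len("extra:"):]: data[k]
                     for k in data.files if k.startswith("extra:")})
    return meta


# ---------------------------------------------------------------------------
# evaluation helper and training loop
# ---------------------------------------------------------------------------

def recalibrate_batchnorm(model: GraphNet, samples, batch_size: int = 4) -> None:
    """Recompute BatchNorm running statistics exactly over ``samples``.

    The exponential running estimates lag badly after short training runs;
    this replaces them with the average batch mean/variance over one full
    pass (precise-BN), which is what evaluation-mode inference then uses.
    """
    bns = [m for m in model.modules() if isinstance(m, nn.BatchNorm2d)]
    if not bns:
        return
    sums = {id(b): (np.zeros_like(b.running_mean), np.zeros_like(b.running_var))
            for b in bns}
    saved = [(b.running_mean.copy(), b.running_var.copy(), b.momentum)
             for b in bns]
    for b in bns:
        b.momentum = 1.0      # each forward writes the current batch stats
    model.train()
    n_batches = 0
    with nn.no_grad():
        for start in range(0, len(samples), batch_size):
            batch = np.stack([img for img, _ in samples[start:start + batch_size]])
            model(Tensor(batch))
            for b in bns:
                s_m, s_v = sums[id(b)]
                s_m += b.running_mean
                s_v += b.running_var
            n_batches += 1
    for b, (m0, v0, mom) in zip(bns, saved):
        b.momentum = mom
        if n_batches:
            s_m, s_v = sums[id(b)]
            b.running_mean[...] = s_m / n_batches
            b.running_var[...] = s_v / n_batches
        else:
            b.running_mean[...], b.running_var[...] = m0, v0


def evaluate_model(model: GraphNet, samples, conf_thresh: float = 0.01,
                   nms_iou: float = 0.45, iou_thresh: float = 0.5) -> dict:
    """mAP@0.5 of a model over in-memory samples."""
    model.eval()
    all_dets: list[list[Detection]] = []
    all_gts: list[list[BBox]] = []
    with nn.no_grad():
        for img, t in samples:
            outs = model(img[None])
            dets = decode_predictions(outs, model.anchors, model.strides,
                                      model.num_classes, conf_thresh, nms_iou)[0]
            all_dets.append(dets)
            all_gts.append([BBox(*row[1:5], class_id=int(row[0])) for row in t])
    model.train()
    return evaluate(all_dets, all_gts, iou_thresh,
                    class_ids=list(range(model.num_classes)))


def train_detector(model: GraphNet, train_samples, cfg: TrainConfig,
                   val_samples=None, out_dir: str | Path | None = None,
                   eval_every: int = 0, log=None) -> dict:
    """SGD training loop; returns the per-epoch history.

    ``train_samples`` is the in-memory list from :func:`load_yolo_split`.
    History rows carry the epoch's mean loss components (and val mAP when
    ``eval_every`` is set); with ``out_dir`` the history is written as CSV
    alongside best/last checkpoints (selected on val mAP, or train loss
    when no validation set is given).
    """
    if not train_samples:
        raise ValueError("empty training set")
    rng = np.random.default_rng(cfg.seed)
    decay, no_decay = [], []
    for name, p in model.named_parameters():
        (decay if name.endswith("weight") and p.data.ndim == 4 else no_decay).append(p)
    opt = nn.SGD([{"params": decay, "weight_decay": cfg.weight_decay},
                  {"params": no_decay, "weight_decay": 0.0}],
                 lr=cfg.lr_init, momentum=cfg.momentum)
    state = L.RunningIoUState()
    size = train_samples[0][0].shape[-1]
    model.train()
    history: list[dict] = []
    best_score = -np.inf
    out_dir = Path(out_dir) if out_dir is not None else None
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
    step = 0
    for epoch in range(cfg.epochs):
        base_lr = lr_schedule(epoch, cfg)
        order = rng.permutation(len(train_samples))
        sums = {"total": 0.0, "box": 0.0, "obj": 0.0, "cls": 0.0}
        n_batches = 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            imgs, tgts = [], []
            for pos, i in enumerate(idx):
                img, t = train_samples[i]
                if cfg.flip_augment:
                    img, t = _flip_sample(img, t, rng, size)
                imgs.append(img)
                if t.size:
                    tgts.append(np.concatenate(
                        [np.full((t.shape[0], 1), pos), t], axis=1))
            batch = Tensor(np.stack(imgs))
            targets = (np.concatenate(tgts) if tgts else np.zeros((0, 6)))
            lr = base_lr * min(1.0, (step + 1) / cfg.warmup_steps) \
                if cfg.warmup_steps else base_lr
            opt.set_lr(lr)
            outs = model(batch)
            parts = assemble_loss(outs, targets, model, cfg, state)
            opt.zero_grad()
            parts["total"].backward()
            opt.step()
            if parts["mean_liou"] is not None:
                L.update_running_mean(state, parts["mean_liou"], cfg.focusing)
            for k in sums:
                sums[k] += parts[k] if k != "total" else float(parts[k].data)
            n_batches += 1
            step += 1
        row = {"epoch": epoch, "lr": base_lr,
               **{k: v / max(n_batches, 1) for k, v in sums.items()}}
        score = -row["total"]
        if eval_every and (epoch + 1) % eval_every == 0:
            recalibrate_batchnorm(model, train_samples, cfg.batch_size)
            res = evaluate_model(model, val_samples or train_samples)
            row["map50"] = res["map"]
            score = res["map"]
        history.append(row)
        if log:
            log(row)
        if out_dir is not None:
            if score > best_score:
                save_checkpoint(out_dir / "best.npz", model, epoch)
            save_checkpoint(out_dir / "last.npz", model, epoch)
        best_score = max(best_score, score)
    recalibrate_batchnorm(model, train_samples, cfg.batch_size)
    if out_dir is not None:
        keys = sorted({k for row in history for k in row})
        with open(out_dir / "history.csv", "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=keys)
            writer.writeheader()
            writer.writerows(history)
    return {"history": history, "state": state}
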