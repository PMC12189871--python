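"""Bounding-box regression losses: IoU, CIoU and the Wise-IoU family.

All losses act on ``(..., 4)`` box arrays in ``(cx, cy, w, h)`` order and
return an elementwise loss of shape ``(...)``; reduction is left to the
caller.  Inputs may be plain numpy arrays or :class:`lsnet.nn.Tensor`, in
which case the loss is differentiable.

The Wise-IoU v3 loss re-weights the distance-attended v1 loss by a
non-monotonic focusing factor of the *outlier degree* β, the ratio of a
box pair's IoU loss to an exponential running mean of IoU losses observed
during training.  A small β marks a high-quality anchor box and receives a
damped gradient gain; so does a very large β (a genuine outlier), which
steers optimisation toward ordinary-quality boxes.  Three quantities are
excluded from gradient flow by construction: the enclosing-box normaliser
of the distance attention, β itself, and the running mean.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .boxes import EPS, InvalidBoxError
from .nn.autograd import Tensor

__all__ = [
    "FocusingConfig", "RunningIoUState",
    "iou", "iou_loss", "ciou_loss", "wiou_v1_loss", "wiou_v2_loss",
    "wiou_v3_loss", "outlier_degree", "focusing_factor", "update_running_mean",
]


# ---------------------------------------------------------------------------
# configuration and running state
# ---------------------------------------------------------------------------

@dataclass
class FocusingConfig:
    """Hyper-parameters of the non-monotonic focusing mechanism.

    alpha : focusing base (> 1); the factor peaks at beta = 1/ln(alpha).
    delta : the beta value at which the factor equals exactly 1.
    momentum : exponential-moving-average momentum of the running IoU loss
        (weight kept on the old mean each update).
    warmup_steps : training steps during which the factor is pinned to 1,
        until the running mean is trustworthy.
    beta_orientation : "quality" computes beta = L_IoU / mean(L_IoU), so
        smaller beta means a better box; "inverse" computes the reciprocal.
    """

    alpha: float = 1.9
    delta: float = 3.0
    momentum: float = 0.99
    warmup_steps: int = 500
    beta_orientation: str = "quality"

    def __post_init__(self):
        if not self.alpha > 1:
            raise ValueError("alpha must exceed 1 for a non-monotonic factor")
        if not self.delta > 0:
            raise ValueError("delta must be positive")
        if not 0 < self.momentum < 1:
            raise ValueError("momentum must lie in (0, 1)")
        if self.beta_orientation not in ("quality", "inverse"):
            raise ValueError("beta_orientation must be 'quality' or 'inverse'")


@dataclass
class RunningIoUState:
    """Exponential running mean of the IoU loss (a constant w.r.t. gradients)."""

    mean_liou: float = 1.0
    initialized: bool = False
    steps: int = 0

    def in_warmup(self, cfg: FocusingConfig) -> bool:
        return self.steps < cfg.warmup_steps or not self.initialized


def update_running_mean(state: RunningIoUState, batch_mean_liou: float,
                        cfg: FocusingConfig) -> RunningIoUState:
    """One EMA step; the first observation seeds the mean directly."""
    batch_mean_liou = float(batch_mean_liou)
    if batch_mean_liou < 0:
        raise ValueError("mean IoU loss cannot be negative")
    if not state.initialized:
        state.mean_liou = batch_mean_liou
        state.initialized = True
    else:
        m = cfg.momentum
        state.mean_liou = m * state.mean_liou + (1.0 - m) * batch_mean_liou
    state.steps += 1
    return state


# ---------------------------------------------------------------------------
# dual numpy / Tensor arithmetic helpers
# ---------------------------------------------------------------------------

def _is_t(x) -> bool:
    return isinstance(x, Tensor)


def _exp(x):
    return x.exp() if _is_t(x) else np.exp(x)


def _arctan(x):
    return x.arctan() if _is_t(x) else np.arctan(x)


def _maximum(a, b):
    if _is_t(a):
        return a.maximum(b)
    if _is_t(b):
        return b.maximum(a)
    return np.maximum(a, b)


def _minimum(a, b):
    if _is_t(a):
        return a.minimum(b)
    if _is_t(b):
        return b.minimum(a)
    return np.minimum(a, b)


def _clip_min(x, lo):
    return x.clip(lo, None) if _is_t(x) else np.clip(x, lo, None)


def _detach(x):
    return x.detach() if _is_t(x) else x


def _component(boxes, i: int):
    return boxes[..., i]


def _check(boxes) -> None:
    data = boxes.data if _is_t(boxes) else np.asarray(boxes)
    if data.shape[-1] != 4:
        raise InvalidBoxError("expected (..., 4) cxcywh boxes")
    if data.size and not np.all(data[..., 2:4] > 0):
        raise InvalidBoxError("boxes with non-positive width or height")


# ---------------------------------------------------------------------------
# shared geometry
# ---------------------------------------------------------------------------

def _geometry(pred, gt):
    """IoU plus the enclosing-box and centre-distance terms both losses share."""
    _check(pred)
    _check(gt)
    if _is_t(pred) != _is_t(gt):
        # promote the plain operand so every op dispatches through the tape
        pred, gt = (pred if _is_t(pred) else Tensor(np.asarray(pred, float)),
                    gt if _is_t(gt) else Tensor(np.asarray(gt, float)))
    px, py, pw, ph = (_component(pred, i) for i in range(4))
    gx, gy, gw, gh = (_component(gt, i) for i in range(4))

    px1, px2 = px - pw * 0.5, px + pw * 0.5
    py1, py2 = py - ph * 0.5, py + ph * 0.5
    gx1, gx2 = gx - gw * 0.5, gx + gw * 0.5
    gy1, gy2 = gy - gh * 0.5, gy + gh * 0.5

    iw = _clip_min(_minimum(px2, gx2) - _maximum(px1, gx1), 0.0)
    ih = _clip_min(_minimum(py2, gy2) - _maximum(py1, gy1), 0.0)
    inter = iw * ih
    union = pw * ph + gw * gh - inter
    iou_val = inter / _clip_min(union, EPS)
    # guard the float boundary: reconstructed corners can give 1 + O(eps)
    iou_val = iou_val.clip(0.0, 1.0) if _is_t(iou_val) else np.clip(iou_val, 0.0, 1.0)

    cw = _maximum(px2, gx2) - _minimum(px1, gx1)   # enclosing box extents
    ch = _maximum(py2, gy2) - _minimum(py1, gy1)
    rho2 = (gx - px).square() if _is_t(pred) or _is_t(gt) else (gx - px) ** 2
    rho2 = rho2 + ((gy - py).square() if _is_t(pred) or _is_t(gt) else (gy - py) ** 2)

    return {
        "iou": iou_val, "rho2": rho2, "cw": cw, "ch": ch,
        "pw": pw, "ph": ph, "gw": gw, "gh": gh,
    }


# ---------------------------------------------------------------------------
# losses
# ---------------------------------------------------------------------------

def iou(pred, gt):
    """Plain intersection-over-union of aligned box pairs, in [0, 1]."""
    return _geometry(pred, gt)["iou"]


def iou_loss(pred, gt):
    """1 - IoU."""
    return 1.0 - iou(pred, gt)


def ciou_loss(pred, gt):
    """Complete-IoU loss: 1 - IoU + centre-distance and aspect penalties.

    L = 1 - IoU + rho^2 / c^2 + alpha * v with
    v = (4/pi^2) (arctan(w_gt/h_gt) - arctan(w/h))^2 and
    alpha = v / (1 - IoU + v); alpha is treated as a weighting constant
    (detached), as in the reference formulation.
    """
    g = _geometry(pred, gt)
    c2 = _clip_min(g["cw"].square() if _is_t(g["cw"]) else g["cw"] ** 2, EPS)
    c2 = c2 + (g["ch"].square() if _is_t(g["ch"]) else g["ch"] ** 2)
    dv = _arctan(g["gw"] / g["gh"]) - _arctan(g["pw"] / g["ph"])
    v = (4.0 / math.pi ** 2) * (dv.square() if _is_t(dv) else dv ** 2)
    liou = 1.0 - g["iou"]
    alpha = _detach(v / _clip_min(liou + v, EPS))
    return liou + g["rho2"] / c2 + alpha * v


def _r_wiou(g):
    """Distance attention exp(rho^2 / (cw^2 + ch^2)); the normaliser is detached."""
    cw, ch = _detach(g["cw"]), _detach(g["ch"])
    denom = (cw.square() if _is_t(cw) else cw ** 2) + \
        (ch.square() if _is_t(ch) else ch ** 2)
    return _exp(g["rho2"] / _clip_min(denom, EPS))


def wiou_v1_loss(pred, gt):
    """Wise-IoU v1: distance-attended IoU loss R_WIoU * (1 - IoU)."""
    g = _geometry(pred, gt)
    return _r_wiou(g) * (1.0 - g["iou"])


def wiou_v2_loss(pred, gt, state: RunningIoUState, gamma: float = 0.5):
    """Wise-IoU v2 (monotonic focusing): (L_IoU*/mean)^gamma * L_WIoUv1.

    Provided for completeness; the detector uses v3.
    """
    g = _geometry(pred, gt)
    liou = 1.0 - g["iou"]
    mean = max(state.mean_liou, EPS) if state.initialized else 1.0
    ratio = _detach(liou) / mean
    factor = ratio ** gamma if not _is_t(ratio) else (ratio + EPS) ** gamma
    return factor * _r_wiou(g) * liou


def outlier_degree(liou, state: RunningIoUState,
                   cfg: FocusingConfig | None = None):
    """Outlier degree beta of an IoU loss against the running mean.

    With the default "quality" orientation beta = L_IoU / mean(L_IoU):
    beta = 0 for a perfect box, beta = 1 on the running mean, and large
    beta marks a low-quality outlier.  The "inverse" orientation computes
    the reciprocal.  The input is detached: beta carries no gradient.
    """
    cfg = cfg or FocusingConfig()
    if not state.initialized:
        raise ValueError("running mean not initialised; update it first")
    if state.mean_liou <= 0 and cfg.beta_orientation == "quality":
        # a zero mean only occurs when every box has been perfect
        mean = EPS
    else:
        mean = max(state.mean_liou, EPS)
    liou = _detach(liou)
    if cfg.beta_orientation == "quality":
        return liou / mean
    return mean / _clip_min(liou, EPS)


def focusing_factor(beta, cfg: FocusingConfig):
    """Non-monotonic gain r = (beta / delta) * alpha^(delta - beta).

    r(0) = 0, r(delta) = 1 exactly, and r attains its unique maximum at
    beta = 1 / ln(alpha), tending to 0 as beta grows.
    """
    log_alpha = math.log(cfg.alpha)
    expo = (cfg.delta - beta) * log_alpha
    return (beta / cfg.delta) * _exp(expo)


def wiou_v3_loss(pred, gt, state: RunningIoUState,
                 cfg: FocusingConfig | None = None):
    """Wise-IoU v3: the focusing factor times the v1 loss.

    During warm-up (or before the running mean is seeded) the factor is
    pinned to 1 and the loss coincides with v1.
    """
    cfg = cfg or FocusingConfig()
    g = _geometry(pred, gt)
    liou = 1.0 - g["iou"]
    v1 = _r_wiou(g) * liou
    if state.in_warmup(cfg):
        return v1
    beta = outlier_degree(liou, state, cfg)
    r = focusing_factor(_detach(beta) if _is_t(beta) else beta, cfg)
    return r * v1
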