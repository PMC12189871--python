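"""The LSNET detector and its YOLOv7-family ablation variants.

The network is described as a flat computation graph (a list of nodes, each
naming its inputs), and that one description drives everything: weight
instantiation, the forward pass, trainable-parameter counting and static
FLOP profiling.  Building blocks follow the YOLOv7 base model:

* CBS — conv + batch-norm + SiLU;
* ELAN / ELAN-W — multi-branch aggregation blocks (backbone / neck forms);
* MP — dual-path down-sampling (max-pool+1x1 alongside 1x1+3x3 stride 2);
* SPPCSPC — CSP-split spatial pyramid pooling with parallel 5/9/13 pools;
* REP — re-parameterisable 3x3 head conv (training form keeps the parallel
  3x3 and 1x1 branches; deploy form is a single fused conv);
* LKASPP — the pyramid-pooling replacement: the same CSP skeleton with
  three *sequential* 7x7 max pools (effective receptive fields 7/13/19) and
  a multi-scale large-kernel-attention gate (three full-channel branches of
  depth-wise 5x5 -> depth-wise dilated 7x7 at dilations 2/3/4 -> point-wise
  1x1, aggregated by a point-wise conv) multiplying the fused features.

Variant wiring follows the published ablation chain: the full detector
keeps the complete backbone (through stride 32) and places the pyramid
pooling on its top; "removing P5" removes the prediction-head units at
stride 32 (the last bottom-up aggregation stage, its REP conv and detect
conv), not the backbone stage; "adding P2" extends the top-down path to the
stride-4 feature map with halved channel widths and mirrors the bottom-up
return path.  Heads therefore sit at strides 4/8/16 with 160/80/40 grids
for a 640 input.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import nn
from .nn import Tensor
from .nn import functional as F

__all__ = [
    "ModelConfig", "GraphNet", "build_model", "build_graph",
    "count_parameters", "count_flops", "summarize",
    "LSNET_ANCHORS", "YOLOV7_ANCHORS", "VARIANTS",
]

# Anchor presets, (w, h) pixels at 640 input, three per head, small to large.
LSNET_ANCHORS: tuple[tuple[tuple[float, float], ...], ...] = (
    ((11, 6), (8, 9), (7.5, 14)),          # P2, stride 4
    ((16, 8), (15, 11), (12, 14)),         # P3, stride 8
    ((18, 16), (13, 22), (28, 27)),        # P4, stride 16
)
YOLOV7_ANCHORS: tuple[tuple[tuple[float, float], ...], ...] = (
    ((12, 16), (19, 36), (40, 28)),        # P3, stride 8
    ((36, 75), (76, 55), (72, 146)),       # P4, stride 16
    ((142, 110), (192, 243), (459, 401)),  # P5, stride 32
)

VARIANTS = ("lsnet", "yolov7", "minus_p5", "minus_p5_p2", "plus_p2")

_VARIANT_STRIDES = {
    "lsnet": (4, 8, 16),
    "minus_p5_p2": (4, 8, 16),
    "yolov7": (8, 16, 32),
    "minus_p5": (8, 16),
    "plus_p2": (4, 8, 16, 32),
}


@dataclass
class ModelConfig:
    """Full structural description of a detector build.

    ``width_multiple`` scales every channel width (floored at 2); the
    published models use 1.0, reduced widths exist for CPU-scale training
    experiments.  ``rep_mode`` selects the training-form ("train", parallel
    3x3+1x1 branches) or fused ("deploy") REP head convs — the ablation
    table's parameter column corresponds to the training form.
    """

    variant: str = "lsnet"
    num_classes: int = 3
    anchors: tuple = LSNET_ANCHORS
    input_size: int = 640
    width_multiple: float = 1.0
    rep_mode: str = "train"
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; one of {VARIANTS}")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if self.input_size % 32:
            raise ValueError("input size must be divisible by 32")
        if self.rep_mode not in ("train", "deploy"):
            raise ValueError("rep_mode must be 'train' or 'deploy'")
        strides = _VARIANT_STRIDES[self.variant]
        if len(self.anchors) != len(strides):
            raise ValueError(f"{self.variant} needs {len(strides)} anchor "
                             f"triplets, got {len(self.anchors)}")
        for head in self.anchors:
            if len(head) != 3:
                raise ValueError("each head takes exactly 3 anchors")
            for (w, h) in head:
                if not (w > 0 and h > 0):
                    raise ValueError("anchors must be positive")

    @property
    def strides(self) -> tuple[int, ...]:
        return _VARIANT_STRIDES[self.variant]

    @property
    def num_outputs_per_anchor(self) -> int:
        return 5 + self.num_classes


# ---------------------------------------------------------------------------
# graph construction
# ---------------------------------------------------------------------------

class _GraphBuilder:
    def __init__(self, width_multiple: float = 1.0):
        self.wm = width_multiple
        self.nodes: list[dict] = []

    def ch(self, c: int) -> int:
        if self.wm == 1.0:
            return c
        return max(2, 2 * int(round(c * self.wm / 2)))

    def add(self, frm, **node) -> int:
        node["from"] = [frm] if isinstance(frm, int) else list(frm)
        self.nodes.append(node)
        return len(self.nodes) - 1

    def conv(self, frm: int, c2: int, k: int = 1, s: int = 1, *, g: int = 1,
             d: int = 1, act: bool = True, bn: bool = True,
             bias: bool = False, scale: bool = True) -> int:
        c2 = self.ch(c2) if scale else c2
        return self.add(frm, op="conv", c2=c2, k=k, s=s, g=g, d=d,
                        act=act, bn=bn, bias=bias)

    def pool(self, frm: int, k: int, s: int = 1) -> int:
        return self.add(frm, op="maxpool", k=k, s=s)

    def elan(self, frm: int, cmid: int, cout: int) -> int:
        a = self.conv(frm, cmid)
        b = self.conv(frm, cmid)
        c1 = self.conv(b, cmid, 3)
        c2 = self.conv(c1, cmid, 3)
        c3 = self.conv(c2, cmid, 3)
        c4 = self.conv(c3, cmid, 3)
        cat = self.add([c4, c2, b, a], op="concat")
        return self.conv(cat, cout)

    def elan_w(self, frm: int, cmid: int, cout: int) -> int:
        half = cmid // 2
        a = self.conv(frm, cmid)
        b = self.conv(frm, cmid)
        c1 = self.conv(b, half, 3)
        c2 = self.conv(c1, half, 3)
        c3 = self.conv(c2, half, 3)
        c4 = self.conv(c3, half, 3)
        cat = self.add([c4, c3, c2, c1, b, a], op="concat")
        return self.conv(cat, cout)

    def mp_branches(self, frm: int, cb: int) -> tuple[int, int]:
        p = self.pool(frm, 2, 2)
        pa = self.conv(p, cb)
        rb = self.conv(frm, cb)
        rb2 = self.conv(rb, cb, 3, 2)
        return rb2, pa

    def mp_down(self, frm: int, cb: int) -> int:
        rb2, pa = self.mp_branches(frm, cb)
        return self.add([rb2, pa], op="concat")

    def sppcspc(self, frm: int, c2: int) -> int:
        c_ = c2
        cv1 = self.conv(frm, c_)
        cv3 = self.conv(cv1, c_, 3)
        cv4 = self.conv(cv3, c_)
        p1 = self.pool(cv4, 5)
        p2 = self.pool(cv4, 9)
        p3 = self.pool(cv4, 13)
        cat = self.add([cv4, p1, p2, p3], op="concat")
        cv5 = self.conv(cat, c_)
        cv6 = self.conv(cv5, c_, 3)
        cv2 = self.conv(frm, c_)
        cat2 = self.add([cv6, cv2], op="concat")
        return self.conv(cat2, c2)

    def lkaspp(self, frm: int, c2: int,
               dilations: Sequence[int] = (2, 3, 4)) -> int:
        c_ = c2
        cv1 = self.conv(frm, c_)
        cv3 = self.conv(cv1, c_, 3)
        cv4 = self.conv(cv3, c_)
        q1 = self.pool(cv4, 7)          # sequential pools: eff. kernels 7/13/19
        q2 = self.pool(q1, 7)
        q3 = self.pool(q2, 7)
        cat = self.add([cv4, q1, q2, q3], op="concat")
        cv5 = self.conv(cat, c_)
        branches = []
        for dil in dilations:           # multi-scale large-kernel attention
            dw = self.conv(cv5, c_, 5, g=-1, act=False, bn=False, bias=True)
            dwd = self.conv(dw, c_, 7, g=-1, d=dil, act=False, bn=False, bias=True)
            pw = self.conv(dwd, c_, 1, act=False, bn=False, bias=True)
            branches.append(pw)
        agg_in = self.add(branches, op="concat")
        attn = self.conv(agg_in, c_, 1, act=False, bn=False, bias=True)
        gated = self.add([cv5, attn], op="mul")
        cv2 = self.conv(frm, c_)
        cat2 = self.add([gated, cv2], op="concat")
        return self.conv(cat2, c2)

    def rep(self, frm: int, c2: int, mode: str) -> int:
        if mode == "deploy":
            return self.conv(frm, c2, 3, act=True, bn=False, bias=True)
        r3 = self.conv(frm, c2, 3, act=False)
        r1 = self.conv(frm, c2, 1, act=False)
        # width scaling already applied inside conv; reuse its channel count
        s = self.add([r3, r1], op="add")
        return self.add(s, op="silu")

    def head(self, frm: int, no: int) -> int:
        return self.conv(frm, no, 1, act=False, bn=False, bias=True, scale=False)


def build_graph(cfg: ModelConfig) -> tuple[list[dict], list[int]]:
    """Emit the node list and head-output indices for a configuration."""
    b = _GraphBuilder(cfg.width_multiple)
    no = 3 * cfg.num_outputs_per_anchor

    # -- backbone ------------------------------------------------------
    x = b.conv(-1, 32, 3)                         # -1 marks the network input
    x = b.conv(x, 64, 3, 2)
    x = b.conv(x, 64, 3)
    x = b.conv(x, 128, 3, 2)
    c2 = b.elan(x, 64, 256)                       # stride 4
    x = b.mp_down(c2, 128)
    c3 = b.elan(x, 128, 512)                      # stride 8
    x = b.mp_down(c3, 256)
    c4 = b.elan(x, 256, 1024)                     # stride 16
    x = b.mp_down(c4, 512)
    c5 = b.elan(x, 256, 1024)                     # stride 32

    spp = b.lkaspp if cfg.variant == "lsnet" else b.sppcspc
    top = spp(c5, 512)                            # stride 32, 512 channels

    # -- top-down path -------------------------------------------------
    t = b.conv(top, 256)
    t = b.add(t, op="upsample")
    r = b.conv(c4, 256)
    t = b.add([t, r], op="concat")
    p4_td = b.elan_w(t, 256, 256)                 # stride 16

    t = b.conv(p4_td, 128)
    t = b.add(t, op="upsample")
    r = b.conv(c3, 128)
    t = b.add([t, r], op="concat")
    p3_td = b.elan_w(t, 128, 128)                 # stride 8

    with_p2 = cfg.variant in ("lsnet", "minus_p5_p2", "plus_p2")
    drop_p5 = cfg.variant in ("lsnet", "minus_p5_p2", "minus_p5")

    if with_p2:
        t = b.conv(p3_td, 64)
        t = b.add(t, op="upsample")
        r = b.conv(c2, 64)
        t = b.add([t, r], op="concat")
        p2_out = b.elan_w(t, 64, 64)              # stride 4

    # -- bottom-up path ------------------------------------------------
    if with_p2:
        rb2, pa = b.mp_branches(p2_out, 64)
        t = b.add([rb2, pa, p3_td], op="concat")
        p3_out = b.elan_w(t, 128, 128)            # stride 8
    else:
        p3_out = p3_td

    rb2, pa = b.mp_branches(p3_out, 128)
    t = b.add([rb2, pa, p4_td], op="concat")
    p4_out = b.elan_w(t, 256, 256)                # stride 16

    if not drop_p5:
        rb2, pa = b.mp_branches(p4_out, 256)
        t = b.add([rb2, pa, top], op="concat")
        p5_out = b.elan_w(t, 512, 512)            # stride 32

    # -- heads -----------------------------------------------------------
    heads: list[int] = []
    if with_p2:
        heads.append(b.head(b.rep(p2_out, 128, cfg.rep_mode), no))
    heads.append(b.head(b.rep(p3_out, 256, cfg.rep_mode), no))
    heads.append(b.head(b.rep(p4_out, 512, cfg.rep_mode), no))
    if not drop_p5:
        heads.append(b.head(b.rep(p5_out, 1024, cfg.rep_mode), no))

    return b.nodes, heads


# ---------------------------------------------------------------------------
# static analysis
# ---------------------------------------------------------------------------

def _node_shapes_params_flops(nodes: list[dict], input_hw: int):
    """Propagate (channels, h, w) through the graph; tally params and FLOPs.

    FLOP convention: 2 x multiply-accumulates, convolution layers only,
    batch norm folded; pooling, up-sampling, activations and elementwise
    gating are not counted.
    """
    shapes: list[tuple[int, int, int]] = []
    params = 0
    flops = 0.0
    for node in nodes:
        src = [(3, input_hw, input_hw) if i == -1 else shapes[i]
               for i in node["from"]]
        op = node["op"]
        if op == "conv":
            c1, h, w = src[0]
            c2, k, s, d = node["c2"], node["k"], node["s"], node["d"]
            g = c1 if node["g"] == -1 else node["g"]
            ho, wo = h // s, w // s
            params += (c1 // g) * c2 * k * k
            if node["bias"]:
                params += c2
            if node["bn"]:
                params += 2 * c2
            flops += 2.0 * (c1 // g) * c2 * k * k * ho * wo
            shapes.append((c2, ho, wo))
        elif op == "maxpool":
            c1, h, w = src[0]
            s = node["s"]
            shapes.append((c1, h // s, w // s))
        elif op == "upsample":
            c1, h, w = src[0]
            shapes.append((c1, h * 2, w * 2))
        elif op == "concat":
            c = sum(c for c, _, _ in src)
            shapes.append((c, src[0][1], src[0][2]))
        elif op in ("add", "mul", "silu"):
            shapes.append(src[0])
        else:  # pragma: no cover
            raise ValueError(f"unknown op {op}")
    return shapes, params, flops


def summarize(cfg: ModelConfig, input_size: int | None = None) -> dict:
    """Static profile of a configuration: parameters, GFLOPs, head grids."""
    nodes, heads = build_graph(cfg)
    size = input_size or cfg.input_size
    if size % 32:
        raise ValueError("input size must be divisible by 32")
    shapes, params, flops = _node_shapes_params_flops(nodes, size)
    return {
        "variant": cfg.variant,
        "input_size": size,
        "parameters": params,
        "gflops": flops / 1e9,
        "head_grids": [shapes[i][1] for i in heads],
        "head_channels": [shapes[i][0] for i in heads],
        "strides": list(cfg.strides),
    }


# ---------------------------------------------------------------------------
# runtime network
# ---------------------------------------------------------------------------

class GraphNet(nn.Module):
    """Executable detector assembled from a graph description."""

    def __init__(self, cfg: ModelConfig):
        super().__init__()
        self.cfg = cfg
        self.graph, self.head_indices = build_graph(cfg)
        rng = np.random.default_rng(cfg.seed)
        modules: list[nn.Module] = []
        shapes, _, _ = _node_shapes_params_flops(self.graph, cfg.input_size)
        self._shapes = shapes
        for idx, node in enumerate(self.graph):
            if node["op"] == "conv":
                c1 = 3 if node["from"][0] == -1 else shapes[node["from"][0]][0]
                g = c1 if node["g"] == -1 else node["g"]
                k, d = node["k"], node["d"]
                pad = (k - 1) * d // 2
                layers: list[nn.Module] = [nn.Conv2d(
                    c1, node["c2"], k, stride=node["s"], padding=pad,
                    dilation=d, groups=g, bias=node["bias"], rng=rng)]
                if node["bn"]:
                    layers.append(nn.BatchNorm2d(node["c2"]))
                if node["act"]:
                    layers.append(nn.SiLU())
                modules.append(nn.Sequential(*layers))
            elif node["op"] == "maxpool":
                modules.append(nn.MaxPool2d(node["k"], node["s"],
                                            padding=(node["k"] - 1) // 2
                                            if node["s"] == 1 else 0))
            else:
                modules.append(nn.Identity())
        self.blocks = modules

        # prior-probability initialisation of the detect-conv biases:
        # objectness starts near sigmoid(-4) so the background-dominated
        # objectness loss is small at step 0, class logits slightly negative
        no = cfg.num_outputs_per_anchor
        for h in self.head_indices:
            bias = self.blocks[h].layers[0].bias
            if bias is not None:
                b = bias.data.reshape(3, no)
                b[:, 4] = -4.0
                b[:, 5:] = -2.0
                bias.data = b.reshape(-1)

        # free intermediates eagerly: last consumer index per node
        last_use = [0] * len(self.graph)
        for idx, node in enumerate(self.graph):
            for src in node["from"]:
                if src >= 0:
                    last_use[src] = idx
        for h in self.head_indices:
            last_use[h] = len(self.graph)
        self._last_use = last_use

    @property
    def num_classes(self) -> int:
        return self.cfg.num_classes

    @property
    def strides(self) -> tuple[int, ...]:
        return self.cfg.strides

    @property
    def anchors(self) -> tuple:
        return self.cfg.anchors

    def forward(self, x: Tensor | np.ndarray) -> list[Tensor]:
        """Run the detector; returns one raw output tensor per head."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError("expected input of shape (N, 3, H, W)")
        if x.shape[2] % 32 or x.shape[3] % 32:
            raise ValueError("input spatial size must be divisible by 32")
        cache: dict[int, Tensor] = {}
        for idx, node in enumerate(self.graph):
            src = [x if i == -1 else cache[i] for i in node["from"]]
            op = node["op"]
            if op in ("conv", "maxpool"):
                out = self.blocks[idx](src[0])
            elif op == "upsample":
                out = F.upsample_nearest(src[0], 2)
            elif op == "concat":
                out = nn.concat(src, axis=1)
            elif op == "add":
                out = src[0] + src[1]
            elif op == "mul":
                out = src[0] * src[1]
            elif op == "silu":
                out = src[0].silu()
            cache[idx] = out
            for i in node["from"]:
                if i >= 0 and self._last_use[i] <= idx:
                    cache.pop(i, None)
        return [cache[i] for i in self.head_indices]

    def forward_features(self, x: Tensor | np.ndarray,
                         indices: Sequence[int]) -> dict[int, Tensor]:
        """Run the graph keeping the requested intermediate activations."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x, dtype=np.float32))
        wanted = set(indices)
        cache: dict[int, Tensor] = {}
        kept: dict[int, Tensor] = {}
        for idx, node in enumerate(self.graph):
            src = [x if i == -1 else cache[i] for i in node["from"]]
            op = node["op"]
            if op in ("conv", "maxpool"):
                out = self.blocks[idx](src[0])
            elif op == "upsample":
                out = F.upsample_nearest(src[0], 2)
            elif op == "concat":
                out = nn.concat(src, axis=1)
            elif op == "add":
                out = src[0] + src[1]
            elif op == "mul":
                out = src[0] * src[1]
            elif op == "silu":
                out = src[0].silu()
            cache[idx] = out
            if idx in wanted:
                kept[idx] = out
            for i in node["from"]:
                if i >= 0 and self._last_use[i] <= idx and i not in wanted:
                    cache.pop(i, None)
        return kept


def build_model(cfg: ModelConfig | None = None, **overrides) -> GraphNet:
    """Instantiate a detector; keyword overrides update the default config."""
    if cfg is None:
        cfg = ModelConfig(**overrides)
    elif overrides:
        raise ValueError("pass either a config or keyword overrides, not both")
    return GraphNet(cfg)


def count_parameters(model: GraphNet) -> int:
    """Total trainable parameter count of an instantiated model."""
    return sum(p.data.size for p in model.parameters())


def count_flops(model: GraphNet | ModelConfig, input_size: int | None = None) -> float:
    """Static GFLOPs (2 x MAC, conv layers only, batch norm folded)."""
    cfg = model.cfg if isinstance(model, GraphNet) else model
    return summarize(cfg, input_size)["gflops"]
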