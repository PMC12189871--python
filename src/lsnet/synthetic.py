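"""Synthetic aerial herd scenes with exact ground truth.

The generator emulates the *statistical structure* of a vertical-view UAV
livestock survey: a grass-textured background, three classes of animals
(sheep, cattle, horses) rendered as anti-aliased elliptical blobs with
class-specific colour and size, clustered into herds, each with a tight
ground-truth bounding box.  Box side lengths are drawn from truncated
normal distributions whose means match the survey statistics (sheep about
20x21 px, cattle 36x38, horse 37x40 at survey resolution) and whose class
mix is dominated by sheep.  Realism is deliberately limited — the point is
separable objects with *known* truth, so that every downstream component
(anchors, tiling, training, evaluation) is testable without the private
survey data.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .boxes import BBox

__all__ = ["ClassSpec", "SceneConfig", "PlacementError", "CLASS_SPECS",
           "sample_box_sizes", "generate_scene", "generate_dataset",
           "split_counts", "DEFAULT_CLASS_NAMES"]

DEFAULT_CLASS_NAMES = ("sheep", "cattle", "horse")


@dataclass(frozen=True)
class ClassSpec:
    """Size distribution and appearance of one animal class.

    Mean box side lengths and truncation ranges follow the survey's
    annotation statistics; the spreads are chosen so that most boxes fall
    in the 10-20 px band for sheep and 25-50 px for cattle/horses.
    """

    name: str
    mean_w: float
    mean_h: float
    sigma_w: float
    sigma_h: float
    range_w: tuple[float, float]
    range_h: tuple[float, float]
    color: tuple[int, int, int]
    color_jitter: float = 18.0


CLASS_SPECS: tuple[ClassSpec, ...] = (
    ClassSpec("sheep", 20.04, 20.89, 5.0, 5.0, (3.0, 61.0), (1.0, 59.0),
              color=(228, 224, 214)),
    ClassSpec("cattle", 35.71, 37.67, 9.0, 9.0, (5.0, 87.0), (6.0, 82.0),
              color=(62, 48, 40)),
    ClassSpec("horse", 37.16, 39.71, 9.0, 9.0, (8.0, 83.0), (7.0, 82.0),
              color=(128, 78, 52)),
)


class PlacementError(RuntimeError):
    """Could not place every requested animal at the required separation."""


@dataclass(frozen=True)
class SceneConfig:
    """One scene's layout parameters.

    ``counts`` orders animals as (sheep, cattle, horse); the default mix
    mirrors the survey's class proportions (roughly 76:21:3) at its mean
    density of ~22 animals per 1024 px patch.
    """

    patch_size: int = 1024
    counts: tuple[int, ...] = (17, 5, 1)
    class_specs: tuple[ClassSpec, ...] = CLASS_SPECS
    animals_per_herd: int = 12
    herd_spread: float = 70.0
    min_separation_factor: float = 0.7
    background_base: tuple[int, int, int] = (96, 116, 66)
    max_retries: int = 200
    seed: int = 0

    def __post_init__(self):
        if len(self.counts) != len(self.class_specs):
            raise ValueError("one count per class required")
        if any(c < 0 for c in self.counts):
            raise ValueError("counts must be non-negative")


def _truncated_normal(rng: np.random.Generator, mean: float, sigma: float,
                      lo: float, hi: float, n: int) -> np.ndarray:
    """Rejection-sampled truncated normal (exact, deterministic given rng)."""
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(mean, sigma, size=max(n - filled, 16))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(ok.size, n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return out


def sample_box_sizes(spec: ClassSpec, n: int,
                     rng: np.random.Generator) -> np.ndarray:
    """Draw n (w, h) box-side pairs for one class."""
    w = _truncated_normal(rng, spec.mean_w, spec.sigma_w, *spec.range_w, n=n)
    h = _truncated_normal(rng, spec.mean_h, spec.sigma_h, *spec.range_h, n=n)
    return np.stack([w, h], axis=1)


def _background(size: int, base: tuple[int, int, int],
                rng: np.random.Generator) -> np.ndarray:
    """Grass-like texture: multi-scale smoothed value noise plus fine grain."""
    field_ = np.zeros((size, size))
    for sigma, amp in ((size / 8, 10.0), (size / 32, 6.0), (2.0, 5.0)):
        noise = gaussian_filter(rng.normal(size=(size, size)), sigma)
        std = noise.std()
        if std > 0:
            field_ += amp * noise / std
    img = np.empty((size, size, 3), dtype=float)
    for c in range(3):
        img[..., c] = base[c] + field_ + rng.normal(0, 2.0, size=(size, size))
    return np.clip(img, 0, 255)


def _ellipse_axes(w: float, h: float, theta: float) -> tuple[float, float]:
    """Semi-axes of the rotated ellipse whose tight support box is (w, h)."""
    c, s = np.cos(theta) ** 2, np.sin(theta) ** 2
    W2, H2 = (w / 2) ** 2, (h / 2) ** 2
    det = c - s
    a2 = (W2 * c - H2 * s) / det
    b2 = (H2 * c - W2 * s) / det
    return float(np.sqrt(a2)), float(np.sqrt(b2))


def _render_blob(img: np.ndarray, cx: float, cy: float, w: float, h: float,
                 theta: float, color: np.ndarray) -> tuple[int, int, int, int] | None:
    """Draw one anti-aliased elliptical body plus a soft shadow.

    Returns the rendered support box (x1, y1, x2, y2) of the body (pixels
    where body coverage exceeds one half), or None if nothing was drawn.
    """
    size = img.shape[0]
    a, b = _ellipse_axes(w, h, theta)
    pad = 3
    x1 = max(int(np.floor(cx - w / 2)) - pad, 0)
    y1 = max(int(np.floor(cy - h / 2)) - pad, 0)
    x2 = min(int(np.ceil(cx + w / 2)) + pad, size)
    y2 = min(int(np.ceil(cy + h / 2)) + pad, size)
    if x1 >= x2 or y1 >= y2:
        return None
    ys, xs = np.mgrid[y1:y2, x1:x2]
    dx, dy = xs + 0.5 - cx, ys + 0.5 - cy
    ct, st = np.cos(theta), np.sin(theta)
    u = dx * ct + dy * st
    v = -dx * st + dy * ct
    q = np.sqrt((u / a) ** 2 + (v / b) ** 2)
    feather = 1.0 / max(min(a, b), 1.0)
    alpha = np.clip((1.0 - q) / feather + 0.5, 0.0, 1.0)

    # soft shadow, offset toward bottom-right, under the body
    sdx, sdy = dx - 2.0, dy - 2.0
    su = sdx * ct + sdy * st
    sv = -sdx * st + sdy * ct
    sq = np.sqrt((su / a) ** 2 + (sv / b) ** 2)
    shadow = np.clip((1.0 - sq) / (3 * feather) + 0.5, 0.0, 1.0) * 0.35
    region = img[y1:y2, x1:x2]
    region *= (1.0 - shadow[..., None] * (1.0 - alpha[..., None]))

    # body with a mild top-left highlight for volume
    highlight = 1.0 + 0.15 * np.clip(-(u + v) / max(a, b), -1, 1)
    body = np.clip(color[None, None, :] * highlight[..., None], 0, 255)
    region += alpha[..., None] * (body - region)

    support = alpha >= 0.5
    if not support.any():
        return None
    rows = np.flatnonzero(support.any(axis=1))
    cols = np.flatnonzero(support.any(axis=0))
    return (x1 + cols[0], y1 + rows[0], x1 + cols[-1] + 1, y1 + rows[-1] + 1)


def _place_centres(cfg: SceneConfig, sizes: list[np.ndarray],
                   rng: np.random.Generator) -> list[np.ndarray]:
    """Herd-clustered centres with pairwise minimum separation."""
    size = cfg.patch_size
    placed_xy: list[tuple[float, float]] = []
    placed_d: list[float] = []
    out: list[np.ndarray] = []
    for class_idx, wh in enumerate(sizes):
        n = wh.shape[0]
        centres = np.empty((n, 2))
        n_herds = max(1, int(np.ceil(n / cfg.animals_per_herd)))
        margin = 40.0
        herd_xy = rng.uniform(margin, size - margin, size=(n_herds, 2))
        for i in range(n):
            diam = float(np.sqrt(wh[i, 0] * wh[i, 1]))
            herd = herd_xy[rng.integers(n_herds)]
            ok = False
            for _ in range(cfg.max_retries):
                cx, cy = herd + rng.normal(0, cfg.herd_spread, size=2)
                if not (wh[i, 0] / 2 + 1 <= cx <= size - wh[i, 0] / 2 - 1 and
                        wh[i, 1] / 2 + 1 <= cy <= size - wh[i, 1] / 2 - 1):
                    continue
                good = True
                for (px, py), pd in zip(placed_xy, placed_d):
                    min_d = cfg.min_separation_factor * 0.5 * (diam + pd)
                    if (cx - px) ** 2 + (cy - py) ** 2 < min_d ** 2:
                        good = False
                        break
                if good:
                    ok = True
                    break
                herd = herd_xy[rng.integers(n_herds)]
            if not ok:
                raise PlacementError(
                    f"could not place animal {i} of class {class_idx} after "
                    f"{cfg.max_retries} retries; reduce counts or separation")
            centres[i] = (cx, cy)
            placed_xy.append((cx, cy))
            placed_d.append(diam)
        out.append(centres)
    return out


def generate_scene(cfg: SceneConfig,
                   seed: int | None = None) -> tuple[np.ndarray, list[BBox]]:
    """Render one scene; returns (uint8 RGB image, ground-truth boxes).

    Deterministic: the same config and seed give a byte-identical image
    and label list.  Ground-truth boxes are the tight pixel-support boxes
    of the rendered bodies (shadows excluded).
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    img = _background(cfg.patch_size, cfg.background_base, rng)
    sizes = [sample_box_sizes(spec, n, rng) if n else np.zeros((0, 2))
             for spec, n in zip(cfg.class_specs, cfg.counts)]
    centres = _place_centres(cfg, sizes, rng)

    boxes: list[BBox] = []
    for class_idx, (spec, wh, ctr) in enumerate(zip(cfg.class_specs, sizes, centres)):
        for i in range(wh.shape[0]):
            w, h = float(wh[i, 0]), float(wh[i, 1])
            theta_max = 0.9 * np.arctan(min(w, h) / max(w, h))
            theta = rng.uniform(-theta_max, theta_max)
            color = np.clip(np.array(spec.color, dtype=float) +
                            rng.normal(0, spec.color_jitter, size=3), 0, 255)
            support = _render_blob(img, ctr[i, 0], ctr[i, 1], w, h, theta, color)
            if support is not None:
                boxes.append(BBox.from_xyxy(*support, class_id=class_idx))
    return np.clip(img, 0, 255).astype(np.uint8), boxes


def split_counts(n: int, ratios: tuple[float, float, float] = (0.81, 0.09, 0.10)
                 ) -> tuple[int, int, int]:
    """Train/val/test scene counts under the nested 9:1, 9:1 partition."""
    if not np.isclose(sum(ratios), 1.0):
        raise ValueError("split ratios must sum to 1")
    n_test = int(round(n * ratios[2]))
    n_val = int(round((n - n_test) * ratios[1] / (ratios[0] + ratios[1])))
    return n - n_val - n_test, n_val, n_test


def generate_dataset(cfg: SceneConfig, n_scenes: int, out_dir: str | Path,
                     split_ratios: tuple[float, float, float] = (0.81, 0.09, 0.10),
                     master_seed: int | None = None) -> dict[str, list[str]]:
    """Write a YOLO-layout dataset tree of synthetic scenes.

    Produces ``images/{train,val,test}/*.png`` and matching
    ``labels/{split}/*.txt`` (``class cx cy w h`` normalised) plus a
    ``classes.txt`` list.  Scene i is generated from ``master_seed + i``,
    so regeneration with the same master seed is identical; the split
    assignment is a seeded permutation.
    """
    from . import data as data_io

    out = Path(out_dir)
    master_seed = cfg.seed if master_seed is None else master_seed
    n_train, n_val, n_test = split_counts(n_scenes, split_ratios)
    order = np.random.default_rng(master_seed).permutation(n_scenes)
    split_of = {}
    for pos, idx in enumerate(order):
        split_of[int(idx)] = ("train" if pos < n_train else
                              "val" if pos < n_train + n_val else "test")
    written: dict[str, list[str]] = {"train": [], "val": [], "test": []}
    for split in written:
        (out / "images" / split).mkdir(parents=True, exist_ok=True)
        (out / "labels" / split).mkdir(parents=True, exist_ok=True)
    for i in range(n_scenes):
        img, boxes = generate_scene(cfg, seed=master_seed + i)
        split = split_of[i]
        stem = f"scene_{i:05d}"
        data_io.save_image(out / "images" / split / f"{stem}.png", img)
        data_io.write_yolo_labels(out / "labels" / split / f"{stem}.txt",
                                  boxes, cfg.patch_size, cfg.patch_size)
        written[split].append(stem)
    names = [s.name for s in cfg.class_specs]
    (out / "classes.txt").write_text("\n".join(names) + "\n")
    return written
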