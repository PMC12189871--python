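"""Overlapping-tile processing of large aerial frames.

UAV survey frames (e.g. 7952x5304) are far larger than the detector input,
and the animals in them only a few tens of pixels, so frames are split into
fixed-size square tiles with a 50% overlap: any animal cut by one tile
boundary lies fully inside a neighbouring tile.  Detections from all tiles
are mapped back to frame coordinates and de-duplicated with class-wise NMS.

Conventions: 0-based pixel coordinates, half-open tiles
``[x0, x0 + tile)``; the final tile along each axis is clamped to the frame
edge (so tile content is always real pixels); frames smaller than the tile
are padded bottom-right with neutral gray (114, 114, 114).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .boxes import BBox, Detection, detections_to_arrays
from .decode import nms

__all__ = ["TileGrid", "compute_grid", "clip_annotations", "merge_detections",
           "extract_tiles", "PAD_VALUE"]

PAD_VALUE = 114  # neutral gray, the letterboxing convention


@dataclass(frozen=True)
class TileGrid:
    """Tile origins covering one frame."""

    frame_w: int
    frame_h: int
    tile: int
    overlap: int
    origins: tuple[tuple[int, int], ...]

    @property
    def stride(self) -> int:
        return self.tile - self.overlap

    def __len__(self) -> int:
        return len(self.origins)


def _axis_origins(dim: int, tile: int, stride: int) -> list[int]:
    if dim <= tile:
        return [0]
    starts = list(range(0, dim - tile + 1, stride))
    if starts[-1] != dim - tile:
        starts.append(dim - tile)
    return starts


def compute_grid(frame_w: int, frame_h: int, tile: int = 1024,
                 overlap: int = 512) -> TileGrid:
    """Tile origins at multiples of ``tile - overlap``, last clamped to the edge."""
    if frame_w < 1 or frame_h < 1:
        raise ValueError("frame dimensions must be positive")
    if not 0 <= overlap < tile:
        raise ValueError(f"overlap must satisfy 0 <= overlap < tile, got "
                         f"overlap={overlap}, tile={tile}")
    stride = tile - overlap
    xs = _axis_origins(frame_w, tile, stride)
    ys = _axis_origins(frame_h, tile, stride)
    origins = tuple((x, y) for y in ys for x in xs)
    return TileGrid(frame_w, frame_h, tile, overlap, origins)


def clip_annotations(grid: TileGrid, boxes: list[BBox],
                     min_visibility: float = 0.3,
                     min_size: float = 2.0) -> list[list[BBox]]:
    """Clip frame-coordinate boxes into each tile (tile-local coordinates).

    A clipped box is kept when its visible fraction — clipped area over
    original area — is at least ``min_visibility`` and both clipped sides
    are at least ``min_size`` pixels.  A box inside several overlapping
    tiles appears in each of them.
    """
    per_tile: list[list[BBox]] = []
    for (x0, y0) in grid.origins:
        x1t, y1t = x0 + grid.tile, y0 + grid.tile
        kept: list[BBox] = []
        for b in boxes:
            cx1, cy1 = max(b.x1, x0), max(b.y1, y0)
            cx2, cy2 = min(b.x2, x1t), min(b.y2, y1t)
            w, h = cx2 - cx1, cy2 - cy1
            if w <= 0 or h <= 0 or w < min_size or h < min_size:
                continue
            if (w * h) / b.area < min_visibility:
                continue
            kept.append(BBox.from_xyxy(cx1 - x0, cy1 - y0, cx2 - x0, cy2 - y0,
                                       b.class_id))
        per_tile.append(kept)
    return per_tile


def merge_detections(per_tile: list[list[Detection]], grid: TileGrid,
                     merge_iou: float = 0.5) -> list[Detection]:
    """Map tile-local detections to frame coordinates and de-duplicate.

    Duplicates of one animal seen in several overlapping tiles are
    collapsed by class-wise NMS at ``merge_iou``, keeping the
    highest-confidence copy.
    """
    if len(per_tile) != len(grid.origins):
        raise ValueError("one detection list per tile expected")
    shifted: list[Detection] = []
    for dets, (x0, y0) in zip(per_tile, grid.origins):
        shifted.extend(d.shift(x0, y0) for d in dets)
    if not shifted:
        return []
    boxes, cls, conf = detections_to_arrays(shifted)
    merged: list[Detection] = []
    for c in np.unique(cls):
        sel = np.flatnonzero(cls == c)
        keep = nms(boxes[sel], conf[sel], merge_iou)
        merged.extend(shifted[sel[i]] for i in keep)
    merged.sort(key=lambda d: -d.confidence)
    return merged


def extract_tiles(image: np.ndarray, grid: TileGrid) -> list[np.ndarray]:
    """Cut (H, W, C) image tiles, gray-padding frames smaller than the tile."""
    h, w = image.shape[:2]
    if (w, h) != (grid.frame_w, grid.frame_h):
        raise ValueError("image dimensions do not match the grid")
    tiles = []
    for (x0, y0) in grid.origins:
        patch = image[y0:y0 + grid.tile, x0:x0 + grid.tile]
        if patch.shape[0] < grid.tile or patch.shape[1] < grid.tile:
            canvas = np.full((grid.tile, grid.tile) + image.shape[2:],
                             PAD_VALUE, dtype=image.dtype)
            canvas[:patch.shape[0], :patch.shape[1]] = patch
            patch = canvas
        tiles.append(patch)
    return tiles
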