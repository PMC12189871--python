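"""Shared fixtures: small synthetic scenes and reduced-width models."""

from __future__ import annotations

import numpy as np
import pytest

from lsnet.anchors import assign_to_heads, cluster_anchors
from lsnet.model import ModelConfig, build_model
from lsnet.synthetic import SceneConfig, generate_scene


@pytest.fixture(scope="session")
def small_scenes():
    """Eight 160-px scenes with survey-like object sizes and known truth."""
    scenes = []
    cfg = SceneConfig(patch_size=160, counts=(4, 2, 2), herd_spread=60.0)
    for i in range(8):
        img, boxes = generate_scene(cfg, seed=100 + i)
        t = np.array([[b.class_id, b.cx, b.cy, b.w, b.h] for b in boxes],
                     dtype=float).reshape(-1, 5)
        scenes.append(((img.astype(np.float32) / 255).transpose(2, 0, 1), t))
    return scenes


@pytest.fixture(scope="session")
def small_anchors(small_scenes):
    wh = np.concatenate([t[:, 3:5] for _, t in small_scenes])
    return assign_to_heads(cluster_anchors(wh, 9, seed=0))


@pytest.fixture(scope="session")
def tiny_model(small_anchors):
    """Width-reduced LSNET for fast real forward/backward passes."""
    cfg = ModelConfig(variant="lsnet", num_classes=3, width_multiple=0.125,
                      input_size=160, anchors=small_anchors, seed=0)
    return build_model(cfg)
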