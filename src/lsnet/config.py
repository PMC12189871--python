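"""YAML run configuration.

A run file has up to three sections — ``model``, ``train``, ``synth`` —
whose keys map directly onto :class:`~lsnet.model.ModelConfig`,
:class:`~lsnet.train.TrainConfig` and :class:`~lsnet.synthetic.SceneConfig`
fields.  Anchors may be given as nine ``[w, h]`` pairs (grouped
3-per-head automatically) or as three triplets.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .anchors import AnchorSet, assign_to_heads
from .losses import FocusingConfig
from .model import ModelConfig
from .synthetic import SceneConfig
from .train import TrainConfig

__all__ = ["load_run_config", "model_config_from_dict", "train_config_from_dict",
           "scene_config_from_dict", "anchors_from_value"]


def anchors_from_value(value) -> tuple:
    """Normalise an anchors entry: 9 flat pairs or 3 triplets of pairs."""
    value = list(value)
    if value and isinstance(value[0][0], (int, float)):
        if len(value) % 3:
            raise ValueError("a flat anchor list must hold 3 pairs per head")
        anchor_set = AnchorSet(tuple((float(w), float(h)) for w, h in value))
        return assign_to_heads(anchor_set, num_heads=len(value) // 3)
    return tuple(tuple((float(w), float(h)) for w, h in head) for head in value)


def model_config_from_dict(d: dict | None) -> ModelConfig:
    d = dict(d or {})
    if "anchors" in d:
        d["anchors"] = anchors_from_value(d["anchors"])
    return ModelConfig(**d)


def train_config_from_dict(d: dict | None) -> TrainConfig:
    d = dict(d or {})
    if "focusing" in d:
        d["focusing"] = FocusingConfig(**d["focusing"])
    return TrainConfig(**d)


def scene_config_from_dict(d: dict | None) -> SceneConfig:
    d = dict(d or {})
    if "counts" in d:
        d["counts"] = tuple(d["counts"])
    return SceneConfig(**d)


def load_run_config(path: str | Path) -> dict:
    """Load a YAML run file into instantiated config objects."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    return {
        "model": model_config_from_dict(raw.get("model")),
        "train": train_config_from_dict(raw.get("train")),
        "synth": scene_config_from_dict(raw.get("synth")),
        "raw": raw,
    }
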