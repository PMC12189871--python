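"""Reading and writing YOLO-layout detection data.

Labels are one text file per image, one ``class cx cy w h`` line per box,
coordinates normalised to the image size.  Detections serialise the same
way with the confidence appended after the class
(``class conf cx cy w h``), matching common evaluation tooling.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
from PIL import Image

from .boxes import BBox, Detection

__all__ = [
    "load_image", "save_image", "read_yolo_labels", "write_yolo_labels",
    "read_detections", "write_detections", "read_class_names",
    "list_image_label_pairs",
]

IMAGE_EXTENSIONS = (".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff")


def load_image(path: str | Path) -> np.ndarray:
    """Load an image as (H, W, 3) uint8 RGB."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def save_image(path: str | Path, image: np.ndarray) -> None:
    Image.fromarray(np.asarray(image, dtype=np.uint8)).save(path)


def read_yolo_labels(path: str | Path, img_w: int, img_h: int) -> list[BBox]:
    """Parse a YOLO label file into pixel-coordinate boxes."""
    boxes: list[BBox] = []
    text = Path(path).read_text()
    for ln, line in enumerate(text.splitlines(), 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 5:
            raise ValueError(f"{path}:{ln}: expected 5 fields, got {len(parts)}")
        cls, cx, cy, w, h = parts
        boxes.append(BBox(float(cx) * img_w, float(cy) * img_h,
                          float(w) * img_w, float(h) * img_h, int(cls)))
    return boxes


def write_yolo_labels(path: str | Path, boxes: list[BBox],
                      img_w: int, img_h: int) -> None:
    lines = []
    for b in boxes:
        cls = 0 if b.class_id is None else int(b.class_id)
        lines.append(f"{cls} {b.cx / img_w:.6f} {b.cy / img_h:.6f} "
                     f"{b.w / img_w:.6f} {b.h / img_h:.6f}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_detections(path: str | Path, img_w: int, img_h: int) -> list[Detection]:
    """Parse a detections file (``class conf cx cy w h`` normalised)."""
    dets: list[Detection] = []
    for ln, line in enumerate(Path(path).read_text().splitlines(), 1):
        parts = line.split()
        if not parts:
            continue
        if len(parts) != 6:
            raise ValueError(f"{path}:{ln}: expected 6 fields, got {len(parts)}")
        cls, conf, cx, cy, w, h = parts
        dets.append(Detection(BBox(float(cx) * img_w, float(cy) * img_h,
                                   float(w) * img_w, float(h) * img_h),
                              int(cls), float(conf)))
    return dets


def write_detections(path: str | Path, dets: list[Detection],
                     img_w: int, img_h: int) -> None:
    lines = [f"{d.class_id} {d.confidence:.6f} {d.box.cx / img_w:.6f} "
             f"{d.box.cy / img_h:.6f} {d.box.w / img_w:.6f} {d.box.h / img_h:.6f}"
             for d in dets]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_class_names(path: str | Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def list_image_label_pairs(images_dir: str | Path,
                           labels_dir: str | Path) -> list[tuple[Path, Path]]:
    """Pair image files with their label files by stem; labels must exist."""
    images_dir, labels_dir = Path(images_dir), Path(labels_dir)
    pairs = []
    for img in sorted(images_dir.iterdir()):
        if img.suffix.lower() not in IMAGE_EXTENSIONS:
            continue
        label = labels_dir / f"{img.stem}.txt"
        if not label.exists():
            raise FileNotFoundError(f"no label file for {img.name}: {label}")
        pairs.append((img, label))
    return pairs
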