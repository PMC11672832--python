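"""Dataset I/O: YOLO-format labels, dataset YAML manifests, letterboxing.

Label dialect: one ``.txt`` per image, whitespace-separated rows
``class cx cy w h`` with coordinates normalized to [0, 1] and 0-based
class ids. The dataset YAML lists the root path, train/val image
directories and the class-name mapping.
"""

from __future__ import annotations

import os
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import yaml
from skimage.transform import resize


def read_labels(path) -> np.ndarray:
    """Return an (n, 5) float array of [class, cx, cy, w, h] rows."""
    path = Path(path)
    if not path.exists() or path.stat().st_size == 0:
        return np.zeros((0, 5), dtype=np.float64)
    rows = np.atleast_2d(np.loadtxt(path, dtype=np.float64, ndmin=2))
    return rows.reshape(-1, 5)


def write_labels(path, rows) -> None:
    rows = np.asarray(rows, dtype=np.float64).reshape(-1, 5)
    with open(path, "w") as fh:
        for r in rows:
            fh.write(f"{int(r[0])} {r[1]:.6f} {r[2]:.6f} {r[3]:.6f} {r[4]:.6f}\n")


def read_image(path) -> np.ndarray:
    """Load an image as float32 RGB in [0, 1], shape (H, W, 3)."""
    img = iio.imread(path)
    if img.ndim == 2:
        img = np.stack([img] * 3, axis=-1)
    if img.shape[-1] == 4:
        img = img[..., :3]
    return img.astype(np.float32) / 255.0


def write_image(path, img) -> None:
    arr = np.clip(np.asarray(img) * 255.0, 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)


def load_dataset_yaml(path) -> dict:
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    root = Path(spec.get("path", Path(path).parent))
    if not root.is_absolute():
        root = Path(path).parent / root
    out = {"path": root, "names": spec["names"]}
    for split in ("train", "val"):
        if split in spec:
            out[split] = root / spec[split]
    return out


def label_path_for(image_path) -> Path:
    p = Path(image_path)
    parts = list(p.parts)
    if "images" in parts:
        parts[len(parts) - 1 - parts[::-1].index("images")] = "labels"
        return Path(*parts).with_suffix(".txt")
    return p.with_suffix(".txt")


def list_images(directory) -> list:
    exts = {".png", ".jpg", ".jpeg", ".bmp", ".tif", ".tiff"}
    return sorted(p for p in Path(directory).iterdir() if p.suffix.lower() in exts)


def letterbox(img: np.ndarray, size: int, fill: float = 114 / 255.0):
    """Aspect-preserving resize onto a size x size canvas with gray padding.

    Returns (canvas, scale, (pad_x, pad_y)); a pixel (x, y) of the source
    maps to (x * scale + pad_x, y * scale + pad_y).
    """
    h, w = img.shape[:2]
    scale = min(size / w, size / h)
    nw, nh = int(round(w * scale)), int(round(h * scale))
    resized = resize(img, (nh, nw), order=1, anti_aliasing=scale < 1.0,
                     preserve_range=True).astype(np.float32)
    canvas = np.full((size, size, img.shape[2]), fill, dtype=np.float32)
    px = (size - nw) // 2
    py = (size - nh) // 2
    canvas[py:py + nh, px:px + nw] = resized
    return canvas, scale, (px, py)


def boxes_to_letterbox(boxes: np.ndarray, src_wh, size: int, scale, pad):
    """Map normalized cxcywh boxes from source frame to letterboxed frame."""
    if len(boxes) == 0:
        return boxes.reshape(-1, 5)
    out = boxes.copy()
    w, h = src_wh
    px, py = pad
    out[:, 1] = (boxes[:, 1] * w * scale + px) / size
    out[:, 2] = (boxes[:, 2] * h * scale + py) / size
    out[:, 3] = boxes[:, 3] * w * scale / size
    out[:, 4] = boxes[:, 4] * h * scale / size
    return out


class YoloDataset:
    """Iterable of (image, boxes) pairs from a dataset YAML split."""

    def __init__(self, yaml_path, split: str = "train"):
        spec = load_dataset_yaml(yaml_path)
        if split not in spec:
            raise ValueError(f"split {split!r} not present in {yaml_path}")
        self.image_dir = spec[split]
        self.names = spec["names"]
        self.images = list_images(self.image_dir)
        if not self.images:
            raise ValueError(f"no images found under {self.image_dir}")

    def __len__(self):
        return len(self.images)

    def __getitem__(self, i):
        img = read_image(self.images[i])
        boxes = read_labels(label_path_for(self.images[i]))
        return img, boxes
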