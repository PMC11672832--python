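"""Detector assembly: config-driven graph building with a stable layer
numbering, augmentation, NMS, training loop and checkpoint I/O.

The graph follows the public YOLOv8 layout — stem, four C2f backbone
stages, SPPF, PAN neck with four C2f fusion blocks, three-level head —
so that the canonical sequential numbering puts the four neck fusion
outputs at indices 12, 15, 18 and 21 (the knowledge-distillation hook
sites) and the head at index 22. The C2f flavour per stage and the head
flavour are selected from :class:`ModelConfig`, which is sufficient to
build every ablation variant (baseline, +star, +star-EMA, full BCS
model) and the larger teacher scale.
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import nn
from .nn import Tensor, concat
from .blocks import Conv, SPPF, make_c2f
from .head import (HeadConfig, SSLDH, BaselineHead, Detection, decode_boxes)
from .losses import DetectionLoss
from . import data as dio

_SCALES = {"n": 0.25, "s": 0.5}
_BASE_WIDTHS = (64, 128, 256, 512, 1024)
_BASE_DEPTHS = (3, 6, 6, 3)
_DEPTH_MULT = {"n": 1 / 3, "s": 1 / 3}

BLOCK_VARIANTS = ("c2f_baseline", "c2f_star", "c2f_star_ema")
HEAD_VARIANTS = ("baseline_decoupled", "ssldh")

# the named ablation variants
VARIANT_ALIASES = {
    "baseline": ("c2f_baseline", "baseline_decoupled"),
    "star": ("c2f_star", "baseline_decoupled"),
    "star-ema": ("c2f_star_ema", "baseline_decoupled"),
    "bcs": ("c2f_star_ema", "ssldh"),
}


@dataclass
class ModelConfig:
    scale: str = "n"
    num_classes: int = 5
    block_variant: str = "c2f_star_ema"
    head_variant: str = "ssldh"
    input_size: int = 640
    reg_max: int = 16
    star_expand_ratio: float = 2.5
    ema_groups: int = 4
    ema_variant: str = "full"
    head_hidden: int | None = None
    gn_groups: int = 16
    width_mult: float | None = None    # override for scaled-down experiments

    def __post_init__(self):
        if self.scale not in _SCALES and self.width_mult is None:
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.block_variant not in BLOCK_VARIANTS:
            raise ValueError(f"unknown block variant {self.block_variant!r}")
        if self.head_variant not in HEAD_VARIANTS:
            raise ValueError(f"unknown head variant {self.head_variant!r}")
        if self.input_size % 32:
            raise ValueError("input_size must be divisible by 32")

    @property
    def widths(self) -> tuple:
        w = self.width_mult if self.width_mult is not None \
            else _SCALES[self.scale]
        return tuple(max(8, int(round(c * w / 8) * 8)) for c in _BASE_WIDTHS)

    @property
    def depths(self) -> tuple:
        d = _DEPTH_MULT.get(self.scale, 1 / 3)
        return tuple(max(1, round(n * d)) for n in _BASE_DEPTHS)

    @classmethod
    def from_variant(cls, variant: str, scale: str = "n", **kw) -> "ModelConfig":
        if variant not in VARIANT_ALIASES:
            raise ValueError(f"unknown variant {variant!r}; "
                             f"choose from {sorted(VARIANT_ALIASES)}")
        block, head = VARIANT_ALIASES[variant]
        return cls(scale=scale, block_variant=block, head_variant=head, **kw)


class _Concat(nn.Module):
    def forward(self, xs):
        return concat(xs, axis=1)


class DetectionModel(nn.Module):
    """Executable detector graph with stable top-level numbering 0..22."""

    # per-layer source indices (-1 = previous layer)
    _FROM = [-1, -1, -1, -1, -1, -1, -1, -1, -1, -1,
             -1, [-1, 6], -1, -1, [-1, 4], -1, -1, [-1, 12], -1, -1,
             [-1, 9], -1, [15, 18, 21]]

    def __init__(self, cfg: ModelConfig, seed: int = 0):
        super().__init__()
        nn.manual_seed(seed)
        self.config = cfg
        c1, c2, c3, c4, c5 = cfg.widths
        d1, d2, d3, d4 = cfg.depths
        bv = cfg.block_variant
        kw = dict(expand_ratio=cfg.star_expand_ratio,
                  ema_groups=cfg.ema_groups, ema_variant=cfg.ema_variant)

        def c2f(ci, co, n, shortcut):
            return make_c2f(ci, co, n, shortcut, bv, **kw)

        head_cfg = HeadConfig(
            level_channels=(c3, c4, c5), level_strides=(8, 16, 32),
            hidden_channels=cfg.head_hidden or c3,
            gn_groups=cfg.gn_groups, num_classes=cfg.num_classes,
            reg_max=cfg.reg_max)
        self.head_cfg = head_cfg
        head = SSLDH(head_cfg) if cfg.head_variant == "ssldh" \
            else BaselineHead(head_cfg)
        self.layers = nn.ModuleList([
            Conv(3, c1, 3, 2),            # 0  P1/2
            Conv(c1, c2, 3, 2),           # 1  P2/4
            c2f(c2, c2, d1, True),        # 2
            Conv(c2, c3, 3, 2),           # 3  P3/8
            c2f(c3, c3, d2, True),        # 4
            Conv(c3, c4, 3, 2),           # 5  P4/16
            c2f(c4, c4, d3, True),        # 6
            Conv(c4, c5, 3, 2),           # 7  P5/32
            c2f(c5, c5, d4, True),        # 8
            SPPF(c5, c5),                 # 9
            nn.Upsample(2),               # 10
            _Concat(),                    # 11
            c2f(c5 + c4, c4, 1, False),   # 12  <- distill site
            nn.Upsample(2),               # 13
            _Concat(),                    # 14
            c2f(c4 + c3, c3, 1, False),   # 15  <- distill site (P3 out)
            Conv(c3, c3, 3, 2),           # 16
            _Concat(),                    # 17
            c2f(c3 + c4, c4, 1, False),   # 18  <- distill site (P4 out)
            Conv(c4, c4, 3, 2),           # 19
            _Concat(),                    # 20
            c2f(c4 + c5, c5, 1, False),   # 21  <- distill site (P5 out)
            head,                         # 22
        ])

    @property
    def head(self):
        return self.layers[22]

    def numbering(self) -> dict:
        return {i: type(m).__name__ for i, m in enumerate(self.layers)}

    def forward(self, x, capture=None):
        """Run the graph. `capture` is an iterable of layer indices whose
        outputs are returned alongside the head output."""
        capture = set(capture or ())
        needed = {4, 6, 9, 12, 15, 18, 21} | capture
        saved: dict[int, Tensor] = {}
        captured: dict[int, Tensor] = {}
        y = x
        for i, (mod, src) in enumerate(zip(self.layers, self._FROM)):
            if isinstance(src, list):
                if i == 22:
                    y = mod(*[saved[j] for j in src])
                else:
                    inputs = [y if j == -1 else saved[j] for j in src]
                    y = mod(inputs)
            else:
                y = mod(y)
            if i in needed:
                saved[i] = y
            if i in capture:
                captured[i] = y
        return (y, captured) if capture else y


def build_model(cfg: ModelConfig, seed: int = 0) -> DetectionModel:
    return DetectionModel(cfg, seed=seed)


# --------------------------------------------------------------------------
# checkpoint I/O
# --------------------------------------------------------------------------

def save_checkpoint(model: DetectionModel, file, precision: str = "single"):
    """Single-file archive: architecture config, layer numbering map, and
    the full state (weights + norm statistics) at the stated precision."""
    if precision not in ("single", "half"):
        raise ValueError("precision must be 'single' or 'half'")
    dtype = np.float16 if precision == "half" else np.float32
    state = model.state_dict()
    arrays = {k: np.asarray(v).astype(dtype) for k, v in state.items()}
    meta = {
        "format": "bcsyolo-checkpoint-v1",
        "config": asdict(model.config) if model.config is not None else None,
        "precision": precision,
        "numbering": model.numbering() if hasattr(model, "numbering") else {},
        "entries": [{"name": k, "shape": list(np.asarray(v).shape)}
                    for k, v in state.items()],
    }
    arrays["__meta__"] = np.frombuffer(
        json.dumps(meta).encode("utf-8"), dtype=np.uint8)
    if isinstance(file, (str, Path)):
        with open(file, "wb") as fh:
            np.savez(fh, **arrays)
    else:
        np.savez(file, **arrays)


def load_checkpoint(file, seed: int = 0) -> DetectionModel:
    with np.load(file if not isinstance(file, (str, Path)) else str(file),
                 allow_pickle=False) as zf:
        meta = json.loads(bytes(zf["__meta__"]).decode("utf-8"))
        state = {k: zf[k].astype(np.float32)
                 for k in zf.files if k != "__meta__"}
    cfg = ModelConfig(**meta["config"])
    model = DetectionModel(cfg, seed=seed)
    model.load_state_dict(state)
    return model


# --------------------------------------------------------------------------
# NMS
# --------------------------------------------------------------------------

def box_iou_xyxy(a: np.ndarray, b: np.ndarray) -> float:
    ix = max(0.0, min(a[2], b[2]) - max(a[0], b[0]))
    iy = max(0.0, min(a[3], b[3]) - max(a[1], b[1]))
    inter = ix * iy
    area_a = (a[2] - a[0]) * (a[3] - a[1])
    area_b = (b[2] - b[0]) * (b[3] - b[1])
    denom = area_a + area_b - inter
    return inter / denom if denom > 0 else 0.0


def nms(dets: list, iou_threshold: float = 0.7) -> list:
    """Greedy per-class suppression by descending confidence; ties broken
    by ascending input index (stable)."""
    order = sorted(range(len(dets)),
                   key=lambda i: (-dets[i].confidence, i))
    keep: list[int] = []
    for i in order:
        d = dets[i]
        if all(dets[j].class_id != d.class_id
               or box_iou_xyxy(d.box, dets[j].box) <= iou_threshold
               for j in keep):
            keep.append(i)
    return [dets[i] for i in sorted(keep)]


# --------------------------------------------------------------------------
# augmentation
# --------------------------------------------------------------------------

@dataclass
class AugmentConfig:
    hsv_h: float = 0.015
    hsv_s: float = 0.7
    hsv_v: float = 0.4
    degrees: float = 0.0
    translate: float = 0.1
    scale: float = 0.5
    shear: float = 0.0
    flipud: float = 0.5
    fliplr: float = 0.5


@dataclass
class TrainConfig:
    epochs: int = 100
    batch: int = 16
    workers: int = 4
    input_size: int = 640
    optimizer: str = "sgd"
    lr0: float = 0.01
    lrf: float = 0.01
    momentum: float = 0.937
    weight_decay: float = 5e-4
    augment: AugmentConfig = field(default_factory=AugmentConfig)
    nms_iou: float = 0.7
    conf_threshold: float = 0.25
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.nms_iou < 1:
            raise ValueError("nms_iou must lie in (0, 1)")
        for p in (self.augment.flipud, self.augment.fliplr):
            if not 0 <= p <= 1:
                raise ValueError("flip probabilities must lie in [0, 1]")


def _hsv_jitter(img: np.ndarray, gains, rng) -> np.ndarray:
    from skimage import color
    r = rng.uniform(-1, 1, 3) * np.asarray(gains) + 1.0
    if np.allclose(r, 1.0):
        return img
    hsv = color.rgb2hsv(np.clip(img, 0, 1))
    hsv[..., 0] = (hsv[..., 0] * r[0]) % 1.0
    hsv[..., 1] = np.clip(hsv[..., 1] * r[1], 0, 1)
    hsv[..., 2] = np.clip(hsv[..., 2] * r[2], 0, 1)
    return color.hsv2rgb(hsv).astype(np.float32)


def augment_sample(img: np.ndarray, boxes: np.ndarray, aug: AugmentConfig,
                   rng: np.random.Generator):
    """HSV jitter, center scale, translation and flips; boxes follow the
    image transform and are re-clipped (degenerate boxes dropped)."""
    boxes = np.asarray(boxes, dtype=np.float64).reshape(-1, 5).copy()
    img = _hsv_jitter(img, (aug.hsv_h, aug.hsv_s, aug.hsv_v), rng)
    h, w = img.shape[:2]

    k = rng.uniform(1 - aug.scale, 1 + aug.scale) if aug.scale else 1.0
    tx = rng.uniform(-aug.translate, aug.translate) * w if aug.translate else 0.0
    ty = rng.uniform(-aug.translate, aug.translate) * h if aug.translate else 0.0
    if k != 1.0 or tx or ty:
        # forward map: p' = k (p - c) + c + t ; warp needs the inverse
        cy, cx = (h - 1) / 2, (w - 1) / 2
        matrix = np.eye(2) / k
        offset = np.array([cy - (cy + ty) / k, cx - (cx + tx) / k])
        warped = np.empty_like(img)
        for ch in range(img.shape[2]):
            warped[..., ch] = ndimage.affine_transform(
                img[..., ch], matrix, offset=offset, order=1,
                mode="constant", cval=114 / 255.0)
        img = warped
        if len(boxes):
            boxes[:, 1] = (k * (boxes[:, 1] * w - cx) + cx + tx) / w
            boxes[:, 2] = (k * (boxes[:, 2] * h - cy) + cy + ty) / h
            boxes[:, 3] *= k
            boxes[:, 4] *= k

    if rng.random() < aug.fliplr:
        img = img[:, ::-1].copy()
        if len(boxes):
            boxes[:, 1] = 1.0 - boxes[:, 1]
    if rng.random() < aug.flipud:
        img = img[::-1].copy()
        if len(boxes):
            boxes[:, 2] = 1.0 - boxes[:, 2]

    if len(boxes):
        x1 = np.clip(boxes[:, 1] - boxes[:, 3] / 2, 0, 1)
        y1 = np.clip(boxes[:, 2] - boxes[:, 4] / 2, 0, 1)
        x2 = np.clip(boxes[:, 1] + boxes[:, 3] / 2, 0, 1)
        y2 = np.clip(boxes[:, 2] + boxes[:, 4] / 2, 0, 1)
        keep = (x2 - x1 > 2e-3) & (y2 - y1 > 2e-3)
        boxes = np.stack([boxes[:, 0], (x1 + x2) / 2, (y1 + y2) / 2,
                          x2 - x1, y2 - y1], axis=1)[keep]
    return img, boxes


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def recalibrate_bn(model: DetectionModel, images, batch: int = 16):
    """Re-estimate BatchNorm running statistics with the current weights.

    Running averages collected while the weights drift understate the
    final activation scale, which is fatal for short training runs; a
    single statistics pass over (letterboxed) training images with the
    final weights fixes inference-mode normalization. `images` is an
    iterable of (3, S, S) arrays.
    """
    from .nn.modules import BatchNorm2d
    bns = [m for _, m in model.named_modules() if isinstance(m, BatchNorm2d)]
    if not bns:
        return
    for bn in bns:
        bn._set_buffer("running_mean", np.zeros_like(bn.running_mean))
        bn._set_buffer("running_var", np.ones_like(bn.running_var))
        bn._set_buffer("num_batches", np.zeros(1, dtype=np.float32))
    was_training = model.training
    model.train()
    images = list(images)
    with nn.no_grad():
        for start in range(0, len(images), batch):
            x = Tensor(np.stack(images[start:start + batch]))
            model(x)
    model.train(was_training)


def lr_at_epoch(cfg: TrainConfig, epoch: int) -> float:
    """Linear decay from lr0 to lr0*lrf over the configured epochs."""
    if cfg.epochs <= 1:
        return cfg.lr0
    frac = epoch / (cfg.epochs - 1)
    return cfg.lr0 * (1 - frac * (1 - cfg.lrf))


def train(model: DetectionModel, dataset, cfg: TrainConfig,
          log_csv=None, augment: bool = True):
    """SGD training on a YoloDataset (or any sequence of (img, boxes)).

    Returns the per-epoch loss log: list of dicts with box/cls/dfl/total
    means. Deterministic for a fixed cfg.seed (single worker path).
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(cfg.seed)
    size = cfg.input_size
    loss_fn = DetectionLoss(model.head_cfg.num_classes, model.head_cfg.reg_max)
    opt = nn.SGD(model.parameters(), lr=cfg.lr0, momentum=cfg.momentum,
                 weight_decay=cfg.weight_decay)
    cache = []
    for i in range(len(dataset)):
        img, boxes = dataset[i]
        canvas, scale, pad = dio.letterbox(img, size)
        lb = dio.boxes_to_letterbox(boxes, (img.shape[1], img.shape[0]),
                                    size, scale, pad)
        cache.append((canvas, lb))
    log = []
    model.train()
    for epoch in range(cfg.epochs):
        opt.lr = lr_at_epoch(cfg, epoch)
        order = rng.permutation(len(cache))
        sums = {"box": 0.0, "cls": 0.0, "dfl": 0.0, "total": 0.0}
        nb = 0
        for start in range(0, len(order), cfg.batch):
            idxs = order[start:start + cfg.batch]
            imgs, boxes_batch = [], []
            for i in idxs:
                img, boxes = cache[i]
                if augment:
                    img, boxes = augment_sample(img, boxes, cfg.augment, rng)
                imgs.append(img.transpose(2, 0, 1))
                boxes_batch.append(boxes)
            x = Tensor(np.stack(imgs))
            raw = model(x)
            total, parts = loss_fn(raw, boxes_batch, size)
            if not np.isfinite(total.data):
                raise FloatingPointError(f"non-finite loss at epoch {epoch}")
            opt.zero_grad()
            total.backward()
            nn.clip_grad_norm(model.parameters(), 10.0)
            opt.step()
            for k, v in parts.items():
                sums[k] += v
            sums["total"] += float(total.data)
            nb += 1
        entry = {"epoch": epoch, "lr": opt.lr}
        entry.update({k: v / nb for k, v in sums.items()})
        log.append(entry)
    recalibrate_bn(model, [img.transpose(2, 0, 1) for img, _ in cache],
                   batch=cfg.batch)
    if log_csv is not None:
        import csv
        with open(log_csv, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=list(log[0].keys()))
            writer.writeheader()
            writer.writerows(log)
    return log


# --------------------------------------------------------------------------
# inference
# --------------------------------------------------------------------------

def predict(model: DetectionModel, img: np.ndarray,
            conf_threshold: float = 0.25, nms_iou: float = 0.7,
            input_size: int | None = None) -> list:
    """Detect on a single H x W x 3 image; boxes returned in source pixels."""
    size = input_size or model.config.input_size
    canvas, scale, (px, py) = dio.letterbox(img, size)
    model.eval()
    with nn.no_grad():
        raw = model(Tensor(canvas.transpose(2, 0, 1)[None]))
    dets = decode_boxes(raw, model.head_cfg, conf_threshold,
                        image_size=(size, size))
    dets = nms(dets, nms_iou)
    h, w = img.shape[:2]
    out = []
    for d in dets:
        box = d.box.copy()
        box[0::2] = np.clip((box[0::2] - px) / scale, 0, w)
        box[1::2] = np.clip((box[1::2] - py) / scale, 0, h)
        out.append(Detection(d.class_id, d.confidence, box))
    return out
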