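"""Detection heads and anchor-free box decoding.

Two heads are provided over the three pyramid levels P3/P4/P5
(strides 8/16/32):

* ``BaselineHead`` — the stock decoupled head: per level, independent
  regression and classification conv stacks.
* ``SSLDH`` — the shared lightweight head: per-level GroupNorm 1x1
  channel adapters bring every level to a common hidden width, after
  which a single shared stack (GroupNorm 3x3 conv, a star-style
  multiplicative FC interaction, another shared GroupNorm 3x3 conv, and
  shared 1x1 output convs) serves all levels. A learnable per-level
  scalar rescales the regression branch to compensate stride-dependent
  regression ranges. Sharing the stack is what removes roughly two
  thirds of the head parameters.

Both heads emit, per level, a regression logits map with 4*reg_max
channels (a discrete distribution over distance bins per box side) and a
classification logits map with num_classes channels. ``decode_boxes``
converts these to pixel-space detections by taking the expectation of
each softmaxed bin distribution, scaling by the level stride around cell
centers, and applying a sigmoid + confidence threshold to class scores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor, concat
from .blocks import star_product


@dataclass
class HeadConfig:
    level_channels: tuple = (64, 128, 256)
    level_strides: tuple = (8, 16, 32)
    hidden_channels: int = 64
    gn_groups: int = 16
    num_classes: int = 5
    reg_max: int = 16

    def __post_init__(self):
        if len(self.level_channels) != 3 or len(self.level_strides) != 3:
            raise ValueError("exactly 3 pyramid levels are expected")
        if list(self.level_strides) != sorted(set(self.level_strides)):
            raise ValueError("level strides must be strictly increasing")
        if self.num_classes < 1:
            raise ValueError("num_classes must be >= 1")
        if self.reg_max < 2:
            raise ValueError("reg_max must be >= 2")


@dataclass
class RawHeadOutput:
    """Per-level raw maps: reg[i] has 4*reg_max channels, cls[i] num_classes."""

    reg: list
    cls: list
    strides: tuple

    def __post_init__(self):
        if len(self.reg) != 3 or len(self.cls) != 3:
            raise ValueError("three pyramid levels are required")


@dataclass
class Detection:
    class_id: int
    confidence: float
    box: np.ndarray            # pixel xyxy

    def __post_init__(self):
        self.box = np.asarray(self.box, dtype=np.float64)


def _init_head_biases(conv_reg, conv_cls, reg_max: int):
    """Prior-based output init: class logits start at a low object prior
    and the distance distributions start biased toward short distances,
    so early training is not spent un-learning a uniform prior."""
    conv_cls.bias.data = np.full_like(conv_cls.bias.data, -4.6)
    reg_bias = np.tile(-0.5 * np.arange(reg_max, dtype=np.float32), 4)
    conv_reg.bias.data = reg_bias


def _gn_groups_for(channels: int, preferred: int) -> int:
    g = min(preferred, channels)
    while channels % g:
        g -= 1
    return g


class GNConv(nn.Module):
    """Convolution + GroupNorm + SiLU; batch-size independent by design."""

    def __init__(self, c1, c2, k=1, gn_groups=16):
        super().__init__()
        groups = _gn_groups_for(c2, gn_groups)
        self.conv = nn.Conv2d(c1, c2, k, padding=k // 2, bias=False)
        self.norm = nn.GroupNorm(groups, c2)
        self.act = nn.SiLU()

    def forward(self, x):
        return self.act(self.norm(self.conv(x)))


def gn_conv_forward(x, block: GNConv) -> Tensor:
    t = Tensor._lift(x)
    squeeze = t.ndim == 3
    if squeeze:
        t = t.reshape((1,) + t.shape)
    out = block(t)
    return out.reshape(out.shape[1:]) if squeeze else out


class SSLDH(nn.Module):
    """Shared star lightweight detection head."""

    def __init__(self, cfg: HeadConfig):
        super().__init__()
        self.cfg = cfg
        hc = cfg.hidden_channels
        self.adapters = nn.ModuleList(
            [GNConv(c, hc, 1, cfg.gn_groups) for c in cfg.level_channels])
        self.shared1 = GNConv(hc, hc, 3, cfg.gn_groups)
        self.fc1 = nn.Conv2d(hc, hc, 1, bias=True)
        self.fc2 = nn.Conv2d(hc, hc, 1, bias=True)
        self.shared2 = GNConv(hc, hc, 3, cfg.gn_groups)
        self.conv_reg = nn.Conv2d(hc, 4 * cfg.reg_max, 1, bias=True)
        self.conv_cls = nn.Conv2d(hc, cfg.num_classes, 1, bias=True)
        _init_head_biases(self.conv_reg, self.conv_cls, cfg.reg_max)
        self.scales = nn.Parameter(np.ones(3, dtype=np.float32))

    def forward(self, p3, p4, p5) -> RawHeadOutput:
        feats = (p3, p4, p5)
        reg, cls = [], []
        for i, (x, c) in enumerate(zip(feats, self.cfg.level_channels)):
            if x.shape[1] != c:
                raise ValueError(
                    f"level {i} expects {c} channels, got {x.shape[1]}")
            y = self.adapters[i](x)
            y = self.shared1(y)
            y = star_product(self.fc1(y).silu(), self.fc2(y))
            y = self.shared2(y)
            reg.append(self.conv_reg(y) * self.scales[i])
            cls.append(self.conv_cls(y))
        return RawHeadOutput(reg, cls, tuple(self.cfg.level_strides))


class BaselineHead(nn.Module):
    """Stock decoupled head: per-level independent reg/cls stacks."""

    def __init__(self, cfg: HeadConfig):
        super().__init__()
        from .blocks import Conv
        self.cfg = cfg
        ch = cfg.level_channels
        c2 = max(16, ch[0] // 4, 4 * cfg.reg_max)
        c3 = max(ch[0], min(cfg.num_classes, 100))
        self.reg_stacks = nn.ModuleList([
            nn.Sequential(Conv(c, c2, 3), Conv(c2, c2, 3),
                          nn.Conv2d(c2, 4 * cfg.reg_max, 1, bias=True))
            for c in ch])
        self.cls_stacks = nn.ModuleList([
            nn.Sequential(Conv(c, c3, 3), Conv(c3, c3, 3),
                          nn.Conv2d(c3, cfg.num_classes, 1, bias=True))
            for c in ch])
        for reg, cls in zip(self.reg_stacks, self.cls_stacks):
            _init_head_biases(reg[-1], cls[-1], cfg.reg_max)

    def forward(self, p3, p4, p5) -> RawHeadOutput:
        feats = (p3, p4, p5)
        reg = [self.reg_stacks[i](x) for i, x in enumerate(feats)]
        cls = [self.cls_stacks[i](x) for i, x in enumerate(feats)]
        return RawHeadOutput(reg, cls, tuple(self.cfg.level_strides))


def ssldh_forward(p3, p4, p5, head: SSLDH) -> RawHeadOutput:
    return head(Tensor._lift(p3), Tensor._lift(p4), Tensor._lift(p5))


# --------------------------------------------------------------------------
# decoding
# --------------------------------------------------------------------------

def anchor_centers(h: int, w: int, stride: int) -> np.ndarray:
    """(h*w, 2) pixel coordinates of cell centers."""
    ys, xs = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    return np.stack([(xs + 0.5) * stride, (ys + 0.5) * stride],
                    axis=-1).reshape(-1, 2)


def decode_distributions(reg: np.ndarray, reg_max: int) -> np.ndarray:
    """Softmax-expectation decode of DFL logits.

    reg: (4*reg_max, h, w) -> distances (h*w, 4) in stride units.
    """
    r, h, w = reg.shape
    logits = reg.reshape(4, reg_max, h * w)
    logits = logits - logits.max(axis=1, keepdims=True)
    p = np.exp(logits)
    p /= p.sum(axis=1, keepdims=True)
    bins = np.arange(reg_max, dtype=np.float64)
    return np.einsum("dbl,b->ld", p, bins)


def decode_boxes(raw: RawHeadOutput, cfg: HeadConfig,
                 conf_threshold: float = 0.25,
                 image_size: tuple | None = None) -> list:
    """Decode raw head maps of a single image into Detections.

    Accepts maps with or without a leading batch dim of 1. Boxes are pixel
    xyxy, clipped to `image_size` (w, h) when given.
    """
    dets: list[Detection] = []
    for reg_t, cls_t, stride in zip(raw.reg, raw.cls, raw.strides):
        reg = reg_t.data if isinstance(reg_t, Tensor) else np.asarray(reg_t)
        cls = cls_t.data if isinstance(cls_t, Tensor) else np.asarray(cls_t)
        if reg.ndim == 4:
            reg, cls = reg[0], cls[0]
        _, h, w = reg.shape
        centers = anchor_centers(h, w, stride)
        dist = decode_distributions(reg, cfg.reg_max) * stride
        x1 = centers[:, 0] - dist[:, 0]
        y1 = centers[:, 1] - dist[:, 1]
        x2 = centers[:, 0] + dist[:, 2]
        y2 = centers[:, 1] + dist[:, 3]
        scores = 1.0 / (1.0 + np.exp(-cls.reshape(cfg.num_classes, h * w)))
        keep_cls, keep_cell = np.where(scores > conf_threshold)
        for c, l in zip(keep_cls, keep_cell):
            box = np.array([x1[l], y1[l], x2[l], y2[l]])
            if image_size is not None:
                iw, ih = image_size
                box[0::2] = np.clip(box[0::2], 0, iw)
                box[1::2] = np.clip(box[1::2], 0, ih)
            box[0], box[2] = min(box[0], box[2]), max(box[0], box[2])
            box[1], box[3] = min(box[1], box[3]), max(box[1], box[3])
            dets.append(Detection(int(c), float(scores[c, l]), box))
    dets.sort(key=lambda d: -d.confidence)
    return dets
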