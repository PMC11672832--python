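"""Feature-extraction blocks for the lightweight BCS detector.

The central primitive is the *star operation*: the element-wise product of
two linearly transformed copies of a feature. Expanding
(w1ᵀx)(w2ᵀx) = Σ_i Σ_j w1_i w2_j x_i x_j shows the product carries every
pairwise monomial of the bias-augmented input, i.e. a linear map into an
implicit (d+1)(d+2)/2-dimensional space at the cost of two linear layers
and one multiply. Stacking such blocks buys high-dimensional feature
mixing at depthwise-conv prices, which is what makes the C2f-Star variant
cheaper than the stock C2f bottleneck while keeping capacity.

EMA (efficient multi-scale attention) complements this with grouped
directional pooling: per channel group, features are average-pooled along
width (z^H) and height (z^W), the two descriptors are spliced
along the spatial axis, passed through a shared 1x1 convolution, and a
sigmoid gate modulates the map. The full cited module adds a 3x3 branch
and cross-spatial interaction; both are available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor, concat


# --------------------------------------------------------------------------
# star operation
# --------------------------------------------------------------------------

def star_product(a, b):
    """Element-wise product of two equally shaped feature arrays.

    This is the fusion step of the star operation; inputs are typically the
    outputs of two parallel linear maps of the same feature.
    """
    if isinstance(a, Tensor) or isinstance(b, Tensor):
        ta, tb = Tensor._lift(a), Tensor._lift(b)
        if ta.shape != tb.shape:
            raise ValueError(f"star_product shape mismatch: {ta.shape} vs {tb.shape}")
        return ta * tb
    a = np.asarray(a)
    b = np.asarray(b)
    if a.shape != b.shape:
        raise ValueError(f"star_product shape mismatch: {a.shape} vs {b.shape}")
    return a * b


def implicit_monomial_count(d: int) -> int:
    """Number of distinct monomials x_i x_j (i <= j) over a bias-augmented
    input of length d+1 — the dimensionality of the implicit feature space
    reached by one star operation: (d+1)(d+2)/2.
    """
    if d < 0:
        raise ValueError(f"input dimensionality must be non-negative, got {d}")
    return (d + 1) * (d + 2) // 2


# --------------------------------------------------------------------------
# standard conv block
# --------------------------------------------------------------------------

class Conv(nn.Module):
    """Conv2d + BatchNorm + SiLU, the workhorse block of the YOLO lineage."""

    def __init__(self, c1, c2, k=1, s=1, act=True):
        super().__init__()
        self.conv = nn.Conv2d(c1, c2, k, stride=s, padding=k // 2, bias=False)
        self.bn = nn.BatchNorm2d(c2)
        self.act = nn.SiLU() if act else nn.Identity()

    def forward(self, x):
        return self.act(self.bn(self.conv(x)))


class Bottleneck(nn.Module):
    """Stock C2f inner block: two 3x3 convs with optional residual."""

    def __init__(self, c, shortcut=True):
        super().__init__()
        self.cv1 = Conv(c, c, 3)
        self.cv2 = Conv(c, c, 3)
        self.add = shortcut

    def forward(self, x):
        y = self.cv2(self.cv1(x))
        return x + y if self.add else y


# --------------------------------------------------------------------------
# star block
# --------------------------------------------------------------------------

@dataclass
class StarBlockParams:
    """Configuration of a StarNet-style block."""

    in_channels: int
    expand_ratio: float = 2.5
    dw_kernel: int = 7
    activation: str = "silu"    # activation on branch 1 only
    residual_enabled: bool = True

    def __post_init__(self):
        if self.expand_ratio <= 0:
            raise ValueError("expand_ratio must be positive")
        if self.dw_kernel % 2 == 0:
            raise ValueError("dw_kernel must be odd for same-padding")


class StarBlock(nn.Module):
    """Depthwise conv -> two parallel pointwise maps -> gated element-wise
    product -> pointwise projection -> depthwise conv -> residual.

    The two pointwise maps share input/output widths; their product is the
    star operation applied pixel-wise over the map.
    """

    def __init__(self, c, expand_ratio=2.5, dw_kernel=7, act="silu",
                 residual=True):
        super().__init__()
        p = StarBlockParams(c, expand_ratio, dw_kernel, act, residual)
        self.params = p
        hidden = int(round(c * expand_ratio))
        k = dw_kernel
        self.dw1 = nn.Conv2d(c, c, k, padding=k // 2, groups=c, bias=False)
        self.bn1 = nn.BatchNorm2d(c)
        self.f1 = nn.Conv2d(c, hidden, 1, bias=True)
        self.f2 = nn.Conv2d(c, hidden, 1, bias=True)
        self.g = nn.Conv2d(hidden, c, 1, bias=False)
        self.bng = nn.BatchNorm2d(c)
        self.dw2 = nn.Conv2d(c, c, k, padding=k // 2, groups=c, bias=True)
        self.act = act
        self.residual = residual

    def _activate(self, t):
        return t.relu6() if self.act == "relu6" else t.silu()

    def forward(self, x):
        if x.shape[1] != self.params.in_channels:
            raise ValueError(
                f"star block expects {self.params.in_channels} channels, "
                f"got {x.shape[1]}")
        y = self.bn1(self.dw1(x))
        y = star_product(self._activate(self.f1(y)), self.f2(y))
        y = self.bng(self.g(y))
        y = self.dw2(y)
        return x + y if self.residual else y


def star_block_forward(x, block: StarBlock) -> Tensor:
    """Functional entry point; accepts C,H,W or N,C,H,W input."""
    t = Tensor._lift(x)
    squeeze = t.ndim == 3
    if squeeze:
        t = t.reshape((1,) + t.shape)
    out = block(t)
    return out.reshape(out.shape[1:]) if squeeze else out


# --------------------------------------------------------------------------
# EMA attention
# --------------------------------------------------------------------------

@dataclass
class EMAParams:
    channels: int
    groups: int = 4

    def __post_init__(self):
        if self.groups < 1:
            raise ValueError("groups must be >= 1")
        if self.channels % self.groups:
            raise ValueError(
                f"channels ({self.channels}) must be divisible by groups "
                f"({self.groups})")


def default_ema_groups(channels: int, preferred: int = 4) -> int:
    """Largest divisor of `channels` not exceeding `preferred`."""
    g = min(preferred, channels)
    while channels % g:
        g -= 1
    return g


def directional_pool(x: Tensor):
    """Eqs for z^H and z^W: mean over width, mean over height.

    x: (N, C, H, W) -> (z_h: (N, C, H), z_w: (N, C, W)).
    """
    return x.mean(axis=3), x.mean(axis=2)


class EMAGate(nn.Module):
    """Directional-pooling sigmoid gate (the core EMA mechanism).

    Per channel group: pool along W and along H, splice the two pooled
    descriptors along the spatial axis (H first, then W — the order is part
    of the contract), apply a shared 1x1 convolution and sigmoid, split
    back and modulate the input multiplicatively in both directions.
    """

    def __init__(self, channels, groups=None):
        super().__init__()
        if groups is None:
            groups = default_ema_groups(channels)
        self.params = EMAParams(channels, groups)
        cg = channels // groups
        self.gate_conv = nn.Conv2d(cg, cg, 1, bias=True)

    def forward(self, x):
        n, c, h, w = x.shape
        g = self.params.groups
        if c != self.params.channels:
            raise ValueError(f"EMA gate expects {self.params.channels} channels")
        xg = x.reshape(n * g, c // g, h, w)
        z_h = xg.mean(axis=3, keepdims=True)                       # (ng,cg,h,1)
        z_w = xg.mean(axis=2, keepdims=True).transpose(0, 1, 3, 2)  # (ng,cg,w,1)
        z = concat([z_h, z_w], axis=2)                             # H then W
        gate = self.gate_conv(z).sigmoid()
        g_h = gate[:, :, :h, :]
        g_w = gate[:, :, h:, :].transpose(0, 1, 3, 2)
        out = xg * g_h * g_w
        return out.reshape(n, c, h, w)


class EMA(nn.Module):
    """Full efficient multi-scale attention: the directional gate plus a
    parallel 3x3 branch and cross-spatial interaction between the two."""

    def __init__(self, channels, groups=None):
        super().__init__()
        if groups is None:
            groups = default_ema_groups(channels)
        self.params = EMAParams(channels, groups)
        cg = channels // groups
        self.conv1x1 = nn.Conv2d(cg, cg, 1, bias=True)
        self.conv3x3 = nn.Conv2d(cg, cg, 3, padding=1, bias=True)
        self.gn = nn.GroupNorm(cg, cg)

    def forward(self, x):
        n, c, h, w = x.shape
        g = self.params.groups
        cg = c // g
        xg = x.reshape(n * g, cg, h, w)
        z_h = xg.mean(axis=3, keepdims=True)
        z_w = xg.mean(axis=2, keepdims=True).transpose(0, 1, 3, 2)
        hw = self.conv1x1(concat([z_h, z_w], axis=2))
        g_h = hw[:, :, :h, :].sigmoid()
        g_w = hw[:, :, h:, :].transpose(0, 1, 3, 2).sigmoid()
        x1 = self.gn(xg * g_h * g_w)
        x2 = self.conv3x3(xg)
        a1 = x1.mean(axis=(2, 3)).reshape(n * g, 1, cg).softmax(axis=2)
        a2 = x2.mean(axis=(2, 3)).reshape(n * g, 1, cg).softmax(axis=2)
        m1 = x2.reshape(n * g, cg, h * w)
        m2 = x1.reshape(n * g, cg, h * w)
        weights = (a1 @ m1 + a2 @ m2).reshape(n * g, 1, h, w).sigmoid()
        return (xg * weights).reshape(n, c, h, w)


def ema_forward(x, gate: EMAGate) -> Tensor:
    """Apply the directional-pooling EMA gate; accepts 3-D or 4-D input."""
    t = Tensor._lift(x)
    squeeze = t.ndim == 3
    if squeeze:
        t = t.reshape((1,) + t.shape)
    out = gate(t)
    return out.reshape(out.shape[1:]) if squeeze else out


# --------------------------------------------------------------------------
# C2f composites
# --------------------------------------------------------------------------

class C2f(nn.Module):
    """CSP-style block: 1x1 expand, channel split, n stacked inner blocks
    with partial concatenation, 1x1 fuse. `inner` selects the stock
    bottleneck or the star block; `attention` optionally appends an
    attention module after the fuse convolution.
    """

    def __init__(self, c1, c2, n=1, shortcut=False, inner="bottleneck",
                 expand_ratio=2.5, attention=None):
        super().__init__()
        if n < 1:
            raise ValueError(f"C2f needs at least one inner block, got n={n}")
        self.c = c2 // 2
        self.cv1 = Conv(c1, 2 * self.c, 1)
        self.cv2 = Conv((2 + n) * self.c, c2, 1)
        if inner == "bottleneck":
            mods = [Bottleneck(self.c, shortcut) for _ in range(n)]
        elif inner == "star":
            # star blocks keep their internal residual regardless of the
            # C2f shortcut flag: input/output widths always match
            mods = [StarBlock(self.c, expand_ratio=expand_ratio,
                              residual=True) for _ in range(n)]
        else:
            raise ValueError(f"unknown inner block {inner!r}")
        self.m = nn.ModuleList(mods)
        self.attn = attention if attention is not None else nn.Identity()

    def forward(self, x):
        y = self.cv1(x)
        a = y[:, : self.c]
        b = y[:, self.c:]
        outs = [a, b]
        for m in self.m:
            outs.append(m(outs[-1]))
        return self.attn(self.cv2(concat(outs, axis=1)))


def make_c2f(c1, c2, n, shortcut, variant, expand_ratio=2.5, ema_groups=4,
             ema_variant="full"):
    """Factory for the three C2f flavours used by the model assembler."""
    if variant == "c2f_baseline":
        return C2f(c1, c2, n, shortcut)
    if variant == "c2f_star":
        return C2f(c1, c2, n, shortcut, inner="star", expand_ratio=expand_ratio)
    if variant == "c2f_star_ema":
        groups = default_ema_groups(c2, ema_groups)
        attn = EMA(c2, groups) if ema_variant == "full" \
            else EMAGate(c2, groups)
        return C2f(c1, c2, n, shortcut, inner="star",
                   expand_ratio=expand_ratio, attention=attn)
    raise ValueError(f"unknown C2f variant {variant!r}")


def c2f_star_ema_forward(x, block: C2f) -> Tensor:
    """Functional composite forward; accepts 3-D or 4-D input."""
    t = Tensor._lift(x)
    squeeze = t.ndim == 3
    if squeeze:
        t = t.reshape((1,) + t.shape)
    out = block(t)
    return out.reshape(out.shape[1:]) if squeeze else out


class SPPF(nn.Module):
    """Spatial pyramid pooling (fast): three chained 5x5 max pools."""

    def __init__(self, c1, c2, k=5):
        super().__init__()
        c_ = c1 // 2
        self.cv1 = Conv(c1, c_, 1)
        self.cv2 = Conv(c_ * 4, c2, 1)
        self.pool = nn.MaxPool2d(k, stride=1, padding=k // 2)

    def forward(self, x):
        y0 = self.cv1(x)
        y1 = self.pool(y0)
        y2 = self.pool(y1)
        y3 = self.pool(y2)
        return self.cv2(concat([y0, y1, y2, y3], axis=1))
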