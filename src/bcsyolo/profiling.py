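"""Deterministic architecture profiling: parameters, FLOPs, serialized size.

FLOP convention (the one under which the stock n-scale baseline prints
its published budget): one multiply-accumulate counts as 2 floating
operations; convolutions count 2 * k^2 * (Cin/groups) * Cout * Hout * Wout
(+ Hout*Wout*Cout when a bias is present); max pooling counts k^2 - 1
comparisons per output element; normalization layers are treated as
folded into the preceding convolution and activations / element-wise
glue are excluded as negligible. Counts are reported per image at a
stated input size.

Two independent counters are provided: ``count_flops`` traces a real
forward pass through the built graph with layer hooks, while
``analytic_flops`` computes the same quantity in closed form from the
:class:`ModelConfig` arithmetic alone. They must agree; tests hold them
to within 1%.

Serialized size is the byte length of the checkpoint archive with
weights stored at the stated precision; MB means 2^20 bytes.
"""

from __future__ import annotations

import io
from dataclasses import dataclass

import numpy as np

from . import nn
from .nn import Tensor
from .nn import modules as _mods


@dataclass
class ProfileReport:
    param_count: int
    flops: int
    serialized_size_bytes: int
    input_size: int

    @property
    def gflops(self) -> float:
        return self.flops / 1e9

    @property
    def size_mb(self) -> float:
        return self.serialized_size_bytes / 2**20


def count_params(model) -> int:
    """Total learnable scalar entries."""
    return int(model.num_parameters())


class _FlopHook:
    def __init__(self):
        self.total = 0

    def __call__(self, module, args, out):
        if isinstance(module, nn.Conv2d):
            n, cout, ho, wo = out.shape
            k = module.kernel_size
            cin_g = module.in_channels // module.groups
            fl = 2 * k * k * cin_g * cout * ho * wo
            if module.bias is not None:
                fl += cout * ho * wo
            self.total += n * fl
        elif isinstance(module, nn.MaxPool2d):
            n = out.shape[0]
            k = module.kernel_size
            self.total += n * (k * k - 1) * int(np.prod(out.shape[1:]))


def count_flops(model, input_size: int | None = None) -> int:
    """Hook-based count from a real forward pass, per image."""
    size = input_size or model.config.input_size
    if size % 32:
        raise ValueError("input_size must be divisible by 32")
    hook = _FlopHook()
    was_training = model.training
    model.eval()
    _mods._FORWARD_HOOKS.append(hook)
    try:
        with nn.no_grad():
            model(Tensor(np.zeros((1, 3, size, size), dtype=np.float32)))
    finally:
        _mods._FORWARD_HOOKS.remove(hook)
        model.train(was_training)
    return int(hook.total)


# --------------------------------------------------------------------------
# closed-form counter (independent of the module graph)
# --------------------------------------------------------------------------

def _conv(cin, cout, k, s_elems, groups=1, bias=False):
    fl = 2 * k * k * (cin // groups) * cout * s_elems
    return fl + (cout * s_elems if bias else 0)


def _star_block(c, e, s_elems, k=7):
    hidden = int(round(c * e))
    fl = _conv(c, c, k, s_elems, groups=c)              # dw1
    fl += 2 * _conv(c, hidden, 1, s_elems, bias=True)   # f1, f2
    fl += _conv(hidden, c, 1, s_elems)                  # g
    fl += _conv(c, c, k, s_elems, groups=c, bias=True)  # dw2
    return fl


def _bottleneck(c, s_elems):
    return 2 * _conv(c, c, 3, s_elems)


def _ema_full(c, groups, h, w):
    cg = c // groups
    fl = groups * _conv(cg, cg, 1, h + w, bias=True)      # gate conv on pooled
    fl += groups * _conv(cg, cg, 3, h * w, bias=True)     # 3x3 branch
    return fl


def _c2f(cin, cout, n, h, w, variant, e, ema_groups, ema_variant):
    s = h * w
    c = cout // 2
    fl = _conv(cin, 2 * c, 1, s)                          # cv1
    if variant == "c2f_baseline":
        fl += n * _bottleneck(c, s)
    else:
        fl += n * _star_block(c, e, s)
    fl += _conv((2 + n) * c, cout, 1, s)                  # cv2
    if variant == "c2f_star_ema":
        from .blocks import default_ema_groups
        g = default_ema_groups(cout, ema_groups)
        if ema_variant == "full":
            fl += _ema_full(cout, g, h, w)
        else:
            cg = cout // g
            fl += g * _conv(cg, cg, 1, h + w, bias=True)
    return fl


def _sppf(c, s_elems):
    c_ = c // 2
    fl = _conv(c, c_, 1, s_elems) + _conv(4 * c_, c, 1, s_elems)
    fl += 3 * 24 * c_ * s_elems                           # three 5x5 max pools
    return fl


def _baseline_head(ch, nc, reg_max, grids):
    c2 = max(16, ch[0] // 4, 4 * reg_max)
    c3 = max(ch[0], min(nc, 100))
    fl = 0
    for c, s in zip(ch, grids):
        fl += _conv(c, c2, 3, s) + _conv(c2, c2, 3, s) \
            + _conv(c2, 4 * reg_max, 1, s, bias=True)
        fl += _conv(c, c3, 3, s) + _conv(c3, c3, 3, s) \
            + _conv(c3, nc, 1, s, bias=True)
    return fl


def _ssldh_head(ch, nc, reg_max, hidden, grids):
    fl = 0
    for c, s in zip(ch, grids):
        fl += _conv(c, hidden, 1, s)                      # adapter
        fl += _conv(hidden, hidden, 3, s)                 # shared 1
        fl += 2 * _conv(hidden, hidden, 1, s, bias=True)  # star FCs
        fl += _conv(hidden, hidden, 3, s)                 # shared 2
        fl += _conv(hidden, 4 * reg_max, 1, s, bias=True)
        fl += _conv(hidden, nc, 1, s, bias=True)
    return fl


def analytic_flops(cfg, input_size: int | None = None) -> int:
    """Closed-form per-image FLOPs from the config arithmetic alone."""
    size = input_size or cfg.input_size
    if size % 32:
        raise ValueError("input_size must be divisible by 32")
    c1, c2, c3, c4, c5 = cfg.widths
    d1, d2, d3, d4 = cfg.depths
    bv, e = cfg.block_variant, cfg.star_expand_ratio
    eg, ev = cfg.ema_groups, cfg.ema_variant
    g = {k: size // (2 ** k) for k in range(1, 6)}        # grid side per level

    def c2f(cin, cout, n, lvl):
        return _c2f(cin, cout, n, g[lvl], g[lvl], bv, e, eg, ev)

    fl = _conv(3, c1, 3, g[1] ** 2)
    fl += _conv(c1, c2, 3, g[2] ** 2)
    fl += c2f(c2, c2, d1, 2)
    fl += _conv(c2, c3, 3, g[3] ** 2)
    fl += c2f(c3, c3, d2, 3)
    fl += _conv(c3, c4, 3, g[4] ** 2)
    fl += c2f(c4, c4, d3, 4)
    fl += _conv(c4, c5, 3, g[5] ** 2)
    fl += c2f(c5, c5, d4, 5)
    fl += _sppf(c5, g[5] ** 2)
    fl += c2f(c5 + c4, c4, 1, 4)                          # 12
    fl += c2f(c4 + c3, c3, 1, 3)                          # 15
    fl += _conv(c3, c3, 3, g[4] ** 2)                     # 16
    fl += c2f(c3 + c4, c4, 1, 4)                          # 18
    fl += _conv(c4, c4, 3, g[5] ** 2)                     # 19
    fl += c2f(c4 + c5, c5, 1, 5)                          # 21
    grids = (g[3] ** 2, g[4] ** 2, g[5] ** 2)
    if cfg.head_variant == "ssldh":
        fl += _ssldh_head((c3, c4, c5), cfg.num_classes, cfg.reg_max,
                          cfg.head_hidden or c3, grids)
    else:
        fl += _baseline_head((c3, c4, c5), cfg.num_classes, cfg.reg_max,
                             grids)
    return int(fl)


def serialized_size(model, precision: str = "half") -> int:
    """Bytes of the saved checkpoint at the given weight precision."""
    from .assembly import save_checkpoint
    buf = io.BytesIO()
    save_checkpoint(model, buf, precision=precision)
    return buf.getbuffer().nbytes


def profile_model(model, input_size: int | None = None,
                  precision: str = "half") -> ProfileReport:
    size = input_size or model.config.input_size
    return ProfileReport(
        param_count=count_params(model),
        flops=count_flops(model, size),
        serialized_size_bytes=serialized_size(model, precision),
        input_size=size,
    )
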