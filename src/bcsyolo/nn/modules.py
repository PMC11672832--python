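"""Layer/module abstraction: parameter registry, state dicts, common layers.

Layers mirror the conventions of mainstream detector codebases: Conv2d
without bias when followed by a norm, BatchNorm with eps 1e-3 and a slow
running-stat momentum, SiLU activations, GroupNorm for batch-independent
heads.
"""

from __future__ import annotations

from collections import OrderedDict

import numpy as np

from .tensor import Tensor
from . import functional as F

__all__ = [
    "manual_seed", "Parameter", "Module", "Sequential", "ModuleList",
    "Conv2d", "BatchNorm2d", "GroupNorm", "SiLU", "Sigmoid", "Identity",
    "MaxPool2d", "Upsample", "SGD",
]

_INIT_RNG = np.random.default_rng(0)


def manual_seed(seed: int):
    """Seed the generator used for parameter initialization."""
    global _INIT_RNG
    _INIT_RNG = np.random.default_rng(seed)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    def __init__(self):
        object.__setattr__(self, "_params", OrderedDict())
        object.__setattr__(self, "_buffers", OrderedDict())
        object.__setattr__(self, "_modules", OrderedDict())
        object.__setattr__(self, "training", True)

    def __setattr__(self, name, value):
        if isinstance(value, Parameter):
            self._params[name] = value
        elif isinstance(value, Module):
            self._modules[name] = value
        object.__setattr__(self, name, value)

    # -- traversal -------------------------------------------------------
    def named_modules(self, prefix: str = ""):
        yield prefix, self
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_modules(sub)

    def named_parameters(self, prefix: str = ""):
        for name, p in self._params.items():
            yield (f"{prefix}.{name}" if prefix else name), p
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_parameters(sub)

    def named_buffers(self, prefix: str = ""):
        for name, b in self._buffers.items():
            yield (f"{prefix}.{name}" if prefix else name), b
        for name, mod in self._modules.items():
            sub = f"{prefix}.{name}" if prefix else name
            yield from mod.named_buffers(sub)

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def num_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def register_buffer(self, name, value):
        self._buffers[name] = np.asarray(value)
        object.__setattr__(self, name, self._buffers[name])

    def _set_buffer(self, name, value):
        self._buffers[name] = value
        object.__setattr__(self, name, value)

    # -- state -----------------------------------------------------------
    def state_dict(self):
        state = OrderedDict()
        for name, p in self.named_parameters():
            state[name] = p.data
        for name, b in self.named_buffers():
            state[name] = b
        return state

    def load_state_dict(self, state):
        own_params = dict(self.named_parameters())
        own_buffers = {}
        for name, mod in self.named_modules():
            for bname in mod._buffers:
                own_buffers[f"{name}.{bname}" if name else bname] = (mod, bname)
        missing = set(own_params) | set(own_buffers)
        for key, value in state.items():
            if key in own_params:
                p = own_params[key]
                if tuple(p.shape) != tuple(value.shape):
                    raise ValueError(f"shape mismatch for {key}: "
                                     f"{p.shape} vs {value.shape}")
                p.data = np.asarray(value, dtype=np.float32)
                missing.discard(key)
            elif key in own_buffers:
                mod, bname = own_buffers[key]
                mod._set_buffer(bname, np.asarray(value,
                                                  dtype=mod._buffers[bname].dtype))
                missing.discard(key)
            else:
                raise KeyError(f"unexpected key in state dict: {key}")
        if missing:
            raise KeyError(f"missing keys in state dict: {sorted(missing)}")

    def train(self, mode: bool = True):
        object.__setattr__(self, "training", mode)
        for mod in self._modules.values():
            mod.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    # -- forward ---------------------------------------------------------
    def forward(self, *args, **kwargs):
        raise NotImplementedError

    def __call__(self, *args, **kwargs):
        out = self.forward(*args, **kwargs)
        for hook in _FORWARD_HOOKS:
            hook(self, args, out)
        return out


# active profiler hooks; see bcsyolo.profiling
_FORWARD_HOOKS: list = []


class Sequential(Module):
    def __init__(self, *mods):
        super().__init__()
        for i, m in enumerate(mods):
            setattr(self, str(i), m)
        self._seq = list(mods)

    def __iter__(self):
        return iter(self._seq)

    def __getitem__(self, i):
        return self._seq[i]

    def forward(self, x):
        for m in self._seq:
            x = m(x)
        return x


class ModuleList(Module):
    def __init__(self, mods=()):
        super().__init__()
        self._list: list[Module] = []
        for m in mods:
            self.append(m)

    def append(self, m: Module):
        setattr(self, str(len(self._list)), m)
        self._list.append(m)
        return self

    def __iter__(self):
        return iter(self._list)

    def __len__(self):
        return len(self._list)

    def __getitem__(self, i):
        return self._list[i]


class Conv2d(Module):
    def __init__(self, in_channels, out_channels, kernel_size, stride=1,
                 padding=0, groups=1, bias=True):
        super().__init__()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel_size = kernel_size
        self.stride = stride
        self.padding = padding
        self.groups = groups
        k = kernel_size
        fan_in = in_channels // groups * k * k
        bound = 1.0 / np.sqrt(fan_in)
        self.weight = Parameter(_INIT_RNG.uniform(
            -bound, bound, (out_channels, in_channels // groups, k, k)))
        self.bias = Parameter(_INIT_RNG.uniform(-bound, bound, out_channels)) \
            if bias else None

    def forward(self, x):
        return F.conv2d(x, self.weight, self.bias, self.stride,
                        self.padding, self.groups)


class BatchNorm2d(Module):
    """Batch normalization; running statistics use a cumulative moving
    average by default (momentum=None), which calibrates inference-mode
    statistics reliably even for short training runs. A layer that has
    never seen a training batch has nothing learned to normalize with,
    so inference mode falls back to batch statistics until the running
    estimates exist (num_batches > 0)."""

    def __init__(self, channels, eps=1e-3, momentum=None):
        super().__init__()
        self.channels = channels
        self.eps = eps
        self.momentum = momentum
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))
        self.register_buffer("running_mean", np.zeros(channels, dtype=np.float32))
        self.register_buffer("running_var", np.ones(channels, dtype=np.float32))
        self.register_buffer("num_batches", np.zeros(1, dtype=np.float32))

    def forward(self, x):
        if self.training:
            mean = x.mean(axis=(0, 2, 3), keepdims=True)
            var = ((x - mean) ** 2).mean(axis=(0, 2, 3), keepdims=True)
            n = float(self.num_batches[0]) + 1.0
            m = self.momentum if self.momentum is not None else 1.0 / n
            self._set_buffer("num_batches",
                             np.array([n], dtype=np.float32))
            self._set_buffer("running_mean", ((1 - m) * self.running_mean
                             + m * mean.data.ravel()).astype(np.float32))
            self._set_buffer("running_var", ((1 - m) * self.running_var
                             + m * var.data.ravel()).astype(np.float32))
        elif float(self.num_batches[0]) > 0:
            mean = Tensor(self.running_mean.reshape(1, -1, 1, 1))
            var = Tensor(self.running_var.reshape(1, -1, 1, 1))
        else:
            mean = Tensor(x.data.mean(axis=(0, 2, 3), keepdims=True))
            var = Tensor(x.data.var(axis=(0, 2, 3), keepdims=True))
        xh = (x - mean) / ((var + self.eps) ** 0.5)
        return xh * self.weight.reshape(1, -1, 1, 1) \
            + self.bias.reshape(1, -1, 1, 1)


class GroupNorm(Module):
    """Per-sample normalization over channel groups (batch-size independent)."""

    def __init__(self, num_groups, channels, eps=1e-5):
        super().__init__()
        if channels % num_groups:
            raise ValueError(
                f"GroupNorm: {channels} channels not divisible by "
                f"{num_groups} groups")
        self.num_groups = num_groups
        self.channels = channels
        self.eps = eps
        self.weight = Parameter(np.ones(channels))
        self.bias = Parameter(np.zeros(channels))

    def normalize(self, x):
        n, c, h, w = x.shape
        g = self.num_groups
        xg = x.reshape(n, g, c // g * h * w)
        mean = xg.mean(axis=2, keepdims=True)
        var = ((xg - mean) ** 2).mean(axis=2, keepdims=True)
        xh = (xg - mean) / ((var + self.eps) ** 0.5)
        return xh.reshape(n, c, h, w)

    def forward(self, x):
        xh = self.normalize(x)
        return xh * self.weight.reshape(1, -1, 1, 1) \
            + self.bias.reshape(1, -1, 1, 1)


class SiLU(Module):
    def forward(self, x):
        return x.silu()


class Sigmoid(Module):
    def forward(self, x):
        return x.sigmoid()


class Identity(Module):
    def forward(self, x):
        return x


class MaxPool2d(Module):
    def __init__(self, kernel_size, stride=None, padding=0):
        super().__init__()
        self.kernel_size = kernel_size
        self.stride = stride or kernel_size
        self.padding = padding

    def forward(self, x):
        return F.max_pool2d(x, self.kernel_size, self.stride, self.padding)


class Upsample(Module):
    def __init__(self, scale: int = 2):
        super().__init__()
        self.scale = scale

    def forward(self, x):
        return F.upsample_nearest(x, self.scale)


def clip_grad_norm(params, max_norm: float) -> float:
    """Scale gradients so their global L2 norm is at most max_norm."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad.astype(np.float64) ** 2).sum())
    norm = float(np.sqrt(total))
    if norm > max_norm > 0:
        scale = max_norm / (norm + 1e-12)
        for p in params:
            if p.grad is not None:
                p.grad = p.grad * scale
    return norm


class SGD:
    """Stochastic gradient descent with classical momentum and weight decay."""

    def __init__(self, params, lr, momentum=0.937, weight_decay=5e-4):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            p.data = p.data - self.lr * v
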