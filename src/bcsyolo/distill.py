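"""Channel-wise knowledge distillation (CWD).

Each channel of a feature map is normalized into a probability
distribution over its H*W spatial positions with a temperature-scaled
softmax; the distillation loss is the KL divergence from the teacher's
per-channel distribution to the student's, scaled by T^2 and averaged
over channels. Because the softmax is over *space*, the loss pushes the
student to reproduce where each teacher channel concentrates its
activation mass — the salient-region structure — rather than raw
activation values, and it is invariant to per-channel additive offsets.

Teacher and student are hooked at matching layer indices (by default
the four neck fusion outputs, 12/15/18/21); when the teacher is wider,
a learnable 1x1 adapter lifts the student map to the teacher width. The
adapters train jointly with the student and are dropped after training,
leaving the deployed student graph unchanged.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from .nn import Tensor
from .losses import DetectionLoss


@dataclass
class ChannelProbMap:
    probs: np.ndarray          # (C, H, W) or (N, C, H, W); sums to 1 per channel
    temperature: float


@dataclass
class DistillConfig:
    layer_pairs: tuple = ((12, 12), (15, 15), (18, 18), (21, 21))
    temperature: float = 4.0
    loss_weight: float = 1.0
    weight_schedule: str = "constant"
    loss_type: str = "feature"

    def __post_init__(self):
        if self.temperature <= 0:
            raise ValueError("temperature must be positive")
        if self.weight_schedule != "constant":
            raise ValueError("only the constant weight schedule is supported")
        if self.loss_type not in ("feature", "logits"):
            raise ValueError("loss_type must be 'feature' or 'logits'")


def _spatial_softmax(t: Tensor, temperature: float) -> Tensor:
    shape = t.shape
    flat = t.reshape(shape[:-2] + (shape[-2] * shape[-1],))
    scaled = flat * (1.0 / temperature)
    p = scaled.softmax(axis=-1)
    return p.reshape(shape)


def channel_softmax(x, temperature: float = 1.0) -> ChannelProbMap:
    """Per-channel spatial softmax probability map (max-stabilized)."""
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    t = Tensor._lift(x)
    return ChannelProbMap(_spatial_softmax(t, temperature).data, temperature)


def cwd_loss(teacher_fm, student_fm, temperature: float = 4.0) -> Tensor:
    """(T^2 / C) * sum_c KL(phi_T(teacher)_c || phi_T(student)_c).

    Gradient flows to the student only; the teacher map is a constant.
    Accepts (C, H, W) or (N, C, H, W); for batched input the loss is
    averaged over the batch.
    """
    if temperature <= 0:
        raise ValueError(f"temperature must be positive, got {temperature}")
    t = Tensor._lift(teacher_fm).detach()
    s = Tensor._lift(student_fm)
    if t.shape != s.shape:
        raise ValueError(
            f"teacher/student shape mismatch after adaptation: "
            f"{t.shape} vs {s.shape}")
    squeeze = t.ndim == 3
    if squeeze:
        t = t.reshape((1,) + t.shape)
        s = s.reshape((1,) + s.shape)
    n, c, h, w = t.shape
    pt = _spatial_softmax(t, temperature).data
    # student log-probabilities, numerically stable
    flat = s.reshape(n, c, h * w) * (1.0 / temperature)
    shifted = flat - Tensor(flat.data.max(axis=2, keepdims=True))
    log_ps = shifted - shifted.exp().sum(axis=2, keepdims=True).log()
    pt_flat = pt.reshape(n, c, h * w)
    log_pt = np.log(np.maximum(pt_flat, 1e-30))
    kl = (Tensor(pt_flat) * (Tensor(log_pt) - log_ps)).sum()
    # Gibbs' inequality guarantees kl >= 0; clamp the float32 dust at zero
    return (kl * (temperature ** 2 / (c * n))).clamp(lo=0.0)


class ChannelAdapter(nn.Module):
    """Learnable 1x1 map from student width to teacher width.

    Identity-initialized when widths match, so an untrained adapter is a
    no-op in that case.
    """

    def __init__(self, in_channels: int, target_channels: int):
        super().__init__()
        self.in_channels = in_channels
        self.target_channels = target_channels
        w = np.zeros((target_channels, in_channels, 1, 1), dtype=np.float32)
        for i in range(min(in_channels, target_channels)):
            w[i, i, 0, 0] = 1.0
        self.conv = nn.Conv2d(in_channels, target_channels, 1, bias=True)
        self.conv.weight.data = w
        self.conv.bias.data = np.zeros(target_channels, dtype=np.float32)

    def forward(self, x):
        return self.conv(x)


def adapt_channels(student_fm, target_channels: int,
                   adapter: ChannelAdapter) -> Tensor:
    t = Tensor._lift(student_fm)
    squeeze = t.ndim == 3
    if squeeze:
        t = t.reshape((1,) + t.shape)
    out = adapter(t)
    return out.reshape(out.shape[1:]) if squeeze else out


class Distiller:
    """Owns the adapters and computes the combined distillation objective."""

    def __init__(self, teacher, student, cfg: DistillConfig | None = None):
        self.cfg = cfg or DistillConfig()
        self.teacher = teacher
        self.student = student
        n_layers = len(student.layers)
        for t_idx, s_idx in self.cfg.layer_pairs:
            if not (0 <= t_idx < len(teacher.layers)) \
                    or not (0 <= s_idx < n_layers):
                raise ValueError(
                    f"layer pair ({t_idx}, {s_idx}) outside graph numbering")
        self.loss_fn = DetectionLoss(student.head_cfg.num_classes,
                                     student.head_cfg.reg_max)
        # probe both graphs once to size the adapters; eval mode so the
        # probe leaves no trace in the normalization statistics
        size = 64
        probe = Tensor(np.zeros((1, 3, size, size), dtype=np.float32))
        t_idxs = [p[0] for p in self.cfg.layer_pairs]
        s_idxs = [p[1] for p in self.cfg.layer_pairs]
        student_was_training = student.training
        teacher.eval()
        student.eval()
        with nn.no_grad():
            _, t_feats = teacher(probe, capture=t_idxs)
            _, s_feats = student(probe, capture=s_idxs)
        student.train(student_was_training)
        self.adapters = []
        for (ti, si) in self.cfg.layer_pairs:
            cs = s_feats[si].shape[1]
            ct = t_feats[ti].shape[1]
            self.adapters.append(ChannelAdapter(cs, ct))

    def trainable_parameters(self):
        params = list(self.student.parameters())
        for a in self.adapters:
            params += a.parameters()
        return params

    def losses(self, x: Tensor, boxes_batch, input_size: int):
        """Returns (total, detection, distill) loss tensors for one batch."""
        t_idxs = [p[0] for p in self.cfg.layer_pairs]
        s_idxs = [p[1] for p in self.cfg.layer_pairs]
        self.teacher.eval()
        with nn.no_grad():
            _, t_feats = self.teacher(x, capture=t_idxs)
        raw, s_feats = self.student(x, capture=s_idxs)
        det_loss, _ = self.loss_fn(raw, boxes_batch, input_size)
        distill = Tensor(0.0)
        for (ti, si), adapter in zip(self.cfg.layer_pairs, self.adapters):
            sf = adapter(s_feats[si])
            distill = distill + cwd_loss(t_feats[ti], sf,
                                         self.cfg.temperature)
        distill = distill * (1.0 / len(self.cfg.layer_pairs))
        total = det_loss + self.cfg.loss_weight * distill
        return total, det_loss, distill


def distill_step(batch, teacher, student, cfg: DistillConfig,
                 distiller: Distiller | None = None,
                 optimizer=None) -> dict:
    """One optimization step of student + adapters on a batch.

    batch: (images (N,3,S,S) array, boxes list). Returns the three loss
    components as floats. The teacher is frozen: it is run in inference
    mode and receives no gradient.
    """
    if distiller is None:
        distiller = Distiller(teacher, student, cfg)
    imgs, boxes_batch = batch
    x = Tensor(np.asarray(imgs, dtype=np.float32))
    size = x.shape[-1]
    student.train()
    total, det, distill = distiller.losses(x, boxes_batch, size)
    if optimizer is not None:
        optimizer.zero_grad()
        total.backward()
        optimizer.step()
    return {"total": float(total.data), "detection": float(det.data),
            "distill": float(distill.data)}
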