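"""Composite detection loss: CIoU box loss, BCE classification and
distribution-focal regression, with a simple center-sampling assigner.

Each ground-truth box is assigned to the finest pyramid level whose
distance bins can represent it, and to the grid cells whose centers fall
inside the central half of the box (at least the center cell). The
regression branch predicts, per cell, four discrete distributions over
``reg_max`` distance bins (in units of the level stride); boxes are
decoded by softmax expectation, so the box loss is differentiable
through the distribution.
"""

from __future__ import annotations

import numpy as np

from .nn import Tensor, concat

BOX_WEIGHT = 7.5
CLS_WEIGHT = 0.5
DFL_WEIGHT = 1.5


def choose_level(w_px: float, h_px: float, strides, reg_max: int) -> int:
    """Finest level whose (reg_max-1)-bin range covers the half-extent."""
    half = max(w_px, h_px) / 2.0
    for i, s in enumerate(strides):
        if half <= (reg_max - 1) * s * 0.8:
            return i
    return len(strides) - 1


def build_targets(boxes_batch, input_size: int, strides, reg_max: int,
                  num_classes: int):
    """Assignment for a batch.

    boxes_batch: list (len N) of (k, 5) arrays [class, cx, cy, w, h]
    normalized. Returns, per level: dict with
      fg:   (N, L) bool
      cls:  (N, L, C) float {0,1}
      dist: (N, L, 4) float, stride units
      box:  (N, L, 4) float, pixel xyxy
    """
    n = len(boxes_batch)
    out = []
    for li, s in enumerate(strides):
        g = input_size // s
        out.append({
            "fg": np.zeros((n, g * g), dtype=bool),
            "cls": np.zeros((n, g * g, num_classes), dtype=np.float32),
            "dist": np.zeros((n, g * g, 4), dtype=np.float32),
            "box": np.zeros((n, g * g, 4), dtype=np.float32),
        })
    for bi, boxes in enumerate(boxes_batch):
        for row in np.asarray(boxes).reshape(-1, 5):
            cid = int(row[0])
            cx, cy = row[1] * input_size, row[2] * input_size
            bw, bh = row[3] * input_size, row[4] * input_size
            if bw <= 0 or bh <= 0:
                continue
            li = choose_level(bw, bh, strides, reg_max)
            s = strides[li]
            g = input_size // s
            x1, y1, x2, y2 = cx - bw / 2, cy - bh / 2, cx + bw / 2, cy + bh / 2
            # all cells whose centers fall inside the box
            j0 = int(np.clip(np.floor(x1 / s - 0.5) + 1, 0, g - 1))
            j1 = int(np.clip(np.ceil(x2 / s - 0.5), 0, g - 1))
            i0 = int(np.clip(np.floor(y1 / s - 0.5) + 1, 0, g - 1))
            i1 = int(np.clip(np.ceil(y2 / s - 0.5), 0, g - 1))
            jc = int(np.clip(cx / s, 0, g - 1))
            ic = int(np.clip(cy / s, 0, g - 1))
            cells = {(ic, jc)}
            for ii in range(i0, i1 + 1):
                for jj in range(j0, j1 + 1):
                    cells.add((ii, jj))
            lvl = out[li]
            for ii, jj in cells:
                idx = ii * g + jj
                acx, acy = (jj + 0.5) * s, (ii + 0.5) * s
                d = np.array([acx - x1, acy - y1, x2 - acx, y2 - acy]) / s
                if d.min() < 0:
                    continue
                lvl["fg"][bi, idx] = True
                lvl["cls"][bi, idx, cid] = 1.0
                lvl["dist"][bi, idx] = np.clip(d, 0, reg_max - 1 - 1e-3)
                lvl["box"][bi, idx] = (x1, y1, x2, y2)
    return out


def _bce_with_logits(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Numerically stable elementwise BCE, summed."""
    t = Tensor(targets)
    # log(1 + e^x) = max(x,0) + log1p(e^-|x|); composed from stable pieces
    m = logits.clamp(lo=0.0)
    soft = ((-(logits.clamp(lo=0.0) * 2 - logits)).exp() + 1.0).log()
    return (m - logits * t + soft).sum()


def ciou_loss(pred: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean complete-IoU loss between (P,4) xyxy tensors."""
    tgt = Tensor(target)
    px1, py1, px2, py2 = pred[:, 0], pred[:, 1], pred[:, 2], pred[:, 3]
    tx1, ty1, tx2, ty2 = tgt[:, 0], tgt[:, 1], tgt[:, 2], tgt[:, 3]
    iw = px2.minimum(tx2) - px1.maximum(tx1)
    ih = py2.minimum(ty2) - py1.maximum(ty1)
    inter = iw.clamp(lo=0.0) * ih.clamp(lo=0.0)
    pw, ph = px2 - px1, py2 - py1
    tw, th = tx2 - tx1, ty2 - ty1
    union = pw * ph + tw * th - inter + eps
    iou = inter / union
    # enclosing box diagonal and center distance
    cw = px2.maximum(tx2) - px1.minimum(tx1)
    ch = py2.maximum(ty2) - py1.minimum(ty1)
    c2 = cw * cw + ch * ch + eps
    rho2 = ((px1 + px2 - tx1 - tx2) ** 2 + (py1 + py2 - ty1 - ty2) ** 2) * 0.25
    v = (4.0 / np.pi ** 2) * ((tw / (th + eps)).atan()
                              - (pw / (ph + eps)).atan()) ** 2
    alpha = Tensor((v / (1.0 - iou + v + eps)).data)   # detached weight
    ciou = iou - rho2 / c2 - alpha * v
    return (1.0 - ciou).mean()


class DetectionLoss:
    """Callable computing (total, parts) from raw head output + labels."""

    def __init__(self, num_classes: int, reg_max: int, strides=(8, 16, 32)):
        self.num_classes = num_classes
        self.reg_max = reg_max
        self.strides = tuple(strides)

    def __call__(self, raw, boxes_batch, input_size: int):
        targets = build_targets(boxes_batch, input_size, self.strides,
                                self.reg_max, self.num_classes)
        n = raw.cls[0].shape[0]
        cls_loss = Tensor(0.0)
        box_terms = []
        dfl_terms = []
        total_pos = 0
        for li, (reg_t, cls_t) in enumerate(zip(raw.reg, raw.cls)):
            tgt = targets[li]
            _, c, h, w = cls_t.shape
            logits = cls_t.reshape(n, c, h * w).transpose(0, 2, 1)
            cls_loss = cls_loss + _bce_with_logits(logits, tgt["cls"])
            bi, cell = np.nonzero(tgt["fg"])
            total_pos += len(bi)
            if len(bi) == 0:
                continue
            rm = self.reg_max
            reg = reg_t.reshape(n, 4, rm, h * w)
            pos = reg[bi, :, :, cell]                # (P, 4, rm)
            logp = pos - Tensor(pos.data.max(axis=2, keepdims=True))
            logp = logp - (logp.exp().sum(axis=2, keepdims=True)).log()
            probs = logp.exp()
            dist = (probs * np.arange(rm, dtype=np.float32)).sum(axis=2)
            # decoded boxes around anchor centers, pixel units
            s = self.strides[li]
            g = input_size // s
            ys, xs = cell // g, cell % g
            acx = (xs + 0.5) * s
            acy = (ys + 0.5) * s
            px1 = Tensor(acx) - dist[:, 0] * s
            py1 = Tensor(acy) - dist[:, 1] * s
            px2 = Tensor(acx) + dist[:, 2] * s
            py2 = Tensor(acy) + dist[:, 3] * s
            pred_boxes = concat([t.reshape(-1, 1)
                                 for t in (px1, py1, px2, py2)], axis=1)
            box_terms.append(ciou_loss(pred_boxes, tgt["box"][bi, cell]))
            # distribution focal: CE against the two neighbouring bins
            td = tgt["dist"][bi, cell]               # (P, 4)
            tl = np.floor(td).astype(int)
            tr = np.minimum(tl + 1, rm - 1)
            wl = (tr - td).astype(np.float32)
            wr = 1.0 - wl
            pp, dd = np.meshgrid(np.arange(len(bi)), np.arange(4),
                                 indexing="ij")
            lp_l = logp[pp, dd, tl]
            lp_r = logp[pp, dd, tr]
            dfl_terms.append(-(lp_l * wl + lp_r * wr).mean())
        npos = max(total_pos, 1)
        cls_loss = cls_loss * (1.0 / npos)
        box_loss = (sum(box_terms[1:], box_terms[0])
                    * (1.0 / len(box_terms))) if box_terms else Tensor(0.0)
        dfl_loss = (sum(dfl_terms[1:], dfl_terms[0])
                    * (1.0 / len(dfl_terms))) if dfl_terms else Tensor(0.0)
        total = (BOX_WEIGHT * box_loss + CLS_WEIGHT * cls_loss
                 + DFL_WEIGHT * dfl_loss)
        parts = {"box": float(box_loss.data), "cls": float(cls_loss.data),
                 "dfl": float(dfl_loss.data)}
        return total, parts
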