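"""Detection evaluation: precision, recall, AP and mAP.

Definitions follow the standard confusion-count form
P = TP / (TP + FP), R = TP / (TP + FN), with greedy one-to-one matching
per class at a stated IoU threshold. AP is the area under the
precision-recall curve; the default uses all-points interpolation (the
precision envelope integrated over recall), with the legacy 11-point
interpolation available for comparability with older evaluation
protocols. mAP averages AP over classes; mAP@50:95 additionally averages
over IoU thresholds 0.50 to 0.95 in steps of 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .assembly import box_iou_xyxy

IOU_SWEEP = tuple(np.round(np.arange(0.5, 0.96, 0.05), 2))


@dataclass
class ConfusionCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def precision(self) -> float:
        d = self.tp + self.fp
        return self.tp / d if d else 0.0

    @property
    def recall(self) -> float:
        d = self.tp + self.fn
        return self.tp / d if d else 0.0


@dataclass
class MetricsReport:
    classes: list
    precision: dict
    recall: dict
    ap50: dict
    ap50_95: dict
    map50: float
    map50_95: float


def match_detections(preds, truths, iou_threshold: float = 0.5):
    """Greedy one-to-one matching of predictions (sorted by descending
    confidence) against ground-truth boxes of the same class.

    preds: list of Detection; truths: (k, 5) array [class, x1, y1, x2, y2]
    in pixels. Returns (ConfusionCounts, tp_flags per prediction).
    """
    truths = np.asarray(truths, dtype=np.float64).reshape(-1, 5)
    order = sorted(range(len(preds)),
                   key=lambda i: (-preds[i].confidence, i))
    matched = np.zeros(len(truths), dtype=bool)
    flags = np.zeros(len(preds), dtype=bool)
    for i in order:
        d = preds[i]
        best_iou, best_j = 0.0, -1
        for j, t in enumerate(truths):
            if matched[j] or int(t[0]) != d.class_id:
                continue
            iou = box_iou_xyxy(d.box, t[1:])
            if iou > best_iou:
                best_iou, best_j = iou, j
        if best_j >= 0 and best_iou >= iou_threshold:
            matched[best_j] = True
            flags[i] = True
    tp = int(flags.sum())
    fp = len(preds) - tp
    fn = int((~matched).sum())
    return ConfusionCounts(tp, fp, fn), flags


def precision_recall_curve(confidences, tp_flags, n_truth: int):
    """Cumulative P-R points from a confidence-ranked prediction list."""
    order = np.argsort(-np.asarray(confidences, dtype=np.float64),
                       kind="stable")
    tps = np.cumsum(np.asarray(tp_flags, dtype=np.float64)[order])
    fps = np.cumsum(1.0 - np.asarray(tp_flags, dtype=np.float64)[order])
    precision = tps / np.maximum(tps + fps, 1e-12)
    recall = tps / n_truth if n_truth else np.zeros_like(tps)
    return recall, precision


def average_precision(recall, precision, mode: str = "all_points") -> float:
    """Area under the P-R curve.

    `all_points`: integrate the precision envelope over recall.
    `eleven_point`: mean of interpolated precision at R = 0.0, 0.1, ... 1.0.
    """
    recall = np.concatenate(([0.0], np.asarray(recall, dtype=np.float64),
                             [1.0]))
    precision = np.concatenate(([1.0],
                                np.asarray(precision, dtype=np.float64),
                                [0.0]))
    env = np.maximum.accumulate(precision[::-1])[::-1]
    if mode == "eleven_point":
        pts = [env[np.searchsorted(recall, r, side="left")]
               if r <= recall[-1] else 0.0 for r in np.linspace(0, 1, 11)]
        return float(np.mean(pts))
    if mode != "all_points":
        raise ValueError(f"unknown AP mode {mode!r}")
    idx = np.where(recall[1:] != recall[:-1])[0]
    return float(np.sum((recall[idx + 1] - recall[idx]) * env[idx + 1]))


def map_over_classes(per_class_ap) -> float:
    per_class_ap = list(per_class_ap)
    if not per_class_ap:
        raise ValueError("mAP over an empty class list is undefined")
    return float(np.mean(per_class_ap))


def evaluate_detections(preds_per_image, truths_per_image, num_classes: int,
                        ap_mode: str = "all_points") -> MetricsReport:
    """Full evaluation over a set of images.

    preds_per_image: list over images of Detection lists.
    truths_per_image: list over images of (k, 5) [class, x1, y1, x2, y2].
    Per-class P/R are reported at the maximum-F1 point of the P-R sweep
    at IoU 0.5.
    """
    classes = list(range(num_classes))
    ap_table = {c: {} for c in classes}
    pr = {}
    for thr in IOU_SWEEP:
        per_class = {c: {"conf": [], "tp": [], "n": 0} for c in classes}
        for preds, truths in zip(preds_per_image, truths_per_image):
            truths = np.asarray(truths, dtype=np.float64).reshape(-1, 5)
            _, flags = match_detections(preds, truths, thr)
            for d, f in zip(preds, flags):
                if d.class_id in per_class:
                    per_class[d.class_id]["conf"].append(d.confidence)
                    per_class[d.class_id]["tp"].append(f)
            for t in truths:
                per_class[int(t[0])]["n"] += 1
        for c in classes:
            n = per_class[c]["n"]
            if n == 0 or not per_class[c]["conf"]:
                ap_table[c][thr] = 0.0
                if thr == 0.5:
                    pr[c] = (0.0, 0.0)
                continue
            rec, prec = precision_recall_curve(
                per_class[c]["conf"], per_class[c]["tp"], n)
            ap_table[c][thr] = average_precision(rec, prec, ap_mode)
            if thr == 0.5:
                f1 = 2 * prec * rec / np.maximum(prec + rec, 1e-12)
                k = int(np.argmax(f1))
                pr[c] = (float(prec[k]), float(rec[k]))
    ap50 = {c: ap_table[c][0.5] for c in classes}
    ap50_95 = {c: float(np.mean([ap_table[c][t] for t in IOU_SWEEP]))
               for c in classes}
    return MetricsReport(
        classes=classes,
        precision={c: pr[c][0] for c in classes},
        recall={c: pr[c][1] for c in classes},
        ap50=ap50,
        ap50_95=ap50_95,
        map50=map_over_classes(ap50.values()),
        map50_95=map_over_classes(ap50_95.values()),
    )
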