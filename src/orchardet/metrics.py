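"""Detection evaluation: greedy IoU matching, 101-point AP, summary metrics.

Average precision follows the COCO convention: detections are sorted by
descending score, greedily matched one-to-one to not-yet-matched ground
truth with IoU at or above the threshold (highest IoU wins, ties to the
lowest ground-truth index), and AP is the mean of the interpolated
precision at the 101 recall points 0.00, 0.01, ..., 1.00.

``evaluate`` reports AP@0.5, AP@0.75, AP@[.50:.95] (mean over thresholds
0.50:0.05:0.95), plus Precision and Recall over all retained detections at
IoU 0.5, each macro-averaged over the classes present in the ground truth.
A class with no ground truth and no detections is undefined and excluded
from the macro means (NaN sentinel).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .detector import DetectionSet, iou

__all__ = [
    "GroundTruth",
    "MetricsRecord",
    "match_detections",
    "average_precision",
    "evaluate",
]

IOU_GRID = tuple(round(0.5 + 0.05 * i, 2) for i in range(10))  # 0.50 .. 0.95


@dataclass(frozen=True)
class GroundTruth:
    """A ground-truth box (half-open pixel coords) with its class."""

    box: tuple[float, float, float, float]
    class_id: int


def _sorted_dets(dets_by_image: dict[str, list]) -> list[tuple[str, object]]:
    """Global score ordering with a deterministic positional tie-break."""
    flat = [(img, d) for img, ds in sorted(dets_by_image.items()) for d in ds]
    flat.sort(key=lambda t: (-t[1].score, t[0], t[1].box[1], t[1].box[0]))
    return flat


def match_detections(
    dets: list, gt_boxes: list, iou_threshold: float
) -> list[bool]:
    """Greedy one-to-one matching of score-sorted detections to ground truth.

    ``dets`` must already be in evaluation order.  Returns one True (TP) or
    False (FP) flag per detection.
    """
    matched = [False] * len(gt_boxes)
    flags: list[bool] = []
    for d in dets:
        best, best_iou = None, 0.0
        for g_idx, g in enumerate(gt_boxes):
            if matched[g_idx]:
                continue
            v = iou(d.box, g)
            if v >= iou_threshold and v > best_iou:
                best, best_iou = g_idx, v
        if best is None:
            flags.append(False)
        else:
            matched[best] = True
            flags.append(True)
    return flags


def _interp_ap_101(tp_flags: list[bool], n_gt: int) -> float:
    tp = np.cumsum(np.asarray(tp_flags, dtype=float))
    fp = np.cumsum(~np.asarray(tp_flags, dtype=bool))
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1)
    ap = 0.0
    for r in np.linspace(0.0, 1.0, 101):
        mask = recall >= r - 1e-12
        ap += float(precision[mask].max()) if mask.any() else 0.0
    return ap / 101.0


def average_precision(
    dets_by_image: dict[str, list],
    gts_by_image: dict[str, list],
    iou_threshold: float,
) -> float:
    """Single-class AP across images at one IoU threshold.

    Returns NaN (excluded from means downstream) when there is neither
    ground truth nor any detection; 0.0 when detections exist without
    ground truth or vice versa.
    """
    n_gt = sum(len(v) for v in gts_by_image.values())
    n_det = sum(len(v) for v in dets_by_image.values())
    if n_gt == 0 and n_det == 0:
        return math.nan
    if n_gt == 0 or n_det == 0:
        return 0.0
    flat = _sorted_dets(dets_by_image)
    matched: dict[str, list[bool]] = {
        img: [False] * len(g) for img, g in gts_by_image.items()
    }
    flags: list[bool] = []
    for img, d in flat:
        gts = gts_by_image.get(img, [])
        state = matched.setdefault(img, [False] * len(gts))
        best, best_iou = None, 0.0
        for g_idx, g in enumerate(gts):
            if state[g_idx]:
                continue
            v = iou(d.box, g.box if isinstance(g, GroundTruth) else g)
            if v >= iou_threshold and v > best_iou:
                best, best_iou = g_idx, v
        if best is None:
            flags.append(False)
        else:
            state[best] = True
            flags.append(True)
    return _interp_ap_101(flags, n_gt)


@dataclass
class MetricsRecord:
    """Macro-averaged detection metrics plus the per-class breakdown."""

    ap50: float
    ap75: float
    ap_50_95: float
    precision: float
    recall_all: float
    per_class: dict[int, dict[str, float]] = field(default_factory=dict)

    FIELDS = ("ap50", "ap75", "ap_50_95", "precision", "recall_all")

    def to_dict(self) -> dict:
        return {
            **{k: getattr(self, k) for k in self.FIELDS},
            "per_class": {
                int(c): dict(v) for c, v in sorted(self.per_class.items())
            },
        }


def _nanmean(values: list[float]) -> float:
    vals = [v for v in values if not math.isnan(v)]
    return float(np.mean(vals)) if vals else math.nan


def evaluate(
    dets_by_image: dict[str, DetectionSet],
    gts_by_image: dict[str, list[GroundTruth]],
) -> MetricsRecord:
    """Full metric suite over a set of images.

    Detections and ground truth are split per class; AP is computed at each
    IoU threshold on the 0.50:0.05:0.95 grid, and Precision / Recall over
    all retained detections at IoU 0.5.  Classes are taken from the ground
    truth; macro averages skip undefined (NaN) classes.
    """
    classes = sorted(
        {g.class_id for gts in gts_by_image.values() for g in gts}
        | {d.class_id for ds in dets_by_image.values() for d in ds.detections}
    )
    per_class: dict[int, dict[str, float]] = {}
    for c in classes:
        dc = {
            img: [d for d in ds.detections if d.class_id == c]
            for img, ds in dets_by_image.items()
        }
        gc = {
            img: [g for g in gts if g.class_id == c]
            for img, gts in gts_by_image.items()
        }
        n_gt = sum(len(v) for v in gc.values())
        n_det = sum(len(v) for v in dc.values())
        aps = {t: average_precision(dc, gc, t) for t in IOU_GRID}
        if n_gt == 0 and n_det == 0:
            prec = rec = math.nan
        else:
            flat = _sorted_dets(dc)
            tp = 0
            matched = {img: [False] * len(g) for img, g in gc.items()}
            for img, d in flat:
                gts = gc.get(img, [])
                state = matched.setdefault(img, [False] * len(gts))
                best, best_iou = None, 0.0
                for g_idx, g in enumerate(gts):
                    if state[g_idx]:
                        continue
                    v = iou(d.box, g.box)
                    if v >= 0.5 and v > best_iou:
                        best, best_iou = g_idx, v
                if best is not None:
                    state[best] = True
                    tp += 1
            prec = tp / n_det if n_det else 0.0
            rec = tp / n_gt if n_gt else math.nan
        per_class[c] = {
            "ap50": aps[0.5],
            "ap75": aps[0.75],
            "ap_50_95": _nanmean(list(aps.values())),
            "precision": prec,
            "recall_all": rec,
        }
    return MetricsRecord(
        ap50=_nanmean([v["ap50"] for v in per_class.values()]),
        ap75=_nanmean([v["ap75"] for v in per_class.values()]),
        ap_50_95=_nanmean([v["ap_50_95"] for v in per_class.values()]),
        precision=_nanmean([v["precision"] for v in per_class.values()]),
        recall_all=_nanmean([v["recall_all"] for v in per_class.values()]),
        per_class=per_class,
    )
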