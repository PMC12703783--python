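"""Attention-Aware Weight Estimator and two-stream fusion.

A scalar descriptor z is obtained by global average pooling of the refined
saliency map; a tiny one-hidden-layer MLP regressor maps it through
``lambda = sigmoid(W2 . relu(W1 * z + b1) + b2)`` to a soft fusion weight
strictly inside (0, 1); and the enhanced-stream and baseline-stream
detector outputs are blended convexly, ``lambda * enhanced +
(1 - lambda) * baseline``.

Two fusion granularities are supported: ``fuse_dense`` combines the
streams' dense pre-decoding prediction grids elementwise (the default,
well-defined linear combination), and ``fuse_detections_wbf`` realizes the
same convex weighting on decoded box sets by clustering same-class boxes
across streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .detector import Detection, DetectionSet, iou
from .errors import NumericalError, ShapeError

__all__ = [
    "AweParams",
    "FusionWeight",
    "global_descriptor",
    "fusion_weight",
    "fuse_dense",
    "fuse_detections_wbf",
]


@dataclass
class AweParams:
    """MLP regressor weights; a deterministic function of ``seed`` at init."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: float
    seed: int | None = None

    def __post_init__(self):
        self.W1 = np.asarray(self.W1, dtype=float).ravel()
        self.b1 = np.asarray(self.b1, dtype=float).ravel()
        self.W2 = np.asarray(self.W2, dtype=float).ravel()
        if not (self.W1.size == self.b1.size == self.W2.size >= 1):
            raise ValueError("W1, b1, W2 must share a hidden width >= 1")
        vals = np.concatenate([self.W1, self.b1, self.W2, [self.b2]])
        if not np.isfinite(vals).all():
            raise NumericalError("non-finite regressor weights")

    @property
    def hidden_width(self) -> int:
        return self.W1.size

    @classmethod
    def zeros(cls, hidden_width: int = 16) -> "AweParams":
        """All-zero weights: lambda = sigmoid(0) = 0.5 for any input."""
        z = np.zeros(hidden_width)
        return cls(W1=z, b1=z.copy(), W2=z.copy(), b2=0.0)

    @classmethod
    def gaussian(cls, seed: int, hidden_width: int = 16, scale: float = 0.5) -> "AweParams":
        rng = np.random.default_rng(seed)
        return cls(
            W1=rng.normal(0.0, scale, hidden_width),
            b1=rng.normal(0.0, scale, hidden_width),
            W2=rng.normal(0.0, scale / np.sqrt(hidden_width), hidden_width),
            b2=float(rng.normal(0.0, scale)),
            seed=seed,
        )


@dataclass(frozen=True)
class FusionWeight:
    """A fusion weight strictly inside (0, 1)."""

    lam: float

    def __post_init__(self):
        if not 0.0 < self.lam < 1.0:
            raise ValueError(f"fusion weight {self.lam} not strictly in (0, 1)")


def global_descriptor(attention: np.ndarray) -> float:
    """Global average pooling of a saliency/attention map to a scalar."""
    a = np.asarray(attention, dtype=float)
    if a.size == 0:
        raise ShapeError("cannot pool an empty map")
    if not np.isfinite(a).all():
        raise NumericalError("non-finite attention map")
    return float(a.mean())


def fusion_weight(z: float, params: AweParams) -> FusionWeight:
    """``lambda = sigmoid(W2 . relu(W1 * z + b1) + b2)``, strictly in (0, 1)."""
    if not np.isfinite(z):
        raise NumericalError("descriptor z must be finite")
    h = np.maximum(params.W1 * z + params.b1, 0.0)
    return FusionWeight(lam=float(expit(np.dot(params.W2, h) + params.b2)))


def _lam_value(lam: FusionWeight | float) -> float:
    lam = lam.lam if isinstance(lam, FusionWeight) else float(lam)
    if not 0.0 <= lam <= 1.0:
        raise ValueError(f"fusion weight {lam} outside [0, 1]")
    return lam


def fuse_dense(
    pred_enh: np.ndarray, pred_base: np.ndarray, lam: FusionWeight | float
) -> np.ndarray:
    """Convex combination ``lam * enhanced + (1 - lam) * baseline`` elementwise.

    Endpoint overrides (lam exactly 0 or 1) reproduce one stream
    bit-identically.  Accepts a raw float in [0, 1] for config overrides.
    """
    a = np.asarray(pred_enh, dtype=float)
    b = np.asarray(pred_base, dtype=float)
    if a.shape != b.shape:
        raise ShapeError(f"stream shapes disagree: {a.shape} vs {b.shape}")
    w = _lam_value(lam)
    if w == 0.0:
        return b.copy()
    if w == 1.0:
        return a.copy()
    return w * a + (1.0 - w) * b


def fuse_detections_wbf(
    dets_enh: DetectionSet,
    dets_base: DetectionSet,
    lam: FusionWeight | float,
    iou_cluster: float = 0.55,
) -> DetectionSet:
    """Box-level convex fusion of two decoded detection streams.

    Same-class boxes across the streams with IoU >= ``iou_cluster`` are
    greedily paired (enhanced boxes visited in descending score order, each
    claiming its best-overlapping unpaired baseline box).  A pair fuses to
    score ``lam * s_enh + (1 - lam) * s_base`` and a score-weighted average
    box; an unpaired box passes through with its stream's weighted score (a
    missing partner contributes score 0).  The endpoints lam = 0 / 1
    reproduce the corresponding stream exactly (the other stream's boxes
    carry weight zero).
    """
    if not 0.0 < iou_cluster < 1.0:
        raise ValueError("iou_cluster must lie in (0, 1)")
    w = _lam_value(lam)
    if w in (0.0, 1.0):
        src = dets_enh if w == 1.0 else dets_base
        kept = sorted(src.detections, key=lambda d: (-d.score, d.box[1], d.box[0], d.class_id))
        return DetectionSet(detections=kept, image_id=dets_base.image_id)
    fused: list[Detection] = []
    base_by_class: dict[int, list[Detection]] = {}
    for d in dets_base.detections:
        base_by_class.setdefault(d.class_id, []).append(d)
    used: dict[int, set[int]] = {c: set() for c in base_by_class}
    enh_sorted = sorted(
        dets_enh.detections, key=lambda d: (-d.score, d.box[1], d.box[0])
    )
    for d in enh_sorted:
        partners = base_by_class.get(d.class_id, [])
        best, best_iou = None, 0.0
        for k, b in enumerate(partners):
            if k in used[d.class_id]:
                continue
            v = iou(d.box, b.box)
            if v >= iou_cluster and v > best_iou:
                best, best_iou = k, v
        if best is None:
            fused.append(Detection(box=d.box, class_id=d.class_id, score=w * d.score))
        else:
            b = partners[best]
            used[d.class_id].add(best)
            total = d.score + b.score
            if total > 0:
                box = tuple(
                    (d.score * np.asarray(d.box) + b.score * np.asarray(b.box)) / total
                )
            else:
                box = d.box
            fused.append(
                Detection(
                    box=box,
                    class_id=d.class_id,
                    score=w * d.score + (1.0 - w) * b.score,
                )
            )
    for c, partners in base_by_class.items():
        for k, b in enumerate(partners):
            if k not in used.get(c, set()):
                fused.append(
                    Detection(box=b.box, class_id=c, score=(1.0 - w) * b.score)
                )
    fused.sort(key=lambda d: (-d.score, d.box[1], d.box[0], d.class_id))
    return DetectionSet(detections=fused, image_id=dets_base.image_id)
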