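"""Detector contract, deterministic color mock detector, decoding and NMS.

The detector seam maps a (3, H, W) real array to a :class:`DensePrediction`
grid of shape (Gh, Gw, 5 + K): per cell an objectness score, four box
fields, and K class scores.  The grid is the linear-combinable form of a
detector output, so two streams can be blended convexly before decoding.

The shipped :class:`MockDetector` is a pure function of its input: the
image is partitioned into Gh x Gw cells; each cell's class scores are the
clipped cosine similarities between the cell's mean RGB color and per-class
prototype colors; the box fields hold a fixed cell-centered box whose side
is ``box_cells`` cell widths.  An adapter around a real detector satisfies
the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidBox, ShapeError

__all__ = [
    "Detection",
    "DetectionSet",
    "DensePrediction",
    "MockDetector",
    "mock_detect",
    "decode",
    "iou",
    "nms",
    "cell_bounds",
]

Box = tuple[float, float, float, float]


@dataclass(frozen=True)
class Detection:
    """A scored, class-labeled box in 0-based half-open pixel coordinates."""

    box: Box
    class_id: int
    score: float

    def __post_init__(self):
        xmin, ymin, xmax, ymax = self.box
        if not (xmin < xmax and ymin < ymax):
            raise InvalidBox(f"degenerate box {self.box}")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score {self.score} outside [0, 1]")
        if self.class_id < 0:
            raise ValueError("class_id must be >= 0")
        object.__setattr__(self, "box", tuple(float(v) for v in self.box))


@dataclass
class DetectionSet:
    """All detections for one image."""

    detections: list[Detection] = field(default_factory=list)
    image_id: str = ""

    def __len__(self) -> int:
        return len(self.detections)

    def __iter__(self):
        return iter(self.detections)

    def to_records(self) -> list[dict]:
        return [
            {
                "box": list(d.box),
                "class_id": int(d.class_id),
                "score": float(d.score),
            }
            for d in self.detections
        ]


@dataclass
class DensePrediction:
    """(Gh, Gw, 5 + K) grid: objectness, 4 box fields, K class scores."""

    grid: np.ndarray
    image_height: int
    image_width: int

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 3 or self.grid.shape[2] < 6:
            raise ShapeError(
                f"dense grid must be (Gh, Gw, 5 + K) with K >= 1, got {self.grid.shape}"
            )
        if not np.isfinite(self.grid).all():
            raise ShapeError("dense grid must be finite")

    @property
    def n_classes(self) -> int:
        return self.grid.shape[2] - 5


def cell_bounds(extent: int, n_cells: int) -> list[tuple[int, int]]:
    """Half-open integer cell boundaries partitioning [0, extent)."""
    edges = [round(i * extent / n_cells) for i in range(n_cells + 1)]
    return [(edges[i], edges[i + 1]) for i in range(n_cells)]


def mock_detect(
    image_like: np.ndarray,
    class_prototypes: np.ndarray,
    grid: tuple[int, int] = (8, 8),
    score_floor: float = 0.0,
    box_cells: float = 2.0,
) -> DensePrediction:
    """Deterministic color-prototype detector on a regular cell grid.

    Per cell, class score k = max(0, cosine(cell mean color, prototype k));
    objectness = max class score clipped to [0, 1], zeroed when it does not
    exceed ``score_floor``; box fields = a fixed cell-centered box of
    ``box_cells`` cell widths per side, in cell-normalized coordinates
    (so the default 2.0 yields a box twice the cell pitch, matched to the
    object scale of the synthetic scenes).
    """
    img = np.asarray(image_like, dtype=float)
    if img.ndim != 3 or img.shape[0] != 3:
        raise ShapeError(f"expected (3, H, W) array, got {img.shape}")
    protos = np.asarray(class_prototypes, dtype=float)
    if protos.ndim != 2 or protos.shape[1] != 3:
        raise ShapeError("class prototypes must be (K, 3) RGB rows")
    gh, gw = grid
    if gh < 1 or gw < 1:
        raise ShapeError("grid must be at least 1x1")
    _, h, w = img.shape
    pn = protos / np.linalg.norm(protos, axis=1, keepdims=True)
    out = np.zeros((gh, gw, 5 + protos.shape[0]), dtype=float)
    rows = cell_bounds(h, gh)
    cols = cell_bounds(w, gw)
    for i, (y0, y1) in enumerate(rows):
        for j, (x0, x1) in enumerate(cols):
            mean = img[:, y0:y1, x0:x1].reshape(3, -1).mean(axis=1)
            norm = np.linalg.norm(mean)
            if norm > 0:
                scores = np.maximum(pn @ (mean / norm), 0.0)
            else:
                scores = np.zeros(protos.shape[0])
            obj = float(np.clip(scores.max(), 0.0, 1.0))
            if obj <= score_floor and score_floor > 0.0:
                obj = 0.0
            half = box_cells / 2.0
            out[i, j, 0] = obj
            out[i, j, 1:5] = (0.5 - half, 0.5 - half, 0.5 + half, 0.5 + half)
            out[i, j, 5:] = scores
    return DensePrediction(grid=out, image_height=h, image_width=w)


class MockDetector:
    """The detector seam bound to fixed prototypes and grid geometry."""

    def __init__(
        self,
        class_prototypes: np.ndarray,
        grid: tuple[int, int] = (8, 8),
        score_floor: float = 0.0,
        box_cells: float = 2.0,
    ):
        self.class_prototypes = np.asarray(class_prototypes, dtype=float)
        self.grid = tuple(grid)
        self.score_floor = float(score_floor)
        self.box_cells = float(box_cells)

    def __call__(self, image_like: np.ndarray) -> DensePrediction:
        return mock_detect(
            image_like, self.class_prototypes, self.grid, self.score_floor,
            self.box_cells,
        )


def decode(pred: DensePrediction, score_threshold: float) -> DetectionSet:
    """Turn grid cells with objectness >= threshold into pixel-space detections.

    Each firing cell yields one detection: argmax class (ties to the lowest
    class id), score = objectness * class score, and the cell's box fields
    mapped from cell-normalized to pixel coordinates, clipped to the image.
    """
    if not 0.0 <= score_threshold:
        raise ValueError("score_threshold must be >= 0")
    gh, gw, _ = pred.grid.shape
    rows = cell_bounds(pred.image_height, gh)
    cols = cell_bounds(pred.image_width, gw)
    dets: list[Detection] = []
    for i in range(gh):
        y0, y1 = rows[i]
        for j in range(gw):
            obj = float(pred.grid[i, j, 0])
            if obj < score_threshold:
                continue
            x0, x1 = cols[j]
            bx0, by0, bx1, by1 = pred.grid[i, j, 1:5]
            cw, ch = x1 - x0, y1 - y0
            box = (
                max(0.0, min(float(pred.image_width), x0 + bx0 * cw)),
                max(0.0, min(float(pred.image_height), y0 + by0 * ch)),
                max(0.0, min(float(pred.image_width), x0 + bx1 * cw)),
                max(0.0, min(float(pred.image_height), y0 + by1 * ch)),
            )
            cls_scores = pred.grid[i, j, 5:]
            k = int(np.argmax(cls_scores))
            score = float(np.clip(obj * cls_scores[k], 0.0, 1.0))
            dets.append(Detection(box=box, class_id=k, score=score))
    return DetectionSet(detections=dets)


def iou(a: Box, b: Box) -> float:
    """Intersection-over-union of two half-open axis-aligned boxes."""
    ax0, ay0, ax1, ay1 = a
    bx0, by0, bx1, by1 = b
    if ax0 >= ax1 or ay0 >= ay1 or bx0 >= bx1 or by0 >= by1:
        raise InvalidBox(f"degenerate box in IoU: {a} vs {b}")
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    union = (ax1 - ax0) * (ay1 - ay0) + (bx1 - bx0) * (by1 - by0) - inter
    return float(inter / union)


def nms(dets: DetectionSet, iou_threshold: float = 0.5) -> DetectionSet:
    """Greedy per-class suppression in descending score order.

    Ties are broken by smaller (ymin, xmin); a box is suppressed when its
    IoU with an already-kept same-class box reaches the threshold.
    """
    if not 0.0 < iou_threshold < 1.0:
        raise ValueError("iou_threshold must lie in (0, 1)")
    kept: list[Detection] = []
    by_class: dict[int, list[Detection]] = {}
    for d in dets.detections:
        by_class.setdefault(d.class_id, []).append(d)
    for c in sorted(by_class):
        pool = sorted(by_class[c], key=lambda d: (-d.score, d.box[1], d.box[0]))
        chosen: list[Detection] = []
        for d in pool:
            if all(iou(d.box, k.box) < iou_threshold for k in chosen):
                chosen.append(d)
        kept.extend(chosen)
    kept.sort(key=lambda d: (-d.score, d.box[1], d.box[0], d.class_id))
    return DetectionSet(detections=kept, image_id=dets.image_id)
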