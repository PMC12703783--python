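"""Readers and writers for every on-disk format the tool touches.

Images are 8-bit PNG/JPEG, decoded to (3, H, W) float64 arrays in [0, 1]
(grayscale replicated to 3 channels).  Ground truth uses YOLO-format label
text files ("class cx cy w h" with normalized center coordinates); masks
are single-channel 8-bit PNGs thresholded at 128 on load.  Structured
outputs (prompt points, detections, metrics) are JSON; the ablation table
is CSV.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
from PIL import Image

from .detector import Detection, DetectionSet
from .errors import FormatError
from .metrics import GroundTruth, MetricsRecord
from .spgm import BinaryMask

__all__ = [
    "LabelRecord",
    "read_image",
    "write_image",
    "read_labels",
    "write_labels",
    "read_mask",
    "write_mask",
    "record_to_box",
    "box_to_record",
    "write_points_json",
    "write_detections_json",
    "read_detections_json",
    "write_metrics_table",
]

Box = tuple[float, float, float, float]


class LabelRecord:
    """One YOLO label line: class id plus normalized center-format box."""

    __slots__ = ("class_id", "cx", "cy", "w", "h")

    def __init__(self, class_id: int, cx: float, cy: float, w: float, h: float):
        for name, v in (("cx", cx), ("cy", cy), ("w", w), ("h", h)):
            if not 0.0 <= v <= 1.0:
                raise FormatError(f"label field {name}={v} outside [0, 1]")
        if w == 0.0 or h == 0.0:
            raise FormatError("label box has zero area")
        self.class_id = int(class_id)
        self.cx, self.cy, self.w, self.h = float(cx), float(cy), float(w), float(h)


def record_to_box(rec: LabelRecord, image_size: tuple[int, int]) -> Box:
    """Denormalize to a 0-based half-open pixel box; image_size is (H, W)."""
    h, w = image_size
    return (
        (rec.cx - rec.w / 2) * w,
        (rec.cy - rec.h / 2) * h,
        (rec.cx + rec.w / 2) * w,
        (rec.cy + rec.h / 2) * h,
    )


def box_to_record(class_id: int, box: Box, image_size: tuple[int, int]) -> LabelRecord:
    h, w = image_size
    xmin, ymin, xmax, ymax = box
    return LabelRecord(
        class_id,
        cx=np.clip((xmin + xmax) / 2 / w, 0.0, 1.0),
        cy=np.clip((ymin + ymax) / 2 / h, 0.0, 1.0),
        w=np.clip((xmax - xmin) / w, 0.0, 1.0),
        h=np.clip((ymax - ymin) / h, 0.0, 1.0),
    )


def read_image(path: str | Path) -> np.ndarray:
    """Decode an image file to (3, H, W) float64 in [0, 1]."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    try:
        with Image.open(path) as img:
            arr = np.asarray(img.convert("RGB"), dtype=np.float64)
    except IOError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise IOError(f"unreadable image file {path}: {exc}") from exc
    return arr.transpose(2, 0, 1) / 255.0


def write_image(path: str | Path, array: np.ndarray) -> None:
    """Quantize a (3, H, W) float array (clipped to [0, 1]) to 8-bit and save."""
    arr = np.asarray(array, dtype=float)
    if arr.ndim != 3 or arr.shape[0] != 3:
        raise FormatError(f"expected (3, H, W) array, got {arr.shape}")
    u8 = np.round(np.clip(arr, 0.0, 1.0) * 255.0).astype(np.uint8)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray(u8.transpose(1, 2, 0)).save(path)


def read_labels(
    path: str | Path, image_size: tuple[int, int]
) -> list[GroundTruth]:
    """Parse a YOLO label file into pixel-space ground-truth boxes."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such label file: {path}")
    out: list[GroundTruth] = []
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.split()
        if len(fields) != 5:
            raise FormatError(f"{path}:{lineno}: expected 5 fields, got {len(fields)}")
        try:
            rec = LabelRecord(int(fields[0]), *(float(v) for v in fields[1:]))
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        except ValueError as exc:
            raise FormatError(f"{path}:{lineno}: unparsable field: {exc}") from exc
        out.append(GroundTruth(box=record_to_box(rec, image_size), class_id=rec.class_id))
    return out


def write_labels(
    path: str | Path,
    boxes: list[tuple[int, Box]],
    image_size: tuple[int, int],
) -> None:
    """Write (class_id, pixel box) pairs as YOLO label lines."""
    lines = []
    for class_id, box in boxes:
        rec = box_to_record(class_id, box, image_size)
        lines.append(
            f"{rec.class_id} {rec.cx:.6f} {rec.cy:.6f} {rec.w:.6f} {rec.h:.6f}"
        )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines) + ("\n" if lines else ""))


def read_mask(path: str | Path) -> BinaryMask:
    """Load a single-channel 8-bit PNG; >= 128 maps to foreground."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such mask file: {path}")
    with Image.open(path) as img:
        if img.mode not in ("L", "1", "P", "I;16"):
            raise FormatError(
                f"{path}: mask must be single-channel, got mode {img.mode!r}"
            )
        arr = np.asarray(img.convert("L"))
    return BinaryMask((arr >= 128).astype(np.uint8), source="file")


def write_mask(path: str | Path, mask: BinaryMask | np.ndarray) -> None:
    """Store a binary mask as {0, 255} single-channel PNG."""
    m = mask.m if isinstance(mask, BinaryMask) else np.asarray(mask)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Image.fromarray((m.astype(np.uint8) * 255)).save(path)


def write_points_json(path: str | Path, points) -> None:
    payload = [
        {"x": int(p.x), "y": int(p.y), "activation": float(p.activation)}
        for p in points
    ]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def write_detections_json(path: str | Path, dets: DetectionSet, extra: dict | None = None) -> None:
    payload = {"image_id": dets.image_id, "detections": dets.to_records()}
    if extra:
        payload.update(extra)
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


def read_detections_json(path: str | Path) -> DetectionSet:
    payload = json.loads(Path(path).read_text())
    dets = [
        Detection(box=tuple(d["box"]), class_id=d["class_id"], score=d["score"])
        for d in payload["detections"]
    ]
    return DetectionSet(detections=dets, image_id=payload.get("image_id", ""))


def write_metrics_table(path: str | Path, rows: dict[str, MetricsRecord]) -> None:
    """CSV ablation table: one row per variant, one column per metric."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["variant", *MetricsRecord.FIELDS])
        for variant, rec in rows.items():
            writer.writerow(
                [variant, *(f"{getattr(rec, f):.6f}" for f in MetricsRecord.FIELDS)]
            )
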