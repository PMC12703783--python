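"""Semantic Prior Generation: prompt points -> class-agnostic binary mask.

The promptable-segmenter seam is a callable ``(image, points) -> mask``
taking a (3, H, W) float image and an (N, 2) integer array of (x, y) seeds
and returning an H x W binary array.  The shipped reference backend is a
deterministic color region grower; an adapter around a real promptable
segmentation model satisfies the same contract.

The segmenter is invoked once with the full point set; the reference
backend internally unions per-seed regions.  Color tolerances are expressed
on the 0-255 RGB scale regardless of the float image encoding.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import ndimage

from .errors import InvalidSeed, NoPromptsError, SegmenterError
from .prompting import PromptPointSet

__all__ = [
    "BinaryMask",
    "ReferenceSegmenter",
    "region_grow_segmenter",
    "generate_mask",
    "mask_postprocess",
]

log = logging.getLogger(__name__)

# 4-connectivity structuring element used throughout (growth, components, holes)
_CROSS = ndimage.generate_binary_structure(2, 1)


@dataclass
class BinaryMask:
    """An H x W {0, 1} mask plus a provenance tag (reference|adapter|file)."""

    m: np.ndarray
    source: str = "reference"

    def __post_init__(self):
        self.m = np.asarray(self.m)
        if self.m.ndim != 2:
            raise ValueError(f"mask must be 2-d, got shape {self.m.shape}")
        vals = np.unique(self.m)
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("mask entries must be strictly binary")
        self.m = self.m.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.m.shape


def _grow_one(
    tol_ok: np.ndarray, seed_xy: tuple[int, int], max_region_pixels: int
) -> np.ndarray:
    """Breadth-first 4-connected growth from one seed over an admissible set.

    Growth proceeds ring by ring (each ring is one binary dilation step
    intersected with the admissible set).  If adding a ring would exceed
    ``max_region_pixels``, the ring is truncated in row-major order so the
    cap is met deterministically.
    """
    h, w = tol_ok.shape
    x, y = seed_xy
    region = np.zeros((h, w), dtype=bool)
    region[y, x] = True
    count = 1
    while count < max_region_pixels:
        grown = ndimage.binary_dilation(region, structure=_CROSS) & tol_ok
        ring = grown & ~region
        n_new = int(ring.sum())
        if n_new == 0:
            break
        if count + n_new > max_region_pixels:
            budget = max_region_pixels - count
            ys, xs = np.nonzero(ring)  # np.nonzero is row-major ordered
            keep = np.zeros_like(ring)
            keep[ys[:budget], xs[:budget]] = True
            ring = keep
        region |= ring
        count += int(ring.sum())
    return region


def region_grow_segmenter(
    image: np.ndarray,
    prompts: PromptPointSet | np.ndarray,
    color_tol: float = 60.0,
    max_region_pixels: int | None = None,
) -> BinaryMask:
    """Deterministic color region growing from seed points.

    For each seed, 4-connected breadth-first growth collects pixels whose
    Euclidean RGB distance (0-255 scale) to the *seed pixel's* color is at
    most ``color_tol``, capped at ``max_region_pixels`` per seed; the output
    is the union over seeds.

    Raises
    ------
    InvalidSeed
        If any seed lies outside the image bounds.
    """
    if color_tol < 0:
        raise ValueError("color_tol must be >= 0")
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[0] != 3:
        raise ValueError(f"expected (3, H, W) image, got {img.shape}")
    _, h, w = img.shape
    if max_region_pixels is None:
        max_region_pixels = h * w
    rgb = img * 255.0
    points = prompts.as_xy() if isinstance(prompts, PromptPointSet) else np.asarray(prompts)
    out = np.zeros((h, w), dtype=bool)
    for x, y in points:
        if not (0 <= x < w and 0 <= y < h):
            raise InvalidSeed(f"seed ({x}, {y}) outside {w}x{h} image")
        seed_color = rgb[:, y, x]
        dist = np.sqrt(((rgb - seed_color[:, None, None]) ** 2).sum(axis=0))
        out |= _grow_one(dist <= color_tol, (int(x), int(y)), max_region_pixels)
    return BinaryMask(out.astype(np.uint8), source="reference")


class ReferenceSegmenter:
    """Region-growing backend bound to fixed parameters (the segmenter seam)."""

    def __init__(self, color_tol: float = 60.0, max_region_pixels: int | None = None):
        self.color_tol = color_tol
        self.max_region_pixels = max_region_pixels

    def __call__(self, image: np.ndarray, points: np.ndarray) -> np.ndarray:
        return region_grow_segmenter(
            image, points, self.color_tol, self.max_region_pixels
        ).m


def mask_postprocess(
    mask: BinaryMask,
    min_component_area: int = 25,
    fill_holes: bool = True,
) -> BinaryMask:
    """Remove small 4-connected specks and optionally fill enclosed holes.

    Foreground components with area below ``min_component_area`` are
    dropped; with ``fill_holes``, background components not touching the
    border become foreground.  The operation is idempotent.
    """
    m = mask.m.astype(bool)
    if min_component_area > 1:
        labels, n = ndimage.label(m, structure=_CROSS)
        if n:
            areas = np.bincount(labels.ravel())
            small = np.flatnonzero(areas < min_component_area)
            m &= ~np.isin(labels, small[small > 0])
    if fill_holes:
        m = ndimage.binary_fill_holes(m, structure=_CROSS)
    return BinaryMask(m.astype(np.uint8), source=mask.source)


def generate_mask(
    image: np.ndarray,
    prompts: PromptPointSet,
    segmenter: Callable[[np.ndarray], np.ndarray] | ReferenceSegmenter,
    min_component_area: int = 25,
    fill_holes: bool = True,
) -> BinaryMask:
    """Run the promptable segmenter once on the full point set, then postprocess.

    Raises
    ------
    NoPromptsError
        If the prompt set is empty.
    SegmenterError
        If the backend fails or returns a mask of the wrong shape.
    """
    if len(prompts) == 0:
        raise NoPromptsError("cannot segment with an empty prompt set")
    img = np.asarray(image, dtype=float)
    try:
        raw = np.asarray(segmenter(img, prompts.as_xy()))
    except InvalidSeed:
        raise
    except Exception as exc:  # noqa: BLE001 - seam boundary
        raise SegmenterError(f"segmenter backend failed: {exc}") from exc
    if raw.shape != img.shape[1:]:
        raise SegmenterError(
            f"segmenter returned shape {raw.shape}, expected {img.shape[1:]}"
        )
    mask = BinaryMask((raw > 0).astype(np.uint8), source=getattr(segmenter, "source", "reference"))
    post = mask_postprocess(mask, min_component_area, fill_holes)
    dropped = [p for p in prompts if post.m[p.y, p.x] == 0 and mask.m[p.y, p.x] == 1]
    if dropped:
        log.warning(
            "mask postprocess removed the region of %d seed point(s)", len(dropped)
        )
    return post
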