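"""Seeded synthetic orchard scenes and the deterministic color mock encoders.

The generator emulates the statistical structure of orchard imagery that
the detection pipeline has to cope with - textured elliptical fruit of
several classes, partial occlusion by leaf-like shapes, and a cluttered
low-frequency background - while staying fully deterministic: identical
(spec, seed) pairs produce bit-identical scenes, ground-truth boxes and
per-instance masks.

The mock encoders live in 3-dimensional RGB embedding space, the minimal
space in which the tile-similarity contract is provable: the text encoder
maps a class name to its L2-normalized base color, the image encoder maps
a tile to its L2-normalized mean color.  Cosine similarity in the positive
RGB octant is permissive (every color pair has cosine well above zero),
which makes the palette the binding design constraint.  The default palette
therefore uses saturated warm class colors of deliberately *similar* hue -
mirroring the subtle inter-cultivar similarity of real orchard imagery -
against neutral gray background and gray-olive leaves whose color
directions nearly coincide: a tile inside a fruit then has a strictly
higher cosine with its class embedding than any pure-background tile
(margin >= 0.05), and no distractor drags the minimum of the similarity
map low enough for fruit-free tiles to survive relative thresholding.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from scipy.interpolate import RegularGridInterpolator

from .errors import DegenerateEmbedding, PlacementError, UnknownClass
from . import io as oio

__all__ = [
    "DEFAULT_CLASSES",
    "BACKGROUND_BASE",
    "LEAF_BASE",
    "SceneSpec",
    "Instance",
    "SceneFixture",
    "generate_scene",
    "generate_dataset",
    "mock_text_encoder",
    "mock_image_encoder",
    "MockTextEncoder",
]

# Saturated warm class colors, near-neutral distractors (see docstring).
DEFAULT_CLASSES: dict[str, tuple[int, int, int]] = {
    "peach": (230, 45, 40),
    "apricot": (240, 120, 45),
    "plum": (220, 60, 120),
}
BACKGROUND_BASE = (105, 105, 108)
LEAF_BASE = (88, 92, 84)


@dataclass
class SceneSpec:
    """Study conditions for one synthetic scene (all units in pixels/0-255 RGB)."""

    image_size: tuple[int, int] = (128, 128)  # (H, W)
    classes: dict[str, tuple[int, int, int]] = field(
        default_factory=lambda: dict(DEFAULT_CLASSES)
    )
    fruits_per_image: tuple[int, int] = (1, 3)
    radius_range: tuple[float, float] = (12.0, 18.0)
    occluder_count: int = 3
    occluder_opacity: float = 1.0
    background_noise: float = 8.0
    color_jitter: float = 8.0
    speckle_sigma: float = 6.0
    min_visible_fraction: float = 0.6
    min_gap: int = 4
    class_separation: float = 60.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.min_visible_fraction <= 1.0:
            raise ValueError("min_visible_fraction must lie in (0, 1]")
        if not 0.0 < self.occluder_opacity <= 1.0:
            raise ValueError("occluder_opacity must lie in (0, 1]")
        names = list(self.classes)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                d = np.linalg.norm(
                    np.asarray(self.classes[a], float) - np.asarray(self.classes[b], float)
                )
                if d < self.class_separation:
                    raise ValueError(
                        f"classes {a!r} and {b!r} are only {d:.0f} RGB units apart "
                        f"(need >= {self.class_separation})"
                    )

    @property
    def class_names(self) -> list[str]:
        return list(self.classes)

    def prototypes(self) -> np.ndarray:
        """(K, 3) base colors in registry order (detector prototypes)."""
        return np.asarray(list(self.classes.values()), dtype=float)


@dataclass
class Instance:
    """One fruit: class, tight box over the full mask, full + visible masks."""

    class_id: int
    box: tuple[float, float, float, float]
    full_mask: np.ndarray
    visible_mask: np.ndarray

    @property
    def visible_fraction(self) -> float:
        return float(self.visible_mask.sum() / max(self.full_mask.sum(), 1))


@dataclass
class SceneFixture:
    image: np.ndarray  # (3, H, W) float in [0, 1]
    instances: list[Instance]
    seed: int


def _tight_box(mask: np.ndarray) -> tuple[float, float, float, float]:
    ys, xs = np.nonzero(mask)
    return (float(xs.min()), float(ys.min()), float(xs.max() + 1), float(ys.max() + 1))


def _low_freq_background(rng: np.random.Generator, h: int, w: int, noise: float) -> np.ndarray:
    """Bilinearly interpolated coarse color-noise field around the base color."""
    nodes = 9
    base = np.asarray(BACKGROUND_BASE, dtype=float)
    grid = base + rng.uniform(-noise, noise, (nodes, nodes, 3))
    interp = RegularGridInterpolator(
        (np.linspace(0, h - 1, nodes), np.linspace(0, w - 1, nodes)), grid
    )
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    return interp(np.stack([yy.ravel(), xx.ravel()], axis=1)).reshape(h, w, 3)


def _ellipse_mask(h, w, cy, cx, ry, rx, theta=0.0) -> np.ndarray:
    yy, xx = np.meshgrid(np.arange(h), np.arange(w), indexing="ij")
    dy, dx = yy - cy, xx - cx
    c, s = np.cos(theta), np.sin(theta)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0


def generate_scene(spec: SceneSpec, seed: int | None = None) -> SceneFixture:
    """Render one scene; bit-identical for identical (spec, seed).

    Fruits are placed without overlap (a ``min_gap`` pixel buffer between
    full masks); leaf occluders are rejected whenever they would push any
    instance below ``min_visible_fraction`` visible pixels, so every fruit
    stays detectable in principle.

    Raises
    ------
    PlacementError
        If a fruit cannot be placed within the bounded retry budget.
    """
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    h, w = spec.image_size
    canvas = _low_freq_background(rng, h, w, spec.background_noise)

    n_fruit = int(rng.integers(spec.fruits_per_image[0], spec.fruits_per_image[1] + 1))
    names = spec.class_names
    instances: list[Instance] = []
    occupied = np.zeros((h, w), dtype=bool)
    for _ in range(n_fruit):
        placed = False
        for _attempt in range(60):
            class_id = int(rng.integers(len(names)))
            rx = float(rng.uniform(*spec.radius_range))
            ry = float(rng.uniform(*spec.radius_range))
            margin = max(rx, ry) + 2
            cx = float(rng.uniform(margin, w - margin))
            cy = float(rng.uniform(margin, h - margin))
            mask = _ellipse_mask(h, w, cy, cx, ry, rx)
            buffer = ndimage.binary_dilation(mask, iterations=spec.min_gap)
            if (buffer & occupied).any():
                continue
            base = np.asarray(spec.classes[names[class_id]], dtype=float)
            color = base + rng.uniform(-spec.color_jitter, spec.color_jitter, 3)
            speckle = rng.normal(0.0, spec.speckle_sigma, (h, w, 3))
            paint = np.clip(color[None, None, :] + speckle, 0, 255)
            canvas[mask] = paint[mask]
            occupied |= mask
            instances.append(
                Instance(
                    class_id=class_id,
                    box=_tight_box(mask),
                    full_mask=mask.astype(np.uint8),
                    visible_mask=mask.astype(np.uint8).copy(),
                )
            )
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"could not place fruit {len(instances) + 1}/{n_fruit} "
                f"after bounded retries (seed {seed})"
            )

    leaf_base = np.asarray(LEAF_BASE, dtype=float)
    for _ in range(spec.occluder_count):
        for _attempt in range(10):
            cx = float(rng.uniform(0, w))
            cy = float(rng.uniform(0, h))
            rx = float(rng.uniform(7, 15))
            ry = float(rng.uniform(3, 6))
            theta = float(rng.uniform(0, np.pi))
            leaf = _ellipse_mask(h, w, cy, cx, ry, rx, theta)
            ok = True
            for inst in instances:
                remaining = inst.visible_mask.astype(bool) & ~leaf
                if remaining.sum() < spec.min_visible_fraction * inst.full_mask.sum():
                    ok = False
                    break
            if not ok:
                continue  # rejection keeps every fruit detectable
            color = leaf_base + rng.uniform(-6, 6, 3)
            alpha = spec.occluder_opacity
            canvas[leaf] = alpha * color[None, :] + (1 - alpha) * canvas[leaf]
            for inst in instances:
                inst.visible_mask = (
                    inst.visible_mask.astype(bool) & ~leaf
                ).astype(np.uint8)
            break

    image = np.clip(np.round(canvas), 0, 255).astype(np.uint8)
    image = image.transpose(2, 0, 1).astype(np.float64) / 255.0
    return SceneFixture(image=image, instances=instances, seed=int(seed))


def _split_counts(n: int, fractions: tuple[float, float, float]) -> list[int]:
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("split fractions must sum to 1")
    counts = [int(np.floor(n * f)) for f in fractions]
    leftover = n - sum(counts)
    for i in range(leftover):  # remainder to the earliest splits
        counts[i % 3] += 1
    return counts


def generate_dataset(
    spec: SceneSpec,
    n_images: int,
    split: tuple[float, float, float] = (0.7, 0.2, 0.1),
    seed: int = 0,
    out_dir: str | Path = "data",
) -> Path:
    """Write a train/val/test tree of scenes with YOLO labels and union masks.

    Layout: ``out/<split>/{images,labels,masks}/scene_XXXX.*`` plus a
    ``manifest.json`` recording per-image seeds so any file can be
    regenerated exactly.
    """
    out = Path(out_dir)
    counts = _split_counts(n_images, split)
    image_seeds = np.random.default_rng(seed).integers(0, 2**31, size=n_images)
    manifest = {"seed": int(seed), "n_images": int(n_images), "splits": {}}
    idx = 0
    h, w = spec.image_size
    for split_name, count in zip(("train", "val", "test"), counts):
        entries = []
        for _ in range(count):
            scene_seed = int(image_seeds[idx])
            fixture = generate_scene(spec, scene_seed)
            stem = f"scene_{idx:04d}"
            for sub in ("images", "labels", "masks"):
                (out / split_name / sub).mkdir(parents=True, exist_ok=True)
            oio.write_image(out / split_name / "images" / f"{stem}.png", fixture.image)
            boxes = [(inst.class_id, inst.box) for inst in fixture.instances]
            oio.write_labels(out / split_name / "labels" / f"{stem}.txt", boxes, (h, w))
            union = np.zeros((h, w), dtype=np.uint8)
            for inst in fixture.instances:
                union |= inst.full_mask
            oio.write_mask(out / split_name / "masks" / f"{stem}.png", union)
            entries.append({"name": stem, "seed": scene_seed, "n_instances": len(fixture.instances)})
            idx += 1
        manifest["splits"][split_name] = entries
    manifest["classes"] = {name: list(rgb) for name, rgb in spec.classes.items()}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return out


def mock_text_encoder(class_name: str, registry: dict[str, tuple[int, int, int]]) -> np.ndarray:
    """L2-normalized base RGB color of a registry class (3-d embedding)."""
    if class_name not in registry:
        raise UnknownClass(
            f"{class_name!r} not in registry {sorted(registry)}"
        )
    v = np.asarray(registry[class_name], dtype=float)
    return v / np.linalg.norm(v)


class MockTextEncoder:
    """The text-encoder seam bound to a class registry."""

    def __init__(self, registry: dict[str, tuple[int, int, int]] | None = None):
        self.registry = dict(registry or DEFAULT_CLASSES)

    def __call__(self, class_name: str) -> np.ndarray:
        return mock_text_encoder(class_name, self.registry)


def mock_image_encoder(tile: np.ndarray) -> np.ndarray:
    """L2-normalized mean RGB of a (3, h, w) tile (3-d embedding)."""
    t = np.asarray(tile, dtype=float)
    if t.ndim != 3 or t.shape[0] != 3 or t[0].size == 0:
        raise DegenerateEmbedding(f"expected non-empty (3, h, w) tile, got {t.shape}")
    mean = t.reshape(3, -1).mean(axis=1)
    norm = np.linalg.norm(mean)
    if norm == 0.0:
        raise DegenerateEmbedding("all-black tile has no color direction")
    return mean / norm
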