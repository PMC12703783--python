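"""Text-guided tile-similarity heatmaps and prompt-point selection.

The image is divided into square tiles on a regular stride; each tile is
embedded by a pluggable image encoder and compared, by cosine similarity,
with the embedding of a free-text class query ("a ripe peach").  Min-max
normalization turns the tile-level similarity map into an attention heatmap
in [0, 1], and a greedy thresholded peak-picker with Chebyshev spatial
suppression turns the heatmap into a small set of prompt points that drive
the downstream promptable segmenter.

Coordinates are 0-based, ``(x, y) = (column, row)``; tile extents are
half-open pixel intervals.  The encoder seam is a plain callable so that
both the deterministic color mock encoders (:mod:`orchardet.synthetic`) and
real vision-language model adapters satisfy it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .errors import (
    DegenerateEmbedding,
    EncoderError,
    InvalidTiling,
    NoSalientRegion,
)

__all__ = [
    "TextQuery",
    "Tile",
    "TileGrid",
    "AttentionHeatmap",
    "PromptPoint",
    "PromptPointSet",
    "tile_image",
    "cosine_similarity",
    "compute_similarity_map",
    "normalize_map",
    "select_prompts",
]


@dataclass(frozen=True)
class TextQuery:
    """A free-text class name or phrase; must be non-blank."""

    text: str

    def __post_init__(self):
        if not self.text.strip():
            raise ValueError("text query must be non-empty after stripping")


@dataclass(frozen=True)
class Tile:
    """One grid tile: (row, col) index and half-open pixel extent."""

    row: int
    col: int
    y0: int
    x0: int
    y1: int
    x1: int

    @property
    def center(self) -> tuple[int, int]:
        """Pixel center (x, y) of the extent midpoint, rounded down."""
        return ((self.x0 + self.x1 - 1) // 2, (self.y0 + self.y1 - 1) // 2)


@dataclass(frozen=True)
class TileGrid:
    """Row-major complete grid of square tiles covering the image.

    When the stride does not cover the image exactly, a final row/column of
    tiles is clamped flush to the border (duplicated coverage is allowed),
    so every pixel is covered by at least one tile.
    """

    image_height: int
    image_width: int
    tile_size: int
    stride: int
    row_starts: tuple[int, ...]
    col_starts: tuple[int, ...]

    @property
    def n_rows(self) -> int:
        return len(self.row_starts)

    @property
    def n_cols(self) -> int:
        return len(self.col_starts)

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def tile(self, row: int, col: int) -> Tile:
        y0 = self.row_starts[row]
        x0 = self.col_starts[col]
        return Tile(row, col, y0, x0, y0 + self.tile_size, x0 + self.tile_size)

    def tiles(self):
        """Yield all tiles in row-major order."""
        for i in range(self.n_rows):
            for j in range(self.n_cols):
                yield self.tile(i, j)

    def extract(self, image: np.ndarray, tile: Tile) -> np.ndarray:
        """Slice a (3, H, W) image down to a tile's (3, t, t) raster."""
        return image[:, tile.y0 : tile.y1, tile.x0 : tile.x1]


@dataclass(frozen=True)
class AttentionHeatmap:
    """Tile-resolution heatmap in [0, 1]; flat maps carry ``degenerate``."""

    a: np.ndarray
    degenerate: bool = False


@dataclass(frozen=True)
class PromptPoint:
    x: int
    y: int
    activation: float


@dataclass
class PromptPointSet:
    """Prompt points ordered by non-increasing activation."""

    points: list[PromptPoint] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def as_xy(self) -> np.ndarray:
        """(N, 2) integer array of (x, y) coordinates."""
        return np.array([[p.x, p.y] for p in self.points], dtype=int).reshape(-1, 2)


def _axis_starts(extent: int, tile_size: int, stride: int) -> tuple[int, ...]:
    starts = list(range(0, extent - tile_size + 1, stride))
    if starts[-1] != extent - tile_size:
        starts.append(extent - tile_size)  # clamped border tile
    return tuple(starts)


def tile_image(image: np.ndarray, tile_size: int, stride: int) -> TileGrid:
    """Divide a (3, H, W) image into a full-coverage grid of square tiles.

    Raises
    ------
    InvalidTiling
        If ``tile_size`` exceeds the smaller image side, or parameters are
        out of range (``1 <= stride <= tile_size``).
    """
    if image.ndim != 3 or image.shape[0] != 3:
        raise InvalidTiling(f"expected (3, H, W) image, got shape {image.shape}")
    _, h, w = image.shape
    if not 1 <= tile_size <= min(h, w):
        raise InvalidTiling(
            f"tile_size {tile_size} outside [1, min(H, W)={min(h, w)}]"
        )
    if not 1 <= stride <= tile_size:
        raise InvalidTiling(f"stride {stride} outside [1, tile_size={tile_size}]")
    return TileGrid(
        image_height=h,
        image_width=w,
        tile_size=tile_size,
        stride=stride,
        row_starts=_axis_starts(h, tile_size, stride),
        col_starts=_axis_starts(w, tile_size, stride),
    )


def cosine_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Cosine of the angle between two embedding vectors, clipped to [-1, 1]."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise DegenerateEmbedding(
            f"dimension mismatch: {a.shape[0]} vs {b.shape[0]}"
        )
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0.0 or nb == 0.0:
        raise DegenerateEmbedding("zero-norm embedding vector")
    return float(np.clip(np.dot(a, b) / (na * nb), -1.0, 1.0))


def compute_similarity_map(
    grid: TileGrid,
    image: np.ndarray,
    image_encoder: Callable[[np.ndarray], np.ndarray],
    text_embedding: np.ndarray,
) -> np.ndarray:
    """Per-tile cosine similarity between tile embeddings and the text embedding.

    Returns a ``grid.shape`` float matrix with entries in [-1, 1].  Encoder
    failures are wrapped in :class:`EncoderError` carrying the tile index.
    """
    text_embedding = np.asarray(text_embedding, dtype=float).ravel()
    s = np.empty(grid.shape, dtype=float)
    for tile in grid.tiles():
        try:
            z = np.asarray(image_encoder(grid.extract(image, tile)), dtype=float)
        except Exception as exc:  # noqa: BLE001 - seam boundary
            raise EncoderError(
                f"image encoder failed on tile {(tile.row, tile.col)}: {exc}",
                tile_index=(tile.row, tile.col),
            ) from exc
        if z.size != text_embedding.size:
            raise EncoderError(
                f"encoder dim {z.size} != text dim {text_embedding.size}",
                tile_index=(tile.row, tile.col),
            )
        s[tile.row, tile.col] = cosine_similarity(z, text_embedding)
    return s


def normalize_map(sim: np.ndarray) -> AttentionHeatmap:
    """Min-max normalize a similarity map to [0, 1].

    A zero-range (constant) map cannot be normalized; it is returned as an
    all-zero heatmap with the ``degenerate`` flag set rather than raising.
    """
    sim = np.asarray(sim, dtype=float)
    lo = float(sim.min())
    hi = float(sim.max())
    if hi == lo:
        return AttentionHeatmap(a=np.zeros_like(sim), degenerate=True)
    return AttentionHeatmap(a=(sim - lo) / (hi - lo), degenerate=False)


def select_prompts(
    heat: AttentionHeatmap,
    grid: TileGrid,
    max_points: int = 5,
    rel_threshold: float = 0.7,
    min_separation: int | None = None,
) -> PromptPointSet:
    """Greedy thresholded peak-picking with Chebyshev spatial suppression.

    Tile centers are visited in non-increasing activation order (ties broken
    row-major: smaller row, then smaller column).  A candidate is kept when
    its activation is at least ``rel_threshold * max(heat)`` and its center
    is at Chebyshev distance >= ``min_separation`` (default: the tile size)
    from every already-selected point.  At most ``max_points`` are returned.

    Raises
    ------
    NoSalientRegion
        On a degenerate heatmap, or if thresholding leaves no candidate.
    """
    if heat.degenerate:
        raise NoSalientRegion("degenerate (flat) attention heatmap")
    if max_points < 1:
        raise ValueError("max_points must be >= 1")
    if not 0.0 < rel_threshold <= 1.0:
        raise ValueError("rel_threshold must lie in (0, 1]")
    if min_separation is None:
        min_separation = grid.tile_size
    a = heat.a
    if a.shape != grid.shape:
        raise NoSalientRegion(
            f"heatmap shape {a.shape} does not match grid shape {grid.shape}"
        )
    cutoff = rel_threshold * float(a.max())
    order = sorted(
        ((i, j) for i in range(a.shape[0]) for j in range(a.shape[1])),
        key=lambda ij: (-a[ij], ij[0], ij[1]),
    )
    selected: list[PromptPoint] = []
    for i, j in order:
        if len(selected) >= max_points:
            break
        act = float(a[i, j])
        if act < cutoff:
            break  # everything after is below threshold too
        x, y = grid.tile(i, j).center
        if any(
            max(abs(x - p.x), abs(y - p.y)) < min_separation for p in selected
        ):
            continue
        selected.append(PromptPoint(x=x, y=y, activation=act))
    if not selected:
        raise NoSalientRegion("no activation survives the relative threshold")
    return PromptPointSet(points=selected)
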