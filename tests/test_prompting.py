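"""Tile grids, cosine similarity maps, normalization and prompt selection."""

import numpy as np
import pytest

from orchardet import (
    AttentionHeatmap,
    TextQuery,
    compute_similarity_map,
    cosine_similarity,
    normalize_map,
    select_prompts,
    tile_image,
)
from orchardet.errors import (
    DegenerateEmbedding,
    EncoderError,
    InvalidTiling,
    NoSalientRegion,
)


def _img(h, w, value=0.5):
    return np.full((3, h, w), value)


class TestTileImage:
    @pytest.mark.parametrize(
        "h, w, tile, stride, shape",
        [
            (64, 64, 32, 32, (2, 2)),  # exact division
            (64, 64, 32, 16, (3, 3)),  # floor((64-32)/16)+1 = 3
            (64, 64, 64, 64, (1, 1)),
            (70, 64, 32, 32, (3, 2)),  # clamped border row appended
            (128, 128, 16, 8, (15, 15)),
        ],
    )
    def test_grid_shape(self, h, w, tile, stride, shape):
        assert tile_image(_img(h, w), tile, stride).shape == shape

    @pytest.mark.parametrize(
        "tile, stride", [(70, 32), (0, 1), (32, 0), (32, 40)]
    )
    def test_invalid_tiling(self, tile, stride):
        with pytest.raises(InvalidTiling):
            tile_image(_img(64, 64), tile, stride)

    @pytest.mark.parametrize("h, w, tile, stride", [(70, 65, 32, 32), (64, 64, 32, 16), (100, 50, 7, 3)])
    def test_full_coverage_and_bounds(self, h, w, tile, stride):
        grid = tile_image(_img(h, w), tile, stride)
        covered = np.zeros((h, w), dtype=bool)
        for t in grid.tiles():
            assert 0 <= t.y0 < t.y1 <= h and 0 <= t.x0 < t.x1 <= w
            assert (t.y1 - t.y0, t.x1 - t.x0) == (tile, tile)
            covered[t.y0 : t.y1, t.x0 : t.x1] = True
        assert covered.all()  # every pixel covered by >= 1 tile

    def test_tile_center_is_floored_midpoint(self):
        grid = tile_image(_img(64, 64), 32, 32)
        assert grid.tile(0, 0).center == (15, 15)
        assert grid.tile(1, 1).center == (47, 47)


class TestCosineSimilarity:
    def test_self_similarity(self):
        v = np.array([0.6, 0.8])
        assert cosine_similarity(v, v) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cosine_similarity([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0)

    def test_known_angle(self):
        got = cosine_similarity([1.0, 0.0], np.array([1.0, 1.0]) / np.sqrt(2))
        assert got == pytest.approx(0.70710678, abs=1e-8)

    def test_zero_norm_rejected(self):
        with pytest.raises(DegenerateEmbedding):
            cosine_similarity([0.0, 0.0], [1.0, 0.0])

    def test_dimension_mismatch_rejected(self):
        with pytest.raises(DegenerateEmbedding):
            cosine_similarity([1.0, 0.0], [1.0, 0.0, 0.0])


class TestSimilarityMap:
    def test_constant_encoder_gives_constant_map(self):
        grid = tile_image(_img(64, 64), 32, 32)
        s = compute_similarity_map(
            grid, _img(64, 64), lambda t: np.array([1.0, 0.0]), np.array([0.0, 2.0])
        )
        assert s.shape == (2, 2)
        assert np.allclose(s, 0.0)

    def test_matches_bruteforce_on_random_grids(self, rng):
        """Elementwise brute-force cosine oracle over seeded random grids."""
        for _ in range(25):
            tile = int(rng.integers(2, 5))
            n = int(rng.integers(1, 6))
            h = w = tile * n
            img = rng.random((3, h, w))
            grid = tile_image(img, tile, tile)
            text = rng.normal(size=3)
            text /= np.linalg.norm(text)

            def enc(t):
                v = t.reshape(3, -1).sum(axis=1) + 0.1
                return v / np.linalg.norm(v)

            s = compute_similarity_map(grid, img, enc, text)
            for t in grid.tiles():
                z = enc(grid.extract(img, t))
                want = float(np.dot(z, text))
                assert abs(s[t.row, t.col] - want) <= 1e-9

    def test_encoder_failure_carries_tile_index(self):
        grid = tile_image(_img(64, 64), 32, 32)

        def bad(t):
            raise RuntimeError("boom")

        with pytest.raises(EncoderError) as err:
            compute_similarity_map(grid, _img(64, 64), bad, np.array([1.0, 0.0]))
        assert err.value.tile_index == (0, 0)


class TestNormalizeMap:
    def test_minmax_values(self):
        heat = normalize_map(np.array([[0.2, 0.4], [0.6, 0.8]]))
        assert not heat.degenerate
        assert np.allclose(heat.a, [[0.0, 1 / 3], [2 / 3, 1.0]])

    def test_constant_map_degenerate(self):
        heat = normalize_map(np.full((3, 3), 0.7))
        assert heat.degenerate
        assert (heat.a == 0.0).all()

    def test_order_preserved_and_idempotent(self, rng):
        s = rng.normal(size=(4, 5))
        heat = normalize_map(s)
        assert (np.argsort(heat.a.ravel()) == np.argsort(s.ravel())).all()
        again = normalize_map(heat.a)
        assert np.allclose(again.a, heat.a)  # idempotent on [0, 1]-spanning maps
        assert heat.a.min() == 0.0 and heat.a.max() == 1.0


class TestSelectPrompts:
    def grid(self):
        return tile_image(_img(64, 64), 16, 16)

    def test_unique_peak(self):
        a = np.zeros((4, 4))
        a[2, 1] = 1.0
        pts = select_prompts(AttentionHeatmap(a), self.grid(), max_points=3)
        assert len(pts) == 1
        p = pts.points[0]
        assert (p.x, p.y, p.activation) == (23, 39, 1.0)

    def test_two_equal_maxima_row_major_ties(self):
        a = np.zeros((4, 4))
        a[3, 2] = a[0, 1] = 1.0
        pts = select_prompts(AttentionHeatmap(a), self.grid(), max_points=5)
        assert [(p.x, p.y) for p in pts] == [(23, 7), (39, 55)]  # row-major first

    def test_spatial_suppression(self):
        a = np.zeros((4, 4))
        a[0, 0] = 1.0
        a[0, 1] = 0.9  # center 16 px away: at the default separation boundary
        a[0, 2] = 0.8
        pts = select_prompts(
            AttentionHeatmap(a), self.grid(), max_points=5, rel_threshold=0.5,
            min_separation=17,
        )
        assert [(p.x, p.y) for p in pts] == [(7, 7), (39, 7)]

    def test_max_points_and_determinism(self, rng):
        a = rng.random((4, 4))
        heat = normalize_map(a)
        p1 = select_prompts(heat, self.grid(), max_points=2, rel_threshold=0.1)
        p2 = select_prompts(heat, self.grid(), max_points=2, rel_threshold=0.1)
        assert len(p1) <= 2
        assert p1.points == p2.points

    def test_degenerate_heatmap_raises(self):
        with pytest.raises(NoSalientRegion):
            select_prompts(
                AttentionHeatmap(np.zeros((4, 4)), degenerate=True), self.grid()
            )


def test_blank_text_query_rejected():
    with pytest.raises(ValueError):
        TextQuery("   ")
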