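"""Scene generator determinism and contracts; color mock encoders."""

import json

import numpy as np
import pytest

from orchardet import (
    DEFAULT_CLASSES,
    SceneSpec,
    cosine_similarity,
    generate_dataset,
    generate_scene,
    mock_image_encoder,
    mock_text_encoder,
)
from orchardet.errors import DegenerateEmbedding, UnknownClass
from orchardet.synthetic import BACKGROUND_BASE, _split_counts
from orchardet import io as oio


class TestGenerateScene:
    def test_single_fruit_tight_box(self):
        spec = SceneSpec(fruits_per_image=(1, 1), occluder_count=0)
        sc = generate_scene(spec, seed=3)
        assert len(sc.instances) == 1
        inst = sc.instances[0]
        ys, xs = np.nonzero(inst.full_mask)
        assert inst.box == (xs.min(), ys.min(), xs.max() + 1, ys.max() + 1)
        assert (inst.visible_mask == inst.full_mask).all()  # no occluders

    def test_bit_identical_replay(self, default_spec):
        a = generate_scene(default_spec, seed=17)
        b = generate_scene(default_spec, seed=17)
        assert (a.image == b.image).all()
        for ia, ib in zip(a.instances, b.instances):
            assert ia.class_id == ib.class_id and ia.box == ib.box
            assert (ia.full_mask == ib.full_mask).all()

    def test_visible_fraction_respected(self):
        spec = SceneSpec(min_visible_fraction=0.5, occluder_count=6)
        for seed in range(10):
            sc = generate_scene(spec, seed)
            for inst in sc.instances:
                assert inst.visible_fraction >= 0.5

    def test_mask_pixels_inside_box_and_bounds(self, default_spec):
        for seed in range(5):
            sc = generate_scene(default_spec, seed)
            for inst in sc.instances:
                ys, xs = np.nonzero(inst.full_mask)
                x0, y0, x1, y1 = inst.box
                assert (xs >= x0).all() and (xs < x1).all()
                assert (ys >= y0).all() and (ys < y1).all()
                assert 0 <= x0 < x1 <= 128 and 0 <= y0 < y1 <= 128

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            SceneSpec(min_visible_fraction=0.0)
        with pytest.raises(ValueError):
            SceneSpec(classes={"a": (200, 0, 0), "b": (210, 0, 0)})


class TestGenerateDataset:
    def test_split_counts_floor_then_remainder(self):
        assert _split_counts(10, (0.7, 0.2, 0.1)) == [7, 2, 1]
        assert _split_counts(5, (0.5, 0.3, 0.2)) == [3, 1, 1]

    def test_tree_layout_and_label_schema(self, tmp_path, default_spec):
        generate_dataset(default_spec, 5, (0.6, 0.2, 0.2), seed=9, out_dir=tmp_path)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        assert sum(len(v) for v in manifest["splits"].values()) == 5
        for split, entries in manifest["splits"].items():
            for e in entries:
                stem = e["name"]
                assert (tmp_path / split / "images" / f"{stem}.png").exists()
                label = tmp_path / split / "labels" / f"{stem}.txt"
                for line in label.read_text().splitlines():
                    fields = line.split()
                    assert len(fields) == 5
                    assert all(0.0 <= float(v) <= 1.0 for v in fields[1:])
                assert (tmp_path / split / "masks" / f"{stem}.png").exists()

    def test_manifest_seed_replay(self, tmp_path, default_spec):
        generate_dataset(default_spec, 3, (1.0, 0.0, 0.0), seed=4, out_dir=tmp_path)
        manifest = json.loads((tmp_path / "manifest.json").read_text())
        entry = manifest["splits"]["train"][0]
        on_disk = oio.read_image(tmp_path / "train" / "images" / f"{entry['name']}.png")
        replayed = generate_scene(default_spec, entry["seed"]).image
        assert (on_disk == replayed).all()


class TestMockEncoders:
    def test_text_embedding_is_normalized_base_color(self):
        z = mock_text_encoder("peach", {"peach": (255, 0, 0)})
        assert np.allclose(z, [1.0, 0.0, 0.0])

    def test_unknown_class(self):
        with pytest.raises(UnknownClass):
            mock_text_encoder("durian", DEFAULT_CLASSES)

    def test_registry_classes_distinct(self):
        names = list(DEFAULT_CLASSES)
        for i, a in enumerate(names):
            for b in names[i + 1 :]:
                cos = cosine_similarity(
                    mock_text_encoder(a, DEFAULT_CLASSES),
                    mock_text_encoder(b, DEFAULT_CLASSES),
                )
                assert cos < 1.0

    def test_pure_class_tile_has_cosine_one(self):
        tile = np.empty((3, 8, 8))
        tile[:] = np.array(DEFAULT_CLASSES["peach"])[:, None, None] / 255.0
        z = mock_image_encoder(tile)
        t = mock_text_encoder("peach", DEFAULT_CLASSES)
        assert cosine_similarity(z, t) == pytest.approx(1.0)

    def test_gray_tile_symmetric_between_swapped_channels(self):
        tile = np.full((3, 4, 4), 0.5)
        reg = {"a": (200, 50, 100), "b": (100, 50, 200)}
        z = mock_image_encoder(tile)
        ca = cosine_similarity(z, mock_text_encoder("a", reg))
        cb = cosine_similarity(z, mock_text_encoder("b", reg))
        assert ca == pytest.approx(cb)

    def test_black_tile_rejected(self):
        with pytest.raises(DegenerateEmbedding):
            mock_image_encoder(np.zeros((3, 4, 4)))

    def test_margin_contract_in_fruit_beats_background(self, default_spec):
        """A tile fully inside a class-c fruit has cosine with the class
        embedding exceeding any pure-background tile's by >= 0.05."""
        from orchardet import tile_image

        names = list(default_spec.classes)
        worst = 1.0
        for seed in range(10):
            sc = generate_scene(default_spec, seed)
            grid = tile_image(sc.image, 16, 8)
            union = np.zeros(default_spec.image_size, bool)
            for inst in sc.instances:
                union |= inst.full_mask.astype(bool)
            for cid in sorted({i.class_id for i in sc.instances}):
                t_emb = mock_text_encoder(names[cid], default_spec.classes)
                mask_c = np.zeros(default_spec.image_size, bool)
                for inst in sc.instances:
                    if inst.class_id == cid:
                        mask_c |= inst.full_mask.astype(bool)
                in_cos, bg_cos = [], []
                for t in grid.tiles():
                    patch = grid.extract(sc.image, t)
                    region = slice(t.y0, t.y1), slice(t.x0, t.x1)
                    leafish = (
                        np.abs(patch * 255 - np.array(BACKGROUND_BASE)[:, None, None])
                        .max(axis=0) > 40
                    )
                    if mask_c[region].all():
                        in_cos.append(cosine_similarity(mock_image_encoder(patch), t_emb))
                    elif not union[region].any() and not leafish.any():
                        bg_cos.append(cosine_similarity(mock_image_encoder(patch), t_emb))
                if in_cos and bg_cos:
                    worst = min(worst, min(in_cos) - max(bg_cos))
        assert worst >= 0.05
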