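"""End-to-end orchestration of the prompt-guided two-stream detection pipeline.

For one image and one text query the pipeline runs: tile-similarity
prompting -> prompt-driven mask prior -> mask-saliency adapter -> feature
enhancement on the semantic stream; the detector on both the enhanced and
the raw stream; and adaptive convex fusion of the two detector outputs
(dense-grid fusion followed by a single decode + NMS by default, or
decoded-box fusion in ``wbf`` mode).

Ablation toggles reproduce the incremental variants (baseline, +MSA,
+MSA+FER, +MSA+FER+AWE).  With MSA active but FER off, the enhanced stream
input is ``I * (1 + S_hat)`` - the saliency gain with a unit modulation
coefficient and no residual; with AWE off but an enhanced stream present,
the fusion weight is fixed at 0.5 (static equal blending).  A degenerate
(flat) heatmap or empty prompt set degrades the run to the baseline stream
(fusion weight forced to 0) with a logged warning instead of aborting.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable

import numpy as np

from .awe import AweParams, fuse_dense, fuse_detections_wbf, fusion_weight, global_descriptor
from .detector import DensePrediction, DetectionSet, decode, nms
from .errors import ConfigError, DatasetError, NoPromptsError, NoSalientRegion
from .fer import FerParams, fer_forward
from .metrics import MetricsRecord, evaluate
from .msa import MsaParams, msa_forward
from .prompting import TextQuery, compute_similarity_map, normalize_map, select_prompts, tile_image
from .spgm import ReferenceSegmenter, generate_mask
from . import io as oio
from .synthetic import DEFAULT_CLASSES, MockTextEncoder, mock_image_encoder
from .detector import MockDetector

__all__ = [
    "PipelineConfig",
    "ComponentBundle",
    "PipelineResult",
    "default_components",
    "run_pipeline",
    "run_ablation",
    "ABLATION_VARIANTS",
]

log = logging.getLogger(__name__)

ABLATION_VARIANTS = (
    ("baseline", dict(use_msa=False, use_fer=False, use_awe=False)),
    ("+MSA", dict(use_msa=True, use_fer=False, use_awe=False)),
    ("+MSA+FER", dict(use_msa=True, use_fer=True, use_awe=False)),
    ("+MSA+FER+AWE", dict(use_msa=True, use_fer=True, use_awe=True)),
)


@dataclass
class PipelineConfig:
    """All tunables of one pipeline run; sub-seeds derive from ``seed``."""

    seed: int = 0
    # tiling / prompting
    tile_size: int = 16
    stride: int = 8
    max_points: int = 5
    rel_threshold: float = 0.7
    min_separation: int | None = None
    # segmenter
    segmenter_backend: str = "reference"
    color_tol: float = 60.0
    max_region_pixels: int | None = None
    min_component_area: int = 25
    fill_holes: bool = True
    # msa / fer
    msa_init: str = "identity"
    msa_epsilon: float = 1e-5
    msa_seed: int | None = None
    fer_init: str = "identity"
    fer_residual: bool = True
    fer_seed: int | None = None
    # awe
    awe_mode: str = "dense"
    awe_source: str = "s_prime"
    awe_lambda_override: float | None = None
    awe_hidden_width: int = 16
    awe_init: str = "gaussian"
    awe_seed: int | None = None
    # detector / decoding
    detector_grid: tuple[int, int] = (8, 8)
    score_threshold: float = 0.95
    score_floor: float = 0.0
    nms_iou: float = 0.5
    # ablation toggles
    use_msa: bool = True
    use_fer: bool = True
    use_awe: bool = True

    def __post_init__(self):
        if self.use_fer and not self.use_msa:
            raise ConfigError("use_fer requires use_msa")
        if self.awe_mode not in ("dense", "wbf"):
            raise ConfigError(f"awe_mode must be dense|wbf, got {self.awe_mode!r}")
        if self.awe_source not in ("s_prime", "s_hat"):
            raise ConfigError(f"awe_source must be s_prime|s_hat, got {self.awe_source!r}")
        if self.awe_lambda_override is not None and not 0.0 <= self.awe_lambda_override <= 1.0:
            raise ConfigError("awe_lambda_override must lie in [0, 1] or be null")
        if self.msa_seed is None:
            self.msa_seed = (self.seed + 1) % 2**31
        if self.fer_seed is None:
            self.fer_seed = (self.seed + 2) % 2**31
        if self.awe_seed is None:
            self.awe_seed = (self.seed + 3) % 2**31
        self.detector_grid = tuple(int(v) for v in self.detector_grid)

    def msa_params(self) -> MsaParams:
        if self.msa_init == "identity":
            return MsaParams.identity(epsilon=self.msa_epsilon)
        return MsaParams.gaussian(self.msa_seed, epsilon=self.msa_epsilon)

    def fer_params(self) -> FerParams:
        if self.fer_init == "identity":
            return FerParams.identity()
        return FerParams.gaussian(self.fer_seed)

    def awe_params(self) -> AweParams:
        if self.awe_init == "zero":
            return AweParams.zeros(self.awe_hidden_width)
        return AweParams.gaussian(self.awe_seed, self.awe_hidden_width)

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["detector_grid"] = list(self.detector_grid)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class ComponentBundle:
    """The pluggable seams: encoders, segmenter and detector."""

    text_encoder: Callable[[str], np.ndarray]
    image_encoder: Callable[[np.ndarray], np.ndarray]
    segmenter: Callable
    detector: Callable[[np.ndarray], DensePrediction]
    class_names: list[str] = field(default_factory=lambda: list(DEFAULT_CLASSES))


def default_components(
    config: PipelineConfig,
    registry: dict[str, tuple[int, int, int]] | None = None,
) -> ComponentBundle:
    """Bundle the deterministic mock encoders/segmenter/detector."""
    registry = dict(registry or DEFAULT_CLASSES)
    prototypes = np.asarray(list(registry.values()), dtype=float)
    return ComponentBundle(
        text_encoder=MockTextEncoder(registry),
        image_encoder=mock_image_encoder,
        segmenter=ReferenceSegmenter(config.color_tol, config.max_region_pixels),
        detector=MockDetector(prototypes, config.detector_grid, config.score_floor),
        class_names=list(registry),
    )


@dataclass
class PipelineResult:
    """Final detections plus all retained intermediates and provenance."""

    detections: DetectionSet
    lam: float | None
    intermediates: dict
    provenance: dict


def _decode_nms(pred: DensePrediction, config: PipelineConfig) -> DetectionSet:
    return nms(decode(pred, config.score_threshold), config.nms_iou)


def run_pipeline(
    image: np.ndarray,
    class_query: str | TextQuery,
    components: ComponentBundle,
    config: PipelineConfig,
    image_id: str = "",
) -> PipelineResult:
    """Run the full two-stream pipeline on one image for one text query."""
    query = class_query if isinstance(class_query, TextQuery) else TextQuery(class_query)
    provenance = {"config_hash": config.config_hash(), "seed": config.seed,
                  "query": query.text}
    base_pred = components.detector(image)
    intermediates: dict = {"baseline_grid": base_pred}

    if not config.use_msa:
        dets = _decode_nms(base_pred, config)
        dets.image_id = image_id
        return PipelineResult(dets, lam=None, intermediates=intermediates,
                              provenance=provenance)

    try:
        grid = tile_image(image, config.tile_size, config.stride)
        sim = compute_similarity_map(
            grid, image, components.image_encoder, components.text_encoder(query.text)
        )
        heat = normalize_map(sim)
        prompts = select_prompts(
            heat, grid, config.max_points, config.rel_threshold, config.min_separation
        )
        mask = generate_mask(
            image, prompts, components.segmenter,
            config.min_component_area, config.fill_holes,
        )
    except (NoSalientRegion, NoPromptsError) as exc:
        log.warning("prompting degenerate (%s); falling back to baseline stream", exc)
        dets = _decode_nms(base_pred, config)
        dets.image_id = image_id
        intermediates["fallback"] = str(exc)
        return PipelineResult(dets, lam=0.0, intermediates=intermediates,
                              provenance=provenance)

    triple = msa_forward(mask, config.msa_params())
    if config.use_fer:
        enhanced = fer_forward(image, triple.S_hat, config.fer_params(),
                               residual=config.fer_residual)
    else:
        # saliency gain with unit modulation coefficient, no residual
        enhanced = image * (1.0 + triple.S_hat)[None, :, :]
    enh_pred = components.detector(enhanced)

    if config.awe_lambda_override is not None:
        lam = float(config.awe_lambda_override)
    elif config.use_awe:
        source = triple.S_prime if config.awe_source == "s_prime" else triple.S_hat
        lam = fusion_weight(global_descriptor(source), config.awe_params()).lam
    else:
        lam = 0.5  # static equal blending when the estimator is disabled

    intermediates.update(
        heatmap=heat, prompts=prompts, mask=mask, saliency=triple,
        enhanced=enhanced, enhanced_grid=enh_pred,
    )
    if config.awe_mode == "dense":
        fused = DensePrediction(
            grid=fuse_dense(enh_pred.grid, base_pred.grid, lam),
            image_height=base_pred.image_height,
            image_width=base_pred.image_width,
        )
        dets = _decode_nms(fused, config)
        intermediates["fused_grid"] = fused
    else:
        dets = fuse_detections_wbf(
            _decode_nms(enh_pred, config), _decode_nms(base_pred, config), lam
        )
    dets.image_id = image_id
    return PipelineResult(dets, lam=lam, intermediates=intermediates,
                          provenance=provenance)


def _detect_image(
    image: np.ndarray,
    components: ComponentBundle,
    config: PipelineConfig,
    image_id: str,
) -> DetectionSet:
    """Multi-class detection: one pipeline run per class query, merged.

    Each run keeps only detections of its queried class (ids follow the
    registry/query order); the baseline configuration ignores the query and
    runs once.
    """
    if not config.use_msa:
        return run_pipeline(image, components.class_names[0], components,
                            config, image_id).detections
    merged = []
    for class_id, name in enumerate(components.class_names):
        result = run_pipeline(image, name, components, config, image_id)
        merged.extend(d for d in result.detections if d.class_id == class_id)
    merged.sort(key=lambda d: (-d.score, d.box[1], d.box[0], d.class_id))
    return DetectionSet(detections=merged, image_id=image_id)


def _load_dataset(dataset_dir: str | Path):
    root = Path(dataset_dir)
    img_dir = root / "images"
    lbl_dir = root / "labels"
    if not img_dir.is_dir():
        raise DatasetError(f"missing images/ under {root}")
    if not lbl_dir.is_dir():
        raise DatasetError(f"missing labels/ under {root}")
    images = sorted(
        p for p in img_dir.iterdir() if p.suffix.lower() in (".png", ".jpg", ".jpeg")
    )
    if not images:
        raise DatasetError(f"no images under {img_dir}")
    entries = []
    for img_path in images:
        lbl_path = lbl_dir / (img_path.stem + ".txt")
        if not lbl_path.exists():
            raise DatasetError(f"missing label file {lbl_path}")
        entries.append((img_path, lbl_path))
    return entries


def _dataset_registry(dataset_dir: Path) -> dict[str, tuple[int, int, int]]:
    for candidate in (dataset_dir / "manifest.json", dataset_dir.parent / "manifest.json"):
        if candidate.exists():
            manifest = json.loads(candidate.read_text())
            if "classes" in manifest:
                return {k: tuple(v) for k, v in manifest["classes"].items()}
    return dict(DEFAULT_CLASSES)


def run_ablation(
    dataset_dir: str | Path,
    config: PipelineConfig,
    registry: dict[str, tuple[int, int, int]] | None = None,
) -> dict[str, MetricsRecord]:
    """Evaluate the incremental variants over a labelled image directory.

    ``dataset_dir`` must contain ``images/`` and ``labels/`` (YOLO format);
    the class registry is taken from a sibling ``manifest.json`` when
    present.  All variants share the same seed and component bundle.
    """
    dataset_dir = Path(dataset_dir)
    entries = _load_dataset(dataset_dir)
    registry = registry or _dataset_registry(dataset_dir)
    table: dict[str, MetricsRecord] = {}
    cache = []
    for img_path, lbl_path in entries:
        image = oio.read_image(img_path)
        cache.append(
            (img_path.stem, image, oio.read_labels(lbl_path, image.shape[1:]))
        )
    for name, toggles in ABLATION_VARIANTS:
        variant_cfg = replace(config, **toggles)
        components = default_components(variant_cfg, registry)
        dets = {}
        gts = {}
        for stem, image, labels in cache:
            dets[stem] = _detect_image(image, components, variant_cfg, stem)
            gts[stem] = labels
        table[name] = evaluate(dets, gts)
        log.info("variant %-13s ap50=%.4f", name, table[name].ap50)
    return table
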