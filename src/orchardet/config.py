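"""YAML run-configuration loading with strict schema validation.

The on-disk schema is a nested mapping mirroring :class:`PipelineConfig`;
unknown keys are rejected, types and ranges are checked before any
computation, and the global ``seed`` propagates deterministically to every
sub-module seed unless a sub-seed is set explicitly.  An empty file yields
the full default configuration.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .errors import ConfigError
from .pipeline import PipelineConfig

__all__ = ["load_config", "config_from_mapping", "SCHEMA"]

# section -> key -> (pipeline-config field, expected types, validator or None)
SCHEMA: dict[str, dict[str, tuple]] = {
    "tiling": {
        "tile_size": ("tile_size", int, lambda v: v >= 1),
        "stride": ("stride", int, lambda v: v >= 1),
    },
    "prompts": {
        "max_points": ("max_points", int, lambda v: v >= 1),
        "rel_threshold": ("rel_threshold", (int, float), lambda v: 0 < v <= 1),
        "min_separation": ("min_separation", (int, type(None)), lambda v: v is None or v >= 0),
    },
    "segmenter": {
        "backend": ("segmenter_backend", str, lambda v: v in ("reference", "adapter")),
        "color_tol": ("color_tol", (int, float), lambda v: v >= 0),
        "max_region_pixels": ("max_region_pixels", (int, type(None)), lambda v: v is None or v >= 1),
        "min_component_area": ("min_component_area", int, lambda v: v >= 0),
        "fill_holes": ("fill_holes", bool, None),
    },
    "msa": {
        "init": ("msa_init", str, lambda v: v in ("identity", "gaussian")),
        "epsilon": ("msa_epsilon", (int, float), lambda v: v > 0),
        "seed": ("msa_seed", (int, type(None)), None),
    },
    "fer": {
        "init": ("fer_init", str, lambda v: v in ("identity", "gaussian")),
        "residual": ("fer_residual", bool, None),
        "seed": ("fer_seed", (int, type(None)), None),
    },
    "awe": {
        "mode": ("awe_mode", str, lambda v: v in ("dense", "wbf")),
        "source": ("awe_source", str, lambda v: v in ("s_prime", "s_hat")),
        "lambda_override": ("awe_lambda_override", (int, float, type(None)),
                            lambda v: v is None or 0 <= v <= 1),
        "hidden_width": ("awe_hidden_width", int, lambda v: v >= 1),
        "init": ("awe_init", str, lambda v: v in ("zero", "gaussian")),
        "seed": ("awe_seed", (int, type(None)), None),
    },
    "detector": {
        "grid": ("detector_grid", (list, tuple), lambda v: len(v) == 2 and all(
            isinstance(x, int) and x >= 1 for x in v)),
        "score_threshold": ("score_threshold", (int, float), lambda v: 0 <= v),
        "score_floor": ("score_floor", (int, float), lambda v: 0 <= v <= 1),
        "nms_iou": ("nms_iou", (int, float), lambda v: 0 < v < 1),
    },
    "ablation": {
        "use_msa": ("use_msa", bool, None),
        "use_fer": ("use_fer", bool, None),
        "use_awe": ("use_awe", bool, None),
    },
}


def config_from_mapping(data: dict | None) -> PipelineConfig:
    """Validate a nested mapping against the schema and build a config."""
    data = dict(data or {})
    kwargs: dict = {}
    seed = data.pop("seed", 0)
    if not isinstance(seed, int) or isinstance(seed, bool):
        raise ConfigError(f"seed must be an integer, got {seed!r}")
    kwargs["seed"] = seed
    for section, entries in data.items():
        if section not in SCHEMA:
            raise ConfigError(f"unknown config section {section!r}")
        if entries is None:
            continue
        if not isinstance(entries, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        for key, value in entries.items():
            if key not in SCHEMA[section]:
                raise ConfigError(f"unknown config key {section}.{key}")
            dest, types, check = SCHEMA[section][key]
            if isinstance(value, bool) and types is int:
                raise ConfigError(f"{section}.{key} must be an integer")
            if not isinstance(value, types):
                raise ConfigError(
                    f"{section}.{key}: expected {types}, got {type(value).__name__}"
                )
            if check is not None and not check(value):
                raise ConfigError(f"{section}.{key}: value {value!r} out of range")
            kwargs[dest] = value
    try:
        return PipelineConfig(**kwargs)
    except ConfigError:
        raise
    except (TypeError, ValueError) as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load and validate a YAML run configuration; None -> full defaults."""
    if path is None:
        return PipelineConfig()
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"no such config file: {path}")
    try:
        data = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"unparsable YAML in {path}: {exc}") from exc
    if data is not None and not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    return config_from_mapping(data)
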