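"""Feature Enhancement Recomposer: saliency-guided image modulation + residual.

Two branches act on the (3, H, W) image array I in [0, 1]:

* saliency-guided pathway - a point-wise convolution of the standardized
  prior S_hat, spatial layer normalization with learnable affine, and a
  sigmoid produce the modulation coefficient ``delta`` in (0, 1); the image
  is then amplified per pixel, ``F_mod[c] = I[c] * (1 + delta * S_hat)``,
  the single-channel gain broadcast over the 3 channels;
* residual compensation pathway - ``R = batchnorm(conv1x1(I))`` with the
  stored running statistics in inference mode (single-image inference makes
  batch statistics ill-defined), which at identity initialization reduces
  to R = I.

The enhanced output ``F_fer = F_mod + R`` stays in image space (3, H, W)
and is NOT clipped to [0, 1]; detectors consume real-valued arrays.  The
batchnorm denominator uses the raw running variance (validated strictly
positive) with no extra stabilizer, so identity initialization is exact at
the bit level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .errors import NumericalError, ShapeError
from .msa import spatial_standardize

__all__ = [
    "FerParams",
    "modulation_coefficient",
    "modulate",
    "residual_branch",
    "fer_forward",
]


def _vec3(value) -> np.ndarray:
    v = np.asarray(value, dtype=float).ravel()
    if v.size == 1:
        v = np.repeat(v, 3)
    if v.size != 3:
        raise ValueError("per-channel parameter must have 1 or 3 entries")
    return v


@dataclass
class FerParams:
    """Recomposer weights; a deterministic function of ``seed`` at init."""

    w_delta: float = 1.0
    b_delta: float = 0.0
    ln_scale: float = 1.0
    ln_shift: float = 0.0
    w_res: np.ndarray = field(default_factory=lambda: np.ones(3))
    b_res: np.ndarray = field(default_factory=lambda: np.zeros(3))
    bn_mean: np.ndarray = field(default_factory=lambda: np.zeros(3))
    bn_var: np.ndarray = field(default_factory=lambda: np.ones(3))
    bn_gamma: np.ndarray = field(default_factory=lambda: np.ones(3))
    bn_beta: np.ndarray = field(default_factory=lambda: np.zeros(3))
    epsilon: float = 1e-5
    seed: int | None = None

    def __post_init__(self):
        for name in ("w_res", "b_res", "bn_mean", "bn_var", "bn_gamma", "bn_beta"):
            setattr(self, name, _vec3(getattr(self, name)))
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")

    @classmethod
    def identity(cls, epsilon: float = 1e-5) -> "FerParams":
        return cls(epsilon=epsilon)

    @classmethod
    def gaussian(cls, seed: int, scale: float = 0.1, epsilon: float = 1e-5) -> "FerParams":
        rng = np.random.default_rng(seed)
        return cls(
            w_delta=float(1.0 + rng.normal(0.0, scale)),
            b_delta=float(rng.normal(0.0, scale)),
            ln_scale=float(1.0 + rng.normal(0.0, scale)),
            ln_shift=float(rng.normal(0.0, scale)),
            w_res=1.0 + rng.normal(0.0, scale, 3),
            b_res=rng.normal(0.0, scale, 3),
            epsilon=epsilon,
            seed=seed,
        )

    def check(self):
        vals = np.concatenate(
            [
                [self.w_delta, self.b_delta, self.ln_scale, self.ln_shift],
                self.w_res, self.b_res, self.bn_mean, self.bn_var,
                self.bn_gamma, self.bn_beta,
            ]
        )
        if not np.isfinite(vals).all():
            raise NumericalError("non-finite recomposer weights")
        if (self.bn_var <= 0).any():
            raise NumericalError("batchnorm running variance must be > 0")

    def state_dict(self) -> dict:
        return {
            "w_delta": np.array(self.w_delta),
            "b_delta": np.array(self.b_delta),
            "ln_scale": np.array(self.ln_scale),
            "ln_shift": np.array(self.ln_shift),
            "w_res": self.w_res.copy(),
            "b_res": self.b_res.copy(),
            "bn_mean": self.bn_mean.copy(),
            "bn_var": self.bn_var.copy(),
            "bn_gamma": self.bn_gamma.copy(),
            "bn_beta": self.bn_beta.copy(),
            "epsilon": np.array(self.epsilon),
        }


def modulation_coefficient(S_hat: np.ndarray, params: FerParams) -> np.ndarray:
    """``delta = sigmoid(g * standardize(w * S_hat + b) + h)``; entries in (0, 1).

    A constant prior standardizes to zeros, so delta collapses to
    sigmoid(h) (0.5 at identity initialization).
    """
    params.check()
    pre = params.w_delta * np.asarray(S_hat, dtype=float) + params.b_delta
    z = spatial_standardize(pre, params.epsilon)
    return expit(params.ln_scale * z + params.ln_shift)


def modulate(I: np.ndarray, delta: np.ndarray, S_hat: np.ndarray) -> np.ndarray:
    """Per-pixel gain ``F_mod[c] = I[c] * (1 + delta * S_hat)`` over 3 channels."""
    I = np.asarray(I, dtype=float)
    delta = np.asarray(delta, dtype=float)
    S_hat = np.asarray(S_hat, dtype=float)
    if I.ndim != 3 or I.shape[0] != 3:
        raise ShapeError(f"expected (3, H, W) image array, got {I.shape}")
    if delta.shape != I.shape[1:] or S_hat.shape != I.shape[1:]:
        raise ShapeError(
            f"spatial shapes disagree: image {I.shape[1:]}, "
            f"delta {delta.shape}, S_hat {S_hat.shape}"
        )
    return I * (1.0 + delta * S_hat)[None, :, :]


def residual_branch(I: np.ndarray, params: FerParams) -> np.ndarray:
    """``R = batchnorm(conv1x1(I))`` with running statistics, inference mode."""
    params.check()
    I = np.asarray(I, dtype=float)
    if I.ndim != 3 or I.shape[0] != 3:
        raise ShapeError(f"expected (3, H, W) image array, got {I.shape}")
    y = params.w_res[:, None, None] * I + params.b_res[:, None, None]
    scale = params.bn_gamma / np.sqrt(params.bn_var)
    return scale[:, None, None] * (y - params.bn_mean[:, None, None]) + params.bn_beta[:, None, None]


def fer_forward(
    I: np.ndarray,
    S_hat: np.ndarray,
    params: FerParams,
    residual: bool = True,
) -> np.ndarray:
    """Enhanced array ``F_fer = F_mod + R`` (or F_mod alone with residual off)."""
    delta = modulation_coefficient(S_hat, params)
    f_mod = modulate(I, delta, S_hat)
    if not residual:
        return f_mod
    return f_mod + residual_branch(I, params)
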