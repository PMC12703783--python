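"""Mask-Saliency Adapter: binary mask -> refined, spatially standardized saliency.

Three cascaded maps are produced from the H x W mask M:

* ``S  = sigmoid(conv3x3(M) + b)`` - the initial saliency response;
* ``S' = ReLU(g * standardize(conv1x1(S)) + h)`` - the refined, non-negative
  map (a point-wise convolution, spatial layer normalization with learnable
  affine (g, h), and a ReLU);
* ``S_hat = standardize(S')`` - the final zero-mean / unit-variance prior,
  where ``standardize(x) = (x - mu) / sqrt(var + eps)`` uses the spatial
  mean and population variance over all H*W entries.

All maps are single-channel.  Parameters default to an identity-like
initialization (center tap 1, zero biases, unit affine) so the untrained
module is analytically predictable; a seeded Gaussian initialization is
available for training scenarios.  Convolutions use zero padding and
preserve shape.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.special import expit

from .errors import NumericalError
from .spgm import BinaryMask

__all__ = [
    "MsaParams",
    "SaliencyTriple",
    "spatial_standardize",
    "saliency_response",
    "refine_saliency",
    "msa_forward",
]


@dataclass
class MsaParams:
    """Weights of the adapter; a deterministic function of ``seed`` at init."""

    c3_kernel: np.ndarray = field(
        default_factory=lambda: np.pad([[1.0]], 1)  # center tap 1
    )
    c3_bias: float = 0.0
    c1_weight: float = 1.0
    c1_bias: float = 0.0
    affine_scale: float = 1.0
    affine_shift: float = 0.0
    epsilon: float = 1e-5
    seed: int | None = None

    def __post_init__(self):
        self.c3_kernel = np.asarray(self.c3_kernel, dtype=float)
        if self.c3_kernel.shape != (3, 3):
            raise ValueError("c3_kernel must be 3x3")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")

    @classmethod
    def identity(cls, epsilon: float = 1e-5) -> "MsaParams":
        """Center tap 1, all biases 0, unit affine: S = sigmoid(M)."""
        k = np.zeros((3, 3))
        k[1, 1] = 1.0
        return cls(c3_kernel=k, epsilon=epsilon)

    @classmethod
    def gaussian(cls, seed: int, scale: float = 0.1, epsilon: float = 1e-5) -> "MsaParams":
        rng = np.random.default_rng(seed)
        return cls(
            c3_kernel=rng.normal(0.0, scale, (3, 3)),
            c3_bias=float(rng.normal(0.0, scale)),
            c1_weight=float(1.0 + rng.normal(0.0, scale)),
            c1_bias=float(rng.normal(0.0, scale)),
            affine_scale=float(1.0 + rng.normal(0.0, scale)),
            affine_shift=float(rng.normal(0.0, scale)),
            epsilon=epsilon,
            seed=seed,
        )

    def check_finite(self):
        vals = np.concatenate(
            [
                self.c3_kernel.ravel(),
                [self.c3_bias, self.c1_weight, self.c1_bias,
                 self.affine_scale, self.affine_shift],
            ]
        )
        if not np.isfinite(vals).all():
            raise NumericalError("non-finite adapter weights")

    def state_dict(self) -> dict:
        """Flat key -> array archive for reproducibility."""
        return {
            "c3_kernel": self.c3_kernel.copy(),
            "c3_bias": np.array(self.c3_bias),
            "c1_weight": np.array(self.c1_weight),
            "c1_bias": np.array(self.c1_bias),
            "affine_scale": np.array(self.affine_scale),
            "affine_shift": np.array(self.affine_shift),
            "epsilon": np.array(self.epsilon),
        }


@dataclass(frozen=True)
class SaliencyTriple:
    """The cascade (S, S', S_hat) of the adapter."""

    S: np.ndarray
    S_prime: np.ndarray
    S_hat: np.ndarray


def spatial_standardize(x: np.ndarray, epsilon: float = 1e-5) -> np.ndarray:
    """Zero-mean / unit-variance standardization over all spatial entries.

    ``(x - mu) / sqrt(var + eps)`` with population variance.  A constant
    input standardizes to exact zeros (the numerator vanishes identically).
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    x = np.asarray(x, dtype=float)
    if x.size and x.max() == x.min():
        return np.zeros_like(x)  # exact zeros: pairwise-summation residue otherwise
    mu = x.mean()
    var = x.var()
    return (x - mu) / np.sqrt(var + epsilon)


def saliency_response(mask: BinaryMask, params: MsaParams) -> np.ndarray:
    """Initial response ``S = sigmoid(conv3x3(M) + b)``; entries in (0, 1)."""
    params.check_finite()
    m = mask.m.astype(float)
    # cross-correlation semantics (conv-layer convention), zero padding
    pre = ndimage.correlate(m, params.c3_kernel, mode="constant", cval=0.0)
    return expit(pre + params.c3_bias)


def refine_saliency(S: np.ndarray, params: MsaParams) -> np.ndarray:
    """Refined map ``S' = ReLU(g * standardize(w*S + b) + h)``; entries >= 0."""
    params.check_finite()
    pre = params.c1_weight * np.asarray(S, dtype=float) + params.c1_bias
    z = spatial_standardize(pre, params.epsilon)
    return np.maximum(params.affine_scale * z + params.affine_shift, 0.0)


def msa_forward(mask: BinaryMask, params: MsaParams) -> SaliencyTriple:
    """Full adapter cascade; deterministic given (mask, params)."""
    S = saliency_response(mask, params)
    S_prime = refine_saliency(S, params)
    S_hat = spatial_standardize(S_prime, params.epsilon)
    return SaliencyTriple(S=S, S_prime=S_prime, S_hat=S_hat)
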