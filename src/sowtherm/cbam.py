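"""Forward pass of the Convolutional Block Attention Module (CBAM).

CBAM refines a C×H×W feature map F in two sequential stages.  The channel
attention module (CAM) pools F globally over space (average and max per
channel), pushes both pooled vectors through a shared two-layer perceptron
with a reduction bottleneck, and combines them through the sigmoid σ.  The
spatial attention module (SAM) pools the channel-refined map F′ over
channels, stacks the average and max maps, and convolves them with a single
7×7 kernel followed by σ.

Two CAM combination variants are provided:

* ``as_printed`` — M_C(F) = σ(MLP(AvgPool F)) + σ(MLP(MaxPool F)),
  a sum of two sigmoids with range (0, 2);
* ``standard``   — M_C(F) = σ(MLP(AvgPool F) + MLP(MaxPool F)),
  the canonical CBAM form with range (0, 1).

The source formulation prints the first; the canonical literature uses the
second.  Both are exact forward math on supplied weights — no training,
no framework graph.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import correlate2d

from .errors import ConfigurationError, ShapeMismatchError

__all__ = [
    "CamWeights",
    "SamKernel",
    "AttentionOutputs",
    "channel_attention",
    "spatial_attention",
    "apply_cbam",
]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class CamWeights:
    """Shared-MLP weights for channel attention.

    ``w1`` maps C → C/r (the reduction bottleneck), ``w2`` maps C/r → C.
    The hidden activation is ReLU.  Biases default to zero.
    """

    w1: np.ndarray
    w2: np.ndarray
    b1: np.ndarray | None = None
    b2: np.ndarray | None = None

    def __post_init__(self):
        w1 = np.asarray(self.w1, dtype=float)
        w2 = np.asarray(self.w2, dtype=float)
        if w1.ndim != 2 or w2.ndim != 2:
            raise ConfigurationError("CAM weights w1, w2 must be 2-D matrices")
        hidden, c = w1.shape
        if w2.shape != (c, hidden):
            raise ConfigurationError(
                f"w2 shape {w2.shape} inconsistent with w1 shape {w1.shape}"
            )
        if c % hidden != 0:
            raise ConfigurationError(
                f"reduction ratio must divide C: C={c}, hidden={hidden}"
            )
        b1 = np.zeros(hidden) if self.b1 is None else np.asarray(self.b1, float)
        b2 = np.zeros(c) if self.b2 is None else np.asarray(self.b2, float)
        if b1.shape != (hidden,) or b2.shape != (c,):
            raise ConfigurationError("CAM bias shapes inconsistent with weights")
        object.__setattr__(self, "w1", w1)
        object.__setattr__(self, "w2", w2)
        object.__setattr__(self, "b1", b1)
        object.__setattr__(self, "b2", b2)

    @property
    def channels(self) -> int:
        return self.w1.shape[1]

    @property
    def reduction_ratio(self) -> int:
        return self.w1.shape[1] // self.w1.shape[0]

    def mlp(self, v: np.ndarray) -> np.ndarray:
        """Shared MLP: W2 · ReLU(W1·v + b1) + b2."""
        hidden = np.maximum(0.0, self.w1 @ v + self.b1)
        return self.w2 @ hidden + self.b2


@dataclass(frozen=True)
class SamKernel:
    """7×7 convolution kernel over the 2 pooled maps (avg, max), plus bias."""

    kernel: np.ndarray
    bias: float = 0.0

    def __post_init__(self):
        k = np.asarray(self.kernel, dtype=float)
        if k.shape != (7, 7, 2):
            raise ConfigurationError(
                f"SAM kernel must have shape (7, 7, 2), got {k.shape}"
            )
        object.__setattr__(self, "kernel", k)


@dataclass(frozen=True)
class AttentionOutputs:
    """mc: per-channel weights; ms: 1×H×W spatial map; refined: output map."""

    mc: np.ndarray
    ms: np.ndarray
    refined: np.ndarray


def _check_feature_map(f) -> np.ndarray:
    f = np.asarray(f, dtype=float)
    if f.ndim != 3 or min(f.shape) < 1:
        raise ShapeMismatchError(
            f"feature map must be C×H×W with all dims >= 1, got {f.shape}"
        )
    if not np.all(np.isfinite(f)):
        raise ShapeMismatchError("feature map contains non-finite values")
    return f


def channel_attention(f, weights: CamWeights,
                      variant: str = "as_printed") -> np.ndarray:
    """Channel attention vector mc (length C) from global avg/max pooling."""
    f = _check_feature_map(f)
    if weights.channels != f.shape[0]:
        raise ShapeMismatchError(
            f"CAM weights expect C={weights.channels}, feature map has C={f.shape[0]}"
        )
    avg = f.mean(axis=(1, 2))
    mx = f.max(axis=(1, 2))
    if variant == "as_printed":
        return _sigmoid(weights.mlp(avg)) + _sigmoid(weights.mlp(mx))
    if variant == "standard":
        return _sigmoid(weights.mlp(avg) + weights.mlp(mx))
    raise ConfigurationError(
        f"variant must be 'as_printed' or 'standard', got {variant!r}"
    )


def spatial_attention(fp, kernel: SamKernel) -> np.ndarray:
    """Spatial attention map ms (1×H×W), every value strictly in (0, 1).

    Channel-wise average and max maps are stacked into a 2×H×W tensor and
    cross-correlated (the deep-learning "convolution") with the 7×7 kernel
    under zero padding 3, stride 1, then passed through the sigmoid.
    """
    fp = _check_feature_map(fp)
    avg = fp.mean(axis=0)
    mx = fp.max(axis=0)
    pre = (correlate2d(avg, kernel.kernel[:, :, 0], mode="same", boundary="fill")
           + correlate2d(mx, kernel.kernel[:, :, 1], mode="same", boundary="fill")
           + kernel.bias)
    return _sigmoid(pre)[np.newaxis, :, :]


def apply_cbam(f, weights: CamWeights, kernel: SamKernel,
               variant: str = "as_printed") -> AttentionOutputs:
    """Full CBAM refinement: F′ = mc ⊙ F, output = ms ⊙ F′ (shape preserved)."""
    f = _check_feature_map(f)
    mc = channel_attention(f, weights, variant=variant)
    fp = mc[:, np.newaxis, np.newaxis] * f
    ms = spatial_attention(fp, kernel)
    refined = ms * fp
    return AttentionOutputs(mc=mc, ms=ms, refined=refined)
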