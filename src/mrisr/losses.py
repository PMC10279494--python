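"""Training losses: pixel, perceptual, edge-aware, and their composite.

The composite objective is

    L = L1(SR, HR) + alpha * L_per(SR, HR) + beta * L_edge(SR, HR)

with defaults alpha = 0.3 and beta = 0.1.  The pixel term is the mean
absolute difference; the perceptual term compares deep features of the two
images under a fixed (never trained here) extractor; the edge term compares
Laplacian responses, penalizing loss of sharp structure that a pure pixel
loss tolerates.

The feature extractor is an injected handle: any deterministic callable
mapping an image batch to a feature map (or a list of feature maps) works.
:class:`RandomConvExtractor` provides the self-contained default — a fixed,
seeded stack of random convolutions with rectifier nonlinearities, a
standard training-free stand-in for learned perceptual features.

All reductions are means over every entry (batch, channels, pixels), so the
weights alpha/beta are scale-free in image size and batch size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, Tuple, Union

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = [
    "LossWeights",
    "IdentityExtractor",
    "RandomConvExtractor",
    "laplacian_response",
    "pixel_loss",
    "perceptual_loss",
    "edge_loss",
    "composite_loss",
    "LAPLACIAN_4",
    "LAPLACIAN_8",
]

ArrayLike = Union[np.ndarray, Tensor]

#: 4-neighbor Laplacian; annihilates constant images under replicate padding.
LAPLACIAN_4 = np.array([[0.0, 1.0, 0.0], [1.0, -4.0, 1.0], [0.0, 1.0, 0.0]])
#: 8-neighbor variant.
LAPLACIAN_8 = np.array([[1.0, 1.0, 1.0], [1.0, -8.0, 1.0], [1.0, 1.0, 1.0]])


def _as_nchw(x: ArrayLike) -> ArrayLike:
    """Accept (H, W), (B, H, W) or (B, C, H, W) and return (B, C, H, W)."""
    nd = ad.as_array(x).ndim
    if nd == 2:
        return x.reshape(1, 1, *ad.as_array(x).shape)
    if nd == 3:
        b, h, w = ad.as_array(x).shape
        return x.reshape(b, 1, h, w)
    if nd == 4:
        return x
    raise ValueError(f"expected 2-4 dims, got {nd}")


def _check_same_shape(a: ArrayLike, b: ArrayLike) -> None:
    if ad.as_array(a).shape != ad.as_array(b).shape:
        raise ValueError(
            f"shape mismatch: {ad.as_array(a).shape} vs {ad.as_array(b).shape}"
        )


class IdentityExtractor:
    """Feature extractor returning the image itself (perceptual == pixel L1)."""

    def __call__(self, x: ArrayLike) -> ArrayLike:
        return x


class RandomConvExtractor:
    """Fixed random-convolution feature stack.

    ``depth`` 3x3 convolution layers (zero padding 1, so feature maps keep the
    image size) with ``channels`` outputs each, rectified between layers.
    Weights are drawn once from a seeded Gaussian scaled by 1/sqrt(fan-in)
    and never change, so the extractor is deterministic: same input, same
    features.  Gradients flow through it to the image being optimized.
    """

    def __init__(self, channels: int = 8, depth: int = 2, seed: int = 0):
        rng = np.random.default_rng(seed)
        self.weights = []
        cin = 1
        for _ in range(depth):
            fan_in = cin * 9
            self.weights.append(rng.normal(0.0, 1.0 / np.sqrt(fan_in), (channels, cin, 3, 3)))
            cin = channels

    def __call__(self, x: ArrayLike) -> ArrayLike:
        f = _as_nchw(x)
        for i, w in enumerate(self.weights):
            f = ad.conv2d(f, w, padding=1)
            if i < len(self.weights) - 1:
                f = ad.relu(f)
        return f


@dataclass
class LossWeights:
    """Composite-loss hyper-parameters (defaults: alpha=0.3, beta=0.1)."""

    alpha: float = 0.3
    beta: float = 0.1
    pixel_kind: str = "l1"
    extractor: Callable[[ArrayLike], ArrayLike] = field(default_factory=RandomConvExtractor)

    def validate(self) -> None:
        if not (np.isfinite(self.alpha) and self.alpha >= 0):
            raise ValueError(f"alpha must be finite and >= 0, got {self.alpha}")
        if not (np.isfinite(self.beta) and self.beta >= 0):
            raise ValueError(f"beta must be finite and >= 0, got {self.beta}")
        if self.pixel_kind.lower() not in ("l1", "l2"):
            raise ValueError(f"pixel_kind must be 'l1' or 'l2', got {self.pixel_kind!r}")


def pixel_loss(sr: ArrayLike, hr: ArrayLike, kind: str = "l1") -> ArrayLike:
    """Mean absolute (L1) or mean squared (L2) pixel difference."""
    _check_same_shape(sr, hr)
    kind = kind.lower()
    diff = sr - hr
    if kind == "l1":
        return ad.mean(ad.absolute(diff))
    if kind == "l2":
        return ad.mean(diff ** 2)
    raise ValueError(f"unknown pixel loss kind {kind!r}")


def perceptual_loss(sr: ArrayLike, hr: ArrayLike, extractor=None) -> ArrayLike:
    """Mean absolute difference between extractor features of sr and hr.

    If the extractor returns several feature maps their per-map means are
    averaged.
    """
    _check_same_shape(sr, hr)
    if extractor is None:
        extractor = IdentityExtractor()
    f_sr, f_hr = extractor(sr), extractor(hr)
    if not isinstance(f_sr, (list, tuple)):
        f_sr, f_hr = [f_sr], [f_hr]
    terms = [ad.mean(ad.absolute(a - b)) for a, b in zip(f_sr, f_hr)]
    total = terms[0]
    for t in terms[1:]:
        total = total + t
    return total / len(terms) if len(terms) > 1 else total


def laplacian_response(img: ArrayLike, kernel: np.ndarray = LAPLACIAN_4) -> ArrayLike:
    """Laplacian edge response with replicate padding (constants map to 0)."""
    x = _as_nchw(img)
    padded = ad.pad2d(x, 1, mode="edge")
    return ad.conv2d(padded, kernel[None, None], padding=0)


def edge_loss(sr: ArrayLike, hr: ArrayLike, eight_neighbor: bool = False) -> ArrayLike:
    """Mean absolute difference between Laplacian responses of sr and hr."""
    _check_same_shape(sr, hr)
    k = LAPLACIAN_8 if eight_neighbor else LAPLACIAN_4
    return ad.mean(ad.absolute(laplacian_response(sr, k) - laplacian_response(hr, k)))


def composite_loss(
    sr: ArrayLike, hr: ArrayLike, weights: LossWeights | None = None
) -> Tuple[ArrayLike, Dict[str, float]]:
    """Composite objective ``pixel + alpha * perceptual + beta * edge``.

    Returns the total (a Tensor when ``sr`` is a Tensor, so it can be
    backpropagated) and a dict of the three component values as floats.
    """
    if weights is None:
        weights = LossWeights()
    weights.validate()
    l_pix = pixel_loss(sr, hr, weights.pixel_kind)
    l_per = perceptual_loss(sr, hr, weights.extractor)
    l_edge = edge_loss(sr, hr)
    total = l_pix + weights.alpha * l_per + weights.beta * l_edge
    parts = {
        "pixel": float(ad.as_array(l_pix)),
        "perceptual": float(ad.as_array(l_per)),
        "edge": float(ad.as_array(l_edge)),
        "total": float(ad.as_array(total)),
    }
    return total, parts
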