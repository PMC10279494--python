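"""Parameter-free 3-D attention (SimAM) and the chunking fusion block (PCFB).

SimAM scores every neuron ``t`` of a channel map by an energy ``e_t*`` that
measures how much the neuron stands out from its channel's spatial
statistics: with spatial mean ``u`` and variance ``s2`` of the channel,

    1 / e_t*  =  (t - u)^2 / (4 * (s2 + lambda))  +  1/2 ,

so distinctive neurons (large squared deviation) get large inverse energy.
The attention map is ``sigmoid(1/e) * x``.  No quantity here is learned —
the whole operator is parameter-free.

The chunking fusion block splits the channel axis into ``n`` contiguous
chunks, applies SimAM to each chunk independently (each chunk therefore uses
its own channel statistics), and concatenates the results back in order.
With ``n = 1`` it degenerates to plain SimAM.

All operators accept a plain ``numpy.ndarray`` or an autodiff
:class:`~mrisr.autodiff.Tensor` of shape ``(batch, channel, height, width)``
and preserve that shape.
"""

from __future__ import annotations

from typing import List, Union

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor

__all__ = ["inverse_energy", "simam", "chunk", "merge", "pcfb", "DEFAULT_LAMBDA"]

#: Regularizer in the energy denominator; keeps attention finite on
#: low-variance channels.
DEFAULT_LAMBDA = 1e-4

ArrayLike = Union[np.ndarray, Tensor]


def _check_feature_map(x: ArrayLike) -> None:
    data = ad.as_array(x)
    if data.ndim != 4:
        raise ValueError(
            f"feature map must be rank-4 (batch, channel, height, width); got shape {data.shape}"
        )
    if not np.all(np.isfinite(data)):
        raise ValueError("feature map contains non-finite entries")


def inverse_energy(x: ArrayLike, lam: float = DEFAULT_LAMBDA, ddof: int = 1) -> ArrayLike:
    """Per-neuron inverse energy ``1/e_t*`` of the SimAM energy function.

    Statistics (spatial mean ``u`` and variance ``s2``) are computed per
    sample and per channel over the spatial positions only.  ``ddof``
    selects the variance convention: 1 (default) divides the squared
    deviations by ``H*W - 1``, 0 divides by ``H*W``.

    The inverse energy is computed directly as
    ``d / (4*(s2 + lam)) + 1/2`` with ``d = (t - u)^2``, never by forming
    ``e`` and inverting, so tiny ``d`` cannot overflow.  When ``lam == 0``
    and a channel map is constant, ``d == 0`` everywhere on that channel and
    the identity ``d = 0  =>  1/e = 1/2`` is applied instead of dividing
    zero by zero.

    Every returned entry is >= 0.5 (``d >= 0``).
    """
    if lam < 0:
        raise ValueError(f"lambda must be non-negative, got {lam}")
    if ddof not in (0, 1):
        raise ValueError("ddof must be 0 or 1")
    _check_feature_map(x)
    h, w = ad.as_array(x).shape[2:]
    n_spatial = h * w
    if n_spatial - ddof < 1:
        raise ValueError(
            f"channel maps need at least {ddof + 1} pixels for the ddof={ddof} variance"
        )
    u = ad.mean(x, axis=(2, 3), keepdims=True)
    d = (x - u) ** 2
    s2 = d.sum(axis=(2, 3), keepdims=True) / (n_spatial - ddof)
    denom = 4.0 * (s2 + lam)
    # lam == 0 on a constant channel: d == 0 there, so the quotient is 0 by
    # the constant-map identity; substitute a unit denominator to avoid 0/0.
    denom_data = ad.as_array(denom)
    if np.any(denom_data == 0.0):
        denom = ad.where(denom_data == 0.0, 1.0, denom)
    return d / denom + 0.5


def simam(x: ArrayLike, lam: float = DEFAULT_LAMBDA, ddof: int = 1) -> ArrayLike:
    """SimAM attention: ``sigmoid(1/e) * x`` elementwise, shape-preserving."""
    return ad.sigmoid(inverse_energy(x, lam=lam, ddof=ddof)) * x


def chunk(x: ArrayLike, n: int) -> List[ArrayLike]:
    """Split the channel axis into ``n`` contiguous equal chunks.

    Chunk ``i`` holds channels ``[i*C/n, (i+1)*C/n)`` of the source, so
    concatenating the chunks in order reproduces the source exactly.
    """
    if not isinstance(n, (int, np.integer)) or n < 1:
        raise ValueError(f"chunk count n must be a positive integer, got {n!r}")
    _check_feature_map(x)
    c = ad.as_array(x).shape[1]
    if c % n != 0:
        raise ValueError(f"channel count {c} is not divisible by n={n}")
    step = c // n
    return [x[:, i * step : (i + 1) * step] for i in range(n)]


def merge(chunks: List[ArrayLike]) -> ArrayLike:
    """Concatenate chunks along the channel axis (inverse of :func:`chunk`)."""
    if len(chunks) == 0:
        raise ValueError("cannot merge an empty chunk list")
    shapes = [ad.as_array(c).shape for c in chunks]
    for s in shapes:
        if len(s) != 4:
            raise ValueError(f"chunks must be rank-4; got shape {s}")
        if (s[0], s[2], s[3]) != (shapes[0][0], shapes[0][2], shapes[0][3]):
            raise ValueError(f"chunk batch/spatial shapes differ: {shapes}")
    if len(chunks) == 1:
        return chunks[0]
    return ad.concatenate(chunks, axis=1)


def pcfb(x: ArrayLike, n: int, lam: float = DEFAULT_LAMBDA, ddof: int = 1) -> ArrayLike:
    """Parameter-free chunking fusion block.

    Splits ``x`` into ``n`` channel chunks, attends to each with SimAM, and
    fuses them back to the original shape.  The operator holds zero learnable
    parameters.
    """
    return merge([simam(xi, lam=lam, ddof=ddof) for xi in chunk(x, n)])
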