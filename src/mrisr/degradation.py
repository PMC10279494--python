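"""HR -> LR degradation simulators and the bicubic no-training baseline.

Two degradations are provided:

* **BD** (bicubic downsampling): separable resampling with the Keys cubic
  kernel (a = -0.5).  On downsampling the kernel is stretched by the scale
  factor (antialiasing), matching the convention of the classical
  ``imresize`` used to build super-resolution benchmarks.
* **TD** (k-space truncation): the image is taken to the 2-D spatial
  frequency domain, the central (H/s) x (W/s) block of low frequencies is
  retained and inverted on the small grid — the physical model of acquiring
  fewer phase/frequency encodes in MR.

Both require the scale to divide the image dimensions exactly (study volumes
are trimmed so that several scale factors fit), and both keep intensities in
[0, 1].  ``bicubic_upsample`` is the interpolation baseline every trained
model is compared against.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "DegradationSpec",
    "cubic_kernel",
    "resize_bicubic",
    "bicubic_downsample",
    "bicubic_upsample",
    "kspace_truncate",
]


@dataclass(frozen=True)
class DegradationSpec:
    """A degradation recipe: mode 'bd' or 'td' and an integer scale >= 2."""

    mode: str
    scale: int

    def __post_init__(self):
        if self.mode.lower() not in ("bd", "td"):
            raise ValueError(f"mode must be 'bd' or 'td', got {self.mode!r}")
        if not isinstance(self.scale, (int, np.integer)) or self.scale < 2:
            raise ValueError(f"scale must be an integer >= 2, got {self.scale!r}")
        object.__setattr__(self, "mode", self.mode.lower())

    def apply(self, hr: np.ndarray) -> np.ndarray:
        if self.mode == "bd":
            return bicubic_downsample(hr, self.scale)
        return kspace_truncate(hr, self.scale)


def cubic_kernel(x: np.ndarray) -> np.ndarray:
    """Keys bicubic convolution kernel with a = -0.5, support |x| < 2."""
    ax = np.abs(np.asarray(x, dtype=np.float64))
    out = np.zeros_like(ax)
    near = ax <= 1
    far = (ax > 1) & (ax < 2)
    out[near] = (1.5 * ax[near] - 2.5) * ax[near] ** 2 + 1.0
    out[far] = ((-0.5 * ax[far] + 2.5) * ax[far] - 4.0) * ax[far] + 2.0
    return out


def _resample_weights(in_len: int, out_len: int):
    """Per-output-pixel source indices and normalized cubic weights.

    Output pixel ``i`` is centered at input coordinate
    ``(i + 0.5) / scale - 0.5``.  When shrinking, the kernel is dilated by
    1/scale so it spans the footprint of the output pixel (antialiasing).
    Out-of-range taps are clamped to the border (replicate).
    """
    scale = out_len / in_len
    coords = (np.arange(out_len) + 0.5) / scale - 0.5
    if scale < 1.0:
        width = 4.0 / scale
        kern = lambda t: scale * cubic_kernel(scale * t)
    else:
        width = 4.0
        kern = cubic_kernel
    left = np.floor(coords - width / 2).astype(int)
    n_taps = int(np.ceil(width)) + 2
    indices = left[:, None] + np.arange(n_taps)[None, :]
    weights = kern(coords[:, None] - indices)
    weights = weights / weights.sum(axis=1, keepdims=True)
    indices = np.clip(indices, 0, in_len - 1)
    return indices, weights


def resize_bicubic(img: np.ndarray, out_h: int, out_w: int) -> np.ndarray:
    """Separable cubic resampling of a 2-D image to (out_h, out_w)."""
    img = np.asarray(img, dtype=np.float64)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    idx, wts = _resample_weights(img.shape[0], out_h)
    img = np.einsum("op,opw->ow", wts, img[idx, :])
    idx, wts = _resample_weights(img.shape[1], out_w)
    img = np.einsum("op,hop->ho", wts, img[:, idx])
    return img


def _check_divisible(img: np.ndarray, s: int) -> None:
    if not isinstance(s, (int, np.integer)) or s < 2:
        raise ValueError(f"scale must be an integer >= 2, got {s!r}")
    h, w = img.shape
    if h % s or w % s:
        raise ValueError(f"scale {s} does not divide image dimensions {img.shape}")


def bicubic_downsample(hr: np.ndarray, s: int) -> np.ndarray:
    """Antialiased cubic downsampling by an integer factor; output in [0,1]."""
    hr = np.asarray(hr, dtype=np.float64)
    if hr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {hr.shape}")
    _check_divisible(hr, s)
    out = resize_bicubic(hr, hr.shape[0] // s, hr.shape[1] // s)
    return np.clip(out, 0.0, 1.0)


def bicubic_upsample(lr: np.ndarray, s: int) -> np.ndarray:
    """Cubic interpolation to (H*s, W*s); the no-training baseline."""
    lr = np.asarray(lr, dtype=np.float64)
    if lr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {lr.shape}")
    if not isinstance(s, (int, np.integer)) or s < 1:
        raise ValueError(f"scale must be a positive integer, got {s!r}")
    out = resize_bicubic(lr, lr.shape[0] * s, lr.shape[1] * s)
    return np.clip(out, 0.0, 1.0)


def kspace_truncate(hr: np.ndarray, s: int, clip: bool = True) -> np.ndarray:
    """Low-frequency k-space truncation to a (H/s, W/s) grid.

    The centered DFT of the image is cropped to its central (H/s) x (W/s)
    block, inverted on the small grid, scaled by 1/s^2 so the mean intensity
    (DC coefficient) is preserved, and the real part is taken.  With
    ``clip=True`` (default) the result is clamped to [0, 1]; ``clip=False``
    exposes the raw linear operator.
    """
    hr = np.asarray(hr, dtype=np.float64)
    if hr.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {hr.shape}")
    _check_divisible(hr, s)
    h, w = hr.shape
    h2, w2 = h // s, w // s
    if h2 < 2 or w2 < 2:
        raise ValueError(f"truncated grid {h2}x{w2} is too small")
    spectrum = np.fft.fftshift(np.fft.fft2(hr))
    r0 = h // 2 - h2 // 2
    c0 = w // 2 - w2 // 2
    block = spectrum[r0 : r0 + h2, c0 : c0 + w2]
    lr = np.fft.ifft2(np.fft.ifftshift(block)).real / (s * s)
    return np.clip(lr, 0.0, 1.0) if clip else lr
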