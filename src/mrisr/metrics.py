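"""Full-reference image quality metrics: RMSE, PSNR, SSIM.

Images are compared on the [0, 1] intensity scale.  RMSE is reported on
that scale directly; PSNR maps differences to the (2^n - 1) gray-level
scale of an n-bit image (n = 8 by default), so the two conventions are
consistent: PSNR = 20 * log10((2^n - 1)) - 20 * log10(RMSE).

SSIM is offered in two modes.  ``windowed`` (default) is the standard
implementation — local statistics under an 11x11 Gaussian window with
sigma = 1.5, averaged over the image.  ``global`` evaluates the SSIM
formula once on whole-image statistics, which admits closed-form checks
(e.g. two constant images).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Iterable, Sequence, Tuple

import numpy as np
from scipy.ndimage import correlate

__all__ = ["MetricsRecord", "rmse", "psnr", "ssim", "evaluate_set", "write_report"]


def _check_pair(hr: np.ndarray, sr: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    hr = np.asarray(hr, dtype=np.float64)
    sr = np.asarray(sr, dtype=np.float64)
    if hr.shape != sr.shape:
        raise ValueError(f"shape mismatch: {hr.shape} vs {sr.shape}")
    return hr, sr


def rmse(hr: np.ndarray, sr: np.ndarray) -> float:
    """Root-mean-square error over all pixels, on the [0,1] scale."""
    hr, sr = _check_pair(hr, sr)
    return float(np.sqrt(np.mean((hr - sr) ** 2)))


def psnr(hr: np.ndarray, sr: np.ndarray, bits: int = 8) -> float:
    """Peak signal-to-noise ratio in dB for an n-bit dynamic range.

    Identical images have zero MSE; the documented sentinel ``math.inf`` is
    returned rather than raising.
    """
    hr, sr = _check_pair(hr, sr)
    peak = float(2 ** bits - 1)
    mse = np.mean(((hr - sr) * peak) ** 2)
    if mse == 0.0:
        return math.inf
    return float(10.0 * np.log10(peak ** 2 / mse))


def _gaussian_window(size: int = 11, sigma: float = 1.5) -> np.ndarray:
    half = (size - 1) / 2
    coords = np.arange(size) - half
    g = np.exp(-(coords ** 2) / (2 * sigma ** 2))
    kernel = np.outer(g, g)
    return kernel / kernel.sum()


def ssim(
    hr: np.ndarray,
    sr: np.ndarray,
    data_range: float = 1.0,
    mode: str = "windowed",
    window_size: int = 11,
    sigma: float = 1.5,
) -> float:
    """Structural similarity index in [-1, 1]; 1 exactly for identical images.

    ``mode='windowed'``: Gaussian-weighted local statistics (the standard
    estimator); ``mode='global'``: one evaluation on whole-image moments.
    Stabilizers are c1 = (0.01 * L)^2, c2 = (0.03 * L)^2 with L the dynamic
    range.
    """
    hr, sr = _check_pair(hr, sr)
    c1 = (0.01 * data_range) ** 2
    c2 = (0.03 * data_range) ** 2
    if mode == "global":
        mu1, mu2 = hr.mean(), sr.mean()
        var1 = np.mean((hr - mu1) * (hr - mu1))
        var2 = np.mean((sr - mu2) * (sr - mu2))
        cov = np.mean((hr - mu1) * (sr - mu2))
        num = (2 * mu1 * mu2 + c1) * (2 * cov + c2)
        den = (mu1 ** 2 + mu2 ** 2 + c1) * (var1 + var2 + c2)
        return float(num / den)
    if mode != "windowed":
        raise ValueError(f"mode must be 'windowed' or 'global', got {mode!r}")
    if min(hr.shape) < window_size:
        raise ValueError(
            f"image {hr.shape} smaller than the {window_size}x{window_size} window"
        )
    win = _gaussian_window(window_size, sigma)
    mu1 = correlate(hr, win, mode="reflect")
    mu2 = correlate(sr, win, mode="reflect")
    mu1mu2 = mu1 * mu2
    var1 = correlate(hr * hr, win, mode="reflect") - mu1 * mu1
    var2 = correlate(sr * sr, win, mode="reflect") - mu2 * mu2
    cov = correlate(hr * sr, win, mode="reflect") - mu1mu2
    num = (2 * mu1mu2 + c1) * (2 * cov + c2)
    den = (mu1 ** 2 + mu2 ** 2 + c1) * (var1 + var2 + c2)
    return float(np.mean(num / den))


@dataclass
class MetricsRecord:
    """Averages of the evaluation triplet over a set of image pairs."""

    psnr: float
    ssim: float
    rmse: float
    n_images: int

    def __post_init__(self):
        if self.rmse < 0:
            raise ValueError("rmse must be non-negative")
        if self.ssim > 1.0 + 1e-12:
            raise ValueError("ssim cannot exceed 1")


def evaluate_set(
    pairs: Sequence[Tuple[np.ndarray, np.ndarray]],
    bits: int = 8,
    ssim_mode: str = "windowed",
) -> MetricsRecord:
    """Arithmetic means of PSNR/SSIM/RMSE over (hr, sr) pairs."""
    pairs = list(pairs)
    if not pairs:
        raise ValueError("evaluate_set requires at least one (hr, sr) pair")
    psnrs = [psnr(hr, sr, bits=bits) for hr, sr in pairs]
    ssims = [ssim(hr, sr, mode=ssim_mode) for hr, sr in pairs]
    rmses = [rmse(hr, sr) for hr, sr in pairs]
    return MetricsRecord(
        psnr=float(np.mean(psnrs)),
        ssim=float(np.mean(ssims)),
        rmse=float(np.mean(rmses)),
        n_images=len(pairs),
    )


def write_report(path, rows: Iterable[Tuple[str, float, float, float]]) -> MetricsRecord:
    """Write a per-image CSV report (id, psnr, ssim, rmse) plus a summary row."""
    rows = list(rows)
    if not rows:
        raise ValueError("report requires at least one row")
    summary = MetricsRecord(
        psnr=float(np.mean([r[1] for r in rows])),
        ssim=float(np.mean([r[2] for r in rows])),
        rmse=float(np.mean([r[3] for r in rows])),
        n_images=len(rows),
    )
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["id", "psnr", "ssim", "rmse"])
        for r in rows:
            writer.writerow([r[0], f"{r[1]:.6f}", f"{r[2]:.6f}", f"{r[3]:.6f}"])
        writer.writerow(["mean", f"{summary.psnr:.6f}", f"{summary.ssim:.6f}", f"{summary.rmse:.6f}"])
    return summary
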