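"""Quantitative evaluation: PSNR, SSIM, RMSE on [0, 1] images.

PSNR uses peak 1.0 on the normalized scale; identical images report a capped
99 dB sentinel instead of infinity.  SSIM is the standard local-window index
with the canonical constants (11×11 Gaussian window, sigma 1.5, K1 = 0.01,
K2 = 0.03, dynamic range 1.0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

from .exceptions import ValidationError

__all__ = ["MetricReport", "rmse", "psnr", "ssim", "report"]

PSNR_CAP = 99.0


def _check_pair(a: np.ndarray, b: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValidationError(f"image shape mismatch: {a.shape} vs {b.shape}")
    return a, b


@dataclass
class MetricReport:
    psnr: float
    ssim: float
    rmse: float

    def __str__(self) -> str:
        return f"PSNR={self.psnr:.4f} dB  SSIM={self.ssim:.4f}  RMSE={self.rmse:.4f}"


def rmse(a: np.ndarray, b: np.ndarray) -> float:
    """Root-mean-square error."""
    a, b = _check_pair(a, b)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def psnr(a: np.ndarray, b: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; 99 dB cap for identical images."""
    a, b = _check_pair(a, b)
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return PSNR_CAP
    return min(PSNR_CAP, 10.0 * np.log10(peak**2 / mse))


def ssim(a: np.ndarray, b: np.ndarray) -> float:
    """Mean structural similarity index (Gaussian window, Wang defaults)."""
    a, b = _check_pair(a, b)
    if min(a.shape) < 11:
        raise ValidationError("images smaller than the 11x11 SSIM window")
    return float(
        structural_similarity(
            a,
            b,
            data_range=1.0,
            gaussian_weights=True,
            sigma=1.5,
            use_sample_covariance=False,
            K1=0.01,
            K2=0.03,
        )
    )


def report(a: np.ndarray, b: np.ndarray) -> MetricReport:
    """All three metrics of an image pair."""
    return MetricReport(psnr=psnr(a, b), ssim=ssim(a, b), rmse=rmse(a, b))
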