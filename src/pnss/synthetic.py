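"""Synthetic piecewise-constant phantoms and Gaussian noise injection.

The phantoms emulate the geometry a CT denoiser must respect — overlapping
soft-tissue-like regions with distinct gray levels, an optional low-amplitude
sinusoidal texture band (a detail-preservation probe), and a few one-pixel
bright lines (a cheap stand-in for structured streak-like features).  Noise
is additive i.i.d. Gaussian in the image domain, parameterized on the
conventional 0-255 scale; this is a deliberate proxy for dose reduction,
which in real acquisitions enters the sinogram before reconstruction and
produces spatially correlated streaks that a Gaussian field does not emulate.

Everything is reproducible from (spec, sigma, seed); no stored fixtures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError

__all__ = ["PhantomSpec", "make_phantom", "add_gaussian_noise"]


@dataclass
class PhantomSpec:
    """Parameters of a reproducible piecewise-constant phantom."""

    size: int = 128
    n_ellipses: int = 6
    include_texture: bool = True
    include_streak_proxy: bool = True
    seed: int = 7
    background: float = 0.15

    def __post_init__(self) -> None:
        if self.size < 32:
            raise ValidationError("phantom size must be >= 32")
        if self.n_ellipses < 0:
            raise ValidationError("n_ellipses must be >= 0")
        if not 0.0 <= self.background <= 1.0:
            raise ValidationError("background level must lie in [0, 1]")


def make_phantom(spec: PhantomSpec) -> np.ndarray:
    """Deterministic phantom with overlapping ellipses on [0, 1]."""
    rng = np.random.default_rng(spec.seed)
    s = spec.size
    img = np.full((s, s), spec.background)
    yy, xx = np.mgrid[0:s, 0:s].astype(np.float64)
    for _ in range(spec.n_ellipses):
        cy, cx = rng.uniform(0.15 * s, 0.85 * s, size=2)
        ay = rng.uniform(0.06 * s, 0.28 * s)
        ax = rng.uniform(0.06 * s, 0.28 * s)
        theta = rng.uniform(0.0, np.pi)
        level = rng.uniform(0.05, 0.95)
        ct, st = np.cos(theta), np.sin(theta)
        u = (xx - cx) * ct + (yy - cy) * st
        v = -(xx - cx) * st + (yy - cy) * ct
        img[(u / ax) ** 2 + (v / ay) ** 2 <= 1.0] = level

    if spec.include_texture:
        # low-amplitude sinusoid in a horizontal band: detail-preservation probe
        band = slice(int(0.70 * s), int(0.70 * s) + max(4, s // 8))
        phase = rng.uniform(0.0, 2 * np.pi)
        img[band, :] += 0.04 * np.sin(2 * np.pi * xx[band, :] / 6.0 + phase)

    if spec.include_streak_proxy:
        for _ in range(3):
            if rng.random() < 0.5:
                r = int(rng.integers(2, s - 2))
                img[r, :] = np.clip(img[r, :] + 0.3, None, 0.95)
            else:
                c = int(rng.integers(2, s - 2))
                img[:, c] = np.clip(img[:, c] + 0.3, None, 0.95)

    return np.clip(img, 0.0, 1.0)


def add_gaussian_noise(image: np.ndarray, sigma_255: float, seed: int) -> np.ndarray:
    """Additive i.i.d. Gaussian noise at sigma on the 0-255 scale, clipped."""
    if sigma_255 < 0:
        raise ValidationError("sigma_255 must be non-negative")
    image = np.asarray(image, dtype=np.float64)
    if sigma_255 == 0:
        return image.copy()
    rng = np.random.default_rng(seed)
    noisy = image + rng.normal(0.0, sigma_255 / 255.0, size=image.shape)
    return np.clip(noisy, 0.0, 1.0)
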