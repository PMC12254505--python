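"""Orthonormal lifting-Haar transform of q×m pixel matrices, bi-hard
thresholding, and empirical Wiener shrinkage.

The transform is separable and full depth on both axes: a q×m matrix Y maps to
coefficients C = H_q · Y · H_mᵀ, where H_s is the s×s orthonormal Haar matrix
(scaling row first, then wavelet rows coarse-to-fine, within a level by
position).  The unitary convention makes Parseval hold exactly, so a noise
standard deviation estimated in the pixel domain is directly comparable to
coefficient magnitudes.

All operations accept stacked inputs of shape (..., q, m) so the pipeline can
transform every pixel matrix of an image in one batched call.

Bi-hard thresholding is a two-part rule: amplitude hard thresholding at
``tau * sigma_g**exponent`` followed by a structural step that zeroes the last
two coefficient rows everywhere except their first column — at full row depth
those rows hold the finest row-direction details, which for groups of truly
similar pixels are dominated by noise.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .exceptions import ValidationError

__all__ = [
    "haar_matrix",
    "forward",
    "inverse",
    "forward_lifting",
    "inverse_lifting",
    "bihard_threshold",
    "wiener_shrink",
]


def _check_pow2(size: int, name: str = "size") -> int:
    size = int(size)
    if size < 1 or size & (size - 1):
        raise ValidationError(f"{name} must be a power of two, got {size}")
    return size


@lru_cache(maxsize=None)
def _haar_matrix_cached(size: int) -> np.ndarray:
    if size == 1:
        return np.ones((1, 1))
    half = _haar_matrix_cached(size // 2)
    top = np.kron(half, [1.0, 1.0]) / np.sqrt(2.0)
    bottom = np.kron(np.eye(size // 2), [1.0, -1.0]) / np.sqrt(2.0)
    out = np.vstack([top, bottom])
    out.setflags(write=False)
    return out


def haar_matrix(size: int) -> np.ndarray:
    """Orthonormal Haar matrix of the given power-of-two size."""
    return _haar_matrix_cached(_check_pow2(size)).copy()


def _check_qm(matrix: np.ndarray) -> tuple[int, int]:
    matrix = np.asarray(matrix)
    if matrix.ndim < 2:
        raise ValidationError("expected a (..., q, m) array")
    q, m = matrix.shape[-2], matrix.shape[-1]
    _check_pow2(q, "q")
    _check_pow2(m, "m")
    return q, m


def forward(pixels: np.ndarray) -> np.ndarray:
    """Full-depth 2-D orthonormal Haar transform of (..., q, m) matrices."""
    pixels = np.asarray(pixels, dtype=np.float64)
    q, m = _check_qm(pixels)
    return _haar_matrix_cached(q) @ pixels @ _haar_matrix_cached(m).T


def inverse(coeffs: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`forward` (transposed orthonormal factors)."""
    coeffs = np.asarray(coeffs, dtype=np.float64)
    q, m = _check_qm(coeffs)
    return _haar_matrix_cached(q).T @ coeffs @ _haar_matrix_cached(m)


def _lift_axis(data: np.ndarray, axis: int, inverse_: bool) -> np.ndarray:
    """Cascaded pairwise sum/difference lifting along one axis, full depth."""
    out = np.moveaxis(np.array(data, dtype=np.float64), axis, -1)
    size = out.shape[-1]
    _check_pow2(size, "axis length")
    sqrt2 = np.sqrt(2.0)
    if not inverse_:
        length = size
        while length > 1:
            block = out[..., :length]
            a, b = block[..., 0::2], block[..., 1::2]
            s, d = (a + b) / sqrt2, (a - b) / sqrt2
            out[..., : length // 2] = s
            out[..., length // 2 : length] = d
            length //= 2
    else:
        length = 2
        while length <= size:
            s = out[..., : length // 2].copy()
            d = out[..., length // 2 : length].copy()
            out[..., 0:length:2] = (s + d) / sqrt2
            out[..., 1:length:2] = (s - d) / sqrt2
            length *= 2
    return np.moveaxis(out, -1, axis)


def forward_lifting(pixels: np.ndarray) -> np.ndarray:
    """Lifting-scheme implementation of :func:`forward`.

    Identical output to the matrix product (property-tested); kept as an
    independent computation route.
    """
    pixels = np.asarray(pixels, dtype=np.float64)
    _check_qm(pixels)
    return _lift_axis(_lift_axis(pixels, -1, False), -2, False)


def inverse_lifting(coeffs: np.ndarray) -> np.ndarray:
    """Lifting-scheme implementation of :func:`inverse`."""
    coeffs = np.asarray(coeffs, dtype=np.float64)
    _check_qm(coeffs)
    return _lift_axis(_lift_axis(coeffs, -2, True), -1, True)


def bihard_threshold(
    coeffs: np.ndarray,
    tau: float,
    sigma_g: float,
    exponent: int = 2,
) -> tuple[np.ndarray, np.ndarray]:
    """Amplitude + structural hard thresholding of Haar coefficients.

    Keeps entry (i, j) only if |C(i, j)| >= tau * sigma_g**exponent AND the
    entry is outside the last two rows, or in the first column.  Returns the
    thresholded array and the per-matrix retained-coefficient count.
    """
    coeffs = np.asarray(coeffs, dtype=np.float64)
    q, _ = _check_qm(coeffs)
    if tau < 0 or sigma_g < 0:
        raise ValidationError("tau and sigma_g must be non-negative")
    if exponent not in (1, 2):
        raise ValidationError("threshold exponent must be 1 or 2")
    threshold = tau * sigma_g**exponent
    keep = np.abs(coeffs) >= threshold
    if q >= 2:
        structural = np.ones(coeffs.shape[-2:], dtype=bool)
        structural[-2:, 1:] = False
        keep &= structural
    out = np.where(keep, coeffs, 0.0)
    return out, keep.sum(axis=(-2, -1))


def wiener_shrink(
    noisy_coeffs: np.ndarray,
    pilot_coeffs: np.ndarray,
    sigma_g: float,
) -> np.ndarray:
    """Empirical Wiener shrinkage of noisy coefficients.

    The gain at each position is p² / (p² + (sigma_g / 2)²) with p the pilot
    (pre-denoised) coefficient — the pilot acts as the local signal-power
    proxy.  A zero noise level gives unit gain everywhere.
    """
    noisy = np.asarray(noisy_coeffs, dtype=np.float64)
    pilot = np.asarray(pilot_coeffs, dtype=np.float64)
    if noisy.shape != pilot.shape:
        raise ValidationError(
            f"coefficient shape mismatch: {noisy.shape} vs {pilot.shape}"
        )
    _check_qm(noisy)
    if sigma_g < 0:
        raise ValidationError("sigma_g must be non-negative")
    if sigma_g == 0.0:
        return noisy.copy()
    p2 = pilot**2
    gain = p2 / (p2 + (sigma_g / 2.0) ** 2)
    return gain * noisy
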