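"""Non-local means denoising with shift-indexed squared-difference prefix sums.

Classical NLM replaces each pixel by a weighted average of the pixels in a
search window, the weight measuring the similarity of the two surrounding
(2P+1)×(2P+1) patches.  Computed naively this costs O(|Ω| K² P²) for a K-wide
search window.  Reorganizing the computation by *displacement* removes the P²
factor: for a fixed shift d, the squared difference image
(v(k) − v(k+d))² is formed once and its 2-D inclusive prefix sum (integral
image) turns every patch SSD at that shift into a four-corner lookup.  The
per-shift work is a handful of whole-image elementwise operations, independent
across shifts, and the accumulation order is fixed so results are bit-exact
regardless of scheduling.

The spatial Gaussian inside the patch distance is replaced by a constant
(uniform patch weighting) in both the fast and the naive path, so the two are
exactly equivalent and either can serve as the oracle for the other.

By default the raw patch SSD is divided by the patch pixel count (2P+1)²
before the similarity kernel, which makes the smoothing scale h an intensity
quantity independent of patch size; ``NLMParams(normalize_ssd=False)``
restores the raw-sum convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ValidationError
from .image_io import pad_symmetric

__all__ = [
    "NLMParams",
    "ShiftSSDField",
    "kernel_g",
    "shift_ssd",
    "patch_weight",
    "nlm_denoise",
    "nlm_denoise_naive",
]


@dataclass
class NLMParams:
    """Tunables of the non-local means stage.

    patch_radius P gives (2P+1)² patches; search_radius the half-width of the
    search window; h the smoothing scale in intensity units.
    """

    patch_radius: int = 5
    search_radius: int = 10
    h: float = 0.15
    kernel: str = "rational"
    normalize_ssd: bool = True
    pad_mode: str = "symmetric"

    def __post_init__(self) -> None:
        if self.patch_radius < 0 or self.search_radius < 0:
            raise ValidationError("patch_radius and search_radius must be >= 0")
        if self.h <= 0:
            raise ValidationError("h must be positive")
        if self.kernel not in ("rational", "exponential"):
            raise ValidationError(f"unknown kernel {self.kernel!r}")


def kernel_g(x: float | np.ndarray, h: float, kind: str = "rational") -> np.ndarray:
    """Similarity kernel g_h: 1/(1+x²/h²) (rational) or exp(−x²/h²)."""
    if h <= 0:
        raise ValidationError("h must be positive")
    x = np.asarray(x, dtype=np.float64)
    if kind == "rational":
        return 1.0 / (1.0 + (x / h) ** 2)
    if kind == "exponential":
        return np.exp(-((x / h) ** 2))
    raise ValidationError(f"unknown kernel {kind!r}")


@dataclass
class ShiftSSDField:
    """Inclusive prefix sums of the squared difference to a shifted image.

    ``cumulative[u, v]`` is the sum of (pad(k) − pad(k + shift))² over the
    rectangle of padded-grid positions k from ``origin`` to
    ``origin + (u, v)`` inclusive; ``origin`` is the padded-grid coordinate of
    ``cumulative[0, 0]`` (non-zero for negative shifts).
    """

    shift: tuple[int, int]
    cumulative: np.ndarray
    origin: tuple[int, int]
    pad_shape: tuple[int, int]

    def window_sum(self, top: int, left: int, bottom: int, right: int) -> float:
        """Sum of squared differences over an inclusive rectangle of
        padded-grid positions, by four-corner inclusion-exclusion."""
        t, l = top - self.origin[0], left - self.origin[1]
        b, r = bottom - self.origin[0], right - self.origin[1]
        if t < 0 or l < 0 or b >= self.cumulative.shape[0] or r >= self.cumulative.shape[1]:
            raise ValidationError("window extends outside the difference field")
        s = self.cumulative
        total = s[b, r]
        if t > 0:
            total = total - s[t - 1, r]
        if l > 0:
            total = total - s[b, l - 1]
        if t > 0 and l > 0:
            total = total + s[t - 1, l - 1]
        return float(total)


def shift_ssd(
    image: np.ndarray,
    shift: tuple[int, int],
    pad_radius: int,
    pad_mode: str = "symmetric",
) -> ShiftSSDField:
    """Squared-difference prefix field between an image and its shifted copy.

    The image is padded by ``pad_radius``; the field covers every padded
    position whose shifted partner also lies inside the padded grid.
    """
    dy, dx = int(shift[0]), int(shift[1])
    pad = pad_symmetric(image, pad_radius, mode=pad_mode)
    hp, wp = pad.shape
    if abs(dy) >= hp or abs(dx) >= wp:
        raise ValidationError(f"shift {shift} exceeds padded extent {pad.shape}")
    r0, c0 = max(0, -dy), max(0, -dx)
    r1, c1 = hp - max(0, dy), wp - max(0, dx)
    diff = pad[r0:r1, c0:c1] - pad[r0 + dy : r1 + dy, c0 + dx : c1 + dx]
    cum = np.cumsum(np.cumsum(diff**2, axis=0), axis=1)
    return ShiftSSDField(
        shift=(dy, dx), cumulative=cum, origin=(r0, c0), pad_shape=(hp, wp)
    )


def patch_weight(field: ShiftSSDField, s: tuple[int, int], params: NLMParams) -> float:
    """NLM weight between the patch at padded position s and at s + shift."""
    p = params.patch_radius
    ssd = field.window_sum(s[0] - p, s[1] - p, s[0] + p, s[1] + p)
    if params.normalize_ssd:
        ssd = ssd / (2 * p + 1) ** 2
    return float(kernel_g(ssd, params.h, params.kernel))


def _window_sums(diff_sq: np.ndarray, p: int) -> np.ndarray:
    """(2p+1)² box sums of a (h+2p)×(w+2p) field at every interior center."""
    cum = np.zeros((diff_sq.shape[0] + 1, diff_sq.shape[1] + 1))
    np.cumsum(diff_sq, axis=0, out=cum[1:, 1:])
    np.cumsum(cum[1:, 1:], axis=1, out=cum[1:, 1:])
    k = 2 * p + 1
    return cum[k:, k:] - cum[:-k, k:] - cum[k:, :-k] + cum[:-k, :-k]


def nlm_denoise(image: np.ndarray, params: NLMParams) -> np.ndarray:
    """Non-local means via per-shift prefix sums (fast path)."""
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValidationError("nlm_denoise expects a 2-D image")
    p, sr = params.patch_radius, params.search_radius
    h_img, w_img = image.shape
    big = pad_symmetric(image, sr + p, mode=params.pad_mode)
    num = np.zeros_like(image)
    den = np.zeros_like(image)
    npx = float((2 * p + 1) ** 2)
    # fixed deterministic shift order: row-major over the search window
    for dy in range(-sr, sr + 1):
        for dx in range(-sr, sr + 1):
            # difference field over the region whose (2p+1)² windows cover the image
            a = big[sr : sr + h_img + 2 * p, sr : sr + w_img + 2 * p]
            b = big[
                sr + dy : sr + dy + h_img + 2 * p,
                sr + dx : sr + dx + w_img + 2 * p,
            ]
            ssd = _window_sums((a - b) ** 2, p)
            if params.normalize_ssd:
                ssd /= npx
            w = kernel_g(ssd, params.h, params.kernel)
            vals = big[
                sr + p + dy : sr + p + dy + h_img, sr + p + dx : sr + p + dx + w_img
            ]
            num += w * vals
            den += w
    return num / den


def nlm_denoise_naive(image: np.ndarray, params: NLMParams) -> np.ndarray:
    """Non-local means by direct patch-difference summation (oracle path).

    Same contract as :func:`nlm_denoise`; the patch SSD is accumulated by an
    explicit loop over patch offsets with no prefix sums.  Exists for testing.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValidationError("nlm_denoise_naive expects a 2-D image")
    p, sr = params.patch_radius, params.search_radius
    h_img, w_img = image.shape
    big = pad_symmetric(image, sr + p, mode=params.pad_mode)
    num = np.zeros_like(image)
    den = np.zeros_like(image)
    npx = float((2 * p + 1) ** 2)
    for dy in range(-sr, sr + 1):
        for dx in range(-sr, sr + 1):
            ssd = np.zeros((h_img, w_img))
            for oy in range(-p, p + 1):
                for ox in range(-p, p + 1):
                    a = big[
                        sr + p + oy : sr + p + oy + h_img,
                        sr + p + ox : sr + p + ox + w_img,
                    ]
                    b = big[
                        sr + p + oy + dy : sr + p + oy + dy + h_img,
                        sr + p + ox + dx : sr + p + ox + dx + w_img,
                    ]
                    ssd += (a - b) ** 2
            if params.normalize_ssd:
                ssd = ssd / npx
            w = kernel_g(ssd, params.h, params.kernel)
            vals = big[
                sr + p + dy : sr + p + dy + h_img, sr + p + dx : sr + p + dx + w_img
            ]
            num += w * vals
            den += w
    return num / den
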