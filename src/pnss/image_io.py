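"""Grayscale image reading, writing, normalization, and boundary padding.

All in-package computation happens on 2-D float arrays normalized to the
[0, 1] intensity range ("image grids").  Integer formats (8/16-bit PNG and
TIFF) are divided by their type maximum on read; floating-point TIFF data
already inside [0, 1] is passed through unchanged, anything else is linearly
rescaled and the affine map back to the stored range is reported so a result
can be written on the original scale.

Noise levels quoted on the conventional 0-255 scale are divided by 255 at the
CLI boundary; nothing below this module ever sees a 0-255 intensity.
"""

from __future__ import annotations

import logging
import os
from pathlib import Path

import numpy as np
import tifffile

from .exceptions import ImageIOError, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "as_image",
    "read_image",
    "write_image",
    "pad_symmetric",
]


def as_image(values: np.ndarray) -> np.ndarray:
    """Validate and coerce *values* into a 2-D float64 image grid on [0, 1]."""
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 2:
        raise ValidationError(f"image must be 2-D, got shape {arr.shape}")
    if arr.size == 0:
        raise ValidationError("image must have at least one pixel")
    if not np.all(np.isfinite(arr)):
        raise ValidationError("image contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValidationError(
            f"image values outside [0, 1]: min={arr.min():.4g}, max={arr.max():.4g}"
        )
    return arr


def _load_raw(path: str | os.PathLike) -> np.ndarray:
    p = Path(path)
    if not p.exists():
        raise ImageIOError(f"no such image file: {p}")
    suffix = p.suffix.lower()
    try:
        if suffix in (".tif", ".tiff"):
            return np.asarray(tifffile.imread(p))
        import imageio.v3 as iio

        return np.asarray(iio.imread(p))
    except ImageIOError:
        raise
    except Exception as exc:  # noqa: BLE001 - wrap any backend failure
        raise ImageIOError(f"could not read image {p}: {exc}") from exc


def read_image(
    path: str | os.PathLike, return_affine: bool = False
) -> np.ndarray | tuple[np.ndarray, tuple[float, float]]:
    """Read a grayscale PNG/TIFF as a float image grid on [0, 1].

    Multi-channel inputs are collapsed by luminance average (logged).  The
    optional affine ``(scale, offset)`` maps a normalized value back to the
    stored range via ``stored = scale * value + offset``.
    """
    raw = _load_raw(path)
    stored_dtype = raw.dtype
    if raw.ndim == 3:
        logger.warning(
            "multi-channel image %s converted to grayscale by channel average", path
        )
        raw = raw.mean(axis=-1) if raw.shape[-1] <= 4 else raw.mean(axis=0)
    if raw.ndim != 2 or raw.size == 0:
        raise ValidationError(f"image {path} is not a non-empty 2-D grayscale image")

    if np.issubdtype(stored_dtype, np.integer):
        maxval = float(np.iinfo(stored_dtype).max) if stored_dtype.itemsize <= 2 else 65535.0
        img = raw.astype(np.float64) / maxval
        affine = (maxval, 0.0)
    else:
        arr = raw.astype(np.float64)
        if not np.all(np.isfinite(arr)):
            raise ValidationError(f"image {path} contains non-finite values")
        lo, hi = float(arr.min()), float(arr.max())
        if 0.0 <= lo and hi <= 1.0:
            img = arr
            affine = (1.0, 0.0)
        else:
            span = hi - lo
            if span == 0.0:
                img = np.zeros_like(arr)
                affine = (1.0, lo)
            else:
                img = (arr - lo) / span
                affine = (span, lo)
            logger.info(
                "float image %s rescaled from [%g, %g] to [0, 1]", path, lo, hi
            )
    img = as_image(img)
    return (img, affine) if return_affine else img


def write_image(
    image: np.ndarray,
    path: str | os.PathLike,
    depth: str | int = 8,
    affine: tuple[float, float] | None = None,
) -> None:
    """Write an image grid to PNG/TIFF at the given bit depth.

    ``depth`` is 8, 16 or ``"float"``.  Integer depths scale by the type
    maximum and round half to even, so a write/read round trip is accurate to
    half a quantization step.  ``affine`` (scale, offset) undoes the rescaling
    reported by :func:`read_image` before writing float data.
    """
    img = as_image(image)
    p = Path(path)
    depth = str(depth)
    try:
        if depth == "8":
            data = np.round(img * 255.0).astype(np.uint8)
        elif depth == "16":
            data = np.round(img * 65535.0).astype(np.uint16)
        elif depth == "float":
            out = img if affine is None else affine[0] * img + affine[1]
            data = out.astype(np.float32)
        else:
            raise ValidationError(f"unsupported depth {depth!r}; use 8, 16 or 'float'")

        suffix = p.suffix.lower()
        if suffix in (".tif", ".tiff"):
            tifffile.imwrite(p, data)
        else:
            if depth == "float":
                raise ValidationError("float depth requires a TIFF path")
            import imageio.v3 as iio

            iio.imwrite(p, data)
    except ValidationError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise ImageIOError(f"could not write image {p}: {exc}") from exc


def pad_symmetric(image: np.ndarray, radius: int, mode: str = "symmetric") -> np.ndarray:
    """Pad an image by *radius* pixels on every side.

    ``symmetric`` is half-sample symmetric reflection (the edge value is
    duplicated: [1,2,3] with radius 1 becomes [1,1,2,3,3]); ``periodic``
    wraps around.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim != 2:
        raise ValidationError("pad_symmetric expects a 2-D image")
    if radius < 0:
        raise ValidationError("padding radius must be non-negative")
    if radius == 0:
        return img.copy()
    if radius > min(img.shape):
        raise ValidationError(
            f"padding radius {radius} exceeds image extent {min(img.shape)}"
        )
    if mode == "symmetric":
        return np.pad(img, radius, mode="symmetric")
    if mode == "periodic":
        return np.pad(img, radius, mode="wrap")
    raise ValidationError(f"unknown padding mode {mode!r}")
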