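"""Three-stage denoising pipeline: grouped Haar thresholding, fast non-local
means, and Haar-domain Wiener refinement.

Stage 1 runs K cycles of: build a grouping image g_k = λ·noisy + (1−λ)·x_{k−1}
(x_0 = noisy), block-match similar patches and select similar pixel rows on
g_k, estimate the global noise level from the selected rows, hard-threshold
every q×m pixel matrix in the Haar domain (amplitude + structural rule), and
aggregate the overlapping denoised matrices by averaging.  The blend weight λ
continually re-injects the observation so detail removed early can be
recovered in later cycles.

Stage 2 refines the stage-1 pilot with non-local means.  Stage 3 re-groups on
the stage-2 image, extracts paired pixel matrices at identical coordinates
from the stage-2 image and the original observation, and applies empirical
Wiener shrinkage to the noisy coefficients using the stage-2 coefficients as
the signal-power proxy and the iteration-1 noise level (the noise of the
original observation) in the gain.

The method is fully deterministic: there is no randomness anywhere in the
pipeline, so two runs with identical inputs produce bit-identical outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, fields, replace

import numpy as np
import yaml

from . import haar
from .exceptions import ValidationError
from .fast_nlm import NLMParams, nlm_denoise
from .grouping import (
    PixelMatrix,
    batch_block_match,
    batch_row_select,
    patch_vectors,
)
from .image_io import as_image
from .noise_estimation import global_sigma, sigma_from_row_distances

logger = logging.getLogger(__name__)

__all__ = [
    "DenoiseConfig",
    "AggregationBuffer",
    "DenoiseResult",
    "scatter",
    "stage1",
    "stage2",
    "stage3",
    "run",
]


@dataclass
class DenoiseConfig:
    """Every tunable of the three stages.

    Defaults are the published operating point: patch side 8 (n = 64),
    m = 16 similar patches in a W = 40 search window, q = 4 similar pixel
    rows, threshold factor τ = 2 on σ_g² (exponent 2), K = 3 stage-1 cycles
    with blend weight λ = 0.6, and NLM with P = 5, h = 0.15.
    """

    side: int = 8
    stride: int = 3
    window: int = 40
    m: int = 16
    q: int = 4
    tau: float = 2.0
    threshold_exponent: int = 2
    iterations: int = 3
    lam: float = 0.6
    patch_radius: int = 5
    search_radius: int = 10
    h: float = 0.15
    kernel: str = "rational"
    padding: str = "symmetric"
    eq10_literal: bool = False
    calibrate: bool = False
    raw_ssd: bool = False
    refresh_groups: bool = True
    refresh_sigma: bool = True
    weighted_aggregation: bool = False
    seed: int | None = None  # reserved for randomized tie-handling; unused

    def __post_init__(self) -> None:
        for name in ("m", "q"):
            v = getattr(self, name)
            if v < 1 or v & (v - 1):
                raise ValidationError(f"{name}={v} must be a power of two")
        if self.q > self.side**2:
            raise ValidationError(f"q={self.q} exceeds n=side²={self.side ** 2}")
        if not 0.0 <= self.lam <= 1.0:
            raise ValidationError("lam must lie in [0, 1]")
        if self.tau < 0:
            raise ValidationError("tau must be non-negative")
        if self.threshold_exponent not in (1, 2):
            raise ValidationError("threshold_exponent must be 1 or 2")
        if self.iterations < 1:
            raise ValidationError("iterations must be >= 1")
        if self.stride < 1:
            raise ValidationError("stride must be >= 1")
        if self.window < self.side:
            raise ValidationError("window must be at least the patch side")

    @property
    def nlm_params(self) -> NLMParams:
        return NLMParams(
            patch_radius=self.patch_radius,
            search_radius=self.search_radius,
            h=self.h,
            kernel=self.kernel,
            normalize_ssd=not self.raw_ssd,
            pad_mode=self.padding,
        )

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, mapping: dict) -> "DenoiseConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(mapping) - known
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**mapping)

    @classmethod
    def from_yaml(cls, path) -> "DenoiseConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValidationError(f"config file {path} must hold a key: value mapping")
        return cls.from_dict(data)

    def replace(self, **kwargs) -> "DenoiseConfig":
        return replace(self, **kwargs)


@dataclass
class AggregationBuffer:
    """Running per-pixel sum of estimates and count of contributions."""

    numerator: np.ndarray
    counts: np.ndarray

    @classmethod
    def for_shape(cls, shape: tuple[int, int]) -> "AggregationBuffer":
        return cls(numerator=np.zeros(shape), counts=np.zeros(shape))

    def finalize(self) -> np.ndarray:
        if np.any(self.counts <= 0):
            raise ValidationError("some pixels received no estimate during aggregation")
        return self.numerator / self.counts


def scatter(buffer: AggregationBuffer, matrix: np.ndarray, pixel_map: PixelMatrix) -> None:
    """Add one denoised q×m matrix back at its image coordinates.

    Entry (t, j) lands at the top-left of member patch j plus the in-patch
    offset of vector index ``row_indices[t]`` (column-major order).
    """
    members = pixel_map.source.members
    side = members[0].side
    matrix = np.asarray(matrix, dtype=np.float64)
    h, w = buffer.numerator.shape
    for t, k in enumerate(pixel_map.row_indices):
        dr, dc = int(k) % side, int(k) // side
        for j, member in enumerate(members):
            r, c = member.top_row + dr, member.top_col + dc
            if not (0 <= r < h and 0 <= c < w):
                raise ValidationError(f"scatter position ({r}, {c}) outside image")
            buffer.numerator[r, c] += matrix[t, j]
            buffer.counts[r, c] += 1.0


# ---------------------------------------------------------------------------
# batched internals
# ---------------------------------------------------------------------------


def _gather_matrices(
    image: np.ndarray, members: np.ndarray, order: np.ndarray, side: int
) -> np.ndarray:
    """Pixel matrices (G, n_ref_rows, q, m) of *image* at the given group
    coordinates and row selections."""
    vecs = patch_vectors(image, side)
    group_mats = vecs[members[..., 0], members[..., 1]].transpose(0, 2, 1)  # (G, n, m)
    g_idx = np.arange(group_mats.shape[0])[:, None, None]
    return group_mats[g_idx, order]


def _scatter_batched(
    shape: tuple[int, int],
    members: np.ndarray,
    order: np.ndarray,
    values: np.ndarray,
    side: int,
    weights: np.ndarray | None = None,
) -> AggregationBuffer:
    """Aggregate all (G, n, q, m) estimates into per-pixel sums via bincount."""
    h, w = shape
    pr = members[:, None, None, :, 0] + (order % side)[..., None]
    pc = members[:, None, None, :, 1] + (order // side)[..., None]
    flat = (pr * w + pc).ravel()
    if weights is None:
        wts = np.ones(values.shape[:2])
    else:
        wts = weights
    wfull = np.broadcast_to(wts[..., None, None], values.shape).ravel()
    num = np.bincount(flat, weights=(values * wts[..., None, None]).ravel(), minlength=h * w)
    cnt = np.bincount(flat, weights=wfull, minlength=h * w)
    return AggregationBuffer(num.reshape(h, w), cnt.reshape(h, w))


def _row_dist_for_order(group_mats: np.ndarray, order: np.ndarray) -> np.ndarray:
    """Euclidean row distances along a frozen row selection."""
    g_idx = np.arange(group_mats.shape[0])[:, None, None]
    sel = group_mats[g_idx, order]  # (G, n, q, m)
    ref = sel[:, :, :1, :]
    return np.sqrt(((sel - ref) ** 2).sum(axis=-1))


@dataclass
class DenoiseResult:
    """Final image plus per-stage diagnostics."""

    image: np.ndarray
    pilot: np.ndarray
    refined: np.ndarray
    sigma_g: float
    sigma_per_iteration: list[float] = field(default_factory=list)
    retained_fraction: list[float] = field(default_factory=list)
    timings: dict = field(default_factory=dict)


def stage1(
    noisy: np.ndarray, cfg: DenoiseConfig, _diag: dict | None = None
) -> tuple[np.ndarray, float]:
    """K cycles of grouped Haar-domain bi-hard thresholding.

    Returns the stage-1 pilot image and the iteration-1 global noise level
    (the noise of the original observation, used again by stage 3).
    """
    noisy = as_image(noisy)
    h, w = noisy.shape
    if min(h, w) <= cfg.side:
        raise ValidationError("image must be larger than the patch side")
    q, m, side = cfg.q, cfg.m, cfg.side
    x = noisy
    sigma_iter1 = 0.0
    members = order = None
    for k in range(cfg.iterations):
        g_img = cfg.lam * noisy + (1.0 - cfg.lam) * x
        if k == 0 or cfg.refresh_groups:
            _, members, group_mats = batch_block_match(
                g_img, side, cfg.stride, cfg.window, m
            )
            order, row_dist = batch_row_select(group_mats, q)
        else:
            vecs = patch_vectors(g_img, side)
            group_mats = vecs[members[..., 0], members[..., 1]].transpose(0, 2, 1)
            row_dist = _row_dist_for_order(group_mats, order)
        sigma_l = sigma_from_row_distances(
            row_dist, m, eq10_literal=cfg.eq10_literal, calibrate=cfg.calibrate
        )
        sigma_g = global_sigma(sigma_l)
        if k == 0:
            sigma_iter1 = sigma_g
        sigma_use = sigma_g if cfg.refresh_sigma else sigma_iter1
        g_idx = np.arange(group_mats.shape[0])[:, None, None]
        mats = group_mats[g_idx, order]  # (G, n, q, m)
        coeffs = haar.forward(mats)
        thr, retained = haar.bihard_threshold(
            coeffs, cfg.tau, sigma_use, cfg.threshold_exponent
        )
        den = haar.inverse(thr)
        weights = 1.0 / (1.0 + retained) if cfg.weighted_aggregation else None
        buf = _scatter_batched((h, w), members, order, den, side, weights)
        x = buf.finalize()
        if _diag is not None:
            _diag.setdefault("sigma_per_iteration", []).append(float(sigma_g))
            _diag.setdefault("retained_fraction", []).append(
                float(retained.sum() / coeffs.size)
            )
        logger.info(
            "stage 1 cycle %d/%d: sigma_g=%.5f, retained %.1f%% of coefficients",
            k + 1,
            cfg.iterations,
            sigma_g,
            100.0 * retained.sum() / coeffs.size,
        )
    return x, sigma_iter1


def stage2(pilot: np.ndarray, cfg: DenoiseConfig) -> np.ndarray:
    """Non-local means refinement of the stage-1 pilot."""
    return nlm_denoise(np.asarray(pilot, dtype=np.float64), cfg.nlm_params)


def stage3(
    noisy: np.ndarray,
    refined: np.ndarray,
    sigma_g: float,
    cfg: DenoiseConfig,
) -> np.ndarray:
    """Haar-domain empirical Wiener refinement.

    Groups are found on the stage-2 image (the best available estimate);
    pixel matrices are extracted at identical coordinates from both that
    image and the original observation, and the noisy coefficients are shrunk
    by gains computed from the stage-2 ("pilot") coefficients.
    """
    noisy = np.asarray(noisy, dtype=np.float64)
    refined = np.asarray(refined, dtype=np.float64)
    if noisy.shape != refined.shape:
        raise ValidationError("noisy and refined images must share a shape")
    h, w = noisy.shape
    _, members, refined_mats = batch_block_match(
        refined, cfg.side, cfg.stride, cfg.window, cfg.m
    )
    order, _ = batch_row_select(refined_mats, cfg.q)
    g_idx = np.arange(refined_mats.shape[0])[:, None, None]
    pilot_mats = refined_mats[g_idx, order]
    noisy_mats = _gather_matrices(noisy, members, order, cfg.side)
    c_noisy = haar.forward(noisy_mats)
    c_pilot = haar.forward(pilot_mats)
    c_out = haar.wiener_shrink(c_noisy, c_pilot, sigma_g)
    den = haar.inverse(c_out)
    buf = _scatter_batched((h, w), members, order, den, cfg.side)
    return buf.finalize()


def run(noisy: np.ndarray, cfg: DenoiseConfig | None = None) -> DenoiseResult:
    """Full three-stage pipeline; the output is clipped to [0, 1]."""
    cfg = cfg or DenoiseConfig()
    noisy = as_image(noisy)
    diag: dict = {}
    timings = {}
    t0 = time.perf_counter()
    pilot, sigma_g = stage1(noisy, cfg, _diag=diag)
    timings["stage1"] = time.perf_counter() - t0
    t0 = time.perf_counter()
    refined = stage2(pilot, cfg)
    timings["stage2"] = time.perf_counter() - t0
    t0 = time.perf_counter()
    final = stage3(noisy, refined, sigma_g, cfg)
    timings["stage3"] = time.perf_counter() - t0
    return DenoiseResult(
        image=np.clip(final, 0.0, 1.0),
        pilot=pilot,
        refined=refined,
        sigma_g=sigma_g,
        sigma_per_iteration=diag.get("sigma_per_iteration", []),
        retained_fraction=diag.get("retained_fraction", []),
        timings=timings,
    )
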