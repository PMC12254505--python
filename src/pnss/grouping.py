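"""Non-local similar-patch grouping and pixel-row selection.

The pixel-level self-similarity prior is built in two steps.  First, for each
reference patch the m most similar patches (itself included) inside a W×W
search window are stacked column-wise into an n×m patch-group matrix, where
n = side² and each patch is vectorized column-major (down each patch column,
then across; vector index k maps to in-patch offset (k % side, k // side)).
Second, within a group, each of the n rows — the same in-patch pixel position
seen across the m similar patches — is paired with its q−1 nearest rows by
Euclidean distance, giving a q×m matrix of mutually similar pixels.

Besides the per-object operations this module provides batched helpers
(:func:`patch_vectors`, :func:`batch_block_match`, :func:`batch_row_select`)
that compute the same quantities for every reference patch of an image at
once; the pipeline uses those, and their agreement with the per-object path
is property-tested.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.spatial.distance import cdist

from .exceptions import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Patch",
    "PatchGroup",
    "PixelMatrix",
    "reference_grid",
    "block_match",
    "row_distance_matrix",
    "select_similar_rows",
    "patch_vectors",
    "batch_block_match",
    "batch_row_select",
]


class Patch(NamedTuple):
    """Top-left corner and side length of a square patch (0-based pixels)."""

    top_row: int
    top_col: int
    side: int


@dataclass
class PatchGroup:
    """n×m matrix of m similar vectorized patches; column 0 is the reference."""

    matrix: np.ndarray
    members: list[Patch]
    distances: np.ndarray
    reference_index: int = 0

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def m(self) -> int:
        return self.matrix.shape[1]


@dataclass
class PixelMatrix:
    """q×m matrix of mutually similar pixel rows drawn from a patch group."""

    matrix: np.ndarray
    row_indices: np.ndarray
    source: PatchGroup = field(repr=False)

    @property
    def q(self) -> int:
        return self.matrix.shape[0]


def _axis_positions(extent: int, side: int, stride: int) -> np.ndarray:
    """Top-left coordinates along one axis: multiples of stride, last clamped
    so the final patch touches the border."""
    last = extent - side
    pos = np.arange(0, last + 1, stride)
    if pos[-1] != last:
        pos = np.append(pos, last)
    return pos


def reference_grid(image: np.ndarray, side: int, stride: int) -> list[Patch]:
    """Reference patches on a stride grid covering every image pixel."""
    image = np.asarray(image)
    h, w = image.shape
    if side > min(h, w):
        raise ValidationError(f"patch side {side} exceeds image extent {min(h, w)}")
    if stride < 1:
        raise ValidationError("stride must be >= 1")
    rows = _axis_positions(h, side, stride)
    cols = _axis_positions(w, side, stride)
    return [Patch(int(r), int(c), side) for r in rows for c in cols]


def _patch_vector(image: np.ndarray, patch: Patch) -> np.ndarray:
    r, c, s = patch
    return image[r : r + s, c : c + s].ravel(order="F")


def patch_vectors(image: np.ndarray, side: int) -> np.ndarray:
    """Column-major vectorizations of every fully-inside patch.

    Returns an array of shape (H−side+1, W−side+1, side²) where entry (r, c)
    is the vectorized patch with top-left corner (r, c).
    """
    image = np.ascontiguousarray(image, dtype=np.float64)
    view = np.lib.stride_tricks.sliding_window_view(image, (side, side))
    # F-order ravel of each (side, side) window = C-order ravel of its transpose
    return view.transpose(0, 1, 3, 2).reshape(
        view.shape[0], view.shape[1], side * side
    )


def _window_bounds(pos: int, half: int, upper: int) -> tuple[int, int]:
    return max(0, pos - half), min(upper, pos + half)


def block_match(image: np.ndarray, ref: Patch, window: int, m: int) -> PatchGroup:
    """Group the m most similar patches to *ref* inside a W×W search window.

    Candidates are all fully-inside patches whose top-left corner lies within
    the window centered on the reference top-left (clipped at borders).  Ties
    are broken by (row, col) scan order; the reference is always column 0.
    """
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    side = ref.side
    if window < side:
        raise ValidationError(f"search window {window} smaller than patch side {side}")
    if m < 1:
        raise ValidationError("m must be >= 1")
    if ref.top_row + side > h or ref.top_col + side > w:
        raise ValidationError(f"reference patch {ref} outside image {image.shape}")

    half = window // 2
    rlo, rhi = _window_bounds(ref.top_row, half, h - side)
    clo, chi = _window_bounds(ref.top_col, half, w - side)
    cand_r, cand_c = np.meshgrid(
        np.arange(rlo, rhi + 1), np.arange(clo, chi + 1), indexing="ij"
    )
    cand_r, cand_c = cand_r.ravel(), cand_c.ravel()

    vecs = patch_vectors(image, side)
    cands = vecs[cand_r, cand_c]
    ref_vec = _patch_vector(image, ref)
    d2 = ((cands - ref_vec) ** 2).sum(axis=1)

    ref_idx = int(
        np.flatnonzero((cand_r == ref.top_row) & (cand_c == ref.top_col))[0]
    )
    d2_rank = d2.copy()
    d2_rank[ref_idx] = -1.0  # reference is always first, ahead of exact ties
    order = np.argsort(d2_rank, kind="stable")  # scan-order tie-break

    if len(order) < m:
        logger.warning(
            "only %d candidates for %d requested members; repeating best matches",
            len(order),
            m,
        )
        order = np.resize(order, m)
    sel = order[:m]

    members = [Patch(int(cand_r[i]), int(cand_c[i]), side) for i in sel]
    matrix = cands[sel].T.copy()
    return PatchGroup(matrix=matrix, members=members, distances=np.sqrt(d2[sel]))


def row_distance_matrix(group: PatchGroup) -> np.ndarray:
    """Pairwise Euclidean distances between the n rows of the group matrix."""
    return cdist(group.matrix, group.matrix)


def select_similar_rows(group: PatchGroup, i: int, q: int) -> PixelMatrix:
    """The q rows of the group nearest to row i (row i itself first).

    Ties are broken by smaller row index; row i always leads even when other
    rows are identical to it.
    """
    n = group.n
    if not 1 <= q <= n:
        raise ValidationError(f"q={q} must lie in [1, n={n}]")
    if q & (q - 1):
        raise ValidationError(f"q={q} must be a power of two")
    dist = row_distance_matrix(group)[i].copy()
    dist[i] = -1.0
    order = np.argsort(dist, kind="stable")[:q]
    return PixelMatrix(
        matrix=group.matrix[order].copy(),
        row_indices=order.astype(np.intp),
        source=group,
    )


# ---------------------------------------------------------------------------
# batched whole-image machinery (same semantics as the per-object operations)
# ---------------------------------------------------------------------------


def batch_block_match(
    image: np.ndarray,
    side: int,
    stride: int,
    window: int,
    m: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Block-match every reference-grid patch at once.

    Returns ``(ref_positions, member_positions, group_matrices)`` with shapes
    (G, 2), (G, m, 2) and (G, n, m); group g's columns are ordered exactly as
    :func:`block_match` orders them.
    """
    image = np.asarray(image, dtype=np.float64)
    h, w = image.shape
    refs = reference_grid(image, side, stride)
    if window < side:
        raise ValidationError(f"search window {window} smaller than patch side {side}")
    vecs = patch_vectors(image, side)
    sq = np.einsum("rcn,rcn->rc", vecs, vecs)
    half = window // 2

    n = side * side
    n_refs = len(refs)
    members = np.empty((n_refs, m, 2), dtype=np.intp)
    matrices = np.empty((n_refs, n, m), dtype=np.float64)
    warned = False
    for g, ref in enumerate(refs):
        rlo, rhi = _window_bounds(ref.top_row, half, h - side)
        clo, chi = _window_bounds(ref.top_col, half, w - side)
        block = vecs[rlo : rhi + 1, clo : chi + 1]
        nr, nc = block.shape[0], block.shape[1]
        cands = block.reshape(nr * nc, n)
        ref_vec = vecs[ref.top_row, ref.top_col]
        d2 = (
            sq[rlo : rhi + 1, clo : chi + 1].ravel()
            - 2.0 * cands @ ref_vec
            + ref_vec @ ref_vec
        )
        ref_idx = (ref.top_row - rlo) * nc + (ref.top_col - clo)
        d2[ref_idx] = -1.0
        # candidates are generated in scan order, so a stable sort breaks
        # distance ties by (row, col) exactly as block_match does
        order = np.argsort(d2, kind="stable")
        if len(order) < m:
            if not warned:
                logger.warning(
                    "only %d candidates for %d members; repeating best matches",
                    len(order),
                    m,
                )
                warned = True
            order = np.resize(order, m)
        order = order[:m]
        members[g, :, 0] = rlo + order // nc
        members[g, :, 1] = clo + order % nc
        matrices[g] = cands[order].T
    ref_positions = np.array([(p.top_row, p.top_col) for p in refs], dtype=np.intp)
    return ref_positions, members, matrices


def batch_row_select(matrices: np.ndarray, q: int) -> tuple[np.ndarray, np.ndarray]:
    """For every group and every reference row, the q nearest rows.

    ``matrices`` has shape (G, n, m).  Returns ``(row_order, row_dist)`` of
    shapes (G, n, q) and (G, n, q): row_order[g, i] lists the selected row
    indices (row i first, ties by smaller index) and row_dist the matching
    Euclidean distances (first entry 0).
    """
    matrices = np.asarray(matrices, dtype=np.float64)
    g_count, n, _ = matrices.shape
    if not 1 <= q <= n or q & (q - 1):
        raise ValidationError(f"q={q} must be a power of two in [1, n={n}]")
    sq = np.einsum("gnm,gnm->gn", matrices, matrices)
    gram = matrices @ matrices.transpose(0, 2, 1)
    d2 = sq[:, :, None] + sq[:, None, :] - 2.0 * gram
    np.maximum(d2, 0.0, out=d2)
    idx = np.arange(n)
    d2[:, idx, idx] = -1.0  # the reference row always leads
    order = np.argsort(d2, axis=-1, kind="stable")[:, :, :q]
    dist2 = np.take_along_axis(d2, order, axis=-1)
    dist2[:, :, 0] = 0.0
    return order.astype(np.intp), np.sqrt(dist2)
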