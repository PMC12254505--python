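import numpy as np
import pytest

from pnss.exceptions import ValidationError
from pnss.grouping import (
    Patch,
    batch_block_match,
    batch_row_select,
    block_match,
    patch_vectors,
    reference_grid,
    row_distance_matrix,
    select_similar_rows,
)


class TestReferenceGrid:
    @pytest.mark.parametrize(
        "shape,side,stride,expected",
        [
            ((16, 16), 8, 8, [(0, 0), (0, 8), (8, 0), (8, 8)]),
            ((10, 10), 8, 3, [(0, 0), (0, 2), (2, 0), (2, 2)]),
            ((9, 9), 8, 1, [(0, 0), (0, 1), (1, 0), (1, 1)]),
        ],
    )
    def test_corner_placement(self, shape, side, stride, expected):
        patches = reference_grid(np.zeros(shape), side, stride)
        assert [(p.top_row, p.top_col) for p in patches] == expected

    @pytest.mark.parametrize("shape,side,stride", [((37, 23), 8, 3), ((32, 32), 8, 7)])
    def test_every_pixel_covered(self, shape, side, stride):
        cover = np.zeros(shape, dtype=int)
        for p in reference_grid(np.zeros(shape), side, stride):
            cover[p.top_row : p.top_row + side, p.top_col : p.top_col + side] += 1
        assert cover.min() >= 1

    def test_oversized_side_rejected(self):
        with pytest.raises(ValidationError):
            reference_grid(np.zeros((6, 6)), 8, 1)


class TestBlockMatch:
    def test_constant_image_scan_order_tiebreak(self):
        img = np.full((12, 12), 0.3)
        ref = Patch(4, 4, 4)
        group = block_match(img, ref, window=8, m=4)
        assert group.members[0] == ref
        assert np.all(group.distances == 0.0)
        # remaining members are the earliest candidates in scan order
        others = [(p.top_row, p.top_col) for p in group.members[1:]]
        assert others == [(0, 0), (0, 1), (0, 2)]

    def test_translated_copy_ranks_first_after_reference(self, rng):
        img = rng.uniform(0, 1, (16, 16))
        img[8:12, 8:12] = img[2:6, 2:6]  # exact distant copy
        group = block_match(img, Patch(2, 2, 4), window=16, m=3)
        assert group.members[0] == Patch(2, 2, 4)
        assert (group.members[1].top_row, group.members[1].top_col) == (8, 8)
        assert group.distances[1] == 0.0

    def test_hand_computed_distances(self):
        # three isolated 2x2 patches separated by far-off columns:
        # ref=[0,0,.1,.1], p_a=[0,0,0,0], p_b=[1,1,1,1]
        img = np.array(
            [
                [0.0, 0.1, 10.0, 0.0, 0.0, 10.0, 1.0, 1.0],
                [0.0, 0.1, 10.0, 0.0, 0.0, 10.0, 1.0, 1.0],
            ]
        )
        group = block_match(img, Patch(0, 0, 2), window=16, m=3)
        coords = [(p.top_row, p.top_col) for p in group.members]
        assert coords == [(0, 0), (0, 3), (0, 6)]
        np.testing.assert_allclose(
            group.distances, [0.0, np.sqrt(0.02), np.sqrt(3.62)]
        )

    def test_column_major_vectorization(self):
        img = np.arange(16, dtype=float).reshape(4, 4) / 16
        group = block_match(img, Patch(0, 0, 2), window=4, m=1)
        # down column 0 then column 1 of the patch
        np.testing.assert_array_equal(
            group.matrix[:, 0], [img[0, 0], img[1, 0], img[0, 1], img[1, 1]]
        )

    def test_distances_sorted_and_reference_first(self, rng):
        img = rng.uniform(0, 1, (24, 24))
        group = block_match(img, Patch(8, 8, 8), window=16, m=8)
        assert group.distances[0] == 0.0
        assert np.all(np.diff(group.distances) >= 0.0)

    def test_tiled_texture_all_distances_zero(self, rng):
        tile = rng.uniform(0, 1, (4, 4))
        img = np.tile(tile, (4, 4))
        group = block_match(img, Patch(4, 4, 4), window=8, m=4)
        assert np.all(group.distances == 0.0)

    def test_too_few_candidates_repeats_best(self):
        img = np.linspace(0, 1, 64).reshape(8, 8)
        group = block_match(img, Patch(0, 0, 8), window=8, m=4)
        assert len(group.members) == 4
        assert all(m == Patch(0, 0, 8) for m in group.members)


class TestRowSelection:
    def test_identical_rows_zero_distance(self):
        from pnss.grouping import PatchGroup

        mat = np.ones((4, 3))
        group = PatchGroup(mat, [Patch(0, 0, 2)] * 3, np.zeros(3))
        assert np.all(row_distance_matrix(group) == 0.0)

    def test_hand_distance(self):
        from pnss.grouping import PatchGroup

        mat = np.array([[1.0, 1.0], [0.0, 0.0]])
        group = PatchGroup(mat, [Patch(0, 0, 1)] * 2, np.zeros(2))
        d = row_distance_matrix(group)
        assert d[0, 1] == pytest.approx(np.sqrt(2.0))
        assert d[0, 0] == 0.0

    def test_matches_brute_force(self, rng):
        from pnss.grouping import PatchGroup

        mat = rng.normal(size=(4, 4))
        group = PatchGroup(mat, [Patch(0, 0, 2)] * 4, np.zeros(4))
        d = row_distance_matrix(group)
        for i in range(4):
            for j in range(4):
                assert d[i, j] == pytest.approx(
                    np.sqrt(((mat[i] - mat[j]) ** 2).sum()), abs=1e-12
                )

    def test_q_one_returns_reference_row_only(self, rng):
        from pnss.grouping import PatchGroup

        mat = rng.normal(size=(4, 4))
        group = PatchGroup(mat, [Patch(0, 0, 2)] * 4, np.zeros(4))
        pm = select_similar_rows(group, 2, 1)
        np.testing.assert_array_equal(pm.matrix, mat[2:3])
        np.testing.assert_array_equal(pm.row_indices, [2])

    def test_exact_duplicate_wins(self):
        from pnss.grouping import PatchGroup

        mat = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [9.0, 9.0]])
        group = PatchGroup(mat, [Patch(0, 0, 2)] * 2, np.zeros(2))
        pm = select_similar_rows(group, 0, 2)
        assert sorted(pm.row_indices.tolist()) == [0, 1]
        assert pm.row_indices[0] == 0  # reference row leads

    def test_matches_brute_force_sort(self, rng):
        from pnss.grouping import PatchGroup

        mat = rng.normal(size=(8, 4))
        group = PatchGroup(mat, [Patch(0, 0, 4)] * 4, np.zeros(4))
        for i in range(8):
            pm = select_similar_rows(group, i, 4)
            d = np.sqrt(((mat - mat[i]) ** 2).sum(axis=1))
            d[i] = -1.0
            expected = np.argsort(d, kind="stable")[:4]
            np.testing.assert_array_equal(pm.row_indices, expected)

    def test_invariant_to_permuting_unselected_rows(self, rng):
        from pnss.grouping import PatchGroup

        mat = rng.normal(size=(8, 4))
        group = PatchGroup(mat, [Patch(0, 0, 4)] * 4, np.zeros(4))
        pm = select_similar_rows(group, 0, 2)
        unselected = [i for i in range(8) if i not in pm.row_indices]
        perm = np.arange(8)
        perm[unselected] = np.array(unselected)[::-1]
        group2 = PatchGroup(mat[perm], [Patch(0, 0, 4)] * 4, np.zeros(4))
        pm2 = select_similar_rows(group2, 0, 2)
        np.testing.assert_array_equal(pm2.matrix, pm.matrix)

    def test_q_larger_than_n_rejected(self, rng):
        from pnss.grouping import PatchGroup

        mat = rng.normal(size=(4, 4))
        group = PatchGroup(mat, [Patch(0, 0, 2)] * 4, np.zeros(4))
        with pytest.raises(ValidationError):
            select_similar_rows(group, 0, 8)


class TestBatchedAgreement:
    """The whole-image batched machinery must reproduce the per-object path."""

    def test_batch_block_match_equals_per_reference(self, rng):
        img = rng.uniform(0, 1, (20, 20))
        side, stride, window, m = 4, 5, 8, 4
        _, members, matrices = batch_block_match(img, side, stride, window, m)
        for g, ref in enumerate(reference_grid(img, side, stride)):
            group = block_match(img, ref, window, m)
            np.testing.assert_array_equal(
                members[g], [(p.top_row, p.top_col) for p in group.members]
            )
            np.testing.assert_array_equal(matrices[g], group.matrix)

    def test_batch_row_select_equals_per_group(self, rng):
        from pnss.grouping import PatchGroup

        mats = rng.normal(size=(3, 8, 4))
        order, dist = batch_row_select(mats, 4)
        for g in range(3):
            group = PatchGroup(mats[g], [Patch(0, 0, 4)] * 4, np.zeros(4))
            for i in range(8):
                pm = select_similar_rows(group, i, 4)
                np.testing.assert_array_equal(order[g, i], pm.row_indices)
                np.testing.assert_array_equal(
                    mats[g][order[g, i]], pm.matrix
                )
        assert np.all(dist[:, :, 0] == 0.0)
        assert np.all(np.diff(dist, axis=-1) >= -1e-9)

    def test_patch_vectors_layout(self, rng):
        img = rng.uniform(0, 1, (6, 7))
        vecs = patch_vectors(img, 3)
        np.testing.assert_array_equal(
            vecs[2, 1], img[2:5, 1:4].ravel(order="F")
        )
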