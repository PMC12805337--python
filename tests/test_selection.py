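"""KNN coverage, CCR, greedy selection, variants, and baselines."""

import itertools

import numpy as np
import pytest

from coverseg.embedding import EmbeddingSet, PatchGrid
from coverseg.selection import (
    build_index,
    build_radius_index,
    ccr,
    cgs,
    cgs_fixed_distance,
    covered,
    enumerate_candidates,
    equispaced_select,
    random_select,
)
from coverseg.volumes import SubVolumeSpec


def line_embeddings(values, patch=(8, 40, 40), stride=(8, 40, 40)):
    """1-D scalar embeddings laid out as patches along x."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    origins = np.array([[0, 0, i * stride[2]] for i in range(n)])
    shape = (patch[0], patch[1], patch[2] + (n - 1) * stride[2])
    return EmbeddingSet(values[:, None], origins, patch, stride, shape)


@pytest.fixture()
def six_points():
    return line_embeddings([0.0, 1.0, 2.0, 10.0, 11.0, 12.0])


class TestBuildIndex:
    def test_k1_is_self(self, six_points):
        idx = build_index(six_points, k=1)
        np.testing.assert_array_equal(idx.neighbor_table.ravel(), np.arange(6))

    def test_k_equals_n_covers_all(self, six_points):
        idx = build_index(six_points, k=6)
        for row in idx.neighbor_lists:
            assert set(row) == set(range(6))

    def test_tie_broken_by_smaller_index(self, six_points):
        idx = build_index(six_points, k=2)
        assert set(idx.neighbor_lists[0]) == {0, 1}
        # point 1: neighbors 0 and 2 equidistant -> pick index 0
        assert set(idx.neighbor_lists[1]) == {1, 0}

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(5):
            vecs = rng.normal(size=(20, 3))
            emb = line_embeddings(np.zeros(20))
            emb.vectors = vecs
            k = int(rng.integers(2, 8))
            idx = build_index(emb, k=k)
            d = np.linalg.norm(vecs[:, None] - vecs[None], axis=2)
            for n in range(20):
                order = np.lexsort((np.arange(20), d[n]))
                assert set(idx.neighbor_lists[n]) == set(order[:k])

    def test_k_out_of_range_rejected(self, six_points):
        with pytest.raises(ValueError):
            build_index(six_points, k=7)


class TestCoverage:
    def test_empty_selection(self, six_points):
        idx = build_index(six_points, k=2)
        assert not covered([], idx).any()
        assert ccr([], idx) == 0.0

    def test_full_selection_covers_everything(self, six_points):
        idx = build_index(six_points, k=2)
        assert covered(range(6), idx).all()
        assert ccr(range(6), idx) == 1.0

    def test_worked_union(self, six_points):
        idx = build_index(six_points, k=2)
        mask = covered([0], idx)
        assert mask.sum() == 2 and mask[0] and mask[1]
        assert ccr([0], idx) == pytest.approx(2 / 6)

    def test_ccr_monotone_under_inclusion(self, rng):
        emb = line_embeddings(rng.normal(size=12))
        idx = build_index(emb, k=3)
        values = [ccr(range(s), idx) for s in range(13)]
        assert all(a <= b for a, b in zip(values, values[1:]))


class TestFixedRadius:
    def test_tiny_radius_covers_self_only(self, six_points):
        idx = build_radius_index(six_points, radius=0.5)
        for n, row in enumerate(idx.neighbor_lists):
            assert list(row) == [n]

    def test_huge_radius_first_pick_covers_all(self, six_points):
        grid = PatchGrid.build((8, 40, 240), (8, 40, 40), (8, 40, 40))
        res = cgs_fixed_distance(six_points, grid, [(8, 40, 40)], radius=100.0)
        assert res.final_ccr == 1.0

    def test_worked_radius_coverage(self, six_points):
        idx = build_radius_index(six_points, radius=1.5)
        assert set(idx.neighbor_lists[1]) == {0, 1, 2}
        assert ccr([1], idx) == pytest.approx(0.5)


class TestEnumerateCandidates:
    def test_full_volume_single_candidate(self, six_points):
        grid = PatchGrid.build((8, 40, 240), (8, 40, 40), (8, 40, 40))
        cands = enumerate_candidates(grid, (8, 40, 240))
        assert len(cands) == 1
        assert len(cands[0][1]) == len(grid)

    def test_exclusions_remove_everything(self, six_points):
        grid = PatchGrid.build((8, 40, 240), (8, 40, 40), (8, 40, 40))
        full = SubVolumeSpec((0, 0, 0), (8, 40, 240))
        assert enumerate_candidates(grid, (8, 40, 80), exclusions=[full]) == []

    def test_worked_candidate_membership(self):
        grid = PatchGrid.build((16, 80, 80), (8, 40, 40), (8, 40, 40))
        cands = enumerate_candidates(grid, (8, 80, 80), scan_stride=(8, 40, 40))
        assert len(cands) == 2
        for _, members in cands:
            assert len(members) == 4

    def test_subvol_smaller_than_patch_rejected(self):
        grid = PatchGrid.build((16, 80, 80), (8, 40, 40), (8, 40, 40))
        with pytest.raises(ValueError):
            enumerate_candidates(grid, (4, 40, 40))


def disjoint_instance(rng, n_patches=12, dim=3):
    """Random embeddings on a lattice of pairwise-disjoint candidate windows."""
    emb = line_embeddings(np.zeros(n_patches))
    emb.vectors = rng.normal(size=(n_patches, dim))
    grid = PatchGrid.build(emb.volume_shape, emb.patch_size, emb.stride)
    return emb, grid


class TestCGS:
    def test_single_candidate_is_chosen(self, six_points):
        grid = PatchGrid.build((8, 40, 240), (8, 40, 40), (8, 40, 40))
        res = cgs(six_points, grid, [(8, 40, 240)], k=2)
        assert res.chosen == [SubVolumeSpec((0, 0, 0), (8, 40, 240))]
        assert res.ccr_trace == [1.0]

    def test_two_clusters_two_blocks_picks_one_each(self, rng):
        # 8 patches along x; first 4 = cluster A, last 4 = cluster B
        emb = line_embeddings(np.zeros(8))
        emb.vectors = np.concatenate(
            [rng.normal(0, 0.1, (4, 2)), rng.normal(10, 0.1, (4, 2))]
        )
        grid = PatchGrid.build(emb.volume_shape, emb.patch_size, emb.stride)
        size = (8, 40, 160)  # fits 4 patches = one block
        scan = (8, 40, 160)  # block-aligned candidates
        res = cgs(emb, grid, [size, size], k=4, scan_stride=scan)
        xs = sorted(s.origin[2] for s in res.chosen)
        assert xs == [0, 160]  # one window per block
        # exhaustive check: no same-budget pair beats it
        idx = build_index(emb, k=4)
        cands = enumerate_candidates(grid, size, scan_stride=scan)
        best_pair = max(
            (
                ccr(np.concatenate([m1, m2]), idx)
                for (s1, m1), (s2, m2) in itertools.combinations(cands, 2)
                if not s1.overlaps(s2)
            )
        )
        assert res.final_ccr == pytest.approx(best_pair)

    @pytest.mark.parametrize("seed", range(6))
    def test_step1_matches_bruteforce_singleton_argmax(self, seed):
        rng = np.random.default_rng(seed)
        emb, grid = disjoint_instance(rng)
        k = int(rng.integers(2, 6))
        idx = build_index(emb, k=k)
        res = cgs(emb, grid, [emb.patch_size], k=k, index=idx)
        cands = enumerate_candidates(grid, emb.patch_size)
        scores = [ccr(m, idx) for _, m in cands]
        best = int(np.argmax(scores))  # first max = lexicographic tie rule
        assert res.chosen[0] == cands[best][0]

    def test_incremental_mask_matches_scratch_recompute(self, rng):
        emb, grid = disjoint_instance(rng, n_patches=10)
        idx = build_index(emb, k=3)
        res = cgs(emb, grid, [emb.patch_size] * 4, index=idx)
        rows = []
        for step, members in enumerate(res.chosen_patch_indices):
            rows.extend(members)
            assert res.ccr_trace[step] == pytest.approx(ccr(rows, idx))
        np.testing.assert_array_equal(res.covered_mask, covered(rows, idx))

    def test_deterministic(self, rng):
        emb, grid = disjoint_instance(rng)
        r1 = cgs(emb, grid, [emb.patch_size] * 3, k=3)
        r2 = cgs(emb, grid, [emb.patch_size] * 3, k=3)
        assert r1.chosen == r2.chosen and r1.ccr_trace == r2.ccr_trace

    def test_space_exhausted_raises(self, six_points):
        grid = PatchGrid.build((8, 40, 240), (8, 40, 40), (8, 40, 40))
        with pytest.raises(RuntimeError):
            cgs(six_points, grid, [(8, 40, 240), (8, 40, 240)], k=2)


class TestBaselines:
    def test_budget_one_single_candidate_both_return_it(self, six_points):
        grid = PatchGrid.build((8, 40, 240), (8, 40, 40), (8, 40, 40))
        size = (8, 40, 240)
        spec = SubVolumeSpec((0, 0, 0), size)
        assert random_select(grid, [size], seed=1).chosen == [spec]
        assert equispaced_select(grid, [size]).chosen == [spec]

    def test_random_seeded_reproducible(self, rng):
        emb, grid = disjoint_instance(rng)
        r1 = random_select(grid, [emb.patch_size] * 3, seed=5)
        r2 = random_select(grid, [emb.patch_size] * 3, seed=5)
        assert r1.chosen == r2.chosen

    def test_random_choices_never_overlap(self, rng):
        grid = PatchGrid.build((16, 80, 80), (8, 40, 40), (8, 40, 40))
        res = random_select(grid, [(8, 40, 40)] * 4, seed=9)
        for a, b in itertools.combinations(res.chosen, 2):
            assert not a.overlaps(b)

    def test_equispaced_lattice_arithmetic(self):
        grid = PatchGrid.build((16, 80, 80), (8, 40, 40), (8, 40, 40))
        res = equispaced_select(grid, [(8, 80, 80)] * 2)
        assert sorted(s.origin[0] for s in res.chosen) == [0, 8]
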