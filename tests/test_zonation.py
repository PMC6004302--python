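from itertools import combinations

import numpy as np
import pytest

import paleozone as pz
from paleozone.resemblance import euclidean_matrix
from paleozone.zonation import coniss, broken_stick_select, broken_stick_table, cut

from conftest import random_dissimilarity


def block_profile(rng, sizes, separations, noise=0.1):
    """1-D profile of well-separated level blocks -> Euclidean matrix."""
    vals = np.concatenate(
        [lvl + noise * rng.standard_normal(n) for n, lvl in zip(sizes, separations)]
    )
    return euclidean_matrix(vals)


def dispersion_of_partition(d, bounds):
    """Within-zone dispersion sum for a contiguous partition (oracle)."""
    total = 0.0
    start = 0
    for b in list(bounds) + [d.shape[0] - 1]:
        idx = range(start, b + 1)
        s = sum(d[i, j] for i in idx for j in idx if i < j)
        total += s / (b + 1 - start)
        start = b + 1
    return total


def exhaustive_best_partition(d, k):
    """Minimum within-zone dispersion over all contiguous k-partitions."""
    n = d.shape[0]
    best = np.inf
    for bounds in combinations(range(n - 1), k - 1):
        best = min(best, dispersion_of_partition(d, bounds))
    return best


class TestConiss:
    def test_two_block_data_final_merge_joins_blocks(self):
        rng = np.random.default_rng(0)
        m = block_profile(rng, [5, 5], [0.0, 10.0])
        tree = coniss(m)
        zones = tree.zones(2)
        assert zones.tolist() == [2] * 5 + [1] * 5

    def test_contiguity_on_random_data(self):
        rng = np.random.default_rng(1)
        tree = coniss(random_dissimilarity(rng, 12))
        for merge in tree.merges:
            # each merged block is an unbroken run adjacent to its partner
            assert merge.left[1] + 1 == merge.right[0]
        for k in range(1, 13):
            z = tree.zones(k)
            assert np.all(np.diff(z) <= 0)  # labels change monotonically

    def test_heights_monotone_nondecreasing(self):
        rng = np.random.default_rng(2)
        tree = coniss(random_dissimilarity(rng, 10))
        assert np.all(np.diff(tree.heights) >= -1e-12)

    def test_reversed_core_same_boundaries(self):
        rng = np.random.default_rng(3)
        vals = rng.random(9)
        a = coniss(euclidean_matrix(vals))
        b = coniss(euclidean_matrix(vals[::-1]))
        n = 9
        for k in (2, 3, 4):
            bounds_a = set(a.boundaries(k))
            bounds_b = {n - 2 - x for x in b.boundaries(k)}
            assert bounds_a == bounds_b

    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_never_beats_exhaustive_contiguous_optimum(self, k):
        rng = np.random.default_rng(4)
        for _ in range(5):
            m = random_dissimilarity(rng, 9)
            tree = coniss(m)
            got = dispersion_of_partition(m.values, tree.boundaries(k))
            best = exhaustive_best_partition(m.values, k)
            assert got >= best - 1e-9

    def test_matches_exhaustive_on_well_separated_blocks(self):
        rng = np.random.default_rng(5)
        m = block_profile(rng, [3, 4, 3], [0.0, 10.0, 25.0], noise=0.05)
        tree = coniss(m)
        got = dispersion_of_partition(m.values, tree.boundaries(3))
        best = exhaustive_best_partition(m.values, 3)
        assert got == pytest.approx(best, rel=1e-9)
        assert tree.boundaries(3) == [2, 6]

    def test_requires_dissimilarity_kind(self, lake_bc_raw):
        sim = pz.convert(lake_bc_raw, "similarity")
        with pytest.raises(ValueError):
            coniss(sim)


class TestBrokenStick:
    def test_three_block_data_selects_three_zones(self):
        rng = np.random.default_rng(6)
        m = block_profile(rng, [5, 5, 5], [0.0, 10.0, 25.0], noise=0.2)
        tree = coniss(m)
        assert broken_stick_select(tree) == 3

    def test_pure_noise_selects_one_zone_in_majority(self):
        # noise model matching the method's use case: exchangeable random
        # compositions (no depth structure) under Bray-Curtis
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            vals = rng.dirichlet(np.full(10, 5.0), size=30)
            c = pz.AssemblageCounts(
                [f"s{i}" for i in range(30)],
                [f"t{j}" for j in range(10)],
                np.arange(30, dtype=float),
                np.arange(1, 31, dtype=float),
                vals,
                mode="transformed",
            )
            if broken_stick_select(coniss(pz.bray_curtis(c))) == 1:
                hits += 1
        assert hits > 25

    def test_expected_column_is_broken_stick(self):
        rng = np.random.default_rng(7)
        tree = coniss(random_dissimilarity(rng, 10))
        table = broken_stick_table(tree)
        n = 10
        for _, row in table.iterrows():
            k = int(row["k"])
            assert row["expected"] == pytest.approx(
                sum(1.0 / i for i in range(k, n + 1)) / n
            )

    def test_max_k_validation(self, lake_bc_raw):
        tree = coniss(lake_bc_raw)
        with pytest.raises(ValueError):
            broken_stick_table(tree, 31)


class TestCut:
    def test_extreme_cuts(self):
        rng = np.random.default_rng(8)
        tree = coniss(random_dissimilarity(rng, 7))
        assert cut(tree, k=1).tolist() == [1] * 7
        assert sorted(cut(tree, k=7).tolist()) == list(range(1, 8))

    def test_height_cut_equals_k_cut(self):
        rng = np.random.default_rng(9)
        tree = coniss(random_dissimilarity(rng, 8))
        h = (tree.heights[4] + tree.heights[5]) / 2  # between merges 5 and 6
        assert cut(tree, height=h).tolist() == cut(tree, k=8 - 5).tolist()

    def test_invalid_arguments(self, lake_bc_raw):
        tree = coniss(lake_bc_raw)
        with pytest.raises(ValueError):
            cut(tree)
        with pytest.raises(ValueError):
            cut(tree, k=0)
        with pytest.raises(ValueError):
            cut(tree, height=-1.0)


class TestLakeZonation:
    def test_three_zones_with_printed_memberships(self, lake_bc_raw):
        tree = coniss(lake_bc_raw)
        assert broken_stick_select(tree) == 3
        zones = tree.zones(3)
        sizes = np.bincount(zones)[1:]
        assert sizes.tolist() == [14, 10, 6]
        assert tree.boundaries(3) == [5, 15]  # after samples 6 and 16

    def test_sqrt_matrix_shifts_one_boundary(self, lake_bc_sqrt):
        # with the sqrt-transformed matrix the shallow/middle boundary moves
        # by one sample; documented sensitivity to the printed rounding
        tree = coniss(lake_bc_sqrt)
        assert tree.boundaries(3) == [6, 15]
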