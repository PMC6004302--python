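from itertools import permutations

import numpy as np
import pytest
from scipy.stats import rankdata, spearmanr

import paleozone as pz
from paleozone.inference import anosim, anosim_exhaustive_p, relate, spearman_profiles
from paleozone.resemblance import euclidean_matrix

from conftest import random_dissimilarity


def anosim_r_reference(d, groups):
    """Independent R computation straight from the definition."""
    n = d.shape[0]
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ranks = rankdata([d[i, j] for i, j in pairs])
    within = [r for r, (i, j) in zip(ranks, pairs) if groups[i] == groups[j]]
    between = [r for r, (i, j) in zip(ranks, pairs) if groups[i] != groups[j]]
    m = len(pairs)
    return (np.mean(between) - np.mean(within)) / (m / 2)


class TestAnosim:
    def test_perfect_separation_r_is_one(self):
        vals = np.array([0.0, 0.1, 0.2, 0.3, 5.0, 5.1, 5.2, 5.3])
        m = euclidean_matrix(vals)
        res = anosim(m, [0, 0, 0, 0, 1, 1, 1, 1], n_perm=999, seed=0)
        assert res.value == pytest.approx(1.0)
        assert res.p_value <= 0.05

    def test_matches_reference_implementation(self):
        rng = np.random.default_rng(10)
        m = random_dissimilarity(rng, 9)
        groups = np.array([0, 0, 1, 1, 1, 2, 2, 2, 0])
        res = anosim(m, groups, n_perm=0)
        assert res.value == pytest.approx(anosim_r_reference(m.values, groups))

    def test_cross_check_against_scikit_bio(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(11)
        m = random_dissimilarity(rng, 10)
        groups = ["a"] * 5 + ["b"] * 5
        ours = anosim(m, groups, n_perm=0).value
        dm = skbio_distance.DistanceMatrix(m.values, ids=m.sample_ids)
        theirs = skbio_distance.anosim(dm, grouping=groups, permutations=0)
        assert ours == pytest.approx(theirs["test statistic"], abs=1e-12)

    def test_null_mean_r_near_zero(self):
        vals = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            m = random_dissimilarity(rng, 10)
            groups = rng.permutation([0] * 5 + [1] * 5)
            vals.append(anosim(m, groups, n_perm=0).value)
        assert abs(np.mean(vals)) < 0.05

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(12)
        m = random_dissimilarity(rng, 8)
        groups = [0, 0, 0, 0, 1, 1, 1, 1]
        r1 = anosim(m, groups, n_perm=0).value
        m2 = pz.ResemblanceMatrix(m.sample_ids, m.values**3, coefficient="random")
        r2 = anosim(m2, groups, n_perm=0).value
        assert r1 == pytest.approx(r2)

    def test_permutation_p_matches_exhaustive_for_five_samples(self):
        rng = np.random.default_rng(13)
        m = random_dissimilarity(rng, 5)
        groups = np.array([0, 0, 1, 1, 1])
        # oracle: enumerate all 10 distinct relabelings directly
        d = m.values
        observed = anosim_r_reference(d, groups)
        stats = []
        for perm in set(permutations(groups)):
            stats.append(anosim_r_reference(d, np.array(perm)))
        exact = np.mean([s >= observed - 1e-12 for s in stats])
        assert len(stats) == 10
        assert anosim_exhaustive_p(m, groups) == pytest.approx(exact)
        res = anosim(m, groups, n_perm=1999, seed=3)
        assert res.p_value == pytest.approx(exact, abs=0.05)

    def test_degenerate_grouping_rejected(self):
        rng = np.random.default_rng(14)
        m = random_dissimilarity(rng, 4)
        with pytest.raises(ValueError):
            anosim(m, [0, 0, 0, 0], n_perm=0)
        with pytest.raises(ValueError):
            anosim(m, [0, 0, 0, 1], n_perm=0)

    def test_seeded_stream_reproducible(self):
        rng = np.random.default_rng(15)
        m = random_dissimilarity(rng, 8)
        groups = [0] * 4 + [1] * 4
        a = anosim(m, groups, n_perm=199, seed=7)
        b = anosim(m, groups, n_perm=199, seed=7)
        assert a.p_value == b.p_value


class TestRelate:
    def test_self_correlation_is_one(self):
        rng = np.random.default_rng(16)
        m = random_dissimilarity(rng, 6)
        assert relate(m, m, n_perm=0).value == pytest.approx(1.0)

    def test_symmetry(self):
        rng = np.random.default_rng(17)
        a = random_dissimilarity(rng, 7)
        b = random_dissimilarity(rng, 7)
        assert relate(a, b, n_perm=0).value == pytest.approx(
            relate(b, a, n_perm=0).value
        )

    def test_hand_computed_four_samples(self):
        a = euclidean_matrix([0.0, 1.0, 3.0, 6.0])
        b = euclidean_matrix([0.0, 2.0, 5.0, 9.0])
        iu = np.triu_indices(4, 1)
        expected = spearmanr(a.values[iu], b.values[iu]).statistic
        assert relate(a, b, n_perm=0).value == pytest.approx(expected)

    def test_cross_check_against_skbio_mantel(self):
        skbio_distance = pytest.importorskip("skbio.stats.distance")
        rng = np.random.default_rng(18)
        a = random_dissimilarity(rng, 9)
        b = random_dissimilarity(rng, 9)
        ours = relate(a, b, n_perm=0).value
        corr, _, _ = skbio_distance.mantel(
            skbio_distance.DistanceMatrix(a.values),
            skbio_distance.DistanceMatrix(b.values),
            method="spearman",
            permutations=0,
        )
        assert ours == pytest.approx(corr, abs=1e-12)

    def test_size_mismatch_and_constant_matrix(self):
        rng = np.random.default_rng(19)
        a = random_dissimilarity(rng, 5)
        b = random_dissimilarity(rng, 6)
        with pytest.raises(ValueError):
            relate(a, b, n_perm=0)
        const = euclidean_matrix([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            relate(a, const, n_perm=0)

    def test_lake_minerogenics_rho(self, lake_bc_sqrt):
        loi = pz.frame_lake_loi()
        env = euclidean_matrix(loi.minerogenics, lake_bc_sqrt.sample_ids)
        res = relate(lake_bc_sqrt, env, n_perm=999, seed=1)
        assert res.value == pytest.approx(0.2204, abs=1e-3)
        assert res.p_value < 0.05


class TestSpearmanProfiles:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert spearman_profiles(x, x).value == pytest.approx(1.0)
        assert spearman_profiles(x, -x).value == pytest.approx(-1.0)

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            spearman_profiles([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])

    def test_permutation_p_consistent_with_analytic(self):
        rng = np.random.default_rng(20)
        x = rng.standard_normal(40)
        y = 0.7 * x + 0.5 * rng.standard_normal(40)
        res = spearman_profiles(x, y, n_perm=999, seed=2)
        assert res.extra["analytic_p"] < 0.01
        assert res.extra["permutation_p"] < 0.01


class TestPValueCalibration:
    def test_permutation_p_super_uniform_under_null(self):
        """Across 200 seeded null replicates, P(p <= alpha) stays near or
        below alpha (the add-one correction makes the test conservative)."""
        ps = []
        for seed in range(200):
            rng = np.random.default_rng(seed)
            m = random_dissimilarity(rng, 10)
            groups = rng.permutation([0] * 5 + [1] * 5)
            ps.append(anosim(m, groups, n_perm=99, seed=seed + 1).p_value)
        ps = np.array(ps)
        for alpha in (0.05, 0.10, 0.25):
            assert (ps <= alpha).mean() <= alpha + 0.07
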