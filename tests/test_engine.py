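"""Clustering engine: oracle equivalence, cuts, dendrogram comparison."""

import numpy as np
import pytest

from bandclust import (BandSimilarity, Dendrogram, cluster, cut,
                       first_difference_index, naive_cluster)
from bandclust.engine import _agglomerate
from conftest import random_band


def ess_constrained_oracle(X):
    """Brute-force adjacency-constrained Ward on points, classical ESS."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[0] == 1:
        X = X.T

    def ess(idx):
        V = X[idx]
        return ((V - V.mean(0)) ** 2).sum()

    clusters = [[i] for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a in range(len(clusters) - 1):
            d = (ess(clusters[a] + clusters[a + 1])
                 - ess(clusters[a]) - ess(clusters[a + 1]))
            key = (d, clusters[a][0])
            if best is None or key < best[0]:
                best = (key, a)
        (d, _), a = best
        merges.append((clusters[a][0], clusters[a + 1][0], d))
        clusters[a:a + 2] = [clusters[a] + clusters[a + 1]]
    return merges


class TestCluster:
    def test_two_objects_single_merge(self, rng):
        B = random_band(2, 2, rng)
        d = cluster(B)
        assert d.n_merges == 1
        assert (d.start[0], d.mid[0], d.end[0]) == (0, 1, 2)
        assert d.left_ref[0] == -1 and d.right_ref[0] == -2

    def test_identity_similarity_leftmost_tiebreak_cascade(self):
        # with h=1 every adjacent linkage equals 1 at every step, so the
        # smaller-left-boundary tie-break produces a pure left cascade
        d = cluster(BandSimilarity.from_dense(np.eye(4), h=1))
        assert [(s, m) for s, m in zip(d.start, d.mid)] == \
            [(0, 1), (0, 2), (0, 3)]
        np.testing.assert_allclose(d.height, 1.0)

    def test_matches_naive_oracle_on_random_instances(self):
        for seed in range(30):
            rng = np.random.default_rng(seed)
            p = int(rng.integers(5, 61))
            h = int(rng.integers(2, p + 1))
            B = random_band(p, h, rng)
            d1, d2 = cluster(B), naive_cluster(B.to_dense())
            np.testing.assert_array_equal(d1.start, d2.start)
            np.testing.assert_array_equal(d1.mid, d2.mid)
            np.testing.assert_array_equal(d1.end, d2.end)
            np.testing.assert_array_equal(d1.left_ref, d2.left_ref)
            np.testing.assert_allclose(d1.height, d2.height, atol=1e-10)

    def test_heights_match_euclidean_ess_oracle(self, rng):
        X = rng.normal(size=(15, 3))
        d = cluster(BandSimilarity.from_dense(X @ X.T))
        oracle = ess_constrained_oracle(X)
        assert [(int(s), int(m)) for s, m in zip(d.start, d.mid)] == \
            [(a, b) for a, b, _ in oracle]
        np.testing.assert_allclose(d.height, [h for _, _, h in oracle],
                                   atol=1e-8)

    def test_partition_invariant_maintained_every_step(self, rng):
        # active fusions always chain into a contiguous partition
        B = random_band(40, 6, rng)
        _agglomerate(B, check=True)

    def test_lazy_deletions_bounded_by_2p(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            p = int(rng.integers(10, 80))
            B = random_band(p, min(5, p), rng)
            d = cluster(B)
            assert d._n_lazy_deletions <= 2 * p

    def test_single_object_raises(self):
        with pytest.raises(ValueError, match="at least 2"):
            cluster(BandSimilarity(np.ones((1, 1))))

    def test_negative_heights_logged(self, rng, caplog):
        B = random_band(20, 5, rng)  # mixed signs: not PSD
        with caplog.at_level("WARNING"):
            cluster(B)
        assert "not positive semidefinite" in caplog.text


class TestNaiveCluster:
    def test_three_collinear_points_first_merge(self):
        X = np.array([[0.0], [1.0], [10.0]])
        d = naive_cluster(X @ X.T)
        assert (d.start[0], d.mid[0]) == (0, 1)
        assert d.height[0] == pytest.approx(0.5)  # ||0-1||^2 / 2

    def test_band_exactness(self):
        # true bandwidth h0: any h >= h0 gives the identical hierarchy
        for seed in range(10):
            rng = np.random.default_rng(seed)
            p = int(rng.integers(10, 50))
            h0 = int(rng.integers(2, p // 2 + 2))
            M = random_band(p, h0, rng, low=0, high=1).to_dense()
            d_h0 = cluster(BandSimilarity.from_dense(M, h=h0))
            d_p = cluster(BandSimilarity.from_dense(M, h=p))
            assert first_difference_index(d_h0, d_p) == 1.0
            np.testing.assert_allclose(d_h0.height, d_p.height, atol=1e-10)


class TestCut:
    @pytest.mark.parametrize("K, expected", [
        (1, [1, 1, 1, 1, 1, 1]),
        (6, [1, 2, 3, 4, 5, 6]),
        (2, [1, 1, 1, 2, 2, 2]),
    ])
    def test_block_similarity_cuts(self, K, expected):
        S = np.kron(np.eye(2), np.ones((3, 3)))
        d = cluster(BandSimilarity.from_dense(S))
        np.testing.assert_array_equal(cut(d, K), expected)

    def test_out_of_range_raises(self, rng):
        d = cluster(random_band(5, 2, rng))
        for K in (0, 6):
            with pytest.raises(ValueError):
                d.cut(K)

    def test_labels_are_contiguous_blocks(self, rng):
        d = cluster(random_band(30, 5, rng))
        for K in range(1, 31):
            lab = d.cut(K)
            assert lab[0] == 1 and lab.max() == K
            assert np.all(np.isin(np.diff(lab), (0, 1)))


class TestFirstDifferenceIndex:
    def test_self_comparison_is_one(self, rng):
        d = cluster(random_band(12, 4, rng))
        assert first_difference_index(d, d) == 1.0

    def test_difference_at_first_step_is_zero(self):
        d1 = cluster(BandSimilarity.from_dense(np.diag([1.0, 1, 1, 5])))
        d2 = cluster(BandSimilarity.from_dense(np.diag([5.0, 1, 1, 1])))
        assert first_difference_index(d1, d2) == 0.0

    def test_mismatched_p_raises(self, rng):
        d1 = cluster(random_band(5, 2, rng))
        d2 = cluster(random_band(6, 2, rng))
        with pytest.raises(ValueError):
            first_difference_index(d1, d2)


class TestExports:
    def test_merge_table_round_trip(self, rng):
        d = cluster(random_band(15, 4, rng))
        d2 = Dendrogram.from_table(d.to_table())
        assert first_difference_index(d, d2) == 1.0
        np.testing.assert_allclose(d.height, d2.height)

    def test_newick_parses_and_has_all_leaves(self, rng):
        import io as _io

        from Bio import Phylo

        B = random_band(10, 3, rng, low=0, high=1)
        nwk = cluster(B).to_newick()
        tree = Phylo.read(_io.StringIO(nwk), "newick")
        names = sorted(t.name for t in tree.get_terminals())
        assert names == sorted(f"L{i}" for i in range(1, 11))

    def test_scipy_linkage_shape_and_sizes(self, rng):
        d = cluster(random_band(9, 3, rng, low=0, high=1))
        Z = d.to_scipy_linkage()
        assert Z.shape == (8, 4)
        assert Z[-1, 3] == 9
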