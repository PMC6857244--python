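"""Band similarity construction, querying, and diagonal shifts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bandclust import BandSimilarity, cluster, naive_cluster
from conftest import random_band


class TestFromDense:
    def test_identity_bandwidth_one(self):
        B = BandSimilarity.from_dense(np.eye(3), h=1)
        assert B.p == 3 and B.h == 1
        assert [B.get(i, i) for i in range(3)] == [1, 1, 1]
        assert B.get(0, 1) == 0.0

    def test_strict_rejects_out_of_band(self):
        with pytest.raises(ValueError, match="outside bandwidth"):
            BandSimilarity.from_dense(np.ones((3, 3)), h=2, strict=True)

    def test_nonstrict_drops_out_of_band(self):
        B = BandSimilarity.from_dense(np.ones((3, 3)), h=2)
        assert B.get(0, 2) == 0.0 and B.get(0, 1) == 1.0

    def test_full_bandwidth_round_trip(self, rng):
        A = rng.normal(size=(10, 10))
        M = A + A.T
        B = BandSimilarity.from_dense(M, h=10)
        np.testing.assert_array_equal(B.to_dense(), M)

    @pytest.mark.parametrize("bad, match", [
        (np.ones((2, 3)), "square"),
        (np.array([[0.0, 1.0], [0.0, 0.0]]), "asymmetric"),
        (np.array([[np.inf, 0.0], [0.0, 0.0]]), "finite"),
    ])
    def test_invalid_dense_inputs(self, bad, match):
        with pytest.raises(ValueError, match=match):
            BandSimilarity.from_dense(bad)

    @pytest.mark.parametrize("h", [0, 5])
    def test_bandwidth_out_of_range(self, h):
        with pytest.raises(ValueError, match="1 <= h <= p"):
            BandSimilarity.from_dense(np.eye(3), h=h)


class TestFromTriplets:
    def test_single_offdiagonal_entry_warns_on_missing_diagonal(self, caplog):
        with caplog.at_level("WARNING"):
            B = BandSimilarity.from_triplets([(1, 2, 0.5)], p=3, h=2)
        assert B.get(0, 1) == 0.5 and B.get(1, 0) == 0.5
        assert all(B.get(i, i) == 0.0 for i in range(3))
        assert "diagonal" in caplog.text

    def test_empty_triplets_give_zero_similarity(self):
        B = BandSimilarity.from_triplets([], p=2, h=2)
        np.testing.assert_array_equal(B.to_dense(), np.zeros((2, 2)))

    def test_matches_dense_construction(self, rng):
        p, h = 12, 4
        trips = []
        M = np.zeros((p, p))
        for _ in range(50):
            i = int(rng.integers(0, p))
            j = int(rng.integers(max(0, i - h + 1), min(p, i + h)))
            if M[i, j]:
                continue
            v = float(rng.uniform(-1, 1))
            M[i, j] = M[j, i] = v
            trips.append((i + 1, j + 1, v))
        B = BandSimilarity.from_triplets(trips, p=p, h=h)
        ref = BandSimilarity.from_dense(M, h=h)
        np.testing.assert_array_equal(B.band, ref.band)

    def test_conflicting_duplicates_raise(self):
        with pytest.raises(ValueError, match="conflicting"):
            BandSimilarity.from_triplets([(1, 2, 0.5), (2, 1, 0.6)],
                                         p=3, h=3)
        # agreeing mirror entries are fine
        B = BandSimilarity.from_triplets([(1, 2, 0.5), (2, 1, 0.5)],
                                         p=3, h=3)
        assert B.get(0, 1) == 0.5

    def test_index_out_of_range(self):
        with pytest.raises(ValueError, match="out of range"):
            BandSimilarity.from_triplets([(0, 1, 1.0)], p=3, h=3)


class TestFromDissimilarity:
    def test_identical_objects_give_zero_linkages(self):
        B = BandSimilarity.from_dissimilarity(np.zeros((4, 4)))
        d = cluster(B)
        np.testing.assert_allclose(d.height, 0.0, atol=1e-12)

    def test_two_points_hand_computed(self):
        D = np.array([[0.0, 2.0], [2.0, 0.0]])
        B = BandSimilarity.from_dissimilarity(D)
        assert B.get(0, 0) == 2.0 and B.get(1, 1) == 2.0
        assert B.get(0, 1) == 0.0
        assert cluster(B).height[0] == pytest.approx(2.0)

    def test_line_points_match_classical_ward(self, rng):
        # sorted 1-D points: hierarchy must equal classical Ward HAC
        from scipy.cluster.hierarchy import ward

        x = np.sort(rng.uniform(0, 10, 10))
        D = np.abs(x[:, None] - x[None, :])
        d = cluster(BandSimilarity.from_dissimilarity(D))
        ess_heights = np.sort(ward(x.reshape(-1, 1))[:, 2] ** 2 / 2)
        np.testing.assert_allclose(np.sort(d.height), ess_heights,
                                   atol=1e-10)

    @pytest.mark.parametrize("D, match", [
        (np.array([[0.0, -1.0], [-1.0, 0.0]]), "nonnegative"),
        (np.array([[1.0, 2.0], [2.0, 0.0]]), "diagonal"),
    ])
    def test_invalid_dissimilarity(self, D, match):
        with pytest.raises(ValueError, match=match):
            BandSimilarity.from_dissimilarity(D)


class TestShiftDiagonal:
    def test_zero_shift_is_identity(self, rng):
        B = random_band(8, 3, rng)
        np.testing.assert_array_equal(B.shift_diagonal(0.0).band, B.band)

    def test_identity_two_by_two(self):
        B = BandSimilarity.from_dense(np.eye(2)).shift_diagonal(3.0)
        assert B.get(0, 0) == 4.0 and B.get(0, 1) == 0.0
        assert cluster(B).height[0] == pytest.approx(4.0)  # 1 + 3

    @pytest.mark.parametrize("lam", [-2.0, 0.5, 10.0])
    def test_shift_preserves_merge_order_shifts_heights(self, lam, rng):
        # Miyamoto: S + lam*I yields the same hierarchy, heights + lam
        for seed in range(20):
            r = np.random.default_rng(seed)
            p = int(r.integers(5, 41))
            h = int(r.integers(2, p + 1))
            B = random_band(p, h, r)
            d0, d1 = cluster(B), cluster(B.shift_diagonal(lam))
            np.testing.assert_array_equal(d0.mid, d1.mid)
            np.testing.assert_array_equal(d0.start, d1.start)
            np.testing.assert_allclose(d1.height - d0.height, lam,
                                       atol=1e-8)

    def test_uniform_shift_of_all_entries_preserves_linkages(self, rng):
        # adding a constant to EVERY entry cancels in the Ward linkage
        A = rng.normal(size=(12, 12))
        M = A + A.T
        d0 = naive_cluster(M)
        d1 = naive_cluster(M + 7.3)
        np.testing.assert_array_equal(d0.mid, d1.mid)
        np.testing.assert_allclose(d0.height, d1.height, atol=1e-10)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(min_value=1, max_value=15), st.integers(min_value=0))
def test_round_trip_dense_band_dense(p_h, seed):
    """dense -> band -> dense is exact at full bandwidth."""
    rng = np.random.default_rng(seed)
    p = p_h
    A = rng.normal(size=(p, p))
    M = A + A.T
    B = BandSimilarity.from_dense(M, h=p)
    np.testing.assert_array_equal(B.to_dense(), M)
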