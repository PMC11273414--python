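"""Hamming index against a brute-force oracle; AP/MAP against hand
evaluation and exhaustive enumeration."""

import itertools

import numpy as np
import pytest

from dafh.retrieval import (RetrievalIndex, average_precision, evaluate,
                            hamming, map1_confusion, mean_average_precision,
                            pack_codes, read_code_table, unpack_codes,
                            write_code_table)


def random_codes(rng, n, length):
    return np.where(rng.uniform(size=(n, length)) > 0.5, 1.0, -1.0)


class TestHamming:
    def test_identity_complement_and_direct_count(self):
        rng = np.random.default_rng(0)
        a = random_codes(rng, 1, 16)[0]
        assert hamming(a, a) == 0
        assert hamming(a, -a) == 16
        assert hamming(np.array([1, -1, 1, 1]), np.array([1, 1, -1, 1])) == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            hamming(np.ones(16), np.ones(32))

    @pytest.mark.parametrize("length", [16, 32, 48])
    def test_pack_unpack_roundtrip(self, length):
        rng = np.random.default_rng(length)
        codes = random_codes(rng, 20, length)
        packed, got_length = pack_codes(codes)
        assert got_length == length
        assert np.array_equal(unpack_codes(packed, length), codes)

    @pytest.mark.parametrize("length", [16, 32, 48])
    def test_popcount_equals_elementwise_count(self, length):
        rng = np.random.default_rng(100 + length)
        a, b = random_codes(rng, 2, length)
        assert hamming(a, b) == int((a != b).sum())


class TestQuery:
    def test_exact_match_ranks_first(self):
        rng = np.random.default_rng(1)
        codes = random_codes(rng, 30, 16)
        codes[17] = codes[4]  # duplicate: lowest index among exact matches wins
        index = RetrievalIndex.from_codes(codes, np.zeros(30))
        ranked = index.query(codes[4])
        assert ranked.order[0] == 4
        assert ranked.distances[0] == 0

    def test_full_ranking_is_total_and_sorted(self):
        rng = np.random.default_rng(2)
        codes = random_codes(rng, 25, 16)
        index = RetrievalIndex.from_codes(codes, np.zeros(25))
        ranked = index.query(codes[0], k=25)
        assert sorted(ranked.order.tolist()) == list(range(25))
        assert np.all(np.diff(ranked.distances) >= 0)

    def test_k_clamped_to_index_size(self):
        rng = np.random.default_rng(3)
        codes = random_codes(rng, 5, 16)
        index = RetrievalIndex.from_codes(codes, np.zeros(5))
        assert len(index.query(codes[0], k=50).order) == 5

    @pytest.mark.parametrize("length", [16, 32, 48])
    def test_matches_brute_force_stable_sort_oracle(self, length):
        rng = np.random.default_rng(200 + length)
        for trial in range(25):
            n = int(rng.integers(2, 201))
            codes = random_codes(rng, n, length)
            q = random_codes(rng, 1, length)[0]
            index = RetrievalIndex.from_codes(codes, np.zeros(n))
            ranked = index.query(q)
            # oracle: elementwise mismatch counts + python stable sort
            dists = [(int((codes[i] != q).sum()), i) for i in range(n)]
            oracle_order = [i for _, i in sorted(dists, key=lambda t: t[0])]
            assert ranked.order.tolist() == oracle_order

    def test_code_length_mismatch_rejected(self):
        index = RetrievalIndex.from_codes(np.ones((3, 16)), np.zeros(3))
        with pytest.raises(ValueError, match="bits"):
            index.query(np.ones(32))

    def test_empty_index_rejected(self):
        index = RetrievalIndex(packed=np.zeros((0, 1), dtype=np.uint64),
                               length=16, labels=np.zeros(0, dtype=int))
        with pytest.raises(ValueError, match="empty"):
            index.query(np.ones(16))

    def test_index_save_load_roundtrip(self, tmp_path):
        rng = np.random.default_rng(4)
        codes = random_codes(rng, 10, 48)
        index = RetrievalIndex.from_codes(codes, np.arange(10) % 3,
                                          [f"id{i}" for i in range(10)])
        index.save(tmp_path / "idx")
        back = RetrievalIndex.load(tmp_path / "idx")
        assert back.length == 48
        assert np.array_equal(back.packed, index.packed)
        assert np.array_equal(back.labels, index.labels)
        assert back.ids == index.ids


def oracle_ap(relevance, n_gt):
    """Brute-force AP: explicit loop over ranks."""
    total = 0.0
    hits = 0
    for k, r in enumerate(relevance, start=1):
        if r:
            hits += 1
            total += hits / k
    return total / n_gt


class TestAveragePrecision:
    @pytest.mark.parametrize("relevance,n_gt,expected", [
        ([1, 1], 2, 1.0),
        ([0, 1], 1, 0.5),
        ([1, 0, 1], 2, (1.0 + 2.0 / 3.0) / 2.0),
        ([0, 0, 0], 3, 0.0),
        ([1], 1, 1.0),
    ])
    def test_hand_evaluated_rankings(self, relevance, n_gt, expected):
        assert average_precision(relevance, n_gt) == pytest.approx(expected, abs=1e-12)

    def test_zero_ground_truth_rejected(self):
        with pytest.raises(ValueError, match="n_gt=0"):
            average_precision([0, 0], 0)

    def test_more_relevant_than_n_gt_rejected(self):
        with pytest.raises(ValueError):
            average_precision([1, 1, 1], 2)

    def test_swapping_relevant_earlier_never_decreases_ap(self):
        # exhaustive over all binary rankings of length <= 6
        for n in range(1, 7):
            for bits in itertools.product([0, 1], repeat=n):
                n_rel = sum(bits)
                if n_rel == 0:
                    continue
                ap = average_precision(list(bits), n_rel)
                for i in range(n - 1):
                    if bits[i] == 0 and bits[i + 1] == 1:
                        swapped = list(bits)
                        swapped[i], swapped[i + 1] = 1, 0
                        assert average_precision(swapped, n_rel) >= ap - 1e-15

    def test_matches_loop_oracle_exactly(self, rng):
        for _ in range(200):
            n = int(rng.integers(1, 30))
            rel = (rng.uniform(size=n) > 0.6).astype(int)
            n_gt = int(rel.sum() + rng.integers(0, 5))
            if n_gt == 0:
                continue
            assert average_precision(rel, n_gt) == pytest.approx(
                oracle_ap(rel, n_gt), abs=1e-12)


class TestMeanAveragePrecision:
    def test_single_query_equals_its_ap(self):
        rel = [1, 0, 1, 0]
        assert mean_average_precision([rel], [2]) == pytest.approx(
            average_precision(rel, 2), abs=1e-15)

    def test_map_at_1_is_top1_accuracy(self, rng):
        rels, n_gts, top1 = [], [], []
        for _ in range(50):
            rel = (rng.uniform(size=10) > 0.5).astype(int)
            if rel.sum() == 0:
                rel[3] = 1
            rels.append(rel)
            n_gts.append(int(rel.sum()))
            top1.append(rel[0])
        assert mean_average_precision(rels, n_gts, k=1) == pytest.approx(
            np.mean(top1), abs=1e-12)

    def test_matches_brute_force_oracle_at_depth(self, rng):
        for _ in range(100):
            q = int(rng.integers(1, 6))
            k = int(rng.integers(1, 8))
            rels, n_gts, expected = [], [], []
            for _ in range(q):
                n = int(rng.integers(k, 20))
                rel = (rng.uniform(size=n) > 0.5).astype(int)
                n_gt = max(1, int(rel.sum()))
                rels.append(rel)
                n_gts.append(n_gt)
                expected.append(oracle_ap(rel[:k], min(n_gt, k)))
            got = mean_average_precision(rels, n_gts, k=k)
            assert got == pytest.approx(np.mean(expected), abs=1e-12)

    def test_raw_normalization_flag(self):
        # perfect top-1 list but 5 database relevants: raw Eq gives 1/5
        assert mean_average_precision([[1]], [5], k=1,
                                      truncated_normalization=False) == \
            pytest.approx(0.2, abs=1e-15)
        assert mean_average_precision([[1]], [5], k=1) == pytest.approx(1.0)

    def test_perfect_and_empty_retrieval_bounds(self):
        assert mean_average_precision([[1, 1, 1]], [3]) == 1.0
        assert mean_average_precision([[0, 0, 0]], [3]) == 0.0

    def test_empty_query_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            mean_average_precision([], [])


class TestMap1Confusion:
    def test_perfect_retrieval_is_identity(self):
        mat = map1_confusion([0, 1, 2], [0, 1, 2], n_classes=3)
        assert np.array_equal(mat, np.eye(3))

    def test_rows_normalize_and_absent_class_is_zero(self):
        mat = map1_confusion([0, 0, 1], [0, 1, 1], n_classes=3)
        assert np.allclose(mat[0], [0.5, 0.5, 0.0])
        assert np.allclose(mat[1], [0.0, 1.0, 0.0])
        assert np.allclose(mat[2], 0.0)

    def test_two_class_hand_placed_codes(self):
        # class-0 database code (1,1,1,1), class-1 code (-1,-1,-1,-1)
        db = np.array([[1, 1, 1, 1], [-1, -1, -1, -1]], dtype=float)
        index = RetrievalIndex.from_codes(db, [0, 1], ["a", "b"])
        queries = np.array([[1, 1, 1, -1],     # nearer class 0
                            [-1, -1, 1, -1],   # nearer class 1
                            [1, -1, -1, -1]])  # nearer class 1 (mislabeled 0)
        report = evaluate(index, queries, [0, 1, 0], k=1)
        assert np.allclose(report.confusion_map1, [[0.5, 0.5], [0.0, 1.0]])
        # class-weighted diagonal equals MAP@1
        weights = np.array([2, 1]) / 3.0
        assert report.map_at_1 == pytest.approx(
            float(weights @ np.diag(report.confusion_map1)), abs=1e-12)


class TestCodeTable:
    def test_roundtrip(self, tmp_path, rng):
        codes = random_codes(rng, 6, 16)
        labels = rng.integers(0, 3, 6)
        ids = [f"img{i}" for i in range(6)]
        write_code_table(codes, labels, ids, tmp_path / "codes.csv")
        back_codes, back_labels, back_ids = read_code_table(tmp_path / "codes.csv")
        assert np.array_equal(back_codes, codes)
        assert np.array_equal(back_labels, labels)
        assert back_ids == ids
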