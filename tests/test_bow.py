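"""Vocabulary building, histogram encoding, chi-square scoring, selection."""

import numpy as np
import pytest
from sklearn.feature_selection import chi2 as sklearn_chi2

from gasfeeg import build_vocabulary, chi2_score, encode, encode_table, select_top_k
from gasfeeg.bow import FeatureTable, Vocabulary
from gasfeeg.exceptions import EncodingError, ScoringError, SelectionError, VocabularyError
from gasfeeg.keypoints import DescriptorSet, Keypoint


def _dset(descriptors, method="sift", image_id="img"):
    descriptors = np.asarray(descriptors, dtype=np.float64)
    return DescriptorSet(
        image_id=image_id,
        method=method,
        keypoints=tuple(Keypoint(0.0, 0.0) for _ in range(descriptors.shape[0])),
        descriptors=descriptors,
    )


class TestBuildVocabulary:
    def test_identical_descriptors_single_centroid(self):
        d = _dset(np.tile([3.0, 4.0], (10, 1)))
        vocab = build_vocabulary([d], k=1, seed=0)
        np.testing.assert_allclose(vocab.centroids, [[3.0, 4.0]])

    def test_two_separated_clusters_recovered(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, (40, 3))
        b = rng.normal(20.0, 1.0, (40, 3))
        vocab = build_vocabulary([_dset(a), _dset(b)], k=2, seed=1)
        means = np.array([a.mean(axis=0), b.mean(axis=0)])
        for m in means:
            assert np.min(np.linalg.norm(vocab.centroids - m, axis=1)) < 1.0

    def test_too_few_descriptors(self):
        with pytest.raises(VocabularyError, match="smaller"):
            build_vocabulary([_dset(np.ones((3, 2)))], k=5)

    def test_order_invariance_under_fixed_seed(self):
        rng = np.random.default_rng(7)
        sets = [_dset(rng.normal(size=(15, 4)), image_id=f"i{i}") for i in range(4)]
        v1 = build_vocabulary(sets, k=3, seed=5)
        v2 = build_vocabulary(sets[::-1], k=3, seed=5)
        np.testing.assert_array_equal(v1.centroids, v2.centroids)

    def test_mixed_methods_rejected(self):
        a = _dset(np.ones((5, 2)), method="sift")
        b = DescriptorSet(
            image_id="o",
            method="orb",
            keypoints=(Keypoint(0, 0),),
            descriptors=np.zeros((1, 16), dtype=np.uint8),
            orb_bits=128,
        )
        with pytest.raises(VocabularyError):
            build_vocabulary([a, b], k=2)

    def test_orb_descriptors_unpacked_for_clustering(self, orb_sets):
        nonempty = [d for d in orb_sets if len(d)]
        vocab = build_vocabulary(nonempty, k=5, seed=0)
        assert vocab.width == 128  # binary dims, not bytes
        assert vocab.method == "orb"


class TestEncode:
    @pytest.fixture()
    def toy_vocab(self):
        centroids = np.zeros((10, 2))
        centroids[:, 0] = np.arange(10) * 10.0  # words at x = 0, 10, ..., 90
        return Vocabulary(centroids=centroids, method="sift", k=10, seed=0, training_hash="t")

    def test_empty_descriptor_set_gives_zero_row(self, toy_vocab):
        row = encode(_dset(np.empty((0, 2))), toy_vocab)
        np.testing.assert_array_equal(row, np.zeros(10))

    def test_counts_by_nearest_centroid(self, toy_vocab):
        d = _dset([[21.0, 0.0], [19.0, 0.0], [71.0, 0.0]])  # nearest words 2, 2, 7
        row = encode(d, toy_vocab, normalization="count")
        expected = np.zeros(10)
        expected[2], expected[7] = 2, 1
        np.testing.assert_array_equal(row, expected)
        # exhaustive nearest-centroid oracle over all k
        for desc in d.descriptors:
            assert row[np.argmin(np.linalg.norm(toy_vocab.centroids - desc, axis=1))] > 0

    def test_frequency_normalization(self, toy_vocab):
        d = _dset([[21.0, 0.0], [19.0, 0.0], [71.0, 0.0]])
        row = encode(d, toy_vocab, normalization="frequency")
        assert row[2] == pytest.approx(2 / 3) and row[7] == pytest.approx(1 / 3)
        assert row.sum() == pytest.approx(1.0)

    def test_tie_goes_to_lowest_index(self):
        vocab = Vocabulary(
            centroids=np.array([[0.0], [2.0]]), method="sift", k=2, seed=0, training_hash="t"
        )
        row = encode(_dset([[1.0]]), vocab, normalization="count")
        np.testing.assert_array_equal(row, [1, 0])

    def test_width_mismatch(self, toy_vocab):
        with pytest.raises(EncodingError):
            encode(_dset(np.ones((2, 3))), toy_vocab)

    def test_count_rows_conserve_descriptor_counts(self, sift_sets):
        nonempty = [d for d in sift_sets if len(d)]
        vocab = build_vocabulary(nonempty, k=8, seed=0)
        table = encode_table(sift_sets, vocab, ["x"] * len(sift_sets), normalization="count")
        np.testing.assert_allclose(table.rows.sum(axis=1), [len(d) for d in sift_sets])


class TestChi2:
    def test_worked_example_scores(self):
        table = FeatureTable(
            rows=np.array([[0.0, 3.0], [0.0, 3.0], [5.0, 3.0], [5.0, 3.0]]),
            labels=np.array([0, 0, 1, 1]),
            normalization="count",
        )
        res = chi2_score(table)
        assert res.scores[0] == pytest.approx(10.0)  # obs [0, 10] vs exp [5, 5]
        assert res.scores[1] == pytest.approx(0.0)  # obs == exp
        assert list(res.ranking[:1]) == [0]

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(1)
        rows = rng.poisson(3.0, size=(30, 6)).astype(float)
        labels = rng.integers(0, 2, 30)
        res = chi2_score(FeatureTable(rows=rows, labels=labels, normalization="count"))
        perm = rng.permutation(30)
        res_p = chi2_score(FeatureTable(rows=rows[perm], labels=labels[perm], normalization="count"))
        np.testing.assert_allclose(res.scores, res_p.scores)

    def test_matches_sklearn_on_counts(self):
        rng = np.random.default_rng(2)
        rows = rng.poisson(4.0, size=(50, 12)).astype(float)
        labels = rng.integers(0, 2, 50)
        res = chi2_score(FeatureTable(rows=rows, labels=labels, normalization="count"))
        sk_scores, sk_p = sklearn_chi2(rows, labels)
        np.testing.assert_allclose(res.scores, sk_scores, atol=1e-10)
        np.testing.assert_allclose(res.p_values, sk_p, atol=1e-10)

    def test_zero_total_feature_scores_zero(self):
        table = FeatureTable(
            rows=np.array([[0.0, 1.0], [0.0, 2.0]]), labels=np.array([0, 1]), normalization="count"
        )
        res = chi2_score(table)
        assert res.scores[0] == 0.0 and res.p_values[0] == 1.0

    def test_single_class_rejected(self):
        with pytest.raises(ScoringError):
            chi2_score(FeatureTable(rows=np.ones((3, 2)), labels=np.zeros(3)))


class TestSelectTopK:
    @pytest.fixture()
    def scored(self):
        table = FeatureTable(
            rows=np.array([[0.0, 3.0], [0.0, 3.0], [5.0, 3.0], [5.0, 3.0]]),
            labels=np.array([0, 0, 1, 1]),
            normalization="count",
        )
        return chi2_score(table), table

    def test_keeps_highest_scoring(self, scored):
        res, table = scored
        out = select_top_k(res, table, 1)
        assert list(out.selected_idx) == [0]
        np.testing.assert_array_equal(out.rows[:, 0], table.rows[:, 0])

    def test_identity_selection(self, scored):
        res, table = scored
        out = select_top_k(res, table, table.n_features)
        np.testing.assert_array_equal(out.rows, table.rows)
        assert list(out.selected_idx) == [0, 1]

    def test_idempotent(self, scored):
        res, table = scored
        once = select_top_k(res, table, 1)
        twice = select_top_k(chi2_score(once), once, 1)
        np.testing.assert_array_equal(once.rows, twice.rows)

    def test_ties_break_to_lower_index(self):
        rows = np.array([[1.0, 1.0, 5.0], [1.0, 1.0, 0.0]])
        table = FeatureTable(rows=rows, labels=np.array([0, 1]), normalization="count")
        res = chi2_score(table)
        assert res.scores[0] == res.scores[1] == 0.0
        out = select_top_k(res, table, 2)
        assert list(out.selected_idx) == [0, 2]

    def test_out_of_range(self, scored):
        res, table = scored
        with pytest.raises(SelectionError):
            select_top_k(res, table, 3)
        with pytest.raises(SelectionError):
            select_top_k(res, table, 0)
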