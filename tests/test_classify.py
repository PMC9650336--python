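import numpy as np
import pytest

import menet as m
from menet.classify import matrix_from_vector, window_bounds
from menet.errors import ConfigurationError, ParameterError

ALPHA, BETA, GAMMA = m.DEFAULT_BANDS


def _block(rng, n_ch=4, fs=256.0, dur=1.0):
    ids = tuple(f"c{k}" for k in range(n_ch))
    return m.EEGEpoch(data=rng.standard_normal((n_ch, int(fs * dur))), fs=fs,
                      channel_ids=ids)


def _noise_featureset(rng, n_samples=500, n_features=40):
    X = rng.standard_normal((n_samples, n_features))
    y = np.array(["ME", "NE"] * (n_samples // 2))
    ids = [(f"a{k}", f"b{k}", "beta") for k in range(n_features)]
    return m.FeatureSet(X=X, y=y, feature_ids=ids, groups=np.arange(n_samples) // 4)


class TestSlidingWindows:
    def test_one_second_block_gives_four_windows(self, rng):
        wins = m.sliding_windows(_block(rng), win=0.4, overlap=0.5)
        assert len(wins) == 4
        assert [w.t0 for w in wins] == pytest.approx([0.0, 51 / 256, 102 / 256, 153 / 256])

    def test_full_length_window_is_the_block(self, rng):
        block = _block(rng)
        wins = m.sliding_windows(block, win=1.0, overlap=0.5)
        assert len(wins) == 1
        assert np.array_equal(wins[0].data, block.data)

    def test_window_sample_count_floor_convention(self, rng):
        wins = m.sliding_windows(_block(rng), win=0.4)
        assert all(w.n_samples == 102 for w in wins)  # floor(256 * 0.4)

    def test_window_longer_than_block_rejected(self, rng):
        with pytest.raises(ParameterError):
            m.sliding_windows(_block(rng), win=2.0)

    def test_bounds_are_half_open_and_inside(self):
        for start, stop in window_bounds(256, 256.0, 0.4, 0.5):
            assert 0 <= start < stop <= 256


class TestVectorize:
    def test_feature_count_128_nodes(self, rng):
        n = 128
        vals = np.eye(n)
        ids = tuple(f"E{k}" for k in range(n))
        conn = m.ConnectivityMatrix(values=vals, node_ids=ids, band=BETA)
        fs = m.vectorize_features([conn], ["ME"], [0])
        assert fs.X.shape[1] == 8128  # 128 * 127 / 2

    def test_upper_triangle_ordering(self):
        n = 4
        vals = np.zeros((n, n))
        iu = np.triu_indices(n, 1)
        vals[iu] = np.arange(6)
        vals += vals.T
        np.fill_diagonal(vals, 1.0)
        ids = ("n1", "n2", "n3", "n4")
        conn = m.ConnectivityMatrix(values=vals, node_ids=ids, band=BETA)
        fs = m.vectorize_features([conn], ["ME"], [0])
        assert fs.feature_ids == [("n1", "n2", "beta"), ("n1", "n3", "beta"),
                                  ("n1", "n4", "beta"), ("n2", "n3", "beta"),
                                  ("n2", "n4", "beta"), ("n3", "n4", "beta")]
        assert np.allclose(fs.X[0], np.arange(6))

    def test_vector_matrix_round_trip(self, rng):
        n = 6
        a = rng.uniform(size=(n, n))
        vals = (a + a.T) / 2
        np.fill_diagonal(vals, 1.0)
        conn = m.ConnectivityMatrix(values=vals, node_ids=tuple("abcdef"), band=BETA)
        fs = m.vectorize_features([conn], ["NE"], [0])
        back = matrix_from_vector(fs.X[0], n)
        assert np.allclose(back, vals)

    def test_node_order_mismatch_rejected(self):
        c1 = m.ConnectivityMatrix(values=np.eye(2), node_ids=("a", "b"), band=BETA)
        c2 = m.ConnectivityMatrix(values=np.eye(2), node_ids=("b", "a"), band=BETA)
        with pytest.raises(ConfigurationError):
            m.vectorize_features([c1, c2], ["ME", "NE"], [0, 1])


class TestGiniRank:
    def test_planted_feature_ranked_first(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            y = np.array(["ME", "NE"] * 50)
            X = rng.standard_normal((100, 100))
            X[:, 17] = (y == "ME") + 0.05 * rng.standard_normal(100)
            ids = [(f"a{k}", f"b{k}", "beta") for k in range(100)]
            fs = m.FeatureSet(X=X, y=y, feature_ids=ids, groups=np.arange(100))
            ranking = m.gini_rank(fs, n_trees=100, seed=seed)
            hits += int(ranking.order[0] == 17)
        assert hits >= 19  # >= 95% of seeds

    def test_importances_sum_to_one(self, rng):
        ranking = m.gini_rank(_noise_featureset(rng, 100, 20), n_trees=50, seed=0)
        assert ranking.gini.sum() == pytest.approx(1.0, abs=1e-6)
        assert np.all(ranking.gini >= 0)

    def test_deterministic_given_seed(self, rng):
        fs = _noise_featureset(rng, 100, 20)
        r1 = m.gini_rank(fs, n_trees=50, seed=5)
        r2 = m.gini_rank(fs, n_trees=50, seed=5)
        assert np.array_equal(r1.order, r2.order)

    def test_single_class_rejected(self, rng):
        fs = _noise_featureset(rng, 50, 10)
        fs.y[:] = "ME"
        with pytest.raises(ParameterError):
            m.gini_rank(fs, n_trees=10, seed=0)


class TestEvaluateTopn:
    def test_separable_data_perfect_accuracy(self, rng):
        fs = _noise_featureset(rng, 200, 30)
        fs.X[:, 3] = (fs.y == "ME") * 2.0 - 1.0  # perfectly separating column
        ranking, report = m.train_and_evaluate(fs, seed=0, n_list=(5, 10), n_trees=100)
        for res in report.results.values():
            assert res["test_accuracy"] == 1.0
            assert res["auc"] == 1.0

    def test_report_contains_the_six_default_subsets(self, rng):
        fs = _noise_featureset(rng, 120, 40)
        _, report = m.train_and_evaluate(fs, seed=0, n_trees=20)
        assert sorted(report.results) == [5, 10, 15, 20, 25, 30]

    def test_n_exceeding_features_rejected(self, rng):
        fs = _noise_featureset(rng, 60, 10)
        ranking = m.gini_rank(fs, n_trees=10, seed=0)
        with pytest.raises(ParameterError):
            m.evaluate_topn(fs, ranking, n_list=(50,), seed=0)

    def test_roc_is_monotone_and_auc_matches_rank_statistic(self, rng):
        fs = _noise_featureset(rng, 200, 30)
        fs.X[:, 0] += (fs.y == "ME") * 0.8
        _, report = m.train_and_evaluate(fs, seed=1, n_list=(10,), n_trees=50)
        res = report.results[10]
        fpr = np.array(res["roc_fpr"])
        tpr = np.array(res["roc_tpr"])
        assert fpr[0] == 0.0 and tpr[0] == 0.0
        assert fpr[-1] == 1.0 and tpr[-1] == 1.0
        assert np.all(np.diff(fpr) >= 0) and np.all(np.diff(tpr) >= 0)

    def test_auc_trapezoid_equals_mann_whitney(self, rng):
        """Dual route: trapezoid AUC over the ROC equals the rank-statistic
        (Mann-Whitney) formulation of AUC."""
        from sklearn.metrics import roc_curve, auc
        scores = rng.standard_normal(300)
        y = (rng.uniform(size=300) < 1 / (1 + np.exp(-scores))).astype(int)
        fpr, tpr, _ = roc_curve(y, scores)
        a_trap = auc(fpr, tpr)
        pos, neg = scores[y == 1], scores[y == 0]
        gt = (pos[:, None] > neg[None, :]).mean()
        eq = (pos[:, None] == neg[None, :]).mean()
        assert a_trap == pytest.approx(gt + 0.5 * eq, abs=1e-10)

    def test_deterministic_report(self, rng):
        fs = _noise_featureset(rng, 120, 30)
        _, r1 = m.train_and_evaluate(fs, seed=3, n_list=(5, 10), n_trees=30)
        _, r2 = m.train_and_evaluate(fs, seed=3, n_list=(5, 10), n_trees=30)
        assert r1.results == r2.results

    def test_no_information_leakage_from_test_labels(self, rng):
        """Corrupting test-split labels must leave all training artifacts
        (ranking, CV accuracy) unchanged."""
        from menet.classify import _split
        fs = _noise_featureset(rng, 150, 25)
        fs.X[:, 2] += (fs.y == "ME") * 0.5
        train_idx, test_idx = _split(fs, seed=4, test_size=0.2, group_split=False)
        r1 = m.gini_rank(fs, n_trees=40, seed=4, sample_idx=train_idx)
        rep1 = m.evaluate_topn(fs, r1, n_list=(5,), seed=4,
                               train_idx=train_idx, test_idx=test_idx)
        corrupted = m.FeatureSet(X=fs.X.copy(), y=fs.y.copy(),
                                 feature_ids=fs.feature_ids, groups=fs.groups)
        corrupted.y[test_idx] = np.where(corrupted.y[test_idx] == "ME", "NE", "ME")
        r2 = m.gini_rank(corrupted, n_trees=40, seed=4, sample_idx=train_idx)
        rep2 = m.evaluate_topn(corrupted, r2, n_list=(5,), seed=4,
                               train_idx=train_idx, test_idx=test_idx)
        assert np.array_equal(r1.order, r2.order)
        assert rep1.results[5]["cv_accuracy_mean"] == rep2.results[5]["cv_accuracy_mean"]

    def test_group_split_keeps_epochs_together(self, rng):
        from menet.classify import _split
        fs = _noise_featureset(rng, 160, 20)
        train_idx, test_idx = _split(fs, seed=0, test_size=0.25, group_split=True)
        assert set(fs.groups[train_idx]).isdisjoint(fs.groups[test_idx])
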