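from itertools import product

import numpy as np
import pytest
from scipy import stats

from gcirnet.evaluation import (
    _holm,
    average_ranking,
    evaluate_subject,
    friedman_test,
    group_gains,
    make_splits,
    pairwise_tests,
    stratify_groups,
)


def _onehot(cls, q=2):
    out = np.zeros((len(cls), q))
    out[np.arange(len(cls)), cls] = 1
    return out


class TestMakeSplits:
    def test_balanced_binary_stratification(self):
        labels = _onehot(np.repeat([0, 1], 50))
        splits = make_splits(labels, n_splits=5, test_size=0.2, seed=0)
        for tr, te in splits:
            cls_te = np.repeat([0, 1], 50)[te]
            assert (cls_te == 0).sum() == 10 and (cls_te == 1).sum() == 10

    def test_train_test_disjoint(self):
        labels = _onehot(np.repeat([0, 1], 20))
        for tr, te in make_splits(labels, seed=1):
            assert len(np.intersect1d(tr, te)) == 0

    def test_deterministic_under_seed(self):
        labels = _onehot(np.repeat([0, 1], 20))
        s1 = make_splits(labels, seed=3)
        s2 = make_splits(labels, seed=3)
        for (a, b), (c, d) in zip(s1, s2):
            np.testing.assert_array_equal(a, c)
            np.testing.assert_array_equal(b, d)

    def test_singleton_class_rejected(self):
        labels = _onehot(np.array([0, 0, 0, 1]))
        with pytest.raises(ValueError):
            make_splits(labels)


class _OracleStub:
    """Predicts the class encoded directly in the feature."""

    def fit(self, X, y):
        return self

    def predict(self, X):
        return X.astype(int)


class _ConstantStub:
    def __init__(self, value):
        self.value = value

    def fit(self, X, y):
        return self

    def predict(self, X):
        return np.full(len(X), self.value)


class TestEvaluateSubject:
    def test_oracle_stub_scores_100(self):
        cls = np.repeat([0, 1], 20)
        labels = _onehot(cls)
        splits = make_splits(labels, seed=0)
        res = evaluate_subject(lambda: _OracleStub(), cls.astype(float), labels, splits)
        assert res["mean"] == 100.0 and res["sd"] == 0.0

    def test_constant_stub_scores_majority_rate(self):
        cls = np.array([0] * 60 + [1] * 40)
        labels = _onehot(cls)
        splits = make_splits(labels, n_splits=3, test_size=0.2, seed=0)
        res = evaluate_subject(lambda: _ConstantStub(0), cls.astype(float), labels, splits)
        assert res["mean"] == pytest.approx(60.0)

    def test_label_permuted_data_near_chance(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((120, 10))
        cls = rng.permutation(np.repeat([0, 1], 60))
        labels = _onehot(cls)
        splits = make_splits(labels, n_splits=5, seed=0)

        from sklearn.linear_model import LogisticRegression

        class _Sk:
            def __init__(self):
                self.clf = LogisticRegression(max_iter=200)

            def fit(self, X, y):
                self.clf.fit(X, np.argmax(y, axis=1))

            def predict(self, X):
                return self.clf.predict(X)

        res = evaluate_subject(_Sk, X, labels, splits)
        assert 35.0 <= res["mean"] <= 65.0

    def test_failing_split_reported_and_skipped(self):
        cls = np.repeat([0, 1], 10)
        labels = _onehot(cls)
        splits = make_splits(labels, n_splits=3, seed=0)
        calls = {"n": 0}

        class _Flaky(_OracleStub):
            def fit(self, X, y):
                calls["n"] += 1
                if calls["n"] == 2:
                    raise RuntimeError("diverged")
                return self

        with pytest.warns(UserWarning, match="failed"):
            res = evaluate_subject(lambda: _Flaky(), cls.astype(float), labels, splits)
        assert len(res["per_split"]) == 2


class TestGroups:
    def test_boundary_convention(self):
        acc = {"s1": 54.65, "s2": 80.0, "s3": 89.64, "s4": 60.0, "s5": 59.99}
        groups = stratify_groups(acc)
        assert groups == {"s1": "Bad", "s2": "Mid", "s3": "Good", "s4": "Mid", "s5": "Bad"}

    def test_equal_models_give_zero_gains(self):
        acc = {"a": 70.0, "b": 85.0, "c": 55.0}
        groups = stratify_groups(acc)
        gains = group_gains(acc, acc, groups)
        for grp in ("Good", "Mid", "Bad"):
            assert gains[grp]["gain"] == 0.0

    def test_toy_gain_of_20(self):
        ref = {"a": 50.0, "b": 60.0}
        new = {"a": 70.0, "b": 80.0}
        groups = {"a": "Bad", "b": "Mid"}
        gains = group_gains(ref, new, groups)
        assert gains["Bad"]["gain"] == pytest.approx(20.0)
        assert gains["Mid"]["gain"] == pytest.approx(20.0)
        assert gains["Good"]["n"] == 0 and gains["Good"]["gain"] is None

    def test_group_means_match_brute_force(self, rng):
        subjects = [f"s{i}" for i in range(20)]
        ref = {s: rng.uniform(40, 95) for s in subjects}
        new = {s: rng.uniform(40, 95) for s in subjects}
        groups = stratify_groups(ref)
        gains = group_gains(ref, new, groups)
        for grp in ("Good", "Mid", "Bad"):
            members = [s for s in subjects if groups[s] == grp]
            if not members:
                continue
            assert gains[grp]["ref"] == pytest.approx(np.mean([ref[s] for s in members]))
            assert gains[grp]["new"] == pytest.approx(np.mean([new[s] for s in members]))


class TestFriedman:
    def test_identical_columns_give_zero_statistic(self):
        acc = np.tile(np.array([70.0, 75, 80, 65, 72])[:, None], (1, 3))
        stat, p = friedman_test(acc)
        assert stat == 0.0 and p == 1.0

    def test_dominating_model_is_significant(self, rng):
        base = rng.uniform(50, 70, (10, 3))
        base[:, 0] += 20.0  # model 0 strictly dominates every subject
        stat, p = friedman_test(base)
        assert p < 0.05

    def test_statistic_matches_rank_formula_oracle(self, rng):
        for _ in range(5):
            acc = rng.uniform(0, 100, (6, 4))  # continuous: no ties
            stat, _ = friedman_test(acc)
            n, k = acc.shape
            ranks = np.array([stats.rankdata(row) for row in acc])
            oracle = 12.0 / (n * k * (k + 1)) * np.sum(ranks.sum(axis=0) ** 2) - 3 * n * (k + 1)
            np.testing.assert_allclose(stat, oracle, atol=1e-10)

    def test_monotone_transform_invariance(self, rng):
        acc = rng.uniform(0, 100, (8, 4))
        s1, p1 = friedman_test(acc)
        s2, p2 = friedman_test(np.exp(acc / 25.0))
        np.testing.assert_allclose(s1, s2, atol=1e-10)

    def test_missing_cells_rejected(self):
        acc = np.ones((4, 3))
        acc[1, 2] = np.nan
        with pytest.raises(ValueError):
            friedman_test(acc)


class TestPairwise:
    def test_holm_hand_computation(self):
        np.testing.assert_allclose(
            _holm(np.array([0.01, 0.02, 0.04])), [0.03, 0.04, 0.04]
        )

    def test_holm_never_decreases_and_is_monotone(self, rng):
        raw = rng.uniform(0, 1, 10)
        adj = _holm(raw)
        assert np.all(adj >= raw - 1e-15)
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_identical_columns_give_p_one(self, rng):
        col = rng.uniform(50, 90, 8)
        acc = np.column_stack([col, col, rng.uniform(50, 90, 8)])
        with pytest.warns(UserWarning):
            res = pairwise_tests(acc, test="paired-t")
        assert res.p_matrix[0, 1] == 1.0

    def test_wilcoxon_matches_enumeration_oracle(self, rng):
        x = rng.standard_normal(7) * 10 + 70
        y = x + rng.standard_normal(7) * 3 + 2
        acc = np.column_stack([x, y])
        res = pairwise_tests(acc, test="wilcoxon")
        d = x - y
        ranks = stats.rankdata(np.abs(d))
        t_plus = ranks[d > 0].sum()
        dist = np.array([
            sum(r for s, r in zip(signs, ranks) if s)
            for signs in product([0, 1], repeat=7)
        ])
        p_exact = min(1.0, 2 * min((dist <= t_plus).mean(), (dist >= t_plus).mean()))
        np.testing.assert_allclose(res.raw_p[0, 1], p_exact, atol=1e-12)

    def test_wilcoxon_needs_six_subjects(self, rng):
        with pytest.raises(ValueError, match="at least 6"):
            pairwise_tests(rng.uniform(0, 100, (4, 3)), test="wilcoxon")

    def test_avg_p_is_mean_of_corrected_row(self, rng):
        acc = rng.uniform(50, 95, (8, 4))
        res = pairwise_tests(acc, test="paired-t")
        for i in range(4):
            np.testing.assert_allclose(
                res.avg_p[i], np.nanmean(np.delete(res.p_matrix[i], i))
            )


class TestAverageRanking:
    def test_dominating_column_ranks_first(self, rng):
        acc = rng.uniform(50, 70, (10, 5))
        acc[:, 2] += 40.0
        ranks = average_ranking(acc)
        assert ranks[2] == 1.0

    def test_identical_columns_share_middle_rank(self):
        acc = np.tile(np.array([60.0, 70, 80])[:, None], (1, 4))
        np.testing.assert_allclose(average_ranking(acc), np.full(4, 2.5))

    def test_matches_sort_based_oracle(self, rng):
        acc = rng.uniform(0, 100, (7, 5))  # continuous: no ties
        got = average_ranking(acc)
        oracle = np.zeros(5)
        for row in acc:
            order = np.argsort(-row)
            for pos, model in enumerate(order):
                oracle[model] += pos + 1
        np.testing.assert_allclose(got, oracle / 7.0)
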