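import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from normbench.benchmarks import (
    compare_extreme_counts,
    fit_bbs,
    summarize_extreme_deviations,
    task1_group_difference,
    task2_svc_classification,
    task3_bbs_regression,
)
from oracles import bh_stepup, pcr_predict, pooled_t


class TestGroupDifference:
    def test_pooled_t_matches_closed_form(self):
        """Worked example: [1,2,3] vs [2,3,4] gives t = -1.2247, p = 0.2879."""
        features = np.array([[1.0], [2.0], [3.0], [2.0], [3.0], [4.0]])
        labels = np.array([1, 1, 1, 0, 0, 0])
        res = task1_group_difference(features, labels)
        assert np.isclose(res.t[0], -1.2247, atol=5e-5)
        assert np.isclose(res.p_raw[0], 0.2879, atol=5e-5)
        t_ref, p_ref = pooled_t([1, 2, 3], [2, 3, 4])
        assert np.isclose(res.t[0], t_ref) and np.isclose(res.p_raw[0], p_ref)

    def test_identical_groups_give_zero_count(self):
        x = np.tile(np.arange(4.0)[:, None], (2, 3))
        labels = np.r_[np.ones(4), np.zeros(4)]
        res = task1_group_difference(x, labels)
        assert np.allclose(res.t, 0.0)
        assert res.count == 0

    def test_count_nondecreasing_in_alpha(self, rng):
        x = rng.standard_normal((60, 30))
        x[:30, :10] += 1.0
        labels = np.r_[np.ones(30), np.zeros(30)]
        counts = [task1_group_difference(x, labels, alpha=a).count for a in (1e-9, 0.01, 0.05, 0.2)]
        assert counts[0] == 0
        assert all(c1 <= c2 for c1, c2 in zip(counts, counts[1:]))

    def test_zero_variance_feature_flagged_and_excluded(self):
        rng = np.random.default_rng(1)
        x = np.column_stack([rng.standard_normal(10) + np.r_[np.ones(5) * 5, np.zeros(5)], np.full(10, 3.0)])
        labels = np.r_[np.ones(5), np.zeros(5)]
        with pytest.warns(RuntimeWarning, match="zero within-group variance"):
            res = task1_group_difference(x, labels)
        assert res.excluded.tolist() == [False, True]
        assert np.isnan(res.p_raw[1])
        assert res.count == 1

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            task1_group_difference(np.zeros((6, 2)), np.zeros(6))

    @given(st.integers(min_value=0, max_value=10_000))
    def test_bh_count_matches_stepup_oracle(self, seed):
        rng = np.random.default_rng(seed)
        m = rng.integers(1, 50)
        p = rng.uniform(0, 1, m) ** rng.uniform(0.5, 3)
        reject_ref, adj_ref = bh_stepup(p, alpha=0.05)
        reject, adj, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert reject.sum() == reject_ref.sum()
        assert np.allclose(adj, adj_ref, atol=1e-12)


class TestExtremeDeviations:
    def test_no_exceedance_gives_zero_counts(self):
        z = np.random.default_rng(0).uniform(-1.9, 1.9, (20, 4))
        s = summarize_extreme_deviations(z, np.r_[np.ones(10), np.zeros(10)])
        assert not s.positive_patient.any() and not s.negative_control.any()

    def test_single_exceedance_localized(self):
        z = np.zeros((6, 3))
        z[0, 1] = 2.5
        s = summarize_extreme_deviations(z, np.r_[np.ones(3), np.zeros(3)])
        assert s.positive_patient.tolist() == [0, 1, 0]
        assert s.positive_control.sum() == 0

    def test_boundary_is_strict(self):
        z = np.full((4, 1), 2.0)
        s = summarize_extreme_deviations(z, np.array([1, 1, 0, 0]))
        assert s.positive_patient[0] == 0 and s.positive_control[0] == 0

    def test_nonpositive_threshold_rejected(self):
        with pytest.raises(ValueError):
            summarize_extreme_deviations(np.zeros((4, 1)), np.array([1, 1, 0, 0]), threshold=0)


class TestCompareExtremeCounts:
    def test_identical_vectors_not_significant(self):
        counts = np.arange(10)
        _, p = compare_extreme_counts(counts, counts)
        assert p >= 0.99

    def test_small_sample_exact_enumeration(self):
        u, p = compare_extreme_counts([1, 2], [3, 4])
        assert u == 0
        assert np.isclose(p, 1 / 3, atol=1e-10)

    def test_large_separation_significant(self):
        a = np.arange(50.0)
        _, p = compare_extreme_counts(a, a + 100.0)
        assert p < 0.001

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            compare_extreme_counts([], [])


class TestClassification:
    def test_separated_clouds_classified_perfectly(self, rng):
        x = rng.standard_normal((200, 5))
        labels = np.r_[np.ones(100), np.zeros(100)]
        x[:100] += 10.0
        res = task2_svc_classification(x, labels, n_folds=10, seed=0)
        assert res.mean_auc == 1.0
        assert all(a == 1.0 for a in res.fold_aucs)

    def test_mean_is_fold_average(self, rng):
        x = rng.standard_normal((60, 4))
        labels = (rng.uniform(size=60) < 0.5).astype(int)
        labels[:10] = 1
        labels[-10:] = 0
        res = task2_svc_classification(x, labels, n_folds=5, seed=1)
        assert res.mean_auc == pytest.approx(np.mean(res.fold_aucs))
        assert len(res.fold_assignments) == 5

    def test_shuffled_labels_give_chance_auc(self):
        rng = np.random.default_rng(2)
        aucs = []
        for rep in range(20):
            x = rng.standard_normal((400, 5))
            labels = np.r_[np.ones(200), np.zeros(200)]
            rng.shuffle(labels)
            aucs.append(task2_svc_classification(x, labels, n_folds=10, seed=rep).mean_auc)
        assert 0.40 < np.mean(aucs) < 0.60

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="single class"):
            task2_svc_classification(np.zeros((20, 2)), np.ones(20))

    def test_too_many_folds_rejected(self):
        labels = np.r_[np.ones(5), np.zeros(15)]
        with pytest.raises(ValueError, match="n_folds"):
            task2_svc_classification(np.zeros((20, 2)), labels, n_folds=10)


class TestBBSRegression:
    def test_exact_interpolation_of_top_component_function(self, rng):
        x = rng.standard_normal((50, 5))
        model = fit_bbs(x, rng.standard_normal(50), k=1)
        y = 2.0 + 3.0 * model.expression_scores(x)[:, 0]
        res = task3_bbs_regression(x, y, x, y, k=1)
        assert res.mse < 1e-10

    def test_matches_svd_normal_equations_oracle(self, rng):
        train = rng.standard_normal((80, 12))
        test = rng.standard_normal((30, 12))
        y = rng.standard_normal(80)
        res = task3_bbs_regression(train, y, test, rng.standard_normal(30), k=6)
        ref = pcr_predict(train, y, test, k=6)
        assert np.max(np.abs(res.predictions - ref)) < 1e-8

    def test_noise_floor_reached(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal((2000, 20))
        model = fit_bbs(x[:1000], np.zeros(1000), k=1)
        signal = model.expression_scores(x)[:, 0]
        signal /= signal[:1000].std()
        y = signal + 0.5 * rng.standard_normal(2000)
        res = task3_bbs_regression(x[:1000], y[:1000], x[1000:], y[1000:], k=15)
        assert abs(res.mse - 0.25) < 0.1

    def test_full_rank_equals_ordinary_least_squares(self, rng):
        x = rng.standard_normal((40, 6))
        y = rng.standard_normal(40)
        test = rng.standard_normal((10, 6))
        res = task3_bbs_regression(x, y, test, np.zeros(10), k=6)
        design = np.column_stack([np.ones(40), x])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        ols_pred = np.column_stack([np.ones(10), test]) @ beta
        assert np.allclose(res.predictions, ols_pred, atol=1e-6)

    def test_components_orthonormal(self, rng):
        model = fit_bbs(rng.standard_normal((60, 8)), rng.standard_normal(60), k=4)
        gram = model.components @ model.components.T
        assert np.allclose(gram, np.eye(4), atol=1e-8)

    def test_k_too_large_rejected(self, rng):
        with pytest.raises(ValueError, match="k="):
            fit_bbs(rng.standard_normal((10, 5)), np.zeros(10), k=10)

    def test_column_mismatch_rejected(self, rng):
        with pytest.raises(ValueError, match="misaligned"):
            task3_bbs_regression(
                rng.standard_normal((20, 5)), np.zeros(20),
                rng.standard_normal((5, 4)), np.zeros(5), k=2,
            )
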