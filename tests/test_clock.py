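"""Elastic-net clock: closed-form oracles, CV honesty, recovery."""

import numpy as np
import pandas as pd
import pytest

from atacage import clock


class TestAssignGroups:
    def test_blocks_dealt_across_age_range(self):
        ages = pd.Series(np.arange(20, 42.0))  # 22 samples
        groups = clock.assign_groups(ages, k=11, seed=0)
        sizes = groups.value_counts()
        assert (sizes == 2).all()
        # each group gets one sample from each 11-sample age block
        young = set(groups.iloc[:11])
        old = set(groups.iloc[11:])
        assert young == old == set(range(1, 12))

    def test_n_equals_k(self):
        groups = clock.assign_groups(pd.Series([30.0, 40, 50]), k=3, seed=1)
        assert sorted(groups) == [1, 2, 3]

    def test_deterministic_and_seed_sensitive(self):
        ages = pd.Series(np.random.default_rng(2).uniform(20, 74, 60))
        g1 = clock.assign_groups(ages, seed=5)
        g2 = clock.assign_groups(ages, seed=5)
        g3 = clock.assign_groups(ages, seed=6)
        assert g1.equals(g2)
        assert not g1.equals(g3)

    def test_groups_span_age_range(self):
        rng = np.random.default_rng(3)
        ages = pd.Series(rng.uniform(20, 74, 150))
        groups = clock.assign_groups(ages, k=11, seed=0)
        full = ages.max() - ages.min()
        for g in range(1, 12):
            span = ages[groups == g].max() - ages[groups == g].min()
            assert span >= 0.6 * full

    def test_k_too_small(self):
        with pytest.raises(ValueError):
            clock.assign_groups(pd.Series([1.0, 2.0]), k=1)


class TestFitElasticNet:
    def test_huge_lambda_gives_intercept_only(self):
        rng = np.random.default_rng(4)
        X = pd.DataFrame(rng.normal(size=(30, 10)))
        y = rng.uniform(20, 74, 30)
        m = clock.fit_elastic_net(X, y, 1e8, 0.5)
        assert np.all(m.coefficients == 0)
        assert np.isclose(m.intercept, y.mean())

    def test_pure_ridge_matches_closed_form(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(5, 3))
        y = rng.normal(50, 10, 5)
        lam = 0.7
        m = clock.fit_elastic_net(pd.DataFrame(X), y, lam, 0.0)
        Z = (X - X.mean(0)) / X.std(0)
        expected = np.linalg.solve(Z.T @ Z + 5 * lam * np.eye(3), Z.T @ (y - y.mean()))
        assert np.allclose(m.coefficients, expected, atol=1e-12)

    def test_planted_sparse_support_recovered(self):
        rng = np.random.default_rng(6)
        X = rng.normal(size=(120, 100))
        beta = np.zeros(100)
        beta[[7, 42, 91]] = [4.0, -3.0, 5.0]
        y = X @ beta + rng.normal(0, 0.5, 120) + 45
        m = clock.fit_elastic_net(pd.DataFrame(X), y, 0.05, 0.9)
        top3 = np.argsort(-np.abs(m.coefficients))[:3]
        assert set(top3) == {7, 42, 91}

    def test_kkt_conditions_at_solution(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 40))
        y = X[:, 0] * 3 + rng.normal(0, 1, 60) + 50
        for lam, a in [(0.3, 0.7), (0.1, 0.9), (1.0, 0.3)]:
            m = clock.fit_elastic_net(pd.DataFrame(X), y, lam, a, tol=1e-12, max_iter=500_000)
            assert clock.kkt_violation(m, X, y) < 1e-6

    def test_zero_variance_feature_dropped(self):
        rng = np.random.default_rng(8)
        X = pd.DataFrame(rng.normal(size=(20, 3)))
        X[1] = 7.0
        y = rng.uniform(20, 70, 20)
        m = clock.fit_elastic_net(X, y, 0.1, 0.5)
        assert m.coefficients[1] == 0.0


class TestPredict:
    def test_training_mean_row_predicts_intercept(self):
        rng = np.random.default_rng(9)
        X = pd.DataFrame(rng.normal(size=(30, 5)))
        y = rng.uniform(20, 74, 30)
        m = clock.fit_elastic_net(X, y, 0.1, 0.5)
        row = pd.DataFrame([X.mean(0)], index=["new"])
        assert np.isclose(clock.predict(m, row).iloc[0], m.intercept)

    def test_duplicate_sample_identical_prediction(self):
        rng = np.random.default_rng(10)
        X = pd.DataFrame(rng.normal(size=(30, 5)))
        y = rng.uniform(20, 74, 30)
        m = clock.fit_elastic_net(X, y, 0.1, 0.5)
        Xn = pd.DataFrame(rng.normal(size=(2, 5)))
        Xn.iloc[1] = Xn.iloc[0]
        p = clock.predict(m, Xn)
        assert p.iloc[0] == p.iloc[1]

    def test_missing_feature_errors(self):
        rng = np.random.default_rng(11)
        X = pd.DataFrame(rng.normal(size=(30, 5)))
        m = clock.fit_elastic_net(X, rng.uniform(20, 74, 30), 0.1, 0.5)
        with pytest.raises(ValueError, match="missing features"):
            clock.predict(m, X[[0, 1, 2]])

    def test_json_roundtrip(self, tmp_path):
        rng = np.random.default_rng(12)
        X = pd.DataFrame(rng.normal(size=(30, 5)))
        y = rng.uniform(20, 74, 30)
        m = clock.fit_elastic_net(X, y, 0.1, 0.5)
        path = tmp_path / "model.json"
        m.to_json(path)
        m2 = clock.ClockModel.from_json(path)
        assert np.allclose(clock.predict(m, X), clock.predict(m2, X.rename(columns=str)))


class TestMetrics:
    def test_constant_shift(self):
        y = np.array([20.0, 30, 40])
        m = clock.metrics(y + 2, y)
        assert m["rmse"] == 2 and m["mae_median"] == 2 and np.isclose(m["pearson_r"], 1)

    def test_hand_example(self):
        m = clock.metrics([25.0, 35], [20.0, 40])
        assert m["rmse"] == 5 and m["mae_median"] == 5 and np.isclose(m["pearson_r"], 1)

    def test_constant_prediction_r_is_nan(self):
        m = clock.metrics([30.0, 30, 30], [20.0, 30, 40])
        assert np.isnan(m["pearson_r"]) and m["rmse"] > 0

    def test_median_ae_robust_to_one_outlier(self):
        y = np.zeros(9)
        pred = np.ones(9) * 2.0
        base = clock.metrics(pred, y)["mae_median"]
        pred_out = pred.copy()
        pred_out[0] = 500.0
        assert clock.metrics(pred_out, y)["mae_median"] == base


class TestNestedCV:
    def make_linear(self, seed=13, n=66, p=30, noise=0.0):
        rng = np.random.default_rng(seed)
        X = pd.DataFrame(rng.normal(size=(n, p)))
        beta = np.zeros(p)
        beta[:4] = [5, -4, 3, 2]
        y = pd.Series(X.to_numpy() @ beta + 45 + rng.normal(0, noise, n))
        return X, y

    def test_noiseless_linear_recovery(self):
        X, y = self.make_linear()
        folds = clock.assign_groups(y, k=6, seed=0)
        rep = clock.nested_cv(X, y, folds, lambda_grid=(1e-4, 1e-2, 1.0), alpha_grid=(0.5,))
        assert rep["overall"]["pearson_r"] > 0.99
        assert rep["overall"]["rmse"] < 1.0

    def test_each_sample_predicted_once(self):
        X, y = self.make_linear(noise=3.0)
        folds = clock.assign_groups(y, k=6, seed=0)
        rep = clock.nested_cv(X, y, folds, lambda_grid=(0.1, 1.0), alpha_grid=(0.5,))
        assert rep["predictions"].notna().all()
        assert len(rep["fold_metrics"]) == 6

    def test_permuted_ages_near_null(self):
        rng = np.random.default_rng(14)
        X, y = self.make_linear(noise=2.0, n=88)
        y_perm = pd.Series(rng.permutation(y.to_numpy()))
        folds = clock.assign_groups(y_perm, k=8, seed=1)
        rep = clock.nested_cv(X, y_perm, folds, lambda_grid=(0.1, 1.0, 10.0), alpha_grid=(0.5,))
        assert abs(rep["overall"]["pearson_r"]) <= 0.25

    def test_no_leakage_from_test_group(self):
        """Perturbing a held-out group's ages leaves its predictions unchanged."""
        X, y = self.make_linear(noise=2.0)
        folds = clock.assign_groups(y, k=6, seed=2)
        rep = clock.nested_cv(X, y, folds, lambda_grid=(0.1, 1.0), alpha_grid=(0.5,))
        g = folds.iloc[0]
        y_corrupt = y.copy()
        y_corrupt[folds == g] += 1000.0
        rep2 = clock.nested_cv(X, y_corrupt, folds, lambda_grid=(0.1, 1.0), alpha_grid=(0.5,))
        mask = (folds == g).to_numpy()
        assert np.allclose(rep["predictions"].to_numpy()[mask],
                           rep2["predictions"].to_numpy()[mask])

    def test_empty_grid_errors(self):
        X, y = self.make_linear()
        folds = clock.assign_groups(y, k=6, seed=0)
        with pytest.raises(ValueError):
            clock.nested_cv(X, y, folds, lambda_grid=(), alpha_grid=(0.5,))


class TestTrainFinalAndMultiomic:
    def test_noiseless_final_fit(self):
        rng = np.random.default_rng(15)
        X = pd.DataFrame(rng.normal(size=(50, 20)))
        y = pd.Series(X[0] * 6 + 40)
        folds = clock.assign_groups(y, k=5, seed=0)
        m = clock.train_final(X, y, folds, lambda_grid=(1e-4, 1e-2), alpha_grid=(0.5,))
        resid = clock.predict(m, X) - y
        assert np.abs(resid).max() < 0.5

    def test_concat_multiomic_ids_and_fallback(self):
        atac = pd.DataFrame(np.ones((3, 2)), index=["a", "b", "c"], columns=["s1", "s2"])
        rna = pd.DataFrame(np.zeros((2, 2)), index=["g1", "g2"], columns=["s1", "s2"])
        joined = clock.concat_multiomic(atac, rna)
        assert list(joined.index) == ["atac:a", "atac:b", "atac:c", "rna:g1", "rna:g2"]
        only = clock.concat_multiomic(atac, rna.iloc[:0])
        assert list(only.index) == ["atac:a", "atac:b", "atac:c"]

    def test_concat_no_common_samples_errors(self):
        atac = pd.DataFrame(np.ones((1, 1)), index=["a"], columns=["s1"])
        rna = pd.DataFrame(np.ones((1, 1)), index=["g"], columns=["s2"])
        with pytest.raises(ValueError):
            clock.concat_multiomic(atac, rna)


class TestSyntheticClockRecovery:
    def test_held_out_prediction_recovers_age(self, small_cohort):
        """Final model trained on half the cohort predicts the other half."""
        c = small_cohort
        X = c["log_normalized"].T
        ages = pd.Series(c["samples"]["age"].to_numpy(), index=X.index)
        train = X.index[: len(X) // 2]
        test = X.index[len(X) // 2:]
        folds = clock.assign_groups(ages[train], k=5, seed=3)
        m = clock.train_final(X.loc[train], ages[train], folds,
                              lambda_grid=(0.1, 1.0, 5.0), alpha_grid=(0.5,))
        pred = clock.predict(m, X.loc[test])
        assert clock.metrics(pred, ages[test])["pearson_r"] > 0.8
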