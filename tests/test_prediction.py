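"""Prediction pipeline: leakage-safe transforms, CV scoring, inference."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from sklearn.decomposition import PCA
from sklearn.linear_model import Ridge
from sklearn.model_selection import KFold

from normdev.prediction import (
    METRICS,
    PCRidge,
    PredictionConfig,
    ScoreDistribution,
    exact_test_of_differences,
    fdr_correct,
    nuisance_residualize,
    pca_reduce,
    permutation_test,
    repeated_cv_predict,
)


def _frame(X):
    return pd.DataFrame(X, columns=[f"ROI_{j:03d}" for j in range(X.shape[1])])


class TestNuisanceResidualize:
    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(0)
        C = rng.standard_normal((80, 3))
        y = rng.standard_normal(80)
        ytr, yte = nuisance_residualize(y[:50], y[50:], C[:50], C[50:])
        # oracle: explicit normal equations on the training rows
        D = np.c_[np.ones(50), C[:50]]
        beta = np.linalg.solve(D.T @ D, D.T @ y[:50])
        np.testing.assert_allclose(ytr, y[:50] - D @ beta, atol=1e-10)
        np.testing.assert_allclose(
            yte, y[50:] - np.c_[np.ones(30), C[50:]] @ beta, atol=1e-10
        )

    def test_perfect_linear_fit_zeroes_training_residuals(self):
        rng = np.random.default_rng(1)
        age = rng.uniform(8, 22, 60)
        y = 3.0 * age - 5.0
        ytr, _ = nuisance_residualize(y[:40], y[40:], age[:40, None], age[40:, None])
        assert np.abs(ytr).max() < 1e-10

    def test_uncorrelated_covariates_leave_centered_y(self):
        rng = np.random.default_rng(2)
        y = rng.standard_normal(400)
        C = rng.standard_normal((400, 2))
        ytr, _ = nuisance_residualize(y[:300], y[300:], C[:300], C[300:])
        rms = np.sqrt(np.mean((ytr - (y[:300] - y[:300].mean())) ** 2))
        assert rms < 0.2  # chance covariate fit is O(sqrt(k/n))

    def test_collinear_covariates_named(self):
        rng = np.random.default_rng(3)
        C = pd.DataFrame({"age": rng.standard_normal(30)})
        C["age_copy"] = C["age"] * 2
        y = rng.standard_normal(30)
        with pytest.raises(ValueError, match="age"):
            nuisance_residualize(y, y, C, C)


class TestPcaReduce:
    def test_rank_three_data_keeps_three_components(self):
        rng = np.random.default_rng(0)
        X = rng.standard_normal((100, 3)) @ rng.standard_normal((3, 20))
        _, _, n = pca_reduce(X, X[:5], threshold=1.0)
        assert n == 3

    def test_scores_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((100, 20))
        Str, _, n = pca_reduce(X, X[:5], threshold=1.0)
        Xc = X - X.mean(axis=0)
        w, V = np.linalg.eigh(Xc.T @ Xc / (len(X) - 1))
        V = V[:, np.argsort(w)[::-1][:n]]
        # eigenvectors are sign-ambiguous; compare magnitudes
        np.testing.assert_allclose(np.abs(Str), np.abs(Xc @ V), atol=1e-8)

    def test_override_fixes_count_for_feature_kind_consistency(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((60, 10))
        _, _, n = pca_reduce(X, X[:5], threshold=1.0, n_override=4)
        assert n == 4

    def test_no_component_reaches_threshold(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((300, 50))
        with pytest.raises(ValueError, match="n_override"):
            pca_reduce(X, X[:5], threshold=50.0)


def test_pcridge_matches_sklearn_pipeline():
    rng = np.random.default_rng(4)
    X, Xte = rng.standard_normal((80, 12)), rng.standard_normal((20, 12))
    y = rng.standard_normal(80)
    est = PCRidge(alpha=1.0, n_components=5).fit(X, y)
    pca = PCA(n_components=5, svd_solver="full").fit(X)
    ridge = Ridge(alpha=1.0).fit(pca.transform(X), y)
    np.testing.assert_allclose(
        est.predict(Xte), ridge.predict(pca.transform(Xte)), atol=1e-8
    )


class TestRepeatedCvPredict:
    def test_noise_target_scores_near_zero(self):
        rng = np.random.default_rng(0)
        X = _frame(rng.standard_normal((500, 20)))
        cohort = pd.DataFrame(
            {"age": rng.uniform(8, 22, 500), "sex": rng.integers(0, 2, 500)}
        )
        y = rng.standard_normal(500)
        cfg = PredictionConfig(n_repeats=10, k_folds=5, seed=0)
        out = repeated_cv_predict(X, y, cohort, cfg)
        assert abs(out["corr_true_pred"].point_estimate) < 0.05
        assert out["neg_rmse"].point_estimate <= 0
        assert out["neg_mae"].point_estimate <= 0

    def test_planted_low_rank_signal_recovered(self):
        rng = np.random.default_rng(1)
        latent = rng.standard_normal((400, 2))
        X = _frame(latent @ rng.standard_normal((2, 30)) * 3
                   + 0.05 * rng.standard_normal((400, 30)))
        y = latent @ np.array([1.0, -0.5])
        cohort = pd.DataFrame(
            {"age": rng.uniform(8, 22, 400), "sex": rng.integers(0, 2, 400)}
        )
        cfg = PredictionConfig(n_repeats=5, k_folds=5, seed=0)
        out = repeated_cv_predict(X, y, cohort, cfg)
        assert out["corr_true_pred"].point_estimate > 0.95

    def test_fold_scores_match_hand_stepped_pipeline(self):
        """n_repeats=2, k=2 on a 20-subject fixture reproduces an explicit
        walk through split -> residualize -> PCA -> ridge -> score."""
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 6))
        y = rng.standard_normal(20)
        cohort = pd.DataFrame(
            {"age": rng.uniform(8, 22, 20), "sex": rng.integers(0, 2, 20)}
        )
        cfg = PredictionConfig(n_repeats=2, k_folds=2, n_components_override=3,
                               seed=7)
        out = repeated_cv_predict(_frame(X), y, cohort, cfg)

        C = cohort[["age", "sex"]].to_numpy()
        expect = {m: [] for m in METRICS}
        for r in range(2):
            kf = KFold(n_splits=2, shuffle=True, random_state=7 + r)
            fold_scores = {m: [] for m in METRICS}
            for tr, te in kf.split(X):
                ytr, yte = nuisance_residualize(y[tr], y[te], C[tr], C[te])
                pca = PCA(n_components=3, svd_solver="full").fit(X[tr])
                ridge = Ridge(alpha=1.0).fit(pca.transform(X[tr]), ytr)
                pred = ridge.predict(pca.transform(X[te]))
                fold_scores["neg_rmse"].append(-np.sqrt(np.mean((yte - pred) ** 2)))
                fold_scores["neg_mae"].append(-np.mean(np.abs(yte - pred)))
                fold_scores["corr_true_pred"].append(np.corrcoef(yte, pred)[0, 1])
            for m in METRICS:
                expect[m].append(np.mean(fold_scores[m]))
        for m in METRICS:
            np.testing.assert_allclose(out[m].values, expect[m], atol=1e-8)

    def test_input_validation(self):
        rng = np.random.default_rng(3)
        X = _frame(rng.standard_normal((30, 4)))
        cohort = pd.DataFrame({"age": rng.uniform(8, 22, 30),
                               "sex": rng.integers(0, 2, 30)})
        with pytest.raises(ValueError, match="non-finite"):
            repeated_cv_predict(X, np.full(30, np.nan), cohort,
                                PredictionConfig(n_repeats=1, k_folds=3))
        with pytest.raises(ValueError, match="fewer than 3"):
            repeated_cv_predict(X, rng.standard_normal(30), cohort,
                                PredictionConfig(n_repeats=1, k_folds=15))


class TestPermutationTest:
    def _data(self, n=150, p=10, seed=0, signal=0.0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, p))
        y = signal * X[:, 0] + np.sqrt(1 - signal**2) * rng.standard_normal(n)
        cohort = pd.DataFrame({"age": rng.uniform(8, 22, n),
                               "sex": rng.integers(0, 2, n)})
        return _frame(X), y, cohort

    def test_strong_signal_reaches_zero_p(self):
        X, y, cohort = self._data(signal=0.9)
        cfg = PredictionConfig(n_repeats=2, k_folds=5, n_permutations=100, seed=0)
        obs = repeated_cv_predict(X, y, cohort, cfg)
        p = permutation_test(obs["corr_true_pred"], X, y, cohort, cfg)
        # plain proportion rule: 0/N is reportable; floor is 1/N
        assert p == 0.0

    def test_observed_worse_than_every_permutation_gives_p_one(self):
        X, y, cohort = self._data()
        cfg = PredictionConfig(n_repeats=1, k_folds=5, n_permutations=100, seed=0)
        hopeless = ScoreDistribution("p", "deviation_z", "corr_true_pred",
                                     np.array([-100.0]))
        assert permutation_test(hopeless, X, y, cohort, cfg) == 1.0

    def test_few_permutations_warn_about_granularity(self):
        X, y, cohort = self._data(n=60)
        cfg = PredictionConfig(n_repeats=1, k_folds=4, n_permutations=50, seed=0)
        obs = repeated_cv_predict(X, y, cohort, cfg)
        with pytest.warns(UserWarning, match="granularity"):
            permutation_test(obs["corr_true_pred"], X, y, cohort, cfg)


class TestFdrCorrect:
    def test_hand_worked_step_up(self):
        p = np.array([0.01, 0.02, 0.03, 0.04, 0.2, 0.9])
        # at q=0.05 no p_(i) clears i*q/m (0.04 > 4*0.05/6); at q=0.1 the
        # largest passing index is i=4, so the first four are rejected
        np.testing.assert_array_equal(fdr_correct(p, q=0.05), [False] * 6)
        np.testing.assert_array_equal(
            fdr_correct(p, q=0.10),
            [True, True, True, True, False, False],
        )

    def test_all_small_all_rejected(self):
        assert fdr_correct(np.full(6, 0.001), q=0.05).all()

    def test_domain_check(self):
        with pytest.raises(ValueError):
            fdr_correct(np.array([0.1, 1.5]))

    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_brute_force_step_up(self, pvals):
        p = np.array(pvals)
        got = fdr_correct(p, q=0.05)
        # oracle: literal BH definition
        order = np.argsort(p, kind="stable")
        m = len(p)
        ks = [i for i in range(1, m + 1) if p[order[i - 1]] <= 0.05 * i / m]
        expect = np.zeros(m, dtype=bool)
        if ks:
            expect[order[: max(ks)]] = True
        np.testing.assert_array_equal(got, expect)


class TestExactTest:
    def test_identical_scores(self):
        a = np.random.default_rng(0).standard_normal(30)
        stat, p = exact_test_of_differences(a, a)
        assert (stat, p) == (0.0, 1.0)

    def test_complete_separation_hits_floor(self):
        a = np.zeros(100) + 1.0
        b = np.zeros(100)
        stat, p = exact_test_of_differences(a, b, n_mc=10000, seed=0)
        assert stat == 1.0
        assert p == pytest.approx(1.0 / 10001.0)

    def test_enumeration_floor_small_n(self):
        a, b = np.ones(10), np.zeros(10)
        _, p = exact_test_of_differences(a, b)
        # identity and global flip both reach |stat|
        assert p == pytest.approx(2.0 / 1024.0)

    def test_monte_carlo_agrees_with_enumeration(self):
        rng = np.random.default_rng(1)
        d = rng.standard_normal(10) * 0.5 + 0.3
        a, b = d, np.zeros(10)
        _, p_exact = exact_test_of_differences(a, b, method="enumerate")
        _, p_mc = exact_test_of_differences(a, b, method="monte_carlo",
                                            n_mc=20000, seed=2)
        se = np.sqrt(p_exact * (1 - p_exact) / 20000)
        assert abs(p_mc - p_exact) < 3 * se + 1e-4

    def test_sign_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.standard_normal(12), rng.standard_normal(12)
        s1, p1 = exact_test_of_differences(a, b)
        s2, p2 = exact_test_of_differences(b, a)
        assert s1 == -s2 and p1 == p2
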