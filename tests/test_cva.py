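"""CVA fitting, Wilk's Lambda routes, BIC Bayes factors, order selection."""

import warnings

import numpy as np
import pandas as pd
import pytest

from cvabms import (
    CvaResult,
    bic_log_bayes_factor,
    compare_feature_models,
    fit_cva,
    log_bayes_factor,
    log_likelihood_ratio,
    partition_covariance,
    select_order,
    wilks_lambda_from_correlations,
    wilks_lambda_from_partition,
)
from cvabms.errors import InconsistentDataError, InsufficientDataError, ShapeError

from conftest import cca_rho1_direct


def _random_instance(rng, n=200, q=2, d=5, coupled=True):
    X = rng.standard_normal((n, q))
    Y = rng.standard_normal((n, d))
    if coupled:
        Y[:, 0] += 0.8 * X[:, 0]
    return X, Y


class TestFitCva:
    def test_perfect_correlation(self, rng):
        x = rng.standard_normal(50)
        res = fit_cva(x, x.copy())
        assert res.rho[0] == pytest.approx(1.0, abs=1e-10)
        assert res.saturated

    def test_orthogonal_sample_gives_zero(self):
        res = fit_cva(
            np.array([1.0, -1.0, 1.0, -1.0]), np.array([1.0, 1.0, -1.0, -1.0])
        )
        assert res.rho[0] == pytest.approx(0.0, abs=1e-12)

    def test_matches_direct_maximization(self, rng):
        X, Y = _random_instance(rng, n=200, q=2, d=5)
        res = fit_cva(X, Y)
        assert res.rho[0] == pytest.approx(cca_rho1_direct(X, Y), abs=1e-6)

    def test_canonical_variate_correlation_equals_rho(self, rng):
        X, Y = _random_instance(rng, n=150, q=3, d=4)
        res = fit_cva(X, Y)
        Xc = X - X.mean(0)
        Yc = Y - Y.mean(0)
        for j in range(res.s):
            u, v = Xc @ res.a[:, j], Yc @ res.b[:, j]
            r = abs(np.corrcoef(u, v)[0, 1])
            assert r == pytest.approx(res.rho[j], abs=1e-8)

    def test_correlations_sorted_in_unit_interval(self, rng):
        X, Y = _random_instance(rng, n=120, q=3, d=6)
        res = fit_cva(X, Y)
        assert np.all(np.diff(res.rho) <= 1e-12)
        assert np.all((res.rho >= 0) & (res.rho <= 1))
        assert res.s == 3

    def test_affine_invariance_of_correlations(self, rng):
        X, Y = _random_instance(rng, n=180, q=2, d=5)
        res0 = fit_cva(X, Y)
        A = rng.standard_normal((5, 5)) + 5 * np.eye(5)
        shift = rng.standard_normal(5)
        res1 = fit_cva(X, Y @ A + shift)
        np.testing.assert_allclose(res0.rho, res1.rho, atol=1e-8)
        B = rng.standard_normal((2, 2)) + 3 * np.eye(2)
        res2 = fit_cva(X @ B, Y)
        np.testing.assert_allclose(res0.rho, res2.rho, atol=1e-8)

    def test_insufficient_data_raises(self, rng):
        with pytest.raises(InsufficientDataError):
            fit_cva(rng.standard_normal((6, 2)), rng.standard_normal((6, 4)))

    def test_row_mismatch_raises(self, rng):
        with pytest.raises(ShapeError):
            fit_cva(rng.standard_normal(10), rng.standard_normal(11))

    def test_rank_deficient_features_warn_but_fit(self, rng):
        Y = rng.standard_normal((50, 3))
        Y = np.column_stack([Y, Y[:, 0]])  # duplicated column
        with pytest.warns(RuntimeWarning, match="rank-deficient"):
            res = fit_cva(rng.standard_normal(50), Y)
        assert np.all(np.isfinite(res.rho))


class TestWilksLambdaRoutes:
    def test_order_zero_is_one(self):
        assert wilks_lambda_from_correlations(np.array([0.9, 0.3]), 0) == 1.0

    def test_perfect_correlation_gives_zero(self):
        assert wilks_lambda_from_correlations(np.array([1.0]), 1) == 0.0

    def test_single_correlation_value(self):
        assert wilks_lambda_from_correlations(np.array([0.6]), 1) == pytest.approx(0.64)

    def test_zero_explained_covariance(self):
        from cvabms.cva import CovPartition

        part = CovPartition(explained=np.zeros((3, 3)), residual=np.eye(3))
        for m in range(4):
            assert wilks_lambda_from_partition(part, m) == pytest.approx(1.0)

    def test_scalar_reduction(self):
        from cvabms.cva import CovPartition

        part = CovPartition(explained=[[2.0]], residual=[[6.0]])
        assert wilks_lambda_from_partition(part, 1) == pytest.approx(6.0 / 8.0)

    def test_three_routes_agree_on_random_instances(self, rng):
        # correlations route, partition-eigenvalue route, and the
        # likelihood-ratio form must coincide to 1e-10
        for _ in range(100):
            n = int(rng.integers(30, 120))
            q = int(rng.integers(1, 4))
            d = int(rng.integers(1, 7))
            X, Y = _random_instance(rng, n=n, q=q, d=d)
            res = fit_cva(X, Y)
            part = partition_covariance(X, Y)
            for m in range(res.s + 1):
                lam_rho = wilks_lambda_from_correlations(res.rho, m)
                lam_part = wilks_lambda_from_partition(part, m)
                lam_lr = np.exp(-2.0 * log_likelihood_ratio(res.rho, m, n) / n)
                assert lam_part == pytest.approx(lam_rho, abs=1e-10)
                assert lam_lr == pytest.approx(lam_rho, abs=1e-10)


class TestLogBayesFactor:
    def test_null_order_is_exactly_zero(self):
        assert bic_log_bayes_factor(np.array([0.5]), 100, 0) == 0.0

    def test_zero_correlation_is_pure_penalty(self):
        val = bic_log_bayes_factor(np.array([0.0]), 200, 1, q=1, d=3)
        assert val == pytest.approx(-(3 / 2) * np.log(200))

    def test_known_value(self):
        # n=100, rho=0.5, m=1, k=3: -(100/2) log(0.75) - 1.5 log(100)
        val = bic_log_bayes_factor(np.array([0.5]), 100, 1, k=3)
        assert val == pytest.approx(
            -50 * np.log(0.75) - 1.5 * np.log(100), abs=1e-12
        )
        assert val == pytest.approx(7.476, abs=1e-3)

    def test_saturated_correlation_flagged_infinite(self):
        assert bic_log_bayes_factor(np.array([1.0]), 50, 1, k=2) == np.inf

    def test_monotone_decreasing_in_k(self):
        vals = [
            bic_log_bayes_factor(np.array([0.5]), 100, 1, k=k) for k in range(1, 12)
        ]
        assert np.all(np.diff(vals) < 0)

    def test_result_accessor_matches(self, rng):
        X, Y = _random_instance(rng, n=100, q=1, d=3)
        res = fit_cva(X, Y)
        assert log_bayes_factor(res, 1) == res.log_bf[1]
        assert log_bayes_factor(res, 0) == 0.0

    def test_default_param_count_matches_band_count_for_q1_m1(self, rng):
        # for the single-label design the one-vector model with d features
        # costs k = d parameters
        X, Y = _random_instance(rng, n=100, q=1, d=5)
        res = fit_cva(X, Y)
        assert res.k[1] == 5


class TestSelectOrder:
    def test_null_wins_when_all_alternatives_negative(self):
        res = CvaResult.from_correlations(np.array([0.05, 0.01]), 50, 2, 4)
        assert select_order(res) == 0
        assert np.all(res.log_bf[1:] < 0)

    def test_strong_dependence_selects_top_order(self):
        res = CvaResult.from_correlations(np.array([0.95, 0.9]), 500, 2, 4)
        assert np.all(np.diff(res.log_bf) > 0)
        assert select_order(res) == 2

    def test_order_recovery_under_rank_one_truth(self, rng):
        # two-column design, rank-1 coupling at rho ~ 0.5
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            X = rng.standard_normal((500, 2))
            Y = rng.standard_normal((500, 4))
            Y[:, 0] += 0.55 * X[:, 0]  # population rho about 0.5
            hits += select_order(fit_cva(X, Y)) == 1
        assert hits / n_rep >= 0.95

    def test_null_calibration(self, rng):
        # independent X and Y: BIC consistency favours order 0
        hits = 0
        n_rep = 500
        for _ in range(n_rep):
            X, Y = _random_instance(rng, n=200, q=1, d=3, coupled=False)
            hits += select_order(fit_cva(X, Y)) == 0
        assert hits / n_rep >= 0.80

    def test_noise_feature_lowers_expected_logbf(self, rng):
        # appending a pure-noise band reduces the mean one-vector logBF
        diffs = []
        for _ in range(100):
            X = rng.standard_normal(150)
            Y = rng.standard_normal((150, 3))
            Y[:, 0] += 0.6 * X
            small = fit_cva(X, Y).log_bf[1]
            big = fit_cva(X, np.column_stack([Y, rng.standard_normal(150)])).log_bf[1]
            diffs.append(big - small)
        assert np.mean(diffs) < 0


class TestCompareFeatureModels:
    def test_pairwise_differences(self):
        mat = compare_feature_models({3: 5.0, 5: 2.0})
        assert mat.loc[3, 5] == pytest.approx(3.0)
        assert mat.loc[5, 3] == pytest.approx(-3.0)
        assert mat.loc[3, 3] == 0.0

    def test_antisymmetric_and_transitive(self, rng):
        bf = {1: 0.7, 3: 4.2, 5: -1.1}
        mat = compare_feature_models(bf)
        np.testing.assert_allclose(mat.values, -mat.values.T, atol=1e-12)
        assert mat.loc[1, 3] + mat.loc[3, 5] == pytest.approx(mat.loc[1, 5])

    def test_mismatched_trial_counts_rejected(self):
        with pytest.raises(InconsistentDataError):
            compare_feature_models(
                {3: 5.0, 5: 2.0}, n_trials_by_model={3: 200, 5: 180}
            )
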