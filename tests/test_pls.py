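"""PLS engine: fit correctness against oracles, resampling inference."""

import numpy as np
import pandas as pd
import pytest

from neuropls.pls import (
    association_with_covariate,
    bootstrap_loadings,
    fit_pls,
    latent_test_correlations,
    permutation_test,
    select_n_components,
)
from tests.conftest import standardize


def _random_standardized(rng, n, p, q):
    return standardize(rng.standard_normal((n, p))), standardize(rng.standard_normal((n, q)))


def _planted(rng, n=200, p=100, q=12, loaded=10, rho=0.5, v=0.3):
    """One latent factor carried by `loaded` X features and all Y tests."""
    F = rng.standard_normal(n)
    X = rng.standard_normal((n, p))
    X[:, :loaded] = rho * F[:, None] + np.sqrt(1 - rho ** 2) * X[:, :loaded]
    Y = np.sqrt(v) * F[:, None] + np.sqrt(1 - v) * rng.standard_normal((n, q))
    return standardize(X), standardize(Y)


class TestFit:
    def test_perfect_rank_one(self, rng):
        # orthogonal standardized predictors: the single PLS weight vector
        # then isolates the matching column exactly
        A = rng.standard_normal((30, 5))
        Q = np.linalg.qr(A - A.mean(axis=0))[0]
        X = Q * np.sqrt(29)  # unit-variance, zero-mean, exactly orthogonal
        Y = X[:, [0]].copy()
        fit = fit_pls(X, Y, 1)
        assert fit.total_variance_explained_y == pytest.approx(1.0, abs=1e-10)

    def test_saturated_fit_reproduces_exact_column(self, rng):
        # with correlated predictors a full-rank fit recovers an exact match
        X = standardize(rng.standard_normal((30, 5)))
        fit = fit_pls(X, X[:, [0]].copy(), 5)
        assert fit.total_variance_explained_y == pytest.approx(1.0, abs=1e-10)

    def test_weights_match_cross_covariance_svd(self):
        """One-component weights equal the dominant left singular vector of
        X'Y on random instances (independent SVD oracle)."""
        for s in range(20):
            r = np.random.default_rng(s)
            X, Y = _random_standardized(r, 20, 5, 2)
            w = fit_pls(X, Y, 1).x_weights[:, 0]
            u = np.linalg.svd(X.T @ Y)[0][:, 0]
            assert abs(u @ w) > 0.999

    def test_saturated_limit_equals_ols(self, rng):
        X, Y = _random_standardized(rng, 10, 4, 3)
        fit = fit_pls(X, Y, 4)
        beta_ols = np.linalg.lstsq(X, Y, rcond=None)[0]
        np.testing.assert_allclose(fit.beta, beta_ols, atol=1e-8)

    def test_matches_sklearn_pls_regression(self, rng):
        from sklearn.cross_decomposition import PLSRegression
        X, Y = _random_standardized(rng, 60, 15, 4)
        fit = fit_pls(X, Y, 3)
        sk = PLSRegression(n_components=3, scale=False, tol=1e-10,
                           max_iter=2000).fit(X, Y)
        # the two NIPALS inner loops stop at slightly different points on
        # noise data where singular values are nearly tied
        np.testing.assert_allclose(fit.predict(X), sk.predict(X), atol=1e-4)

    def test_scores_orthogonal_and_varexp_monotone(self, rng):
        X, Y = _random_standardized(rng, 50, 12, 6)
        fit = fit_pls(X, Y, 4)
        G = fit.x_scores.T @ fit.x_scores
        assert np.abs(G - np.diag(np.diag(G))).max() < 1e-8
        cum = np.cumsum(fit.variance_explained_y)
        assert (np.diff(cum) >= -1e-12).all() and cum[-1] <= 1 + 1e-12

    def test_varexp_invariant_to_joint_permutations(self, rng):
        X, Y = _random_standardized(rng, 40, 8, 3)
        base = fit_pls(X, Y, 2).total_variance_explained_y
        rows = rng.permutation(40)
        cols = rng.permutation(8)
        permuted = fit_pls(X[rows][:, cols], Y[rows], 2).total_variance_explained_y
        assert permuted == pytest.approx(base, abs=1e-10)

    def test_sign_convention(self, rng):
        X, Y = _random_standardized(rng, 40, 8, 3)
        fit = fit_pls(X, Y, 2)
        for a in range(2):
            w = fit.x_weights[:, a]
            assert w[np.argmax(np.abs(w))] > 0

    def test_errors(self, rng):
        X, Y = _random_standardized(rng, 20, 5, 2)
        with pytest.raises(ValueError, match="exceeds"):
            fit_pls(X, Y, 6)
        with pytest.raises(ValueError, match="z-score"):
            fit_pls(X + 1.0, Y, 1)


class TestPermutation:
    def test_planted_signal_detected(self):
        r = np.random.default_rng(11)
        X, Y = _planted(r, n=200, p=50, v=0.3)
        res = permutation_test(X, Y, 1, n_perm=500, seed=1)
        assert res.p_value <= 0.01

    def test_p_value_bounds_and_add_one(self, rng):
        X, Y = _random_standardized(rng, 30, 6, 3)
        res = permutation_test(X, Y, 1, n_perm=19, seed=2)
        assert 1 / 20 <= res.p_value <= 1.0
        assert len(res.null_distribution) == 19

    def test_single_permutation_extremes(self, rng):
        X, Y = _random_standardized(rng, 30, 6, 3)
        res = permutation_test(X, Y, 1, n_perm=1, seed=3)
        expected = 1.0 if res.null_distribution[0] >= res.observed_statistic else 0.5
        assert res.p_value == expected

    def test_reproducible(self, rng):
        X, Y = _random_standardized(rng, 40, 8, 3)
        a = permutation_test(X, Y, 1, n_perm=50, seed=7)
        b = permutation_test(X, Y, 1, n_perm=50, seed=7)
        np.testing.assert_array_equal(a.null_distribution, b.null_distribution)

    def test_invalid_n_perm(self, rng):
        X, Y = _random_standardized(rng, 30, 6, 3)
        with pytest.raises(ValueError):
            permutation_test(X, Y, 1, n_perm=0)


class TestComponentSelection:
    def test_null_mostly_zero(self):
        hits = 0
        for s in range(50):
            r = np.random.default_rng(1000 + s)
            X, Y = _random_standardized(r, 100, 30, 12)
            hits += select_n_components(X, Y, 4, n_perm=200, seed=s) == 0
        assert hits >= 45

    def test_single_factor_mostly_one(self):
        hits = 0
        for s in range(30):
            r = np.random.default_rng(2000 + s)
            X, Y = _planted(r, n=200, p=30, loaded=30, rho=0.5, v=0.15)
            hits += select_n_components(X, Y, 4, n_perm=200, seed=s) == 1
        assert hits >= 27

    def test_two_factors_majority_two(self):
        hits = 0
        for s in range(20):
            r = np.random.default_rng(3000 + s)
            n = 500
            F = r.standard_normal((n, 2))
            Lx = np.zeros((40, 2))
            Lx[:8, 0] = 0.5
            Lx[8:16, 1] = 0.5
            X = standardize(F @ Lx.T + r.standard_normal((n, 40))
                            * np.sqrt(1 - (Lx ** 2).sum(1)))
            Ly = np.zeros((12, 2))
            Ly[::2, 0] = np.sqrt(0.15)
            Ly[1::2, 1] = np.sqrt(0.15)
            Y = standardize(F @ Ly.T + r.standard_normal((n, 12))
                            * np.sqrt(1 - (Ly ** 2).sum(1)))
            hits += select_n_components(X, Y, 5, n_perm=100, seed=s) == 2
        assert hits > 10


class TestBootstrap:
    def test_planted_features_flagged(self):
        r = np.random.default_rng(5)
        X, Y = _planted(r, n=200, p=60, loaded=8, rho=0.6, v=0.3)
        res = bootstrap_loadings(X, Y, 1, n_boot=300, seed=1)
        assert res.significant_mask[:8, 0].sum() >= 7
        assert res.significant_mask[8:, 0].mean() <= 0.05

    def test_mask_matches_threshold_exactly(self, rng):
        X, Y = _planted(rng, n=100, p=20, loaded=5, v=0.3)
        res = bootstrap_loadings(X, Y, 1, n_boot=100, seed=2)
        np.testing.assert_array_equal(res.significant_mask,
                                      np.abs(res.z_ratio) > 3.0)

    def test_row_duplication_preserves_z_direction(self):
        r = np.random.default_rng(9)
        X, Y = _planted(r, n=120, p=30, loaded=6, rho=0.6, v=0.3)
        base = bootstrap_loadings(X, Y, 1, n_boot=200, seed=3)
        Xd = standardize(np.vstack([X, X]))
        Yd = standardize(np.vstack([Y, Y]))
        dup = bootstrap_loadings(Xd, Yd, 1, n_boot=200, seed=3)
        strong = np.abs(base.z_ratio[:, 0]) > 3
        assert (np.sign(base.z_ratio[strong, 0])
                == np.sign(dup.z_ratio[strong, 0])).all()

    def test_reproducible(self, rng):
        X, Y = _random_standardized(rng, 60, 10, 3)
        a = bootstrap_loadings(X, Y, 1, n_boot=50, seed=4)
        b = bootstrap_loadings(X, Y, 1, n_boot=50, seed=4)
        np.testing.assert_array_equal(a.z_ratio, b.z_ratio)


class TestLatentTestCorrelations:
    def test_score_equal_to_test_is_significant(self):
        r = np.random.default_rng(13)
        n = 100
        X = standardize(r.standard_normal((n, 10)))
        y0 = standardize(X[:, :3].sum(axis=1)[:, None])[:, 0]
        Y = pd.DataFrame({"t0": y0, "t1": r.standard_normal(n)})
        fit = fit_pls(X, standardize(Y.to_numpy()), 1)
        out = latent_test_correlations(fit, Y)
        row = out[(out.component == 1) & (out.test == "t0")].iloc[0]
        assert row.r > 0.9 and row.significant

    def test_bonferroni_family_size(self, rng):
        X, Y = _random_standardized(rng, 60, 10, 12)
        fit = fit_pls(X, Y, 2)
        out = latent_test_correlations(fit, pd.DataFrame(Y, columns=[f"t{i}" for i in range(12)]))
        assert len(out) == 24
        ratio = out.p_bonferroni / out.p_raw
        assert np.allclose(ratio[out.p_bonferroni < 1], 24)

    def test_null_bonferroni_rejections_rare_out_of_sample(self):
        """On noise, latent scores computed for held-out rows are uncorrelated
        with held-out tests and Bonferroni rejections are rare. (In-sample
        fitted scores are optimistically correlated with Y by construction,
        so calibration must be assessed out of sample.)"""
        import dataclasses
        n_sig = 0
        for s in range(10):
            r = np.random.default_rng(4000 + s)
            Xtr, Ytr = _random_standardized(r, 200, 10, 12)
            Xte, Yte = _random_standardized(r, 200, 10, 12)
            fit = fit_pls(Xtr, Ytr, 1)
            heldout = dataclasses.replace(fit, x_scores=fit.transform(Xte))
            out = latent_test_correlations(
                heldout, pd.DataFrame(Yte, columns=[f"t{i}" for i in range(12)]))
            n_sig += int(out.significant.sum())
        assert n_sig <= 2  # 120 Bonferroni-corrected null comparisons

    def test_constant_column_flagged_not_significant(self, rng, caplog):
        X, Y = _random_standardized(rng, 40, 8, 2)
        fit = fit_pls(X, Y, 1)
        Yraw = pd.DataFrame({"t0": Y[:, 0], "flat": np.ones(40)})
        with caplog.at_level("WARNING"):
            out = latent_test_correlations(fit, Yraw)
        row = out[out.test == "flat"].iloc[0]
        assert not row.significant and np.isnan(row.r)


class TestCovariateAssociation:
    def test_perfect_correlations(self, rng):
        s = rng.standard_normal(50)
        assert association_with_covariate(s, s)[0] == pytest.approx(1.0)
        assert association_with_covariate(s, -s)[0] == pytest.approx(-1.0)

    def test_independent_near_zero(self):
        r = np.random.default_rng(6)
        rr, _ = association_with_covariate(r.standard_normal(1000),
                                           r.standard_normal(1000))
        assert abs(rr) < 0.1

    def test_errors(self, rng):
        with pytest.raises(ValueError):
            association_with_covariate(np.ones(10), rng.standard_normal(10))
        with pytest.raises(ValueError):
            association_with_covariate(np.arange(3.0), np.arange(3.0))
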