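"""Mixed-model GWAS: spectral likelihood, scan calibration, lambda."""

import numpy as np
import pytest
from scipy import stats

import socgwas
from socgwas.grm import grm_sqrt_factor
from socgwas.gwas import (MixedModelGWAS, _reml_neg_loglik, bonferroni_thresholds,
                          fit_mlm_null, format_threshold, genomic_lambda,
                          wald_scan)


def _random_panel(rng, n, p, f_lo=0.1, f_hi=0.5):
    f = rng.uniform(f_lo, f_hi, p)
    return (rng.random((n, p)) < f).astype(float) + (rng.random((n, p)) < f)


def dense_reml_oracle(y, X, G, sa2, se2):
    """Direct dense-matrix restricted likelihood, written independently."""
    n = len(y)
    V = sa2 * G + se2 * np.eye(n)
    Vi = np.linalg.inv(V)
    _, ldV = np.linalg.slogdet(V)
    XtViX = X.T @ Vi @ X
    _, ldX = np.linalg.slogdet(XtViX)
    P = Vi - Vi @ X @ np.linalg.solve(XtViX, X.T @ Vi)
    q = np.linalg.matrix_rank(X)
    return -0.5 * (ldV + ldX + y @ P @ y + (n - q) * np.log(2 * np.pi))


class TestNullFit:
    def test_spectral_equals_dense_at_probe_deltas(self, rng):
        n = 200
        M = _random_panel(rng, n, 300)
        G = socgwas.grm_centered(M)
        y = rng.standard_normal(n)
        null = fit_mlm_null(y, G)
        for log_delta in (-2.0, -1.0, 0.0, 1.0, 2.0):
            sp = -_reml_neg_loglik(log_delta, null.eigenvalues, null.y_rot,
                                   null.X_rot)
            # profile sigma_a2 at this delta, then evaluate densely
            xi = null.eigenvalues + np.exp(log_delta)
            w = 1.0 / xi
            Xw = null.X_rot * w[:, None]
            beta = np.linalg.solve(null.X_rot.T @ Xw, Xw.T @ null.y_rot)
            r = null.y_rot - null.X_rot @ beta
            sa2 = float(r @ (w * r)) / (n - 1)
            dn = dense_reml_oracle(y, null.X, G, sa2, sa2 * np.exp(log_delta))
            assert sp == pytest.approx(dn, abs=1e-8)

    def test_zero_heritability_not_invented(self, rng):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(seed)
            M = _random_panel(r, 500, 300)
            G = socgwas.grm_centered(M)
            G *= 500 / np.trace(G)
            y = r.standard_normal(500)
            null = fit_mlm_null(y, G)
            ratio = null.sigma_a2 * np.trace(G) / 500 / (
                null.sigma_a2 + null.sigma_e2)
            hits += ratio < 0.1
        assert hits >= 18

    def test_unit_variance_ratio_recovered(self, rng):
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(100 + seed)
            M = _random_panel(r, 500, 400)
            G = socgwas.grm_centered(M)
            G *= 500 / np.trace(G)
            L = grm_sqrt_factor(M) * np.sqrt(500 / np.trace(socgwas.grm_centered(M)))
            y = L @ r.standard_normal(L.shape[1]) + r.standard_normal(500)
            null = fit_mlm_null(y, G)
            ratio = null.sigma_e2 / null.sigma_a2  # delta; truth 1
            hits += 0.5 <= ratio <= 2.0
        assert hits >= 18

    def test_zero_variance_response_rejected(self):
        with pytest.raises(ValueError):
            fit_mlm_null(np.ones(50), np.eye(50))


class TestWaldScan:
    def test_ols_limit_matches_textbook_regression(self, rng):
        n = 150
        M = _random_panel(rng, n, 40)
        y = rng.standard_normal(n)
        null = fit_mlm_null(y, np.zeros((n, n)))
        scan = wald_scan(M, null)
        for j in range(40):
            p_ols = stats.linregress(M[:, j], y).pvalue
            assert scan["p"].iloc[j] == pytest.approx(p_ols, abs=1e-10)

    def test_intercept_collinear_marker_flagged(self, rng):
        n = 100
        M = np.column_stack([np.ones(n), _random_panel(rng, n, 3)])
        y = rng.standard_normal(n)
        null = fit_mlm_null(y, np.eye(n))
        scan = wald_scan(M, null)
        assert scan["reason"].iloc[0] in {"monomorphic", "collinear"}
        assert np.isnan(scan["p"].iloc[0])
        assert scan["p"].iloc[1:].notna().all()

    def test_monomorphic_marker_flagged(self, rng):
        n = 80
        M = np.column_stack([np.full(n, 2.0), _random_panel(rng, n, 2)])
        null = fit_mlm_null(rng.standard_normal(n), np.eye(n))
        scan = wald_scan(M, null)
        assert scan["reason"].iloc[0] == "monomorphic"

    def test_p3d_and_per_marker_reml_agree_in_rank(self, rng):
        n, p = 150, 150
        M = _random_panel(rng, n, p)
        G = socgwas.grm_centered(M)
        L = grm_sqrt_factor(M)
        y = L @ rng.standard_normal(L.shape[1]) + rng.standard_normal(n)
        null = fit_mlm_null(y, G)
        p3d = wald_scan(M, null, mode="p3d")["p"].to_numpy()
        pm = wald_scan(M, null, mode="per-marker-reml")["p"].to_numpy()
        rank_corr = stats.spearmanr(p3d, pm).statistic
        assert rank_corr > 0.99

    def test_joint_permutation_equivariance(self, rng):
        n = 120
        M = _random_panel(rng, n, 30)
        G = socgwas.grm_centered(M)
        y = rng.standard_normal(n) + 0.3 * M[:, 0]
        p0 = wald_scan(M, fit_mlm_null(y, G))["p"].to_numpy()
        perm = rng.permutation(n)
        p1 = wald_scan(M[perm], fit_mlm_null(y[perm], G[np.ix_(perm, perm)]))[
            "p"].to_numpy()
        np.testing.assert_allclose(p0, p1, rtol=1e-6)


class TestThresholds:
    @pytest.mark.parametrize(
        "n_tests,gw,sugg",
        [(36969, "1.35e-06", "2.70e-05"),
         (3072572, "1.63e-08", "3.25e-07"),
         (274741, "1.82e-07", "3.64e-06")],
    )
    def test_printed_panel_regimes(self, n_tests, gw, sugg):
        g, s = bonferroni_thresholds(n_tests)
        assert format_threshold(g) == gw
        assert format_threshold(s) == sugg

    def test_invalid_count(self):
        with pytest.raises(ValueError):
            bonferroni_thresholds(0)


class TestGenomicLambda:
    def test_uniform_grid_is_one(self):
        m = 5000
        p = (np.arange(1, m + 1) - 0.5) / m
        assert genomic_lambda(p) == pytest.approx(1.0, abs=0.01)

    def test_doubling_statistics_doubles_lambda(self):
        m = 5000
        p = (np.arange(1, m + 1) - 0.5) / m
        chi = stats.chi2.isf(p, 1)
        p2 = stats.chi2.sf(2 * chi, 1)
        assert genomic_lambda(p2) == pytest.approx(2.0, abs=0.02)

    def test_null_simulation_in_band(self, rng):
        z = rng.standard_normal(5000)
        p = stats.chi2.sf(z**2, 1)
        assert 0.9 <= genomic_lambda(p) <= 1.1

    def test_regression_method_close_to_median_under_null(self, rng):
        z = rng.standard_normal(5000)
        p = stats.chi2.sf(z**2, 1)
        lam_m = genomic_lambda(p, method="median")
        lam_r = genomic_lambda(p, method="regression")
        assert abs(lam_m - lam_r) < 0.1

    def test_few_tests_warns(self):
        with pytest.warns(UserWarning):
            genomic_lambda(np.linspace(0.01, 0.99, 50))


class TestModelObject:
    def test_fit_null_cached_and_scan_runs(self, rng):
        n = 100
        M = _random_panel(rng, n, 50)
        G = socgwas.grm_centered(M)
        gm = MixedModelGWAS(rng.standard_normal(n), G)
        assert gm.fit_null() is gm.fit_null()
        tab = gm.scan(M)
        assert tab["p"].notna().sum() == 50
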