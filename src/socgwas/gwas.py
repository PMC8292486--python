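"""Single-locus mixed-model association on deregressed EBVs.

The test model for each marker (or haplotype-allele pseudo-marker) is

    y = X m + a + e,   a ~ N(0, G s2_a),  e ~ N(0, I s2_e)

with y the deregressed-EBV response and G the centered genomic relationship
matrix. The polygenic structure is handled spectrally: with G = U D U' the
model rotates to independent observations with variances s2_a (d_i + delta),
delta = s2_e / s2_a, and the null delta is found by a one-dimensional bounded
search on log(delta). Markers are then tested by generalized least squares,
either reusing the null delta for every marker (P3D, the default) or
re-optimizing delta per marker.

The per-marker test is a Wald test of m = 0. By default the squared
standardized effect is referred to F(1, n - q), which reduces exactly to the
ordinary-regression t-test when the polygenic variance is zero; a 1-df
chi-square reference is available via ``reference="chisq"``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .grm import mean_impute

_CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, 1))  # 0.4549364...


@dataclass
class MLMNull:
    """Null-model fit: spectral data, variance ratio and rotated quantities."""

    eigenvalues: np.ndarray
    rotation: np.ndarray          # U, orthonormal columns
    delta: float                  # s2_e / s2_a at the null optimum
    sigma_a2: float
    sigma_e2: float
    loglik: float
    y_rot: np.ndarray
    X_rot: np.ndarray
    y: np.ndarray
    X: np.ndarray
    n_clipped_eigenvalues: int

    @property
    def weights(self) -> np.ndarray:
        """1 / (d_i + delta), proportional to the GLS precision."""
        return 1.0 / (self.eigenvalues + self.delta)


def _reml_neg_loglik(log_delta: float, d: np.ndarray, yr: np.ndarray,
                     Xr: np.ndarray) -> float:
    """Negative restricted log-likelihood profiled over the scale sigma_a2."""
    delta = np.exp(log_delta)
    xi = d + delta
    w = 1.0 / xi
    Xw = Xr * w[:, None]
    XtWX = Xr.T @ Xw
    beta = np.linalg.solve(XtWX, Xw.T @ yr)
    resid = yr - Xr @ beta
    rss = float(resid @ (w * resid))
    n, q = yr.shape[0], Xr.shape[1]
    nq = n - q
    sign, logdetX = np.linalg.slogdet(XtWX)
    if sign <= 0 or rss <= 0:
        return np.inf
    ll = -0.5 * (
        nq * np.log(2 * np.pi * rss / nq) + nq
        + np.log(xi).sum() + logdetX
    )
    return -ll


def reml_loglik_dense(y: np.ndarray, X: np.ndarray, G: np.ndarray,
                      sigma_a2: float, sigma_e2: float) -> float:
    """Direct dense-matrix restricted log-likelihood (reference path)."""
    n, q = y.shape[0], X.shape[1]
    V = sigma_a2 * G + sigma_e2 * np.eye(n)
    Vi = np.linalg.inv(V)
    sign, logdetV = np.linalg.slogdet(V)
    XtViX = X.T @ Vi @ X
    s2, logdetX = np.linalg.slogdet(XtViX)
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    r = y - X @ beta
    return -0.5 * (logdetV + logdetX + float(r @ Vi @ r) + (n - q) * np.log(2 * np.pi))


def fit_mlm_null(y: np.ndarray, G: np.ndarray,
                 X: np.ndarray | None = None) -> MLMNull:
    """Fit the polygenic null model by spectral REML.

    ``X`` defaults to an intercept. Negative GRM eigenvalues are clipped at
    zero (the centered GRM is rank-deficient by construction); the count of
    clipped eigenvalues is recorded on the result.
    """
    y = np.asarray(y, dtype=float)
    n = y.shape[0]
    if not np.all(np.isfinite(y)):
        raise ValueError("response contains non-finite values")
    if np.var(y) == 0:
        raise ValueError("response has zero variance")
    if X is None:
        X = np.ones((n, 1))
    d, U = np.linalg.eigh(G)
    tol = 1e-8 * max(d.max(), 1.0)
    n_clip = int((d < -tol).sum())
    d = np.maximum(d, 0.0)
    yr = U.T @ y
    Xr = U.T @ X

    res = optimize.minimize_scalar(
        _reml_neg_loglik, bounds=(-10.0, 10.0), args=(d, yr, Xr),
        method="bounded", options={"xatol": 1e-9},
    )
    # guard against a boundary optimum missed by the bounded search
    candidates = [(-float(res.fun), float(res.x))]
    for ld in (-10.0, 10.0):
        candidates.append((-_reml_neg_loglik(ld, d, yr, Xr), ld))
    ll, log_delta = max(candidates)
    delta = float(np.exp(log_delta))

    xi = d + delta
    w = 1.0 / xi
    Xw = Xr * w[:, None]
    beta = np.linalg.solve(Xr.T @ Xw, Xw.T @ yr)
    resid = yr - Xr @ beta
    q = Xr.shape[1]
    sigma_a2 = float(resid @ (w * resid)) / (n - q)
    return MLMNull(
        eigenvalues=d, rotation=U, delta=delta,
        sigma_a2=sigma_a2, sigma_e2=delta * sigma_a2,
        loglik=float(ll), y_rot=yr, X_rot=Xr, y=y, X=X,
        n_clipped_eigenvalues=n_clip,
    )


def wald_scan(
    dosage: np.ndarray,
    null: MLMNull,
    mode: str = "p3d",
    markers: pd.DataFrame | None = None,
    reference: str = "f",
) -> pd.DataFrame:
    """Per-marker GLS effect, SE and Wald p under the polygenic covariance.

    Parameters
    ----------
    dosage : (n, p) array
        Marker (or haplotype-allele) dosages; missing values mean-imputed.
    null : MLMNull
    mode : {"p3d", "per-marker-reml"}
        P3D reuses the null variance ratio for every marker; the alternative
        re-optimizes delta with the marker in the model.
    markers : optional DataFrame with id/chrom/pos/a1/a2 for annotation.
    reference : {"f", "chisq"}
        Null reference for the squared Wald statistic.

    Monomorphic or covariate-collinear markers get a missing p with a reason
    code instead of a test.
    """
    if mode not in {"p3d", "per-marker-reml"}:
        raise ValueError(f"unknown scan mode: {mode!r}")
    if reference not in {"f", "chisq"}:
        raise ValueError(f"unknown test reference: {reference!r}")
    M = mean_impute(np.asarray(dosage, dtype=float))
    n, p = M.shape
    if n != null.y.shape[0]:
        raise ValueError("marker matrix does not match the null model's samples")
    q = null.X.shape[1]
    df = n - q - 1

    beta = np.full(p, np.nan)
    se = np.full(p, np.nan)
    pval = np.full(p, np.nan)
    reason = np.array([""] * p, dtype=object)

    mono = M.std(axis=0) == 0
    reason[mono] = "monomorphic"

    Mr = null.rotation.T @ M  # rotate all markers at once

    def _test_rotated(w: np.ndarray, xcol: np.ndarray):
        """FWL GLS of y on [X, x] with weights w, rotated coordinates."""
        Xw = null.X_rot * w[:, None]
        XtWX = null.X_rot.T @ Xw
        XtWXi = np.linalg.inv(XtWX)
        # residualize x and y against X under w
        bx = XtWXi @ (Xw.T @ xcol)
        x_t = xcol - null.X_rot @ bx
        by = XtWXi @ (Xw.T @ null.y_rot)
        y_t = null.y_rot - null.X_rot @ by
        xwx = float(x_t @ (w * x_t))
        if xwx <= 1e-10 * float(xcol @ (w * xcol) + 1e-300):
            return None
        b = float(x_t @ (w * y_t)) / xwx
        rss = float(y_t @ (w * y_t)) - b * b * xwx
        s2 = max(rss, 0.0) / df
        return b, np.sqrt(s2 / xwx)

    if mode == "p3d":
        w = null.weights
        for j in range(p):
            if mono[j]:
                continue
            out = _test_rotated(w, Mr[:, j])
            if out is None:
                reason[j] = "collinear"
                continue
            beta[j], se[j] = out
    else:  # per-marker-reml
        d = null.eigenvalues
        for j in range(p):
            if mono[j]:
                continue
            Xj = np.column_stack([null.X_rot, Mr[:, j]])
            res = optimize.minimize_scalar(
                _reml_neg_loglik, bounds=(-10.0, 10.0),
                args=(d, null.y_rot, Xj), method="bounded",
                options={"xatol": 1e-8},
            )
            w = 1.0 / (d + np.exp(res.x))
            out = _test_rotated(w, Mr[:, j])
            if out is None:
                reason[j] = "collinear"
                continue
            beta[j], se[j] = out

    ok = np.isfinite(beta) & (se > 0)
    stat = np.zeros(p)
    stat[ok] = (beta[ok] / se[ok]) ** 2
    if reference == "f":
        pval[ok] = stats.f.sf(stat[ok], 1, df)
    else:
        pval[ok] = stats.chi2.sf(stat[ok], 1)

    if markers is not None:
        out_df = markers.reset_index(drop=True).copy()
        if "a1" in out_df.columns and "a2" in out_df.columns:
            out_df["allele"] = out_df["a1"].astype(str) + "/" + out_df["a2"].astype(str)
    else:
        out_df = pd.DataFrame({"id": [f"m{j}" for j in range(p)]})
    out_df["beta"] = beta
    out_df["se"] = se
    out_df["p"] = pval
    out_df["reason"] = reason
    return out_df


def bonferroni_thresholds(n_tests: int) -> tuple[float, float]:
    """Genome-wide (0.05 / N) and suggestive (1 / N) Bonferroni thresholds."""
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    return 0.05 / n_tests, 1.0 / n_tests


def format_threshold(x: float) -> str:
    """Display a threshold at 3 significant digits, as conventionally printed."""
    return f"{x:.2e}"


def genomic_lambda(pvalues: np.ndarray, method: str = "median") -> float:
    """Genomic inflation factor from a vector of p-values.

    ``median``: ratio of the median 1-df chi-square quantile of the observed
    p-values to the null median 0.4549. ``regression``: slope through the
    origin of observed on expected chi-square quantiles (GenABEL-style).
    Fewer than 100 tests triggers a warning but still returns a value.
    """
    p = np.asarray(pvalues, dtype=float)
    p = p[np.isfinite(p)]
    if p.size == 0:
        raise ValueError("no p-values")
    if p.size < 100:
        import warnings

        warnings.warn(f"only {p.size} tests: lambda is unstable", stacklevel=2)
    chi = stats.chi2.isf(p, 1)
    if method == "median":
        return float(np.median(chi) / _CHI2_MEDIAN_1DF)
    if method == "regression":
        expected = stats.chi2.isf((np.arange(1, p.size + 1) - 0.5) / p.size, 1)
        observed = np.sort(chi)[::-1]
        return float((observed @ expected) / (expected @ expected))
    raise ValueError(f"unknown lambda method: {method!r}")


class MixedModelGWAS:
    """Convenience model object binding a response, GRM and covariates.

    ``fit_null()`` caches the spectral null fit; ``scan()`` runs the Wald
    scan and returns the association table.
    """

    def __init__(self, y: np.ndarray, G: np.ndarray,
                 X: np.ndarray | None = None):
        self.y = np.asarray(y, dtype=float)
        self.G = G
        self.X = X
        self._null: MLMNull | None = None

    def fit_null(self) -> MLMNull:
        if self._null is None:
            self._null = fit_mlm_null(self.y, self.G, self.X)
        return self._null

    def scan(self, dosage: np.ndarray, mode: str = "p3d",
             markers: pd.DataFrame | None = None,
             reference: str = "f") -> pd.DataFrame:
        return wald_scan(dosage, self.fit_null(), mode=mode,
                         markers=markers, reference=reference)
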