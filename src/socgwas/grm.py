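"""Genomic relationship matrix.

The default GRM is the centered cross-product form

    G = (1/p) * sum_i (X_i - 1 xbar_i)(X_i - 1 xbar_i)^T

over the p marker columns X_i — the centered relatedness convention of
GEMMA-style MLM tools; no per-marker variance scaling is applied. A
variance-scaled (VanRaden-2 style) variant divides each centered column by
sqrt(2 f (1-f)) and is available via ``method="scaled"``.

Missing dosages are mean-imputed per marker before centering, the standard
practice for MLM GWAS.
"""

from __future__ import annotations

import numpy as np

from .genio import GenotypeMatrix


def mean_impute(dosage: np.ndarray) -> np.ndarray:
    """Replace missing dosages by the marker mean (in place on a copy)."""
    d = np.array(dosage, dtype=float)
    nanmask = np.isnan(d)
    if nanmask.any():
        col_mean = np.nanmean(np.where(nanmask, np.nan, d), axis=0)
        col_mean = np.where(np.isnan(col_mean), 0.0, col_mean)
        idx = np.where(nanmask)
        d[idx] = col_mean[idx[1]]
    return d


def grm_centered(
    geno: GenotypeMatrix | np.ndarray, method: str = "centered"
) -> np.ndarray:
    """Compute the n x n genomic relationship matrix.

    Parameters
    ----------
    geno : GenotypeMatrix or (n, p) dosage array
    method : {"centered", "scaled"}
        ``"centered"`` is the plain cross-product form; ``"scaled"``
        additionally standardizes each marker by sqrt(2 f (1-f)).
    """
    dosage = geno.dosage if isinstance(geno, GenotypeMatrix) else np.asarray(geno, float)
    n, p = dosage.shape
    if p == 0:
        raise ValueError("no markers: cannot build a GRM")
    X = mean_impute(dosage)
    Xc = X - X.mean(axis=0, keepdims=True)
    if method == "scaled":
        f = X.mean(axis=0) / 2.0
        denom = np.sqrt(2.0 * f * (1.0 - f))
        denom[denom == 0] = 1.0  # monomorphic columns contribute zero anyway
        Xc = Xc / denom
    elif method != "centered":
        raise ValueError(f"unknown GRM method: {method!r}")
    return (Xc @ Xc.T) / p


def grm_sqrt_factor(dosage: np.ndarray) -> np.ndarray:
    """Symmetric square root of the centered GRM, as an n x r factor.

    Returns L with L @ L.T = G; computed from the thin SVD of the centered
    dosage matrix, so the cost is O(n p min(n, p)) rather than O(n^3).
    """
    X = mean_impute(dosage)
    Xc = X - X.mean(axis=0, keepdims=True)
    p = Xc.shape[1]
    U, s, _ = np.linalg.svd(Xc, full_matrices=False)
    return U * (s / np.sqrt(p))
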