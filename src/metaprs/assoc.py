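"""Per-study GWAS engine.

Inverse-rank normalization of the trait, principal components of the dosage
matrix, and per-variant ordinary-least-squares association producing summary
statistics in the standard (CHR POS ID EA OA EAF BETA SE P N K) layout the
meta-analysis consumes.  Mixed-model association is deliberately out of
scope: the synthetic cohorts contain no cryptic relatedness, and downstream
stages consume only (beta, SE).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .synthdata import GenotypePanel

log = logging.getLogger(__name__)

SUMMARY_COLUMNS = ["CHR", "POS", "ID", "EA", "OA", "EAF", "BETA", "SE", "P", "N", "K"]

def inverse_normal_transform(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse normal transform.

    Maps value with rank r (average ranks for ties) to
    ``Phi^-1((r - offset) / (n - 2*offset + 1))``.  The default offset is the
    Blom constant 3/8.  Rejects inputs with no rank information (all values
    identical).
    """
    x = np.asarray(values, dtype=float).ravel()
    if x.size < 2:
        raise ValueError("need at least two values")
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if np.all(x == x[0]):
        raise ValueError("all values identical: no rank information")
    ranks = stats.rankdata(x, method="average")
    n = x.size
    return stats.norm.ppf((ranks - offset) / (n - 2.0 * offset + 1.0))

def _standardize_dosages(dosages: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center/scale dosage columns; returns (standardized, keep mask)."""
    X = dosages.astype(np.float64)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Xs = (X[:, keep] - mu[keep]) / sd[keep]
    return Xs, keep

def compute_pcs(panel: GenotypePanel, k: int, seed: int = 0) -> np.ndarray:
    """Leading principal components of the standardized dosage matrix.

    Returns an individuals x k matrix of orthonormal scores (left singular
    vectors), explained variance non-increasing across columns.  Sign fixed by
    making each component's largest-magnitude variant loading positive.
    Monomorphic variants are dropped before standardization.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    Xs, keep = _standardize_dosages(panel.dosages)
    if k >= min(Xs.shape):
        raise ValueError(f"k={k} must be < min(n_individuals, n_variants)={min(Xs.shape)}")
    solver = "full" if min(Xs.shape) <= 500 else "randomized"
    pca = PCA(n_components=k, svd_solver=solver, random_state=seed)
    scores = pca.fit_transform(Xs)
    sv = pca.singular_values_
    scores = scores / sv  # back to orthonormal left singular vectors
    for j in range(k):
        load = pca.components_[j]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, j] = -scores[:, j]
    return scores

def _design(pheno: pd.DataFrame, covariates, extra: np.ndarray | None = None) -> np.ndarray:
    """Intercept + covariate design matrix; 'sex' coded female = 1."""
    cols = [np.ones(len(pheno))]
    for c in covariates:
        v = pheno[c]
        if c == "sex" or not pd.api.types.is_numeric_dtype(v):
            if c == "sex":
                cols.append((v.to_numpy() == "F").astype(float))
            else:
                d = pd.get_dummies(v, drop_first=True, dtype=float)
                cols.extend(d[c2].to_numpy() for c2 in d.columns)
        else:
            cols.append(v.to_numpy(dtype=float))
    C = np.column_stack(cols)
    if extra is not None:
        C = np.column_stack([C, extra])
    return C

def run_gwas(
    panel: GenotypePanel,
    pheno: pd.DataFrame,
    covariates=(),
    trait: str = "trait",
    pcs: np.ndarray | None = None,
    chunk: int = 4096,
) -> pd.DataFrame:
    """Per-variant OLS association of ``trait`` on dosage + covariates.

    The covariates (plus optional pre-computed PC scores) are projected out of
    both trait and dosages (Frisch-Waugh-Lovell), after which each variant's
    effect reduces to a simple regression on its residualized dosage; beta, SE
    and the two-sided t-test p-value are identical to the full joint OLS fit.
    Monomorphic variants yield rows with missing beta/se and are counted in a
    logged skip total.  The trait is expected to be inverse-rank normalized
    already.
    """
    if len(pheno) != panel.n_individuals:
        raise ValueError("phenotype rows must match panel individuals")
    y = pheno[trait].to_numpy(dtype=float)
    C = _design(pheno, covariates, extra=pcs)
    n, p = C.shape
    Q, _ = np.linalg.qr(C)
    y_res = y - Q @ (Q.T @ y)
    dof = n - p - 1

    m = panel.n_variants
    beta = np.full(m, np.nan)
    se = np.full(m, np.nan)
    pval = np.full(m, np.nan)
    eaf = panel.dosages.mean(axis=0) / 2.0
    yss = float(y_res @ y_res)
    skipped = 0
    for lo in range(0, m, chunk):
        hi = min(lo + chunk, m)
        X = panel.dosages[:, lo:hi].astype(np.float64)
        mono = X.std(axis=0) == 0
        skipped += int(mono.sum())
        Xr = X - Q @ (Q.T @ X)
        xx = np.einsum("ij,ij->j", Xr, Xr)
        xy = y_res @ Xr
        ok = ~mono & (xx > 0)
        b = np.where(ok, xy / np.where(xx > 0, xx, 1.0), np.nan)
        rss = yss - b * xy
        sigma2 = rss / dof
        s = np.sqrt(np.maximum(sigma2, 0.0) / np.where(xx > 0, xx, np.nan))
        with np.errstate(divide="ignore", invalid="ignore"):
            t = b / s
        beta[lo:hi] = np.where(ok, b, np.nan)
        se[lo:hi] = np.where(ok, s, np.nan)
        pval[lo:hi] = np.where(ok, 2.0 * stats.t.sf(np.abs(t), dof), np.nan)
    if skipped:
        log.info("run_gwas: skipped %d monomorphic variants", skipped)

    out = panel.variants[["CHR", "POS", "ID", "EA", "OA"]].copy()
    out["EAF"] = eaf
    out["BETA"] = beta
    out["SE"] = se
    out["P"] = pval
    out["N"] = n
    out["K"] = 1
    out.attrs["skipped_monomorphic"] = skipped
    return out
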