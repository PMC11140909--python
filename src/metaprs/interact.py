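"""PRS x environment / sex / region interaction models and region contrasts.

Linear interaction models of the trait on PRS, a modifier (sex, region, or a
lifestyle covariate), their product, and adjustment covariates; stratified
PRS evaluation with a pooled interaction test; and the descriptive
region-comparison statistics — allele-frequency correlation between panels
and the LD-decay (r-squared versus physical distance) profile.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .prs import IncrementalR2, incremental_r2
from .synthdata import GenotypePanel

log = logging.getLogger(__name__)

#: Reference levels for dummy-coded categorical modifiers.
REFERENCE_LEVELS = {
    "sex": "M",
    "region": "East",
    "smoking": "never",
    "alcohol": "never",
    "socioeconomic": "low",
}

@dataclass
class InteractionFit:
    term: str
    estimate: float
    se: float
    p_int: float
    n: int

@dataclass
class InteractionResult:
    fits: list[InteractionFit]
    omnibus_f: float
    omnibus_p: float
    n: int
    model: object  # fitted statsmodels results, for inspection

def _standardize(x: np.ndarray, name: str) -> np.ndarray:
    sd = x.std()
    if sd == 0:
        raise ValueError(f"{name} is constant")
    return (x - x.mean()) / sd

def _modifier_columns(pheno: pd.DataFrame, modifier: str):
    """Encode the modifier: list of (label, column) plus dropped-level log."""
    col = pheno[modifier]
    if modifier not in ("sex",) and pd.api.types.is_numeric_dtype(col):
        return [(modifier, _standardize(col.to_numpy(dtype=float), modifier))], []
    ref = REFERENCE_LEVELS.get(modifier)
    if ref is None or ref not in set(col):
        # fall back to the first level so the design stays full-rank
        fallback = sorted(map(str, pd.unique(col)))[0]
        if ref is not None:
            log.info("fit_interaction: reference level %r absent, using %r",
                     ref, fallback)
        ref = fallback
    levels = [l for l in pd.unique(col) if str(l) != str(ref)]
    if not levels:
        raise ValueError(f"modifier {modifier!r} has a single level")
    dropped = []
    out = []
    for level in sorted(map(str, levels)):
        ind = (col.astype(str) == level).to_numpy().astype(float)
        if ind.sum() == 0:
            dropped.append(level)
            continue
        out.append((f"{modifier}[{level}]", ind))
    if dropped:
        log.info("fit_interaction: empty categories omitted: %s", dropped)
    return out, dropped

def fit_interaction(
    pheno: pd.DataFrame,
    score_values,
    modifier: str,
    covariates=(),
    trait: str = "trait",
) -> InteractionResult:
    """OLS of trait on PRS + modifier + PRS x modifier + covariates.

    The PRS is standardized; categorical modifiers are dummy-coded against
    the field's reference levels (never-smoker, never-consumer, male, East
    region); continuous modifiers are standardized.  Returns one
    :class:`InteractionFit` per interaction contrast plus an omnibus F-test
    of all interaction terms jointly (the single-p-per-factor style used in
    epidemiological reports).
    """
    s = _standardize(np.asarray(score_values, dtype=float), "PRS")
    y = pheno[trait].to_numpy(dtype=float)
    mod_cols, _ = _modifier_columns(pheno, modifier)

    names = ["const"]
    X_parts = [np.ones(len(y)), s]
    names.append("PRS")
    for label, colv in mod_cols:
        X_parts.append(colv)
        names.append(label)
    int_names = []
    for label, colv in mod_cols:
        X_parts.append(s * colv)
        nm = f"PRS:{label}"
        names.append(nm)
        int_names.append(nm)
    from .prs import _covariate_matrix

    C = _covariate_matrix(pheno, covariates)[:, 1:]  # drop duplicate intercept
    X = np.column_stack(X_parts + ([C] if C.size else []))
    cov_names = []
    for c in covariates:
        v = pheno[c]
        if c == "sex" or not pd.api.types.is_numeric_dtype(v):
            if c == "sex":
                cov_names.append("sex[F]")
            else:
                cov_names.extend(f"{c}[{l}]" for l in pd.get_dummies(v, drop_first=True).columns)
        else:
            cov_names.append(c)
    names = names + cov_names

    ok = np.all(np.isfinite(X), axis=1) & np.isfinite(y)
    res = sm.OLS(y[ok], pd.DataFrame(X[ok], columns=names)).fit()
    fits = [
        InteractionFit(
            term=f"PRS x {nm.split(':', 1)[1]}" if ":" in nm else nm,
            estimate=float(res.params[nm]),
            se=float(res.bse[nm]),
            p_int=float(res.pvalues[nm]),
            n=int(ok.sum()),
        )
        for nm in int_names
    ]
    restriction = np.zeros((len(int_names), X.shape[1]))
    for i, nm in enumerate(int_names):
        restriction[i, names.index(nm)] = 1.0
    ftest = res.f_test(restriction)
    return InteractionResult(
        fits=fits,
        omnibus_f=float(ftest.fvalue),
        omnibus_p=float(ftest.pvalue),
        n=int(ok.sum()),
        model=res,
    )

@dataclass
class StratifiedEval:
    per_stratum: pd.DataFrame  # stratum, incremental, p_prs, n
    interaction_p: float
    interaction_f: float

def stratified_prs_eval(
    pheno: pd.DataFrame,
    score_values,
    stratum: str,
    covariates=(),
    trait: str = "trait",
) -> StratifiedEval:
    """Incremental R^2 per stratum plus a pooled PRS x stratum interaction test."""
    s = np.asarray(score_values, dtype=float)
    levels = sorted(map(str, pd.unique(pheno[stratum])))
    if len(levels) < 2:
        raise ValueError(f"stratum {stratum!r} has a single level")
    rows = []
    for level in levels:
        mask = (pheno[stratum].astype(str) == level).to_numpy()
        sub = pheno[mask].reset_index(drop=True)
        res: IncrementalR2 = incremental_r2(sub, s[mask], covariates=covariates, trait=trait)
        rows.append((level, res.incremental, res.p_prs, res.n))
    pooled = fit_interaction(pheno, s, modifier=stratum, covariates=covariates, trait=trait)
    return StratifiedEval(
        per_stratum=pd.DataFrame(rows, columns=["stratum", "incremental", "p_prs", "n"]),
        interaction_p=pooled.omnibus_p,
        interaction_f=pooled.omnibus_f,
    )

def allele_freq_correlation(
    panel_a: GenotypePanel,
    panel_b: GenotypePanel,
    variant_ids=None,
) -> tuple[float, pd.DataFrame]:
    """Pearson correlation of effect-allele frequencies between two panels.

    Frequencies are paired on shared variant IDs (restricted to
    ``variant_ids`` when given, e.g. the SNPs of a region-specific PRS).
    Symmetric in its panel arguments.
    """
    fa = pd.Series(panel_a.eaf(), index=panel_a.variants["ID"])
    fb = pd.Series(panel_b.eaf(), index=panel_b.variants["ID"])
    shared = fa.index.intersection(fb.index)
    if variant_ids is not None:
        shared = shared.intersection(pd.Index(variant_ids))
    if len(shared) < 2:
        raise ValueError("need at least two shared variants")
    r, _ = stats.pearsonr(fa[shared], fb[shared])
    pairs = pd.DataFrame({"ID": shared, "freq_a": fa[shared].to_numpy(),
                          "freq_b": fb[shared].to_numpy()})
    return float(r), pairs

def ld_decay_profile(
    panel: GenotypePanel,
    variant_ids=None,
    max_distance: int = 500_000,
    bins: int = 20,
) -> pd.DataFrame:
    """Mean pairwise dosage r-squared binned by physical distance.

    All within-chromosome pairs closer than ``max_distance`` are computed
    from standardized dosages; returns (bin_lo, bin_hi, mean_r2, n_pairs)
    with equal-width bins covering [0, max_distance).
    """
    pv = panel.variants
    mask = np.ones(len(pv), dtype=bool)
    if variant_ids is not None:
        mask = pv["ID"].isin(set(variant_ids)).to_numpy()
    X = panel.dosages[:, mask].astype(np.float64)
    pos = pv["POS"].to_numpy()[mask]
    chrom = pv["CHR"].astype(str).to_numpy()[mask]
    n = X.shape[0]
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = np.inf
    Xs = (X - mu) / sd

    dists, r2s = [], []
    for c in np.unique(chrom):
        idx = np.where(chrom == c)[0]
        cpos = pos[idx]
        order = np.argsort(cpos, kind="mergesort")
        idx, cpos = idx[order], cpos[order]
        for a in range(len(idx)):
            b_hi = np.searchsorted(cpos, cpos[a] + max_distance, side="right")
            if b_hi <= a + 1:
                continue
            tgt = idx[a + 1 : b_hi]
            r = (Xs[:, tgt].T @ Xs[:, idx[a]]) / n
            dists.append(cpos[a + 1 : b_hi] - cpos[a])
            r2s.append(r**2)
    if not dists:
        raise ValueError("no variant pairs within max_distance")
    d = np.concatenate(dists).astype(float)
    r2 = np.concatenate(r2s)
    edges = np.linspace(0.0, float(max_distance), bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, bins - 1)
    rows = []
    for b in range(bins):
        m = which == b
        rows.append((edges[b], edges[b + 1],
                     float(r2[m].mean()) if m.any() else np.nan, int(m.sum())))
    return pd.DataFrame(rows, columns=["bin_lo", "bin_hi", "mean_r2", "n_pairs"])

def fit_ld_decay(profile: pd.DataFrame, allele_freq: float | None = 0.5,
                 n_individuals: int | None = None) -> float:
    """Estimate the latent LD-decay scale (bp) from an r^2-vs-distance profile.

    The generator's latent haplotype correlation is rho(d) = exp(-d/L); the
    dosage correlation of thresholded Gaussians is attenuated, with the exact
    inverse r = (2/pi) asin(rho) at allele frequency 0.5.  With
    ``allele_freq=0.5`` the bin means are mapped back through the tetrachoric
    transform and L comes from a weighted log-linear fit of rho on distance;
    otherwise a plain exp(-2d/L) fit of r^2 is used (small attenuation bias).
    ``n_individuals`` subtracts the finite-sample noise floor 1/n from r^2.
    """
    prof = profile.dropna(subset=["mean_r2"])
    d = ((prof["bin_lo"] + prof["bin_hi"]) / 2.0).to_numpy()
    r2 = prof["mean_r2"].to_numpy().copy()
    w = prof["n_pairs"].to_numpy(dtype=float)
    if n_individuals:
        r2 = r2 - 1.0 / n_individuals
    good = r2 > 1e-4
    d, r2, w = d[good], r2[good], w[good]
    if len(d) < 2:
        raise ValueError("not enough informative distance bins")
    r = np.sqrt(r2)
    if allele_freq is not None and abs(allele_freq - 0.5) < 1e-6:
        rho = np.sin(np.pi * np.clip(r, 0, 1) / 2.0)
    else:
        rho = np.clip(r, 1e-12, 1)
    lo = np.log(rho)
    # weighted least squares through the origin: log rho = -d/L
    slope = float((w * d * lo).sum() / (w * d**2).sum())
    if slope >= 0:
        raise ValueError("no decay detected")
    return -1.0 / slope
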