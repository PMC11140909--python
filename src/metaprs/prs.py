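"""Clumping-and-thresholding polygenic scores and their evaluation.

Covers the C+T workflow: LD clumping of discovery summary statistics against
a target genotype panel (default 250 kb window, r-squared 0.8), a grid search
over p-value thresholds on a validation split, additive scoring, incremental
variance explained (full model with PRS minus covariates-only model), decile
contrasts, and a sex/region-stratified validation/test split of the target
cohort.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthdata import GenotypePanel

log = logging.getLogger(__name__)

DEFAULT_GRID = (5e-8, 1e-6, 1e-5, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.2, 0.5, 1.0)

@dataclass
class PRSModel:
    """(variant, effect allele, weight) list plus the C+T parameters behind it."""

    weights: pd.DataFrame  # columns ID, EA, BETA
    clump_distance: int
    clump_r2: float
    p_threshold: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.weights["ID"].duplicated().any():
            raise ValueError("duplicate variant IDs in PRS weights")
        if not np.all(np.isfinite(self.weights["BETA"])):
            raise ValueError("weights must be finite")

    @property
    def n_variants(self) -> int:
        return len(self.weights)

def clump(
    summary: pd.DataFrame,
    panel: GenotypePanel,
    distance: int = 250_000,
    r2_threshold: float = 0.8,
) -> pd.DataFrame:
    """Greedy LD clumping of ``summary`` using LD computed in ``panel``.

    Variants are processed by ascending p (ties: lower position first); each
    index variant is retained and every unprocessed variant within
    ``distance`` bp whose dosage r-squared with the index exceeds
    ``r2_threshold`` is removed.  Summary variants absent from the panel are
    dropped with a logged count.  Returns the retained subset of ``summary``.
    """
    pv = panel.variants
    key_to_col = {(c, p): j for j, (c, p) in enumerate(zip(pv["CHR"].astype(str), pv["POS"]))}
    sm = summary.dropna(subset=["BETA", "SE", "P"]).copy()
    cols = [key_to_col.get((str(c), p), -1) for c, p in zip(sm["CHR"], sm["POS"])]
    sm["_col"] = cols
    n_missing = int((sm["_col"] < 0).sum())
    if n_missing:
        log.info("clump: %d summary variants absent from panel, dropped", n_missing)
        sm = sm[sm["_col"] >= 0]
    if len(sm) == 0:
        raise ValueError("no overlap between summary statistics and panel")
    sm = sm.sort_values(["P", "POS"], kind="mergesort").reset_index(drop=True)

    X = panel.dosages.astype(np.float32)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = np.inf  # monomorphic: zero correlation with anything
    Xs = (X - mu) / sd
    n = X.shape[0]

    order_pos = sm["POS"].to_numpy()
    order_chr = sm["CHR"].astype(str).to_numpy()
    order_col = sm["_col"].to_numpy()
    alive = np.ones(len(sm), dtype=bool)
    retained = []
    # within-chromosome candidate lookup sorted by position
    by_chr: dict[str, np.ndarray] = {}
    for c in np.unique(order_chr):
        idx = np.where(order_chr == c)[0]
        by_chr[c] = idx[np.argsort(order_pos[idx], kind="mergesort")]
    pos_sorted = {c: order_pos[idx] for c, idx in by_chr.items()}

    for i in range(len(sm)):
        if not alive[i]:
            continue
        alive[i] = False
        retained.append(i)
        c = order_chr[i]
        idx_sorted = by_chr[c]
        ps = pos_sorted[c]
        lo = np.searchsorted(ps, order_pos[i] - distance, side="left")
        hi = np.searchsorted(ps, order_pos[i] + distance, side="right")
        cand = idx_sorted[lo:hi]
        cand = cand[alive[cand]]
        if cand.size == 0:
            continue
        r = (Xs[:, order_col[cand]].T @ Xs[:, order_col[i]]) / n
        kill = cand[r**2 > r2_threshold]
        alive[kill] = False
    out = (sm.iloc[sorted(retained)].drop(columns="_col")
           .sort_values(["CHR", "POS"], kind="mergesort").reset_index(drop=True))
    return out

def _orient_dosage(panel: GenotypePanel, weights: pd.DataFrame):
    """Match model variants to panel columns, resolving effect-allele flips.

    Returns (column indices, sign/offset arrays, matched mask): a model
    variant whose effect allele equals the panel's other allele contributes
    2 - dosage.
    """
    pv = panel.variants
    id_to_col = {vid: j for j, vid in enumerate(pv["ID"])}
    cols, flip, matched = [], [], []
    for row in weights.itertuples(index=False):
        j = id_to_col.get(row.ID, -1)
        if j < 0:
            cols.append(-1); flip.append(False); matched.append(False)
            continue
        ea, oa = pv["EA"].iloc[j], pv["OA"].iloc[j]
        if row.EA == ea:
            cols.append(j); flip.append(False); matched.append(True)
        elif row.EA == oa:
            cols.append(j); flip.append(True); matched.append(True)
        else:
            cols.append(-1); flip.append(False); matched.append(False)
    return (np.asarray(cols), np.asarray(flip), np.asarray(matched))

def score(panel: GenotypePanel, model: PRSModel,
          max_unmatched_frac: float = 0.5) -> np.ndarray:
    """Additive PRS: sum of beta_j x effect-allele dosage.

    Variants missing from the panel (or with mismatched alleles) contribute 0
    and are counted; more than ``max_unmatched_frac`` unmatched is an error.
    """
    if model.n_variants == 0:
        return np.zeros(panel.n_individuals)
    cols, flip, matched = _orient_dosage(panel, model.weights)
    n_unmatched = int((~matched).sum())
    if n_unmatched > max_unmatched_frac * model.n_variants:
        raise ValueError(
            f"{n_unmatched}/{model.n_variants} model variants unmatched in panel"
        )
    if n_unmatched:
        log.info("score: %d model variants unmatched, contribute 0", n_unmatched)
    betas = model.weights["BETA"].to_numpy()[matched]
    use_cols = cols[matched]
    use_flip = flip[matched]
    D = panel.dosages[:, use_cols].astype(float)
    D[:, use_flip] = 2.0 - D[:, use_flip]
    return D @ betas

@dataclass
class IncrementalR2:
    r2_full: float
    r2_null: float
    incremental: float
    p_prs: float
    n: int

def _ols_r2(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """R^2 plus coefficient vector and their SEs for an OLS fit with intercept."""
    coef, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    dof = len(y) - X.shape[1]
    sigma2 = rss / dof
    XtX_inv = np.linalg.pinv(X.T @ X)
    se = np.sqrt(np.maximum(np.diag(XtX_inv) * sigma2, 0.0))
    r2 = 1.0 - rss / tss if tss > 0 else np.nan
    return r2, coef, se

def _covariate_matrix(pheno: pd.DataFrame, covariates) -> np.ndarray:
    cols = [np.ones(len(pheno))]
    for c in covariates:
        v = pheno[c]
        if c == "sex":
            cols.append((v.to_numpy() == "F").astype(float))
        elif pd.api.types.is_numeric_dtype(v):
            cols.append(v.to_numpy(dtype=float))
        else:
            d = pd.get_dummies(v, drop_first=True, dtype=float)
            cols.extend(d[c2].to_numpy() for c2 in d.columns)
    return np.column_stack(cols)

def incremental_r2(
    pheno: pd.DataFrame,
    score_values,
    covariates=(),
    trait: str = "trait",
) -> IncrementalR2:
    """Variance explained by the PRS over the covariates-only model.

    Fits trait ~ covariates (null) and trait ~ covariates + PRS (full) by
    OLS on complete cases; incremental = R2_full - R2_null (non-negative for
    nested fits); p_prs is the two-sided t-test of the PRS coefficient.
    Rows with missing values are deleted and logged.
    """
    s = np.asarray(score_values, dtype=float)
    y = pheno[trait].to_numpy(dtype=float)
    C = _covariate_matrix(pheno, covariates)
    ok = np.isfinite(y) & np.isfinite(s) & np.all(np.isfinite(C), axis=1)
    n_drop = int((~ok).sum())
    if n_drop:
        log.info("incremental_r2: dropped %d incomplete rows", n_drop)
    y, s, C = y[ok], s[ok], C[ok]
    n = len(y)
    if n <= C.shape[1] + 2:
        raise ValueError("fewer rows than model parameters")
    r2_null, _, _ = _ols_r2(y, C)
    Xf = np.column_stack([C, s])
    r2_full, coef, se = _ols_r2(y, Xf)
    dof = n - Xf.shape[1]
    if se[-1] > 0:
        t = coef[-1] / se[-1]
        p = float(2.0 * stats.t.sf(abs(t), dof))
    else:
        p = np.nan if np.var(s) == 0 else 0.0
    return IncrementalR2(
        r2_full=float(r2_full),
        r2_null=float(r2_null),
        incremental=float(max(r2_full - r2_null, 0.0)),
        p_prs=p,
        n=n,
    )

@dataclass
class ThresholdSearchResult:
    best_model: PRSModel
    grid: pd.DataFrame  # threshold, n_variants, r2_full, r2_null, incremental, p_prs

def threshold_search(
    summary: pd.DataFrame,
    panel_valid: GenotypePanel,
    pheno_valid: pd.DataFrame,
    grid=DEFAULT_GRID,
    clump_distance: int = 250_000,
    clump_r2: float = 0.8,
    covariates=(),
    trait: str = "trait",
    source: str = "",
) -> ThresholdSearchResult:
    """Select the best p-value threshold on the validation cohort.

    Clumps once at (clump_distance, clump_r2) against the validation panel,
    then for each threshold in ``grid`` filters to p <= threshold, scores the
    validation individuals, and records incremental R^2.  The returned model
    maximizes incremental R^2; exact ties go to the smaller (stricter)
    threshold.  Thresholds whose model is empty are reported with missing
    metrics rather than failing.
    """
    clumped = clump(summary, panel_valid, distance=clump_distance, r2_threshold=clump_r2)
    rows = []
    best = None
    for thr in sorted(grid):
        sel = clumped[clumped["P"] <= thr]
        if len(sel) == 0:
            rows.append((thr, 0, np.nan, np.nan, np.nan, np.nan))
            continue
        model = PRSModel(
            weights=sel[["ID", "EA", "BETA"]].reset_index(drop=True),
            clump_distance=clump_distance,
            clump_r2=clump_r2,
            p_threshold=thr,
            source=source,
        )
        s = score(panel_valid, model)
        res = incremental_r2(pheno_valid, s, covariates=covariates, trait=trait)
        rows.append((thr, model.n_variants, res.r2_full, res.r2_null,
                     res.incremental, res.p_prs))
        if best is None or res.incremental > best[0]:
            best = (res.incremental, model)
    grid_df = pd.DataFrame(
        rows,
        columns=["threshold", "n_variants", "r2_full", "r2_null", "incremental", "p_prs"],
    )
    if best is None:
        raise ValueError("every grid threshold produced an empty model")
    return ThresholdSearchResult(best_model=best[1], grid=grid_df)

def decile_contrast(score_values, trait_values) -> pd.DataFrame:
    """Mean trait difference of each PRS decile against decile 1.

    Deciles are rank-based on the score (stable sort; ties fall to the lower
    decile).  Returns a 10-row table (decile, n, mean_trait, diff_vs_d1);
    the first difference is 0 by construction.
    """
    s = np.asarray(score_values, dtype=float)
    y = np.asarray(trait_values, dtype=float)
    n = len(s)
    if n < 10:
        raise ValueError("need at least 10 individuals for deciles")
    order = np.argsort(s, kind="mergesort")
    decile = np.empty(n, dtype=int)
    decile[order] = (10 * np.arange(n)) // n + 1
    rows = []
    ref = y[decile == 1].mean()
    for d in range(1, 11):
        mask = decile == d
        rows.append((d, int(mask.sum()), float(y[mask].mean()),
                     float(y[mask].mean() - ref)))
    return pd.DataFrame(rows, columns=["decile", "n", "mean_trait", "diff_vs_d1"])

@dataclass
class SplitPlan:
    assignment: pd.Series  # "validation" / "test" per individual index
    strata: list[str]
    frac_validation: float
    seed: int

    @property
    def validation_index(self) -> np.ndarray:
        return np.where(self.assignment.to_numpy() == "validation")[0]

    @property
    def test_index(self) -> np.ndarray:
        return np.where(self.assignment.to_numpy() == "test")[0]

def stratified_split(
    pheno: pd.DataFrame,
    frac_validation: float,
    strata=("sex", "region"),
    seed: int = 0,
) -> SplitPlan:
    """Random validation/test partition balanced within strata.

    Within each stratum cell exactly round(frac * n_cell) individuals go to
    validation; deterministic under ``seed``.
    """
    if not (0.0 < frac_validation < 1.0):
        raise ValueError("frac_validation must be in (0, 1)")
    strata = list(strata)
    for c in strata:
        if c not in pheno.columns:
            raise ValueError(f"stratum column {c!r} missing")
    rng = np.random.default_rng(seed)
    assign = np.full(len(pheno), "test", dtype=object)
    cells = pheno.groupby(strata, sort=True).indices if strata else {"all": np.arange(len(pheno))}
    for _, idx in sorted(cells.items(), key=lambda kv: str(kv[0])):
        idx = np.asarray(idx)
        n_val = int(round(frac_validation * len(idx)))
        chosen = rng.choice(idx, size=n_val, replace=False)
        assign[chosen] = "validation"
    return SplitPlan(
        assignment=pd.Series(assign, index=pheno.index),
        strata=strata,
        frac_validation=frac_validation,
        seed=seed,
    )

def subset_panel(panel: GenotypePanel, index: np.ndarray) -> GenotypePanel:
    """Row-subset of a panel (same variants)."""
    return GenotypePanel(
        dosages=panel.dosages[index],
        variants=panel.variants,
        populations=panel.populations[index],
    )
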