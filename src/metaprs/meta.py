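"""Fixed-effects inverse-variance-weighted meta-analysis with double genomic control.

The correction pipeline mirrors the two-stage scheme used for multi-ancestry
BMI meta-analysis: per-study standard errors are first inflated by the square
root of a supplied correction factor (an LDSC intercept where available, the
study's own lambda_GC in ``"auto"`` mode); the corrected studies are combined
by inverse-variance weighting; lambda_GC of the combined z-scores is then
applied once more to the meta-analysis standard errors ("double" genomic
control).  Correction factors are clamped at 1 when applied — standard errors
are never deflated — but the unclamped lambdas are always reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import CHI2_1_MEDIAN

_AMBIGUOUS = {frozenset(("A", "T")), frozenset(("C", "G"))}

def ivw_meta(betas, ses) -> tuple[float, float, float]:
    """Fixed-effects inverse-variance-weighted combination.

    beta = sum(w_i b_i) / sum(w_i) with w_i = 1/SE_i^2;
    SE = sum(w_i)^(-1/2); p from the two-sided normal test of beta/SE.
    """
    b = np.asarray(betas, dtype=float)
    s = np.asarray(ses, dtype=float)
    if b.size == 0:
        raise ValueError("need at least one study")
    if np.any(s <= 0):
        raise ValueError("all standard errors must be positive")
    w = 1.0 / s**2
    beta = float((w * b).sum() / w.sum())
    se = float(w.sum() ** -0.5)
    p = float(2.0 * stats.norm.sf(abs(beta / se)))
    return beta, se, p

def genomic_control_lambda(z_scores, min_variants: int = 100) -> float:
    """lambda_GC = median(z^2) / median of chi-square_1 (0.4549364)."""
    z = np.asarray(z_scores, dtype=float)
    z = z[np.isfinite(z)]
    if z.size < min_variants:
        raise ValueError(f"need >= {min_variants} finite z-scores, got {z.size}")
    return float(np.median(z**2) / CHI2_1_MEDIAN)

@dataclass
class HarmonizedStudies:
    """Long-format alignment of several summary-statistic tables.

    ``table`` has one row per (variant key, study) with betas oriented to the
    first study reporting the variant; ``drop_log`` records every discarded
    row with a reason code (ambiguous_alleles, allele_mismatch).
    """

    table: pd.DataFrame
    drop_log: pd.DataFrame

def harmonize(studies: list[pd.DataFrame]) -> HarmonizedStudies:
    """Align studies on (chromosome, position, allele pair) keys.

    Effect sizes and frequencies are flipped where a study reports the
    effect/other alleles swapped relative to the first study carrying the
    variant.  Strand-ambiguous pairs (A/T, C/G) and allele-pair mismatches are
    dropped and logged; a duplicate key within one study is an error.
    """
    ref_alleles: dict = {}
    pair_at_pos: dict = {}
    rows = []
    drops = []
    for s_idx, df in enumerate(studies):
        key_seen = set()
        for row in df.itertuples(index=False):
            pair = frozenset((row.EA, row.OA))
            pos_key = (row.CHR, int(row.POS))
            key = (row.CHR, int(row.POS), tuple(sorted(pair)))
            if key in key_seen:
                raise ValueError(f"duplicate variant key {key} in study {s_idx}")
            key_seen.add(key)
            if pair in _AMBIGUOUS or row.EA == row.OA:
                drops.append((s_idx, row.CHR, row.POS, row.EA, row.OA, "ambiguous_alleles"))
                continue
            if pos_key in pair_at_pos and pair_at_pos[pos_key] != pair:
                drops.append((s_idx, row.CHR, row.POS, row.EA, row.OA, "allele_mismatch"))
                continue
            pair_at_pos[pos_key] = pair
            if key not in ref_alleles:
                ref_alleles[key] = (row.EA, row.OA, row.ID)
            ea_ref, oa_ref, id_ref = ref_alleles[key]
            if (row.EA, row.OA) == (ea_ref, oa_ref):
                beta, eaf = row.BETA, row.EAF
            elif (row.EA, row.OA) == (oa_ref, ea_ref):
                beta, eaf = -row.BETA, 1.0 - row.EAF
            else:
                drops.append((s_idx, row.CHR, row.POS, row.EA, row.OA, "allele_mismatch"))
                continue
            rows.append(
                (row.CHR, int(row.POS), id_ref, ea_ref, oa_ref, s_idx,
                 eaf, beta, row.SE, row.P, int(row.N))
            )
    table = pd.DataFrame(
        rows,
        columns=["CHR", "POS", "ID", "EA", "OA", "study", "EAF", "BETA", "SE", "P", "N"],
    )
    if len(table):
        table["K"] = table.groupby(["CHR", "POS", "EA", "OA"])["study"].transform("size")
    else:
        table["K"] = pd.Series(dtype=int)
    drop_log = pd.DataFrame(
        drops, columns=["study", "CHR", "POS", "EA", "OA", "reason"]
    )
    return HarmonizedStudies(table=table, drop_log=drop_log)

def _meta_collapse(long: pd.DataFrame) -> pd.DataFrame:
    """IVW-combine a harmonized long table; one output row per variant key."""
    w = 1.0 / long["SE"] ** 2
    g = long.assign(_w=w, _wb=w * long["BETA"], _wf=w * long["EAF"]).groupby(
        ["CHR", "POS", "ID", "EA", "OA"], sort=True
    )
    agg = g.agg(
        wsum=("_w", "sum"),
        wbsum=("_wb", "sum"),
        wfsum=("_wf", "sum"),
        N=("N", "sum"),
        K=("study", "size"),
    ).reset_index()
    agg["BETA"] = agg["wbsum"] / agg["wsum"]
    agg["SE"] = agg["wsum"] ** -0.5
    agg["EAF"] = agg["wfsum"] / agg["wsum"]
    z = agg["BETA"] / agg["SE"]
    agg["P"] = 2.0 * stats.norm.sf(np.abs(z))
    return agg[["CHR", "POS", "ID", "EA", "OA", "EAF", "BETA", "SE", "P", "N", "K"]]

def meta_analyze(studies: list[pd.DataFrame], min_k: int = 2) -> pd.DataFrame:
    """Plain fixed-effects IVW meta-analysis (no genomic control).

    Harmonizes the studies, keeps variants reported by >= ``min_k`` of them,
    and IVW-combines per variant.  Use :func:`double_gc_meta` when residual
    structural inflation must be corrected; genomic control assumes the bulk
    of variants are null, so on signal-dense designs this uncorrected
    combination is the appropriate one.
    """
    harm = harmonize(studies)
    keep = harm.table["K"] >= min_k
    return _meta_collapse(harm.table[keep])

@dataclass
class DoubleGCResult:
    """Output of :func:`double_gc_meta`.

    ``table`` is the final (stage gc2) meta-analysis; ``stages`` stacks the
    raw / gc1 / gc2 meta tables with a ``stage`` column for audit;
    ``lambda_raw``/``lambda_gc1`` are lambda_GC of the meta z-scores before
    and after stage-1 per-study correction; ``lambda_meta`` is the (unclamped)
    lambda applied at stage 2; ``study_factors`` the per-study stage-1
    correction factors actually applied.
    """

    table: pd.DataFrame
    stages: pd.DataFrame
    lambda_raw: float
    lambda_gc1: float
    lambda_meta: float
    study_factors: list[float]
    drop_log: pd.DataFrame = field(default_factory=pd.DataFrame)

def double_gc_meta(
    studies: list[pd.DataFrame],
    ldsc_intercepts="auto",
    min_k: int = 2,
    min_variants: int = 100,
) -> DoubleGCResult:
    """Meta-analysis with single + double genomic control.

    Stage 1 multiplies each study's SEs by sqrt(c_i), where c_i is the
    supplied LDSC intercept, or the study's own lambda_GC in ``"auto"`` mode
    (``None`` entries mean "no intercept available" and get factor 1, the
    convention for multi-ancestry studies where a single intercept is not
    meaningful).  Stage 2 IVW-combines the corrected studies, computes
    lambda_GC of the combined z-scores, and multiplies the meta SEs by
    sqrt(max(lambda, 1)).  Variants reported by fewer than ``min_k`` studies
    are excluded from the meta tables.
    """
    n_stud = len(studies)
    if ldsc_intercepts == "auto":
        factors = []
        for df in studies:
            z = (df["BETA"] / df["SE"]).to_numpy()
            factors.append(genomic_control_lambda(z, min_variants=min_variants))
    else:
        if len(ldsc_intercepts) != n_stud:
            raise ValueError("one intercept (or None) required per study")
        factors = [1.0 if c is None else float(c) for c in ldsc_intercepts]
        if any(c <= 0 for c in factors):
            raise ValueError("intercepts must be positive")
    applied = [max(c, 1.0) for c in factors]

    corrected = []
    for df, c in zip(studies, applied):
        d = df.copy()
        d["SE"] = d["SE"] * np.sqrt(c)
        corrected.append(d)

    harm_raw = harmonize(studies)
    harm = harmonize(corrected)
    keep = harm.table["K"] >= min_k
    keep_raw = harm_raw.table["K"] >= min_k

    meta_raw = _meta_collapse(harm_raw.table[keep_raw])
    meta_gc1 = _meta_collapse(harm.table[keep])
    z_raw = (meta_raw["BETA"] / meta_raw["SE"]).to_numpy()
    z_gc1 = (meta_gc1["BETA"] / meta_gc1["SE"]).to_numpy()
    lambda_raw = genomic_control_lambda(z_raw, min_variants=min_variants)
    lambda_meta = genomic_control_lambda(z_gc1, min_variants=min_variants)

    meta_gc2 = meta_gc1.copy()
    meta_gc2["SE"] = meta_gc2["SE"] * np.sqrt(max(lambda_meta, 1.0))
    z2 = meta_gc2["BETA"] / meta_gc2["SE"]
    meta_gc2["P"] = 2.0 * stats.norm.sf(np.abs(z2))

    stages = pd.concat(
        [meta_raw.assign(stage="raw"), meta_gc1.assign(stage="gc1"),
         meta_gc2.assign(stage="gc2")],
        ignore_index=True,
    )
    return DoubleGCResult(
        table=meta_gc2.assign(stage="gc2"),
        stages=stages,
        lambda_raw=lambda_raw,
        lambda_gc1=lambda_meta,
        lambda_meta=lambda_meta,
        study_factors=applied,
        drop_log=harm.drop_log,
    )
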