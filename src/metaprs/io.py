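"""Readers and writers for the pipeline's plain-text formats.

Summary statistics travel as TSV with the fixed header
(CHR POS ID EA OA EAF BETA SE P N K); genotypes as VCF v4.2 (GT) or a
documented dosage TSV; phenotypes/covariates as TSV with header.  All
coordinates are 1-based, intervals closed.  Every writer can prepend
provenance comment lines (stage, config hash, seed), which every reader
skips; floats are serialized with a fixed "%.10g" format so reruns are
byte-identical.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .synthdata import GenotypePanel, TraitTruth

log = logging.getLogger(__name__)

SUMMARY_REQUIRED = ["CHR", "POS", "ID", "EA", "OA", "EAF", "BETA", "SE", "P", "N"]
_FLOAT_FMT = "%.10g"

def _provenance_lines(stage: str | None, config_hash: str | None, seed: int | None):
    if stage is None:
        return []
    parts = [f"stage={stage}", "schema=1"]
    if config_hash is not None:
        parts.append(f"config_sha256={config_hash}")
    if seed is not None:
        parts.append(f"seed={seed}")
    return ["# metaprs " + " ".join(parts)]

def write_tsv(df: pd.DataFrame, path, stage: str | None = None,
              config_hash: str | None = None, seed: int | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _provenance_lines(stage, config_hash, seed):
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)

def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")

def write_summary_stats(df: pd.DataFrame, path, **prov) -> None:
    cols = SUMMARY_REQUIRED + (["K"] if "K" in df.columns else [])
    extra = [c for c in df.columns if c not in cols]
    write_tsv(df[cols + extra], path, **prov)

def read_summary_stats(path) -> pd.DataFrame:
    """Parse a summary-statistics TSV.

    Columns are header-keyed (any order); optional extra columns are kept;
    rows with missing or non-numeric required fields are dropped and counted
    in ``df.attrs['n_dropped']``.  A missing K column defaults to 1
    (single-study file).
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"CHR": str, "ID": str})
    missing = [c for c in SUMMARY_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"summary stats {path} missing columns {missing}")
    if "K" not in df.columns:
        df["K"] = 1
    numeric = ["POS", "EAF", "BETA", "SE", "P", "N", "K"]
    for c in numeric:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    ok = df[numeric].notna().all(axis=1)
    n_dropped = int((~ok).sum())
    if n_dropped:
        log.info("read_summary_stats(%s): dropped %d malformed rows", path, n_dropped)
    df = df[ok].reset_index(drop=True)
    df["POS"] = df["POS"].astype(np.int64)
    df["N"] = df["N"].astype(np.int64)
    df["K"] = df["K"].astype(np.int64)
    df.attrs["n_dropped"] = n_dropped
    return df

def write_phenotypes(pheno: pd.DataFrame, path, **prov) -> None:
    write_tsv(pheno, path, **prov)

def read_phenotypes(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")

# -- genotypes ---------------------------------------------------------------

def write_dosage_tsv(panel: GenotypePanel, path, sample_prefix: str = "s", **prov) -> None:
    """Dosage TSV: CHR POS ID OA EA then one {0,1,2} column per individual."""
    df = panel.variants[["CHR", "POS", "ID", "OA", "EA"]].copy()
    names = [f"{sample_prefix}{i}" for i in range(panel.n_individuals)]
    dos = pd.DataFrame(panel.dosages.T, columns=names)
    write_tsv(pd.concat([df.reset_index(drop=True), dos], axis=1), path, **prov)

def read_dosage_tsv(path, populations=None) -> GenotypePanel:
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"CHR": str, "ID": str})
    meta_cols = ["CHR", "POS", "ID", "OA", "EA"]
    sample_cols = [c for c in df.columns if c not in meta_cols]
    variants = df[meta_cols].copy()
    variants["ancestral_freq"] = np.nan
    dosages = df[sample_cols].to_numpy(dtype=np.int8).T
    pops = (np.asarray(populations) if populations is not None
            else np.repeat("NA", dosages.shape[0]))
    return GenotypePanel(dosages=dosages, variants=variants, populations=pops)

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}

def write_vcf(panel: GenotypePanel, path, sample_prefix: str = "s") -> None:
    """Plain-text VCF v4.2 with GT genotypes (REF = other allele, ALT = effect)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    names = [f"{sample_prefix}{i}" for i in range(panel.n_individuals)]
    pv = panel.variants
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=metaprs\n")
        for chrom in pd.unique(pv["CHR"]):
            length = int(pv.loc[pv["CHR"] == chrom, "POS"].max()) + 1
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(names) + "\n")
        dos = panel.dosages
        for j in range(panel.n_variants):
            row = pv.iloc[j]
            gts = "\t".join(_GT[int(d)] for d in dos[:, j])
            fh.write(f"{row['CHR']}\t{row['POS']}\t{row['ID']}\t{row['OA']}\t"
                     f"{row['EA']}\t.\tPASS\t.\tGT\t{gts}\n")

def read_vcf(path, populations=None) -> GenotypePanel:
    """Read a VCF into a dosage panel.

    GT is converted to effect-allele (ALT) counts; missing genotypes are
    mean-imputed to exactly 2 x EAF of the non-missing calls (PRSice
    convention; the panel then carries float dosages in [0, 2] instead of
    integer counts) and logged; multi-allelic records are dropped with a
    count.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    rows, dosage_rows = [], []
    n_multi = n_missing = 0
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        gt = np.asarray(v.gt_types)  # 0 HOM_REF, 1 HET, 2 UNKNOWN, 3 HOM_ALT
        d = np.where(gt == 3, 2, gt).astype(float)
        miss = gt == 2
        if miss.any():
            n_missing += int(miss.sum())
            eaf = d[~miss].mean() / 2.0 if (~miss).any() else 0.0
            d[miss] = 2.0 * eaf
        rows.append((str(v.CHROM), int(v.POS), v.ID or f"{v.CHROM}:{v.POS}",
                     v.REF, v.ALT[0]))
        dosage_rows.append(d)
    if n_multi:
        log.info("read_vcf(%s): dropped %d multi-allelic records", path, n_multi)
    if n_missing:
        log.info("read_vcf(%s): mean-imputed %d missing genotypes", path, n_missing)
    variants = pd.DataFrame(rows, columns=["CHR", "POS", "ID", "OA", "EA"])
    variants["ancestral_freq"] = np.nan
    if dosage_rows:
        dosages = np.vstack(dosage_rows).T
        if n_missing == 0:
            dosages = dosages.astype(np.int8)
    else:
        dosages = np.empty((0, 0), dtype=np.int8)
    pops = (np.asarray(populations) if populations is not None
            else np.repeat("NA", dosages.shape[0]))
    panel = GenotypePanel(dosages=dosages, variants=variants, populations=pops)
    panel.variants.attrs["n_multiallelic_dropped"] = n_multi
    return panel

# -- truth -------------------------------------------------------------------

def write_truth(truth: TraitTruth, path, **prov) -> None:
    """Ground-truth TSV: causal ID + beta rows, model scalars as comments."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for line in _provenance_lines(prov.get("stage"), prov.get("config_hash"),
                                      prov.get("seed")):
            fh.write(line + "\n")
        fh.write(f"# h2={truth.h2:.10g} sex_effect_ratio={truth.sex_effect_ratio:.10g}\n")
        for cov, delta in truth.gxe_terms:
            fh.write(f"# gxe {cov}={delta:.10g}\n")
        fh.write("ID\tBETA\n")
        for vid, b in zip(truth.causal_ids, truth.betas):
            fh.write(f"{vid}\t{b:.10g}\n")
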