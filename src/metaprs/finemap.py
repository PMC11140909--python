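"""Locus definition and Bayesian fine-mapping with 99% credible sets.

A locus is a genome-wide-significant lead variant (p < 5e-8) plus a 1 Mb
flank on each side, with leads greedily selected in order of significance
subject to a >= 1 Mb separation.  Within a locus each variant's evidence is an
approximate Bayes factor computed from its meta-analysis z-score and the
number of contributing studies,

    log BF_i = (z_i^2 - log K_i) / 2,

normalized to posterior probabilities pi_i = BF_i / sum_j BF_j via
log-sum-exp (z around 40 overflows naive exponentials), and the 99% credible
set is the smallest prefix of the posterior-ranked variants whose cumulative
probability reaches the coverage target.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

GENOME_WIDE_P = 5e-8

@dataclass(frozen=True)
class Locus:
    chromosome: str
    lead_id: str
    lead_pos: int
    lead_p: float
    start: int
    end: int

    @property
    def key(self) -> tuple[str, int]:
        return (self.chromosome, self.lead_pos)

@dataclass
class CredibleSet:
    """Ranked posterior table for one locus.

    ``rows`` is sorted by posterior descending with columns
    ID, POS, z, K, log10_bf, posterior, cumulative, in_set; the in-set
    variants form a prefix of the sorted order. ``coverage`` is the attained
    cumulative posterior of the set.
    """

    locus: Locus
    rows: pd.DataFrame
    coverage: float

    @property
    def size(self) -> int:
        return int(self.rows["in_set"].sum())

def define_loci(
    meta: pd.DataFrame,
    p_threshold: float = GENOME_WIDE_P,
    min_separation: int = 1_000_000,
    flank: int = 1_000_000,
) -> list[Locus]:
    """Greedy lead selection: smallest remaining p, discarding significant
    variants within ``min_separation`` of each chosen lead; locus interval is
    lead +/- ``flank`` (closed, clipped at position 1)."""
    if len(meta) == 0:
        return []
    sig = meta.loc[meta["P"] < p_threshold, ["CHR", "POS", "ID", "P"]].copy()
    sig = sig.sort_values(["P", "CHR", "POS"], kind="mergesort").reset_index(drop=True)
    loci: list[Locus] = []
    alive = np.ones(len(sig), dtype=bool)
    chrom = sig["CHR"].to_numpy()
    pos = sig["POS"].to_numpy()
    for i in range(len(sig)):
        if not alive[i]:
            continue
        lead = sig.iloc[i]
        loci.append(
            Locus(
                chromosome=str(lead["CHR"]),
                lead_id=str(lead["ID"]),
                lead_pos=int(lead["POS"]),
                lead_p=float(lead["P"]),
                start=max(1, int(lead["POS"]) - flank),
                end=int(lead["POS"]) + flank,
            )
        )
        near = (chrom == lead["CHR"]) & (np.abs(pos - int(lead["POS"])) < min_separation)
        alive &= ~near
    loci.sort(key=lambda l: (l.chromosome, l.lead_pos))
    return loci

def log_bayes_factor(z, k) -> np.ndarray:
    """log BF = (z^2 - log K) / 2 for K contributing studies (K >= 1)."""
    z = np.asarray(z, dtype=float)
    k = np.asarray(k, dtype=float)
    if np.any(k < 1):
        raise ValueError("k must be >= 1")
    if not np.all(np.isfinite(z)):
        raise ValueError("z must be finite")
    return (z**2 - np.log(k)) / 2.0

def bayes_factor(z, k):
    """Approximate Bayes factor exp[(z^2 - log K)/2] (exponentiated for
    reporting only; internal arithmetic stays in log space)."""
    return np.exp(log_bayes_factor(z, k))

def credible_set(
    locus_rows: pd.DataFrame,
    locus: Locus | None = None,
    coverage_target: float = 0.99,
) -> CredibleSet:
    """Build the credible set for one locus.

    ``locus_rows`` needs columns ID, POS, z, K.  Posteriors are the softmax
    of the log Bayes factors; the set is the minimal prefix of the
    posterior-ranked variants with cumulative posterior >= coverage_target.
    Rank ties are broken by higher |z|, then lower position — deterministic
    and recorded in the sort itself.
    """
    if len(locus_rows) == 0:
        raise ValueError("empty locus")
    df = locus_rows.copy()
    log_bf = log_bayes_factor(df["z"].to_numpy(), df["K"].to_numpy())
    log_post = log_bf - logsumexp(log_bf)
    df["log10_bf"] = log_bf / np.log(10.0)
    df["posterior"] = np.exp(log_post)
    df["_absz"] = np.abs(df["z"])
    df = df.sort_values(
        ["posterior", "_absz", "POS"], ascending=[False, False, True], kind="mergesort"
    ).drop(columns="_absz").reset_index(drop=True)
    cum = df["posterior"].cumsum()
    # 1e-12 slack so accumulated rounding never pushes an exact-boundary
    # prefix (e.g. 99 x 0.01) past the target
    n_set = int(np.searchsorted(cum.to_numpy(), coverage_target - 1e-12) + 1)
    n_set = min(n_set, len(df))
    df["cumulative"] = cum
    df["in_set"] = np.arange(len(df)) < n_set
    if locus is None:
        lead = df.iloc[0]
        locus = Locus("?", str(lead["ID"]), int(lead["POS"]), np.nan,
                      int(df["POS"].min()), int(df["POS"].max()))
    return CredibleSet(locus=locus, rows=df, coverage=float(cum.iloc[n_set - 1]))

def finemap_table(
    meta: pd.DataFrame,
    loci: list[Locus],
    coverage_target: float = 0.99,
) -> list[CredibleSet]:
    """Credible sets for every locus, from a meta-analysis summary table."""
    out = []
    z_all = meta["BETA"] / meta["SE"]
    for locus in loci:
        mask = (
            (meta["CHR"].astype(str) == locus.chromosome)
            & (meta["POS"] >= locus.start)
            & (meta["POS"] <= locus.end)
        )
        rows = pd.DataFrame(
            {
                "ID": meta.loc[mask, "ID"],
                "POS": meta.loc[mask, "POS"],
                "z": z_all[mask],
                "K": meta.loc[mask, "K"],
            }
        )
        out.append(credible_set(rows, locus=locus, coverage_target=coverage_target))
    return out

@dataclass
class ResolutionSummary:
    median_a: float
    median_b: float
    single_snp_a: int
    single_snp_b: int
    pairs: pd.DataFrame  # locus key, size_a, size_b

def compare_resolution(
    sets_a: list[CredibleSet], sets_b: list[CredibleSet]
) -> ResolutionSummary:
    """Credible-set-size comparison between two analyses over shared loci.

    Loci are matched by (chromosome, lead position); returns per-analysis
    median sizes, single-variant-set counts, and the paired size table.
    """
    by_key_a = {s.locus.key: s for s in sets_a}
    by_key_b = {s.locus.key: s for s in sets_b}
    shared = sorted(set(by_key_a) & set(by_key_b))
    if not shared:
        raise ValueError("no shared loci between the two analyses")
    pairs = pd.DataFrame(
        {
            "CHR": [k[0] for k in shared],
            "lead_pos": [k[1] for k in shared],
            "size_a": [by_key_a[k].size for k in shared],
            "size_b": [by_key_b[k].size for k in shared],
        }
    )
    return ResolutionSummary(
        median_a=float(pairs["size_a"].median()),
        median_b=float(pairs["size_b"].median()),
        single_snp_a=int((pairs["size_a"] == 1).sum()),
        single_snp_b=int((pairs["size_b"] == 1).sum()),
        pairs=pairs,
    )
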