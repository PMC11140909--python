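"""Canonical validation experiments on synthetic cohorts.

Each function builds a self-contained simulation study — simulator fidelity,
genomic-control calibration, fine-mapping resolution, PRS portability,
interaction recovery, sex dimorphism — at the study conditions documented in
docs/methods.md, and returns the measured quantities.  They are exercised by
the test suite and by ``scripts/acceptance.py``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import assoc, finemap, interact, meta, prs
from . import synthdata as sd
from ._utils import rng_for

# ---------------------------------------------------------------------------
# simulator fidelity

def fst_recovery(seed: int, fst: float = 0.15, n_variants: int = 2000,
                 n_individuals: int = 10_000) -> float:
    """Realized Hudson FST between two populations simulated at ``fst``."""
    rng = rng_for(seed, "experiments", "fst")
    anc = rng.uniform(0.1, 0.9, n_variants)
    pos = 1 + 10_000 * np.arange(n_variants)
    freqs = []
    for name in ("a", "b"):
        spec = sd.PopulationSpec(name=name, fst=fst, ld_decay_bp=1e-3,
                                 n_individuals=n_individuals)
        f = sd.draw_subpopulation_frequencies(anc, fst, rng, freq_bounds=None)
        panel = sd.simulate_genotypes(spec, f, pos, rng)
        freqs.append(panel.eaf())
    return sd.hudson_fst(freqs[0], freqs[1], 2 * n_individuals, 2 * n_individuals)

def heritability_recovery(seed: int, h2: float = 0.3, n_individuals: int = 20_000,
                          n_variants: int = 2000, n_causal: int = 100) -> float:
    """Realized R^2 of the trait on the true genetic score (target = h2)."""
    rng = rng_for(seed, "experiments", "h2")
    spec = sd.PopulationSpec(name="a", fst=0.05, ld_decay_bp=1e-3,
                             n_individuals=n_individuals)
    vm = sd.make_variant_map(n_variants, seed=rng)
    f = sd.draw_subpopulation_frequencies(vm["ancestral_freq"].to_numpy(), 0.05, rng)
    panel = sd.simulate_genotypes(spec, f, vm["POS"].to_numpy(), rng, vm)
    cov = sd.simulate_covariates(spec, rng)
    arch = sd.ArchitectureSpec(n_variants=n_variants, n_causal=n_causal, h2=h2)
    pheno, truth = sd.simulate_phenotypes(panel, cov, arch, seed=rng)
    s = truth.standardized_score(panel)
    y = pheno["trait"].to_numpy()
    return float(np.corrcoef(s, y)[0, 1] ** 2)

def ld_scale_recovery(seed: int, ld_decay_bp: float = 50_000.0,
                      n_individuals: int = 5000, n_variants: int = 600,
                      spacing_bp: int = 5000, n_reps: int = 3) -> float:
    """Fitted LD-decay scale from pooled r^2-vs-distance profiles (target = L).

    Variants are placed at allele frequency 0.5 where the tetrachoric
    inversion used by :func:`metaprs.interact.fit_ld_decay` is exact.
    """
    pos = 1 + spacing_bp * np.arange(n_variants)
    profiles = []
    for r in range(n_reps):
        rng = rng_for(seed, "experiments", f"ld:{r}")
        spec = sd.PopulationSpec(name="a", fst=0.0, ld_decay_bp=ld_decay_bp,
                                 n_individuals=n_individuals)
        panel = sd.simulate_genotypes(spec, np.full(n_variants, 0.5), pos, rng)
        profiles.append(interact.ld_decay_profile(panel, max_distance=150_000, bins=15))
    pooled = profiles[0].copy()
    pooled["mean_r2"] = np.mean([p["mean_r2"] for p in profiles], axis=0)
    return interact.fit_ld_decay(pooled, allele_freq=0.5, n_individuals=n_individuals)

# ---------------------------------------------------------------------------
# genomic-control calibration

@dataclass
class GCCalibration:
    lambda_raw: float
    lambda_final: float
    study_lambdas: list[float]

def gc_calibration(seed: int, n_variants: int = 50_000, n_studies: int = 3,
                   n_per_subpop: int = 750, subpop_fst: float = 0.05,
                   shift: float = 0.6) -> GCCalibration:
    """Null GWAS with hidden stratification, before/after double GC.

    Each study pools two diverged subpopulations whose trait means differ by
    ``shift`` SD; population labels and PCs are withheld from the per-study
    GWAS, injecting structural inflation that double genomic control must
    remove.
    """
    rng = rng_for(seed, "experiments", "gc")
    vm = sd.make_variant_map(n_variants, spacing_bp=1000, seed=rng)
    anc = vm["ancestral_freq"].to_numpy()
    pos = vm["POS"].to_numpy()
    studies = []
    for s in range(n_studies):
        dosages, trait = [], []
        for sub in range(2):
            spec = sd.PopulationSpec(name=f"s{s}_{sub}", fst=subpop_fst,
                                     ld_decay_bp=1e-3, n_individuals=n_per_subpop)
            f = sd.draw_subpopulation_frequencies(anc, subpop_fst, rng)
            p = sd.simulate_genotypes(spec, f, pos, rng, vm)
            dosages.append(p.dosages)
            trait.append(shift * sub + rng.standard_normal(n_per_subpop))
        panel = sd.GenotypePanel(np.vstack(dosages), vm,
                                 np.repeat(["x", "y"], n_per_subpop))
        ph = pd.DataFrame({"trait": assoc.inverse_normal_transform(np.concatenate(trait))})
        ss = assoc.run_gwas(panel, ph)
        studies.append(ss.dropna(subset=["BETA", "SE", "P"]).reset_index(drop=True))
    res = meta.double_gc_meta(studies, ldsc_intercepts="auto")
    z_final = (res.table["BETA"] / res.table["SE"]).to_numpy()
    return GCCalibration(
        lambda_raw=res.lambda_raw,
        lambda_final=meta.genomic_control_lambda(z_final),
        study_lambdas=res.study_factors,
    )

# ---------------------------------------------------------------------------
# fine-mapping resolution

@dataclass
class ResolutionRep:
    median_multi: float
    median_single: float
    singles_multi: int
    singles_single: int

def resolution_experiment(seed: int, n_reps: int = 20, n_loci: int = 50,
                          variants_per_locus: int = 40, spacing_bp: int = 5000,
                          beta: float = 0.18, n_per_study: int = 1500,
                          ld_a: float = 100_000.0, ld_b: float = 50_000.0,
                          ) -> list[ResolutionRep]:
    """Credible-set resolution: multi-ancestry vs single-population meta.

    One shared causal variant per locus.  Both arms combine study A with a
    second study of equal size; in the single-population arm the second study
    has A's LD-decay scale, in the multi-ancestry arm it decays two-fold
    faster.  The two second studies are built from common random numbers
    (identical latent Gaussians, frequencies and trait noise; only the LD
    scale differs), so each replicate is a paired comparison of LD structure
    rather than of sampling noise.
    """
    per = variants_per_locus
    m = n_loci * per
    pos = np.concatenate(
        [2_000_000 * i + 1 + np.arange(per) * spacing_bp for i in range(n_loci)]
    )
    out = []
    for rep in range(n_reps):
        rng = rng_for(seed, "experiments", f"resolution:{rep}")
        vm = pd.DataFrame({"CHR": "1", "POS": pos,
                           "ID": [f"v{i}" for i in range(m)],
                           "OA": "A", "EA": "G",
                           "ancestral_freq": rng.uniform(0.2, 0.8, m)})
        anc = vm["ancestral_freq"].to_numpy()
        causal = np.array([i * per + per // 2 for i in range(n_loci)])
        betas = np.zeros(m)
        betas[causal] = beta * np.sign(rng.standard_normal(n_loci))
        seeds = rng.integers(0, 2**31 - 1, 4)

        def study(name, ld, geno_seed, pheno_seed, freq_seed):
            spec = sd.PopulationSpec(name=name, fst=0.02, ld_decay_bp=ld,
                                     n_individuals=n_per_study)
            f = sd.draw_subpopulation_frequencies(
                anc, 0.02, np.random.default_rng(freq_seed))
            p = sd.simulate_genotypes(spec, f, pos,
                                      np.random.default_rng(geno_seed), vm)
            y = (p.dosages.astype(float) @ betas
                 + np.random.default_rng(pheno_seed).standard_normal(n_per_study))
            ph = pd.DataFrame({"trait": assoc.inverse_normal_transform(y)})
            return assoc.run_gwas(p, ph).dropna(subset=["BETA"]).reset_index(drop=True)

        ss_a = study("A", ld_a, seeds[0], seeds[1], seeds[2])
        ss_a2 = study("A2", ld_a, seeds[3], seeds[1] + 1, seeds[2] + 1)
        ss_b = study("B", ld_b, seeds[3], seeds[1] + 1, seeds[2] + 1)
        loci = [finemap.Locus("1", f"v{c}", int(pos[c]), 0.0,
                              int(pos[c]) - per * spacing_bp,
                              int(pos[c]) + per * spacing_bp)
                for c in causal]
        sets_multi = finemap.finemap_table(meta.meta_analyze([ss_a, ss_b]), loci)
        sets_single = finemap.finemap_table(meta.meta_analyze([ss_a, ss_a2]), loci)
        sm = np.array([s.size for s in sets_multi])
        ss = np.array([s.size for s in sets_single])
        out.append(ResolutionRep(float(np.median(sm)), float(np.median(ss)),
                                 int((sm == 1).sum()), int((ss == 1).sum())))
    return out

# ---------------------------------------------------------------------------
# PRS portability

@dataclass
class PortabilityRep:
    r2_target_a: float
    r2_target_b: float
    r2_target_b_meta: float

def portability_experiment(seed: int, n_reps: int = 20,
                           n_discovery_a: int = 20_000,
                           n_discovery_b: int = 10_000,
                           n_target: int = 2000, n_variants: int = 1200,
                           n_causal: int = 50, h2: float = 0.3,
                           fst_b: float = 0.15) -> list[PortabilityRep]:
    """C+T PRS portability across ancestry.

    A PRS trained on the population-A discovery GWAS is evaluated in an
    A-like and a B-like target (FST ``fst_b`` from the ancestral pool,
    two-fold faster LD decay); a second PRS trained on the A+B double-GC-free
    IVW meta-analysis is evaluated in the B-like target.
    """
    out = []
    for rep in range(n_reps):
        rep_seed = int(rng_for(seed, "experiments", f"port:{rep}").integers(2**31 - 1))
        arch = sd.ArchitectureSpec(n_variants=n_variants, n_causal=n_causal,
                                   h2=h2, seed=rep_seed)
        specs = [
            sd.PopulationSpec(name="discA", fst=0.01, ld_decay_bp=100_000,
                              n_individuals=n_discovery_a, region="disc"),
            sd.PopulationSpec(name="discB", fst=fst_b, ld_decay_bp=50_000,
                              n_individuals=n_discovery_b, region="disc"),
            sd.PopulationSpec(name="tgtA", fst=0.005, parent="discA",
                              ld_decay_bp=100_000, n_individuals=n_target,
                              region="A"),
            sd.PopulationSpec(name="tgtB", fst=0.005, parent="discB",
                              ld_decay_bp=50_000, n_individuals=n_target,
                              region="B"),
        ]
        cohorts = sd.simulate_multistudy(specs, arch, spacing_bp=5000)
        (p_a, ph_a, _), (p_b, ph_b, _), (t_a, th_a, _), (t_b, th_b, _) = cohorts
        for ph in (ph_a, ph_b, th_a, th_b):
            ph["trait"] = assoc.inverse_normal_transform(ph["trait"])
        ss_a = assoc.run_gwas(p_a, ph_a, covariates=["age", "age2", "sex"])
        ss_a = ss_a.dropna(subset=["BETA"]).reset_index(drop=True)
        ss_b = assoc.run_gwas(p_b, ph_b, covariates=["age", "age2", "sex"])
        ss_b = ss_b.dropna(subset=["BETA"]).reset_index(drop=True)

        def evaluate(summary, panel, pheno):
            split = prs.stratified_split(pheno, 0.3, strata=["sex"], seed=rep_seed)
            vi, ti = split.validation_index, split.test_index
            search = prs.threshold_search(
                summary, prs.subset_panel(panel, vi),
                pheno.iloc[vi].reset_index(drop=True), covariates=["age", "sex"])
            sc = prs.score(prs.subset_panel(panel, ti), search.best_model)
            return prs.incremental_r2(pheno.iloc[ti].reset_index(drop=True), sc,
                                      covariates=["age", "sex"]).incremental

        mtab = meta.meta_analyze([ss_a, ss_b])
        out.append(PortabilityRep(
            r2_target_a=evaluate(ss_a, t_a, th_a),
            r2_target_b=evaluate(ss_a, t_b, th_b),
            r2_target_b_meta=evaluate(mtab, t_b, th_b),
        ))
    return out

# ---------------------------------------------------------------------------
# interaction models

def interaction_recovery(seed: int, delta: float = 0.2, n: int = 50_000,
                         n_reps: int = 10) -> list[float]:
    """Recover a PRS x E product coefficient from y = 0.5 PRS + 0.3 E + d PRS E + e."""
    est = []
    for rep in range(n_reps):
        rng = rng_for(seed, "experiments", f"gxe:{rep}")
        s = rng.standard_normal(n)
        e = rng.standard_normal(n)
        y = 0.5 * s + 0.3 * e + delta * s * e + rng.standard_normal(n)
        ph = pd.DataFrame({"trait": y, "env": e})
        fit = interact.fit_interaction(ph, s, modifier="env")
        est.append(fit.fits[0].estimate)
    return est

def interaction_type1(seed: int, n: int = 5000, n_reps: int = 1000,
                      alpha: float = 0.05) -> float:
    """Fraction of replicates with p_int < alpha when no interaction exists."""
    hits = 0
    rng = rng_for(seed, "experiments", "gxe-null")
    for _ in range(n_reps):
        s = rng.standard_normal(n)
        e = rng.standard_normal(n)
        y = 0.5 * s + 0.3 * e + rng.standard_normal(n)
        ph = pd.DataFrame({"trait": y, "env": e})
        fit = interact.fit_interaction(ph, s, modifier="env")
        hits += fit.fits[0].p_int < alpha
    return hits / n_reps

# ---------------------------------------------------------------------------
# sex dimorphism

@dataclass
class SexContrastRep:
    contrast_female: float
    contrast_male: float

def sex_dimorphism(seed: int, n_reps: int = 20, sex_effect_ratio: float = 2.0,
                   n_individuals: int = 4000, n_variants: int = 400,
                   n_causal: int = 30, h2: float = 0.3) -> list[SexContrastRep]:
    """Decile-10-vs-1 trait contrast by sex with sex-dimorphic genetic effects.

    The PRS is the true standardized genetic score, isolating the dimorphism
    of the decile contrast from PRS estimation error.
    """
    out = []
    for rep in range(n_reps):
        rng = rng_for(seed, "experiments", f"sex:{rep}")
        spec = sd.PopulationSpec(name="a", fst=0.05, ld_decay_bp=1e-3,
                                 n_individuals=n_individuals)
        vm = sd.make_variant_map(n_variants, seed=rng)
        f = sd.draw_subpopulation_frequencies(vm["ancestral_freq"].to_numpy(), 0.05, rng)
        panel = sd.simulate_genotypes(spec, f, vm["POS"].to_numpy(), rng, vm)
        cov = sd.simulate_covariates(spec, rng)
        arch = sd.ArchitectureSpec(n_variants=n_variants, n_causal=n_causal,
                                   h2=h2, sex_effect_ratio=sex_effect_ratio)
        pheno, truth = sd.simulate_phenotypes(panel, cov, arch, seed=rng)
        score = truth.standardized_score(panel)
        contrasts = {}
        for sex in ("F", "M"):
            mask = (pheno["sex"] == sex).to_numpy()
            dec = prs.decile_contrast(score[mask], pheno["trait"].to_numpy()[mask])
            contrasts[sex] = float(dec["diff_vs_d1"].iloc[-1])
        out.append(SexContrastRep(contrasts["F"], contrasts["M"]))
    return out
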