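"""End-to-end pipeline driver: simulate -> gwas -> meta -> finemap -> prs -> interact.

Every stage writes its artifacts as TSV (plus a resolved-config YAML copy and
a JSON summary of scalar results) under the run directory, each file headed
by a provenance comment (stage, config hash, seed).  Reruns with the same
config and seed are byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import assoc, finemap, interact, io, meta, prs, synthdata
from .config import RunConfig

log = logging.getLogger(__name__)

@dataclass
class PipelineResult:
    out_dir: Path
    summary: dict

def _pop_spec(cfg) -> synthdata.PopulationSpec:
    env = {k: tuple(v) if isinstance(v, list) else v for k, v in cfg.env.items()}
    return synthdata.PopulationSpec(
        name=cfg.name, fst=cfg.fst, ld_decay_bp=cfg.ld_decay_bp,
        n_individuals=cfg.n_individuals, region=cfg.region,
        parent=cfg.parent, env=env,
    )

def _concat_panels(panels, phenos):
    dosages = np.vstack([p.dosages for p in panels])
    pops = np.concatenate([p.populations for p in panels])
    panel = synthdata.GenotypePanel(dosages=dosages, variants=panels[0].variants,
                                    populations=pops)
    pheno = pd.concat(phenos, ignore_index=True)
    return panel, pheno

def run_pipeline(config: RunConfig, out_dir) -> PipelineResult:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = config.sha256()
    prov = dict(config_hash=chash, seed=config.seed)
    config.to_yaml(out / "resolved_config.yaml")
    summary: dict = {"config_sha256": chash, "seed": config.seed}

    # -- simulate ------------------------------------------------------------
    arch = synthdata.ArchitectureSpec(
        n_variants=config.n_variants, n_causal=config.n_causal, h2=config.h2,
        beta_sd=config.beta_sd,
        gxe_terms=[tuple(t) for t in config.gxe_terms],
        env_effects=dict(config.env_effects),
        sex_effect_ratio=config.sex_effect_ratio, seed=config.seed,
    )
    specs = [_pop_spec(p) for p in config.discovery] + [_pop_spec(p) for p in config.targets]
    cohorts = synthdata.simulate_multistudy(specs, arch, shared_causals=True,
                                            spacing_bp=config.spacing_bp)
    n_disc = len(config.discovery)
    discovery = cohorts[:n_disc]
    targets = cohorts[n_disc:]
    truth = cohorts[0][2]
    io.write_truth(truth, out / "simulate" / "truth.tsv", stage="simulate", **prov)
    for (panel, pheno, _), cfg in zip(cohorts, config.discovery + config.targets):
        io.write_phenotypes(pheno, out / "simulate" / f"pheno_{cfg.name}.tsv",
                            stage="simulate", **prov)

    # -- per-study GWAS ------------------------------------------------------
    sumstats = []
    for (panel, pheno, _), cfg in zip(discovery, config.discovery):
        ph = pheno.copy()
        ph["trait"] = assoc.inverse_normal_transform(ph["trait"])
        pcs = (assoc.compute_pcs(panel, config.gwas_n_pcs)
               if config.gwas_n_pcs > 0 else None)
        ss = assoc.run_gwas(panel, ph, covariates=config.gwas_covariates, pcs=pcs)
        io.write_summary_stats(ss, out / "gwas" / f"{cfg.name}.tsv",
                               stage="gwas", **prov)
        sumstats.append(ss.dropna(subset=["BETA", "SE", "P"]).reset_index(drop=True))

    # -- meta-analysis with double GC ---------------------------------------
    mres = meta.double_gc_meta(sumstats, ldsc_intercepts=config.ldsc_intercepts,
                               min_k=config.min_k)
    io.write_summary_stats(mres.table.drop(columns="stage"), out / "meta" / "meta.tsv",
                           stage="meta", **prov)
    io.write_tsv(mres.stages, out / "meta" / "meta_stages.tsv", stage="meta", **prov)
    io.write_tsv(mres.drop_log, out / "meta" / "drop_log.tsv", stage="meta", **prov)
    summary["lambda_raw"] = mres.lambda_raw
    summary["lambda_meta"] = mres.lambda_meta
    summary["study_gc_factors"] = mres.study_factors
    summary["n_meta_variants"] = int(len(mres.table))

    # -- fine-mapping --------------------------------------------------------
    loci = finemap.define_loci(mres.table, p_threshold=config.p_threshold,
                               min_separation=config.min_separation, flank=config.flank)
    sets_meta = finemap.finemap_table(mres.table, loci, coverage_target=config.coverage)
    # single-study comparator: first discovery cohort at the same loci
    first = sumstats[0]
    sets_single = finemap.finemap_table(first.assign(K=1), loci,
                                        coverage_target=config.coverage) if loci else []
    cs_rows = []
    for cs in sets_meta:
        df = cs.rows.copy()
        df.insert(0, "locus", f"{cs.locus.chromosome}:{cs.locus.lead_pos}")
        cs_rows.append(df)
    if cs_rows:
        io.write_tsv(pd.concat(cs_rows, ignore_index=True),
                     out / "finemap" / "credible_sets.tsv", stage="finemap", **prov)
    summary["n_loci"] = len(loci)
    if loci:
        comp = finemap.compare_resolution(sets_single, sets_meta)
        io.write_tsv(comp.pairs, out / "finemap" / "resolution_pairs.tsv",
                     stage="finemap", **prov)
        summary["credible_set_median_single"] = comp.median_a
        summary["credible_set_median_meta"] = comp.median_b

    # -- PRS -----------------------------------------------------------------
    tgt_panel, tgt_pheno = _concat_panels([t[0] for t in targets],
                                          [t[1] for t in targets])
    tgt_pheno = tgt_pheno.reset_index(drop=True)
    tgt_pheno["trait_int"] = assoc.inverse_normal_transform(tgt_pheno["trait"])
    pcs_t = assoc.compute_pcs(tgt_panel, config.gwas_n_pcs)
    for j in range(pcs_t.shape[1]):
        tgt_pheno[f"PC{j+1}"] = pcs_t[:, j]
    pc_cols = [f"PC{j+1}" for j in range(pcs_t.shape[1])]
    eval_covars = ["age", "sex"] + pc_cols

    split = prs.stratified_split(tgt_pheno, config.frac_validation,
                                 strata=config.split_strata, seed=config.seed)
    io.write_tsv(pd.DataFrame({"individual": np.arange(len(tgt_pheno)),
                               "assignment": split.assignment}),
                 out / "prs" / "split.tsv", stage="prs", **prov)
    vi, ti = split.validation_index, split.test_index
    tune_idx = np.arange(len(tgt_pheno)) if config.tune_on_combined else vi
    search = prs.threshold_search(
        mres.table, prs.subset_panel(tgt_panel, tune_idx),
        tgt_pheno.iloc[tune_idx].reset_index(drop=True),
        grid=config.p_grid, clump_distance=config.clump_distance,
        clump_r2=config.clump_r2, covariates=eval_covars,
        trait="trait_int", source="meta",
    )
    model = search.best_model
    io.write_tsv(model.weights, out / "prs" / "weights.tsv", stage="prs", **prov)
    io.write_tsv(search.grid, out / "prs" / "grid.tsv", stage="prs", **prov)

    test_panel = prs.subset_panel(tgt_panel, ti)
    test_pheno = tgt_pheno.iloc[ti].reset_index(drop=True)
    test_score = prs.score(test_panel, model)
    eval_res = prs.incremental_r2(test_pheno, test_score, covariates=eval_covars,
                                  trait="trait_int")
    summary["prs_threshold"] = model.p_threshold
    summary["prs_n_variants"] = model.n_variants
    summary["prs_incremental_r2_test"] = eval_res.incremental
    summary["prs_p_test"] = eval_res.p_prs
    deciles = prs.decile_contrast(test_score, test_pheno["trait"])
    io.write_tsv(deciles, out / "prs" / "deciles.tsv", stage="prs", **prov)

    # -- interactions and region contrasts -----------------------------------
    int_rows = []
    for modifier in config.interaction_modifiers:
        if modifier not in test_pheno.columns:
            continue
        if test_pheno[modifier].nunique() < 2:
            log.info("pipeline: modifier %r constant in test set, skipped", modifier)
            continue
        if modifier == "sex":
            covars = ["age"] + pc_cols
        elif modifier == "region":
            covars = ["age", "sex"] + pc_cols[: config.region_n_pcs]
        else:
            covars = ["age", "sex"] + pc_cols
        fit = interact.fit_interaction(test_pheno, test_score, modifier=modifier,
                                       covariates=covars, trait="trait_int")
        for f in fit.fits:
            int_rows.append((modifier, f.term, f.estimate, f.se, f.p_int, f.n))
        int_rows.append((modifier, f"PRS x {modifier} [omnibus F]",
                         fit.omnibus_f, np.nan, fit.omnibus_p, fit.n))
    io.write_tsv(pd.DataFrame(int_rows, columns=["modifier", "term", "estimate",
                                                 "se", "p", "n"]),
                 out / "interact" / "interactions.tsv", stage="interact", **prov)

    if test_pheno["region"].nunique() >= 2:
        strat = interact.stratified_prs_eval(
            test_pheno, test_score, stratum="region",
            covariates=["age", "sex"] + pc_cols[:config.region_n_pcs],
            trait="trait_int")
        io.write_tsv(strat.per_stratum, out / "interact" / "region_eval.tsv",
                     stage="interact", **prov)
        summary["region_interaction_p"] = strat.interaction_p
    if len(targets) >= 2:
        r, pairs = interact.allele_freq_correlation(
            targets[0][0], targets[1][0],
            variant_ids=model.weights["ID"] if model.n_variants >= 2 else None)
        io.write_tsv(pairs, out / "interact" / "allele_freqs.tsv",
                     stage="interact", **prov)
        summary["target_allele_freq_r"] = r
    # LD profile on a contiguous 2,000-variant slab (full panel would be slow
    # and adds nothing: decay is stationary along the synthetic chromosome)
    slab = targets[0][0].variants["ID"].iloc[:2000]
    prof = interact.ld_decay_profile(targets[0][0], variant_ids=slab,
                                     max_distance=200_000, bins=20)
    io.write_tsv(prof, out / "interact" / "ld_decay.tsv", stage="interact", **prov)

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return PipelineResult(out_dir=out, summary=summary)
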