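import numpy as np
import pandas as pd
import pytest

from metaprs import synthdata as sd

@pytest.fixture(scope="session")
def small_panel():
    """500 individuals x 300 variants with moderate LD, fixed seed."""
    spec = sd.PopulationSpec(name="pop", fst=0.05, ld_decay_bp=50_000,
                             n_individuals=500)
    vm = sd.make_variant_map(300, spacing_bp=5000, seed=11)
    rng = np.random.default_rng(12)
    f = sd.draw_subpopulation_frequencies(vm["ancestral_freq"].to_numpy(), 0.05, rng)
    return sd.simulate_genotypes(spec, f, vm["POS"].to_numpy(), rng, vm)

@pytest.fixture(scope="session")
def small_cohort(small_panel):
    """Panel + phenotype table with h2=0.4 sparse architecture."""
    spec = sd.PopulationSpec(name="pop", n_individuals=small_panel.n_individuals)
    cov = sd.simulate_covariates(spec, 13)
    arch = sd.ArchitectureSpec(n_variants=small_panel.n_variants, n_causal=20,
                               h2=0.4, seed=14)
    pheno, truth = sd.simulate_phenotypes(small_panel, cov, arch)
    return small_panel, pheno, truth

def random_summary(rng, n=50, chrom="1", start=1, spacing=10_000):
    """A syntactically valid summary-statistics table with random content."""
    pos = start + spacing * np.arange(n)
    beta = 0.1 * rng.standard_normal(n)
    se = rng.uniform(0.02, 0.1, n)
    from scipy import stats

    z = beta / se
    return pd.DataFrame({
        "CHR": chrom, "POS": pos, "ID": [f"v{chrom}_{p}" for p in pos],
        "EA": "G", "OA": "A", "EAF": rng.uniform(0.05, 0.95, n),
        "BETA": beta, "SE": se, "P": 2 * stats.norm.sf(np.abs(z)),
        "N": 1000, "K": 1,
    })
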