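"""Generator correctness: frequency divergence, LD, heritability, determinism."""

import numpy as np
import pandas as pd
import pytest

from metaprs import synthdata as sd

class TestSubpopulationFrequencies:
    def test_fst_zero_is_identity(self):
        p = np.array([0.1, 0.5, 0.9])
        np.testing.assert_array_equal(
            sd.draw_subpopulation_frequencies(p, 0.0, 1), p)

    def test_beta_variance_matches_balding_nichols(self):
        # Var = p(1-p)F for the Balding-Nichols Beta
        draws = sd.draw_subpopulation_frequencies(
            np.full(10_000, 0.5), 0.1, 7, freq_bounds=None)
        assert abs(draws.var() - 0.025) < 0.0025

    def test_hudson_fst_recovered(self):
        rng = np.random.default_rng(3)
        anc = rng.uniform(0.1, 0.9, 50_000)
        fa = sd.draw_subpopulation_frequencies(anc, 0.15, 4, freq_bounds=None)
        fb = sd.draw_subpopulation_frequencies(anc, 0.15, 5, freq_bounds=None)
        assert abs(sd.hudson_fst(fa, fb) - 0.15) < 0.02

    @pytest.mark.parametrize("bad", [-0.1, 1.0])
    def test_invalid_fst_rejected(self, bad):
        with pytest.raises(ValueError):
            sd.draw_subpopulation_frequencies(np.array([0.5]), bad, 1)

    def test_boundary_frequency_rejected(self):
        with pytest.raises(ValueError):
            sd.draw_subpopulation_frequencies(np.array([0.0, 0.5]), 0.1, 1)

    def test_rare_variant_guard_respects_bounds(self):
        draws = sd.draw_subpopulation_frequencies(
            np.full(2000, 0.05), 0.3, 8, freq_bounds=(0.01, 0.99))
        assert draws.min() >= 0.01 and draws.max() <= 0.99

class TestGenotypeSimulation:
    def test_marginal_frequency_calibrated(self):
        spec = sd.PopulationSpec(name="a", ld_decay_bp=1e-3, n_individuals=20_000)
        pos = 1 + 10_000 * np.arange(50)
        panel = sd.simulate_genotypes(spec, np.full(50, 0.3), pos, 1)
        assert np.all(np.abs(panel.eaf() - 0.3) < 0.01)

    def test_independence_limit(self):
        # ld_decay ~ 0: adjacent variants 10 kb apart are uncorrelated
        spec = sd.PopulationSpec(name="a", ld_decay_bp=1.0, n_individuals=5000)
        pos = 1 + 10_000 * np.arange(200)
        panel = sd.simulate_genotypes(spec, np.full(200, 0.5), pos, 2)
        X = panel.dosages.astype(float)
        Xs = (X - X.mean(0)) / X.std(0)
        r = np.einsum("ij,ij->j", Xs[:, :-1], Xs[:, 1:]) / len(X)
        assert np.mean(r**2) < 0.01

    def test_zero_distance_perfect_ld(self):
        spec = sd.PopulationSpec(name="a", ld_decay_bp=10_000, n_individuals=500)
        vm = pd.DataFrame({"CHR": ["1", "2"], "POS": [100, 100],
                           "ID": ["x", "y"], "OA": "A", "EA": "G",
                           "ancestral_freq": 0.4})
        panel = sd.simulate_genotypes(spec, np.array([0.4, 0.4]),
                                      np.array([100, 100]), 3, vm)
        np.testing.assert_array_equal(panel.dosages[:, 0], panel.dosages[:, 1])

    def test_dosages_in_range(self, small_panel):
        assert set(np.unique(small_panel.dosages)) <= {0, 1, 2}

    def test_nonincreasing_positions_rejected(self):
        spec = sd.PopulationSpec(name="a", n_individuals=10)
        with pytest.raises(ValueError):
            sd.simulate_genotypes(spec, np.array([0.5, 0.5]),
                                  np.array([200, 100]), 1)

    def test_deterministic_under_seed(self):
        spec = sd.PopulationSpec(name="a", n_individuals=100)
        pos = 1 + 5000 * np.arange(50)
        a = sd.simulate_genotypes(spec, np.full(50, 0.3), pos, 42)
        b = sd.simulate_genotypes(spec, np.full(50, 0.3), pos, 42)
        np.testing.assert_array_equal(a.dosages, b.dosages)

class TestPhenotypes:
    def _make(self, h2, n=2000, ratio=1.0, seed=5, **arch_kw):
        spec = sd.PopulationSpec(name="a", ld_decay_bp=1e-3, n_individuals=n)
        vm = sd.make_variant_map(200, seed=seed)
        rng = np.random.default_rng(seed)
        f = sd.draw_subpopulation_frequencies(vm["ancestral_freq"].to_numpy(), 0.05, rng)
        panel = sd.simulate_genotypes(spec, f, vm["POS"].to_numpy(), rng, vm)
        cov = sd.simulate_covariates(spec, rng)
        arch = sd.ArchitectureSpec(n_variants=200, n_causal=20, h2=h2,
                                   sex_effect_ratio=ratio, seed=seed, **arch_kw)
        pheno, truth = sd.simulate_phenotypes(panel, cov, arch)
        return panel, pheno, truth

    def test_h2_one_trait_equals_standardized_score(self):
        panel, pheno, truth = self._make(1.0)
        np.testing.assert_allclose(pheno["trait"],
                                   truth.standardized_score(panel), atol=1e-10)

    def test_h2_zero_trait_independent_of_genotype(self):
        panel, pheno, truth = self._make(0.0, n=5000)
        s = truth.raw_score(panel)
        r2 = np.corrcoef(s, pheno["trait"])[0, 1] ** 2
        assert r2 < 0.005

    def test_h2_recovered_at_large_n(self):
        panel, pheno, truth = self._make(0.3, n=20_000)
        r2 = np.corrcoef(truth.standardized_score(panel), pheno["trait"])[0, 1] ** 2
        assert abs(r2 - 0.3) < 0.02

    def test_invalid_h2_rejected(self):
        with pytest.raises(ValueError):
            sd.ArchitectureSpec(n_variants=10, n_causal=2, h2=1.5)

    def test_gxe_term_changes_trait(self):
        _, ph0, _ = self._make(0.3)
        _, ph1, _ = self._make(0.3, gxe_terms=[("physical_activity", 0.5)])
        assert not np.allclose(ph0["trait"], ph1["trait"])

class TestMultistudy:
    def _specs(self, fsts, **kw):
        return [sd.PopulationSpec(name=f"p{i}", fst=f, n_individuals=300,
                                  ld_decay_bp=50_000, **kw)
                for i, f in enumerate(fsts)]

    def test_identical_variant_maps(self):
        arch = sd.ArchitectureSpec(n_variants=100, n_causal=10, seed=1)
        cohorts = sd.simulate_multistudy(self._specs([0.02, 0.1, 0.15]), arch)
        maps = [c[0].variants[["CHR", "POS", "ID"]] for c in cohorts]
        for m in maps[1:]:
            pd.testing.assert_frame_equal(maps[0], m)

    def test_no_divergence_when_fst_zero(self):
        arch = sd.ArchitectureSpec(n_variants=500, n_causal=10, seed=2)
        specs = [sd.PopulationSpec(name=f"p{i}", fst=0.0, n_individuals=2000)
                 for i in range(2)]
        cohorts = sd.simulate_multistudy(specs, arch)
        fst = sd.hudson_fst(cohorts[0][0].eaf(), cohorts[1][0].eaf(), 4000, 4000)
        assert fst < 0.005

    def test_frequency_correlation_decreases_with_fst(self):
        # closer populations (low FST) keep more correlated frequencies
        wins = 0
        for seed in range(10):
            arch = sd.ArchitectureSpec(n_variants=300, n_causal=10, seed=seed)
            cohorts = sd.simulate_multistudy(
                self._specs([0.05, 0.05, 0.15, 0.15]), arch, seed=seed)
            freqs = [c[0].eaf() for c in cohorts]
            r_low = np.corrcoef(freqs[0], freqs[1])[0, 1]
            r_high = np.corrcoef(freqs[2], freqs[3])[0, 1]
            wins += r_low > r_high
        assert wins >= 9

    def test_shared_causals_reuse_truth(self):
        arch = sd.ArchitectureSpec(n_variants=100, n_causal=10, seed=3)
        cohorts = sd.simulate_multistudy(self._specs([0.02, 0.1]), arch)
        assert cohorts[0][2] is cohorts[1][2]

    def test_parent_population_hierarchical_divergence(self):
        arch = sd.ArchitectureSpec(n_variants=400, n_causal=10, seed=4)
        specs = self._specs([0.15, 0.15])
        specs[1].parent = "p0"
        specs[1].fst = 0.005
        specs += [sd.PopulationSpec(name="far", fst=0.15, n_individuals=300)]
        cohorts = sd.simulate_multistudy(specs, arch, seed=4)
        f0, f1, f2 = (c[0].eaf() for c in cohorts)
        assert np.corrcoef(f0, f1)[0, 1] > np.corrcoef(f0, f2)[0, 1]

    def test_single_spec_rejected(self):
        arch = sd.ArchitectureSpec(n_variants=10, n_causal=2)
        with pytest.raises(ValueError):
            sd.simulate_multistudy(self._specs([0.1]), arch)

def test_covariate_categories_follow_spec_probabilities():
    spec = sd.PopulationSpec(
        name="a", n_individuals=20_000,
        env={"smoking": {"never": 0.9, "ever": 0.1}})
    cov = sd.simulate_covariates(spec, 6)
    assert abs((cov["smoking"] == "never").mean() - 0.9) < 0.01
    assert set(cov["alcohol"]) <= {"never", "current_nonproblematic",
                                   "current_problematic", "former"}

def test_bad_category_probabilities_rejected():
    with pytest.raises(ValueError):
        sd.PopulationSpec(name="a", n_individuals=10,
                          env={"smoking": {"never": 0.5, "ever": 0.4}})
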