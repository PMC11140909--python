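"""C+T PRS: clumping, scoring, threshold search, evaluation, splitting."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metaprs import prs
from metaprs import synthdata as sd

def make_panel(dosages, positions=None, chrom="1"):
    dosages = np.asarray(dosages, dtype=np.int8)
    m = dosages.shape[1]
    pos = positions if positions is not None else 1 + 10_000 * np.arange(m)
    vm = pd.DataFrame({"CHR": chrom, "POS": pos,
                       "ID": [f"v{j}" for j in range(m)],
                       "OA": "A", "EA": "G", "ancestral_freq": 0.5})
    return sd.GenotypePanel(dosages, vm, np.repeat("p", dosages.shape[0]))

def summary_for(panel, p_values):
    pv = panel.variants
    return pd.DataFrame({
        "CHR": pv["CHR"], "POS": pv["POS"], "ID": pv["ID"],
        "EA": pv["EA"], "OA": pv["OA"], "EAF": panel.eaf(),
        "BETA": 0.1, "SE": 0.05, "P": p_values,
        "N": panel.n_individuals, "K": 2})

def brute_force_clump(summary, r2_matrix, distance, r2_threshold):
    """Oracle: greedy clumping re-checking every removal against the full
    pairwise r^2 matrix."""
    order = summary.sort_values(["P", "POS"], kind="mergesort").index.to_list()
    removed = set()
    kept = []
    pos = summary["POS"]
    for i in order:
        if i in removed:
            continue
        kept.append(i)
        for j in order:
            if j == i or j in removed or j in kept:
                continue
            if abs(pos[j] - pos[i]) <= distance and r2_matrix[i, j] > r2_threshold:
                removed.add(j)
    return sorted(kept)

class TestClump:
    def _correlated_panel(self, rng, n=400):
        # v0 and v1 in near-perfect LD; v2 independent
        base = rng.binomial(1, 0.5, (n, 2)).sum(axis=1)
        noise = rng.binomial(1, 0.5, (n, 2)).sum(axis=1)
        v1 = base.copy()
        flip = rng.random(n) < 0.03
        v1[flip] = 2 - v1[flip]
        return make_panel(np.column_stack([base, v1, noise]),
                          positions=[1_000, 50_000, 90_000])

    def test_stated_three_variant_example(self):
        rng = np.random.default_rng(41)
        panel = self._correlated_panel(rng)
        summ = summary_for(panel, [1e-10, 1e-8, 1e-4])
        kept = prs.clump(summ, panel, distance=100_000, r2_threshold=0.8)
        assert list(kept["ID"]) == ["v0", "v2"]

    def test_vacuous_threshold_keeps_all(self):
        rng = np.random.default_rng(42)
        panel = self._correlated_panel(rng)
        summ = summary_for(panel, [1e-10, 1e-8, 1e-4])
        kept = prs.clump(summ, panel, distance=100_000, r2_threshold=1.0)
        assert len(kept) == 3

    def test_matches_bruteforce_oracle(self, small_panel):
        rng = np.random.default_rng(43)
        pvals = 10.0 ** rng.uniform(-12, 0, small_panel.n_variants)
        summ = summary_for(small_panel, pvals)
        X = small_panel.dosages.astype(float)
        Xs = (X - X.mean(0)) / X.std(0)
        r2 = (Xs.T @ Xs / len(X)) ** 2
        for dist, thr in [(50_000, 0.5), (100_000, 0.2), (250_000, 0.8)]:
            kept = prs.clump(summ, small_panel, distance=dist, r2_threshold=thr)
            want = brute_force_clump(summ, r2, dist, thr)
            assert sorted(kept.index) != []  # non-degenerate
            assert list(kept["ID"]) == [f"snp1_{small_panel.variants['POS'][i]}"
                                        for i in want]

    def test_no_retained_pair_exceeds_threshold(self, small_panel):
        rng = np.random.default_rng(44)
        summ = summary_for(small_panel,
                           10.0 ** rng.uniform(-12, 0, small_panel.n_variants))
        kept = prs.clump(summ, small_panel, distance=100_000, r2_threshold=0.4)
        cols = [small_panel.variants.index[small_panel.variants["ID"] == i][0]
                for i in kept["ID"]]
        X = small_panel.dosages[:, cols].astype(float)
        Xs = (X - X.mean(0)) / X.std(0)
        r2 = (Xs.T @ Xs / len(X)) ** 2
        pos = kept["POS"].to_numpy()
        for a in range(len(cols)):
            for b in range(a + 1, len(cols)):
                if abs(pos[a] - pos[b]) <= 100_000:
                    assert r2[a, b] <= 0.4 + 1e-9

    def test_empty_overlap_rejected(self, small_panel):
        summ = summary_for(small_panel, np.full(small_panel.n_variants, 0.5))
        summ["POS"] += 7  # no positional match
        with pytest.raises(ValueError):
            prs.clump(summ, small_panel)

class TestScore:
    def test_arithmetic(self):
        panel = make_panel(np.array([[0, 1, 2]]))
        model = prs.PRSModel(
            weights=pd.DataFrame({"ID": ["v0", "v1", "v2"], "EA": "G",
                                  "BETA": [0.1, 0.2, -0.3]}),
            clump_distance=250_000, clump_r2=0.8, p_threshold=1.0)
        assert abs(prs.score(panel, model)[0] - (-0.4)) < 1e-12

    def test_zero_model(self):
        panel = make_panel(np.array([[0, 1, 2], [2, 1, 0]]))
        model = prs.PRSModel(
            weights=pd.DataFrame({"ID": ["v0", "v1", "v2"], "EA": "G",
                                  "BETA": [0.0, 0.0, 0.0]}),
            clump_distance=250_000, clump_r2=0.8, p_threshold=1.0)
        assert np.all(prs.score(panel, model) == 0.0)

    def test_allele_flip_reparameterization(self):
        rng = np.random.default_rng(45)
        panel = make_panel(rng.integers(0, 3, (50, 3)))
        w = pd.DataFrame({"ID": ["v0", "v1", "v2"], "EA": ["G", "G", "G"],
                          "BETA": [0.1, 0.2, -0.3]})
        m1 = prs.PRSModel(w, 250_000, 0.8, 1.0)
        w2 = w.copy()
        w2.loc[1, "EA"] = "A"
        w2.loc[1, "BETA"] = -0.2
        m2 = prs.PRSModel(w2, 250_000, 0.8, 1.0)
        s1, s2 = prs.score(panel, m1), prs.score(panel, m2)
        # equivalent up to the additive constant 2*beta of the flipped variant
        np.testing.assert_allclose(s2, s1 - 0.4, atol=1e-12)
        assert np.std(s1 - s2) < 1e-12

    def test_unmatched_fraction_rejected(self):
        panel = make_panel(np.array([[0, 1, 2]]))
        w = pd.DataFrame({"ID": ["v0", "x1", "x2"], "EA": "G",
                          "BETA": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError, match="unmatched"):
            prs.score(panel, prs.PRSModel(w, 250_000, 0.8, 1.0))

class TestIncrementalR2:
    def test_perfect_predictor(self):
        rng = np.random.default_rng(46)
        s = rng.standard_normal(100)
        ph = pd.DataFrame({"trait": s})
        res = prs.incremental_r2(ph, s)
        assert abs(res.incremental - 1.0) < 1e-12

    def test_null_score(self):
        rng = np.random.default_rng(47)
        ph = pd.DataFrame({"trait": rng.standard_normal(10_000)})
        res = prs.incremental_r2(ph, rng.standard_normal(10_000))
        assert res.incremental < 0.001

    def test_collinear_score_absorbed(self):
        rng = np.random.default_rng(48)
        c = rng.standard_normal(500)
        ph = pd.DataFrame({"trait": c + 0.1 * rng.standard_normal(500), "c": c})
        res = prs.incremental_r2(ph, c, covariates=["c"])
        assert res.incremental < 1e-10

    def test_nonnegative_by_construction(self):
        rng = np.random.default_rng(49)
        for _ in range(20):
            ph = pd.DataFrame({"trait": rng.standard_normal(80),
                               "c": rng.standard_normal(80)})
            res = prs.incremental_r2(ph, rng.standard_normal(80),
                                     covariates=["c"])
            assert res.incremental >= 0.0

    def test_too_few_rows_rejected(self):
        ph = pd.DataFrame({"trait": [1.0, 2.0], "c": [0.1, 0.2]})
        with pytest.raises(ValueError):
            prs.incremental_r2(ph, np.array([0.5, 0.6]), covariates=["c"])

class TestDecileContrast:
    def test_monotone_map_strictly_increasing(self):
        rng = np.random.default_rng(50)
        s = rng.uniform(0, 1, 10_000)
        out = prs.decile_contrast(s, s)
        d = out["diff_vs_d1"].to_numpy()
        assert d[0] == 0.0 and np.all(np.diff(d) > 0)

    def test_null_contrasts_small(self):
        rng = np.random.default_rng(51)
        s = rng.standard_normal(20_000)
        y = rng.standard_normal(20_000)
        out = prs.decile_contrast(s, y)
        se = 1.0 / np.sqrt(2000)
        assert np.all(np.abs(out["diff_vs_d1"].to_numpy()[1:]) < 3 * se * np.sqrt(2))

    def test_ten_distinct_scores_one_per_decile(self):
        out = prs.decile_contrast(np.arange(10), np.arange(10.0))
        assert (out["n"] == 1).all()

    def test_fewer_than_ten_rejected(self):
        with pytest.raises(ValueError):
            prs.decile_contrast(np.arange(5), np.arange(5.0))

class TestThresholdSearch:
    def _cohort(self, seed=52, n=1500, m=150):
        spec = sd.PopulationSpec(name="a", ld_decay_bp=1e-3, n_individuals=n)
        vm = sd.make_variant_map(m, seed=seed)
        rng = np.random.default_rng(seed)
        f = sd.draw_subpopulation_frequencies(vm["ancestral_freq"].to_numpy(),
                                              0.05, rng)
        panel = sd.simulate_genotypes(spec, f, vm["POS"].to_numpy(), rng, vm)
        cov = sd.simulate_covariates(spec, rng)
        arch = sd.ArchitectureSpec(n_variants=m, n_causal=10, h2=0.5, seed=seed)
        pheno, truth = sd.simulate_phenotypes(panel, cov, arch)
        return panel, pheno, truth

    def test_singleton_grid_returned(self):
        panel, pheno, _ = self._cohort()
        summ = summary_for(panel, np.full(panel.n_variants, 1e-9))
        res = prs.threshold_search(summ, panel, pheno, grid=[0.05])
        assert res.best_model.p_threshold == 0.05

    def test_tie_prefers_stricter_threshold(self):
        panel, pheno, _ = self._cohort()
        # all variants significant at 1e-9: both thresholds give same model
        summ = summary_for(panel, np.full(panel.n_variants, 1e-9))
        res = prs.threshold_search(summ, panel, pheno, grid=[1e-6, 0.5])
        assert res.best_model.p_threshold == 1e-6

    def test_empty_cell_reported_missing(self):
        panel, pheno, _ = self._cohort()
        summ = summary_for(panel, np.full(panel.n_variants, 1e-3))
        res = prs.threshold_search(summ, panel, pheno, grid=[5e-8, 0.01])
        row = res.grid[res.grid["threshold"] == 5e-8].iloc[0]
        assert row["n_variants"] == 0 and np.isnan(row["incremental"])

    def test_sparse_architecture_prefers_strict_threshold(self):
        # out-of-sample validation should pick a threshold that keeps the
        # sparse true signal and discards the noise tail
        from metaprs import assoc
        wins = 0
        for seed in range(8):
            arch = sd.ArchitectureSpec(n_variants=150, n_causal=8, h2=0.5,
                                       seed=60 + seed)
            specs = [sd.PopulationSpec(name=n, fst=0.02, ld_decay_bp=1e-3,
                                       n_individuals=nn)
                     for n, nn in (("disc", 4000), ("valid", 1500))]
            cohorts = sd.simulate_multistudy(specs, arch, seed=60 + seed)
            (p_d, ph_d, _), (p_v, ph_v, _) = cohorts
            ss = assoc.run_gwas(p_d, ph_d).dropna(subset=["BETA"])
            res = prs.threshold_search(ss.reset_index(drop=True), p_v, ph_v,
                                       grid=[1e-6, 1e-4, 0.05, 0.5, 1.0])
            wins += res.best_model.p_threshold <= 1e-4
        assert wins >= 6

class TestStratifiedSplit:
    def _pheno(self, n=200, seed=53):
        rng = np.random.default_rng(seed)
        return pd.DataFrame({"sex": rng.choice(["M", "F"], n),
                             "region": rng.choice(["East", "West"], n)})

    def test_exact_fraction_single_stratum(self):
        ph = pd.DataFrame({"sex": ["M"] * 100})
        plan = prs.stratified_split(ph, 0.1, strata=["sex"], seed=1)
        assert len(plan.validation_index) == 10

    def test_per_stratum_fraction(self):
        ph = pd.DataFrame({"sex": ["M"] * 90 + ["F"] * 10})
        plan = prs.stratified_split(ph, 0.1, strata=["sex"], seed=2)
        a = plan.assignment
        assert (a[ph["sex"] == "M"] == "validation").sum() == 9
        assert (a[ph["sex"] == "F"] == "validation").sum() == 1

    def test_deterministic_under_seed(self):
        ph = self._pheno()
        a = prs.stratified_split(ph, 0.2, seed=7).assignment
        b = prs.stratified_split(ph, 0.2, seed=7).assignment
        pd.testing.assert_series_equal(a, b)

    def test_partition_complete(self):
        ph = self._pheno()
        plan = prs.stratified_split(ph, 0.25, seed=8)
        assert set(plan.validation_index) | set(plan.test_index) == set(range(200))
        assert not (set(plan.validation_index) & set(plan.test_index))
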