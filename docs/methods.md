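# Methods

This note documents the statistical models implemented in `metaprs`, the
generative model behind its synthetic cohorts, the parameter choices that
matter, and what the validation experiments do and do not establish.

## The analysis chain

### Inverse rank normalization

Traits are mapped to normal scores Φ⁻¹((r − c)/(n − 2c + 1)) with the Blom
offset c = 3/8 and average ranks for ties.  The offset is configurable; the
choice is immaterial for downstream inference (any offset gives the same
rank order and near-identical scores) but is fixed for reproducibility.
Constant input is rejected — there is no rank information to transform.

### Per-variant association

Ordinary least squares of the (already normalized) trait on dosage plus
covariates, computed by projecting the covariates out of trait and dosages
once (Frisch–Waugh–Lovell) so each variant costs one inner product.  The
result is numerically identical to the joint fit (checked against
statsmodels at 1e-10).  Linear mixed models are deliberately not
implemented: the synthetic cohorts contain no cryptic relatedness, and every
downstream consumer uses only (β, SE).  Monomorphic variants yield missing
effect rows and a logged skip count.

Principal components come from the standardized dosage matrix (full SVD
below 500 samples/variants, randomized otherwise, fixed random state); scores
are orthonormal left singular vectors with the sign convention that each
component's largest-magnitude loading is positive.

### Meta-analysis and double genomic control

Fixed-effects inverse-variance weighting.  Variants are keyed by
(chromosome, position, sorted allele pair); β and EAF are flipped when a
study reports the alleles swapped; strand-ambiguous pairs (A/T, C/G) and
allele-pair mismatches at a position are dropped with reason codes; variants
reported by fewer than two studies are excluded.

Double genomic control follows the two-stage scheme used for multi-ancestry
meta-analyses: per-study SEs are multiplied by the square root of a
correction factor (an externally estimated LDSC intercept where available;
factor 1 where no meaningful intercept exists, e.g. pooled multi-ancestry
studies), the corrected studies are combined, and λ_GC of the combined
z-scores is applied once more to the meta SEs.  In `auto` mode the per-study
λ_GC stands in for the LDSC intercept — estimating LDSC intercepts requires
external LD reference panels and is out of scope.  Correction factors are
clamped at 1 when applied (SEs are never deflated); unclamped values are
always reported.  The χ²₁ median is fixed at 0.4549364.

Genomic control assumes the median test statistic is driven by null
variants.  On signal-dense designs (e.g. the fine-mapping resolution
experiment, one causal variant per 40) this assumption fails and λ would
absorb true signal; such analyses use the plain IVW combination
(`meta.meta_analyze`) instead.

### Fine-mapping

Loci: greedy selection of genome-wide-significant leads (p < 5×10⁻⁸) in
order of significance, discarding significant variants within 1 Mb of each
chosen lead; the locus is the lead ±1 Mb (closed interval, clipped at
position 1).  Leads of distinct loci are therefore ≥1 Mb apart; flanks may
overlap and a variant may then appear in two credible sets.

Per variant, log BF = (z² − log K)/2 with K the number of contributing
studies; posteriors are the softmax of the log Bayes factors (log-sum-exp —
z² beyond 1,400 is routine and overflows naive exponentials).  The 99%
credible set is the minimal posterior-ranked prefix with cumulative
probability ≥ 0.99; a 10⁻¹² slack on the boundary keeps accumulated float
rounding from pushing an exact-boundary prefix (99 × 0.01) past the target.
Rank ties break by higher |z|, then lower position.  The K-dependent term is
constant within one analysis and cancels in the softmax; it matters when
K varies across variants of one locus (variants reported by more studies are
penalized as specified).

### C+T polygenic scores

Clumping is greedy by ascending p (ties: lower position), removing
unprocessed variants within 250 kb of the index whose dosage r² exceeds 0.8,
with LD computed in the target panel (as PRSice does).  The p-threshold grid
{5e-8, 1e-6, 1e-5, 1e-4, 1e-3, 0.01, 0.05, 0.1, 0.2, 0.5, 1} spans the range
used in practice; the best threshold maximizes incremental R² on a
validation split stratified by sex and region, with exact ties going to the
stricter threshold.  By default tuning uses the validation split only; a
`tune_on_combined` switch reproduces the alternative ordering in which clump
parameters are tuned on the full target before splitting (a known leakage
risk, provided for comparability).  Scoring is additive in effect-allele
dosage; model variants absent from the panel contribute zero (error above
50% unmatched); a variant reported on the opposite allele contributes
2 − dosage, which shifts scores by a constant 2β — equivalent for every
variance-based evaluation.  Deciles are rank-based with stable sort, ties
falling to the lower decile.

### Interaction models

OLS of trait on standardized PRS, modifier, PRS×modifier and covariates.
Categorical modifiers are dummy-coded against fixed reference levels
(male; East region; never-smoker; never-consumer; low socioeconomic status),
falling back to the first observed level when the reference is absent so the
design stays full-rank; continuous modifiers are standardized.  Both
per-contrast t-tests and an omnibus F-test over all interaction terms are
reported, matching the single-p-per-factor style of epidemiological tables
while keeping the contrasts inspectable.  Region-stratified models default
to 5 PCs; others to 10 (both configurable).

## The synthetic cohort generator

The generator is a study-design emulator, not a population-genetic
simulator.  It produces:

- **Allele frequencies** per population from the Balding–Nichols model,
  Beta(p(1−F)/F, (1−p)(1−F)/F) around a shared ancestral frequency p at
  divergence F; a `parent` mechanism lets populations diverge from another
  population's realized frequencies instead (e.g. two African regions nearly
  identical to each other, distant from the ancestral pool).  Draws outside
  [0.01, 0.99] are resampled, mirroring the MAF ≥ 1% filters of the cohorts
  being emulated (configurable).
- **Genotypes** as two haplotypes per individual, each a thresholded
  Ornstein–Uhlenbeck Gaussian: latent correlation exp(−d/L) between variants
  at distance d, thresholded at Φ⁻¹(p) so marginals match the frequencies.
  `ld_decay_bp` (L) is the distance at which the *latent* correlation falls
  to 1/e.  Dosage correlation is attenuated relative to the latent one; at
  p = 0.5 the relation is exactly r = (2/π)·asin(ρ), which
  `interact.fit_ld_decay` inverts (tetrachoric transform) before its
  log-linear fit — at other frequencies the plain exponential fit carries a
  small attenuation bias, well inside the 25% tolerance used in validation.
- **Traits** as y = √h²·γ(sex)·S + Σαc·Ec + Σδc·√h²·S·Ec + √(1−h²)·ε, with S
  the standardized true genetic score over a sparse causal set, γ the
  female/male effect ratio, and Ec standardized environment codes.  With no
  interactions and γ = 1 the R² of trait on true score converges to h²
  (validated within ±0.02 at n = 20,000).
- **Covariates** per population: sex, age (plus age²), region label, and
  categorized lifestyle variables (physical activity, socioeconomic status,
  smoking {never, ever}, alcohol {never, current non-problematic, current
  problematic, former}).  The emulated study reports regional environment
  distributions only as figures, so the defaults here are plausible
  placeholders with the right structure; region-specific values are set in
  the run config (the demo shifts physical-activity means by ±0.5 SD).

Not modeled: recombination maps, mutation, selection, demography,
relatedness, imputation error, genotyping platforms, X chromosome,
multi-allelic variation.  Variants sit on one uniformly spaced synthetic
chromosome by default.  Consequently, passing validation shows the
*estimators and the pipeline logic* behave correctly under controlled
frequency divergence, LD decay, heritability and interaction structure — it
does not certify performance on real cohort data, where none of the above
idealizations hold.

All randomness derives from one seed; sub-streams are keyed by
(module, purpose) strings so adding a consumer never perturbs existing
draws.  Pipeline artifacts are written with fixed float formatting and no
timestamps; reruns are byte-identical.

## Validation experiment design

Problem sizes were chosen so each experiment measures its effect with
comfortable margin on a single CPU:

- **Estimator oracles.**  Credible sets are compared exactly against a
  brute-force ranking oracle on 1,000 random loci (≤100 variants, |z| up to
  40, K ∈ {2,3,4}); IVW against an explicit weighted-least-squares solve on
  10,000 random inputs at 1e-10.
- **Double-GC calibration.**  Three null studies of 50,000 independent
  variants, each pooling two subpopulations (FST 0.05) whose trait means
  differ by 0.6 SD, analyzed without population adjustment: raw meta λ ≈ 8;
  after double GC λ returns to within 5% of 1.
- **Resolution direction.**  50 loci × 40 variants (5 kb spacing), one
  shared causal variant per locus at 0.18 SD per allele, two studies of
  1,500.  The multi-ancestry arm pairs study A (L = 100 kb) with a study
  whose LD decays two-fold faster; the single-population arm pairs the same
  study A with an A-like study.  The two comparator studies share common
  random numbers (identical latent Gaussians, frequencies and trait noise;
  only L differs), making each replicate a paired comparison of LD structure.
  The effect size is chosen to keep credible sets in the informative 2–4
  variant regime: much weaker, and set sizes are dominated by per-locus
  sampling noise of the causal z (which exponentiates through the Bayes
  factor); much stronger, and every set collapses to one variant.  At
  matched total sample size the multi-ancestry advantage is real but modest —
  unpaired designs show it on average without clearing a 90% replicate
  threshold.
- **Portability.**  Discovery A of 20,000 (FST 0.01, L = 100 kb); targets of
  2,000 hanging off discovery A and off a divergent discovery B (FST 0.15,
  L = 50 kb); 1,200 variants, 50 causal, h² = 0.3.  The A-trained PRS is
  tuned on each target's validation split and evaluated on its test split;
  the meta arm adds a B discovery of 10,000 via plain IVW.
- **Interactions.**  δ = 0.2 recovered at n = 50,000 (10 replicates);
  type-I error at δ = 0 from 1,000 replicates of n = 5,000.
- **Sex dimorphism.**  γ = 2, h² = 0.3, n = 4,000; the decile-10-vs-1
  contrast uses the true genetic score as the PRS, isolating the dimorphism
  of the contrast from PRS estimation error.

## Known limitations

- Genomic control is a blunt correction; the package reports unclamped λ so
  users can see what was absorbed, but it cannot separate polygenicity from
  confounding the way LD-score regression does.
- The single-causal-variant Bayes factor has no model for multiple causal
  variants per locus or for functional priors; credible sets at loci with
  allelic heterogeneity will be miscalibrated (as with any single-signal
  fine-mapper).
- C+T with target-panel LD inherits the instability of greedy clumping under
  sampling noise in small validation panels.
- The trait model is linear and homoscedastic; variance-QTL-type effects are
  representable only through explicit PRS×E terms.
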