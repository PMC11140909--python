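"""Synthetic multi-population cohort generator.

Emulates the statistical structure of a multi-ancestry body-mass-index study:
several discovery cohorts of divergent ancestry plus target cohorts split into
geographic regions.  Allele-frequency divergence between populations follows
the Balding-Nichols model (Beta draws around a shared ancestral frequency at a
controlled FST); linkage disequilibrium is realized through Gaussian-copula
haplotypes whose latent correlation decays exponentially with physical
distance; the quantitative trait is built from a shared sparse causal
architecture with optional sex-dimorphic genetic effects, environment main
effects and gene-environment interactions.

Nothing here is coalescent-exact: there are no recombination maps, no
mutation model and a single synthetic chromosome by default.  The point is
controllable marginal frequencies, FST, LD decay and heritability so that
every downstream stage (GWAS, meta-analysis, fine-mapping, PRS, interaction
models) can be tested quantitatively without external data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from ._utils import rng_for

# Non-strand-ambiguous allele pairs (other_allele, effect_allele); A/T and C/G
# pairs are never emitted so harmonization keeps every simulated variant.
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C")]

#: Default per-covariate environment distributions.  Categorical entries map
#: category -> probability; tuples are (mean, sd) of a normal draw.  The real
#: study reports these only as figures, so these defaults are placeholders
#: with the right shape (see docs/methods.md).
DEFAULT_ENV: dict = {
    "sex": {"M": 0.5, "F": 0.5},
    "age": (45.0, 12.0),
    "physical_activity": (0.0, 1.0),
    "socioeconomic": {"low": 0.4, "middle": 0.4, "high": 0.2},
    "smoking": {"never": 0.8, "ever": 0.2},
    "alcohol": {
        "never": 0.5,
        "current_nonproblematic": 0.3,
        "current_problematic": 0.1,
        "former": 0.1,
    },
}

@dataclass
class PopulationSpec:
    """One simulated cohort/population.

    Parameters
    ----------
    name : population label.
    fst : Balding-Nichols divergence from the ancestral population, in [0, 1).
    ld_decay_bp : distance (bp) at which the latent haplotype correlation
        falls to 1/e.
    n_individuals : cohort size (>= 2).
    region : region label attached to every individual (e.g. East/West/South).
    parent : optional name of an earlier population in the same
        :func:`simulate_multistudy` call; frequencies then diverge from that
        population's realized frequencies instead of the ancestral vector
        (hierarchical divergence — e.g. two African regions that are nearly
        identical to each other but distant from the ancestral pool).
    env : per-covariate distributions; categorical entries are
        category -> probability mappings summing to 1, continuous entries are
        (mean, sd) tuples.  Missing covariates fall back to ``DEFAULT_ENV``.
    """

    name: str
    fst: float = 0.05
    ld_decay_bp: float = 50_000.0
    n_individuals: int = 1000
    region: str = "East"
    parent: str | None = None
    env: Mapping = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.fst < 1.0):
            raise ValueError(f"fst must be in [0, 1), got {self.fst}")
        if self.n_individuals < 2:
            raise ValueError("n_individuals must be >= 2")
        if self.ld_decay_bp <= 0:
            raise ValueError("ld_decay_bp must be > 0")
        for key, dist in self.env.items():
            if isinstance(dist, Mapping):
                total = float(sum(dist.values()))
                if abs(total - 1.0) > 1e-9:
                    raise ValueError(
                        f"category probabilities for {key!r} sum to {total}, not 1"
                    )

    def env_dist(self, key: str):
        if key in self.env:
            return self.env[key]
        return DEFAULT_ENV[key]

@dataclass
class ArchitectureSpec:
    """Shared genetic architecture of the simulated trait.

    ``h2`` is the narrow-sense heritability target: with no interactions and
    ``sex_effect_ratio == 1`` the trait is built as
    sqrt(h2) * standardized genetic score + sqrt(1 - h2) * noise, so the
    realized R^2 of the trait on the true score converges to h2.
    ``sex_effect_ratio`` multiplies the genetic component in females relative
    to males; ``gxe_terms`` lists (covariate, delta) product terms between the
    scaled genetic score and the standardized covariate; ``env_effects`` adds
    covariate main effects on top.
    """

    n_variants: int = 1000
    n_causal: int = 50
    h2: float = 0.3
    beta_sd: float = 1.0
    gxe_terms: Sequence[tuple[str, float]] = ()
    env_effects: Mapping[str, float] = field(default_factory=dict)
    sex_effect_ratio: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.h2 <= 1.0):
            raise ValueError(f"h2 must be in [0, 1], got {self.h2}")
        if self.n_causal > self.n_variants:
            raise ValueError("n_causal must be <= n_variants")
        if self.n_causal < 0 or self.n_variants <= 0:
            raise ValueError("counts must be positive")

@dataclass
class GenotypePanel:
    """Individuals x variants dosage matrix plus variant metadata.

    ``dosages`` holds effect-allele counts in {0, 1, 2} (int8; float values
    in [0, 2] appear only after mean imputation of missing VCF genotypes);
    ``variants`` is a DataFrame with columns
    CHR, POS (1-based), ID, OA, EA, ancestral_freq;
    ``populations`` labels each individual.
    """

    dosages: np.ndarray
    variants: pd.DataFrame
    populations: np.ndarray

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages)
        self.populations = np.asarray(self.populations)
        if self.dosages.shape[0] != len(self.populations):
            raise ValueError("dosages rows must match populations length")
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("dosages columns must match variant count")
        pos = self.variants["POS"].to_numpy()
        chrom = self.variants["CHR"].to_numpy()
        same = chrom[1:] == chrom[:-1]
        # ties allowed (duplicated variants at distance 0); decreasing is not
        if np.any(same & (np.diff(pos) < 0)):
            raise ValueError("positions must be non-decreasing within chromosome")

    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def eaf(self) -> np.ndarray:
        """Empirical effect-allele frequency per variant."""
        return self.dosages.mean(axis=0) / 2.0

@dataclass
class TraitTruth:
    """Ground-truth parameters recorded by :func:`simulate_phenotypes`."""

    causal_indices: np.ndarray
    causal_ids: list[str]
    betas: np.ndarray
    h2: float
    sex_effect_ratio: float
    gxe_terms: list[tuple[str, float]]
    score_mean: float
    score_sd: float

    def raw_score(self, panel: GenotypePanel) -> np.ndarray:
        """Unstandardized true genetic score of ``panel`` individuals."""
        g = panel.dosages[:, self.causal_indices].astype(float)
        return g @ self.betas

    def standardized_score(self, panel: GenotypePanel) -> np.ndarray:
        """True score standardized with the *training-time* mean and sd."""
        return (self.raw_score(panel) - self.score_mean) / self.score_sd

def draw_subpopulation_frequencies(
    ancestral_freqs,
    fst: float,
    seed: int | np.random.Generator = 0,
    freq_bounds: tuple[float, float] | None = (0.01, 0.99),
    max_resample: int = 100,
) -> np.ndarray:
    """Balding-Nichols subpopulation frequencies.

    Each frequency is drawn from Beta(p(1-F)/F, (1-p)(1-F)/F) around its
    ancestral value p.  ``fst == 0`` returns the ancestral frequencies
    unchanged.  Draws outside ``freq_bounds`` are resampled (the studies
    being emulated applied MAF >= 0.01 filters); set ``freq_bounds=None``
    to disable the guard.  After ``max_resample`` rounds any stragglers are
    clipped to the bounds.
    """
    p = np.asarray(ancestral_freqs, dtype=float)
    if np.any((p <= 0.0) | (p >= 1.0)):
        raise ValueError("ancestral frequencies must lie strictly in (0, 1)")
    if not (0.0 <= fst < 1.0):
        raise ValueError(f"fst must be in [0, 1), got {fst}")
    if fst == 0.0:
        return p.copy()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    scale = (1.0 - fst) / fst
    out = rng.beta(p * scale, (1.0 - p) * scale)
    if freq_bounds is not None:
        lo, hi = freq_bounds
        for _ in range(max_resample):
            bad = (out < lo) | (out > hi)
            if not bad.any():
                break
            out[bad] = rng.beta(p[bad] * scale, (1.0 - p[bad]) * scale)
        out = np.clip(out, lo, hi)
    return out

def make_variant_map(
    n_variants: int,
    spacing_bp: int = 5_000,
    chrom: str = "1",
    start_bp: int = 1,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Uniformly spaced variants on one synthetic chromosome.

    Allele pairs are drawn from the non-strand-ambiguous set so harmonization
    never drops simulated variants; ancestral frequencies are uniform on
    (0.1, 0.9).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pos = start_bp + spacing_bp * np.arange(n_variants, dtype=np.int64)
    pairs = [_ALLELE_PAIRS[i] for i in rng.integers(0, len(_ALLELE_PAIRS), n_variants)]
    return pd.DataFrame(
        {
            "CHR": chrom,
            "POS": pos,
            "ID": [f"snp{chrom}_{p}" for p in pos],
            "OA": [a for a, _ in pairs],
            "EA": [b for _, b in pairs],
            "ancestral_freq": rng.uniform(0.1, 0.9, n_variants),
        }
    )

def _haplotypes(n_hap: int, freqs: np.ndarray, positions: np.ndarray,
                ld_decay_bp: float, rng: np.random.Generator) -> np.ndarray:
    """Thresholded Ornstein-Uhlenbeck Gaussians: exp(-d/L) latent correlation."""
    m = len(freqs)
    d = np.diff(positions).astype(float)
    rho = np.exp(-d / float(ld_decay_bp)).astype(np.float32)
    thresh = stats.norm.ppf(np.asarray(freqs, dtype=float)).astype(np.float32)
    if m == 1 or np.all(rho < 1e-8):
        # independence limit: skip the sequential recursion entirely
        z = rng.standard_normal((n_hap, m), dtype=np.float32)
        return (z < thresh).astype(np.int8)
    z = np.empty((n_hap, m), dtype=np.float32)
    z[:, 0] = rng.standard_normal(n_hap, dtype=np.float32)
    innov_sd = np.sqrt(1.0 - rho**2).astype(np.float32)
    eps = rng.standard_normal((n_hap, m - 1), dtype=np.float32)
    for j in range(1, m):
        z[:, j] = rho[j - 1] * z[:, j - 1] + innov_sd[j - 1] * eps[:, j - 1]
    return (z < thresh).astype(np.int8)

def simulate_genotypes(
    pop_spec: PopulationSpec,
    freqs,
    positions,
    seed: int | np.random.Generator = 0,
    variants: pd.DataFrame | None = None,
) -> GenotypePanel:
    """Simulate a dosage panel with exponential-decay LD.

    Two haplotypes per individual; each haplotype is a thresholded correlated
    Gaussian so the marginal allele frequency matches ``freqs`` and the latent
    correlation between variants at distance d is exp(-d / ld_decay_bp).
    Dosage = haplotype sum, counted on the effect allele.
    """
    freqs = np.asarray(freqs, dtype=float)
    positions = np.asarray(positions, dtype=np.int64)
    if freqs.shape != positions.shape:
        raise ValueError("freqs and positions must have the same length")
    if np.any(np.diff(positions) < 0):
        raise ValueError("positions must be non-decreasing")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = pop_spec.n_individuals
    hap = _haplotypes(2 * n, freqs, positions, pop_spec.ld_decay_bp, rng)
    dosages = hap[0::2] + hap[1::2]
    if variants is None:
        variants = pd.DataFrame(
            {
                "CHR": "1",
                "POS": positions,
                "ID": [f"snp1_{p}" for p in positions],
                "OA": "A",
                "EA": "G",
                "ancestral_freq": freqs,
            }
        )
    pops = np.repeat(pop_spec.name, n)
    return GenotypePanel(dosages=dosages, variants=variants.reset_index(drop=True), populations=pops)

def simulate_covariates(pop_spec: PopulationSpec,
                        seed: int | np.random.Generator = 0) -> pd.DataFrame:
    """Draw the per-individual covariate table for one population."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = pop_spec.n_individuals
    cols: dict = {}
    for key in ("sex", "age", "physical_activity", "socioeconomic", "smoking", "alcohol"):
        dist = pop_spec.env_dist(key)
        if isinstance(dist, Mapping):
            cats = list(dist.keys())
            probs = np.asarray([dist[c] for c in cats], dtype=float)
            cols[key] = rng.choice(cats, size=n, p=probs / probs.sum())
        else:
            mean, sd = dist
            cols[key] = mean + sd * rng.standard_normal(n)
    df = pd.DataFrame(cols)
    df["age2"] = df["age"] ** 2
    df["region"] = pop_spec.region
    df["population"] = pop_spec.name
    return df

def _numeric_env(table: pd.DataFrame, column: str) -> np.ndarray:
    """Numeric, standardized encoding of an environment column.

    Continuous columns are z-scored; ``sex`` is coded female = 1, male = 0
    and centered; other categoricals are coded by category index and z-scored.
    """
    col = table[column]
    if column == "sex":
        x = (col.to_numpy() == "F").astype(float)
    elif pd.api.types.is_numeric_dtype(col):
        x = col.to_numpy(dtype=float)
    else:
        x = pd.Categorical(col).codes.astype(float)
    sd = x.std()
    if sd == 0:
        raise ValueError(f"environment column {column!r} is constant")
    return (x - x.mean()) / sd

def simulate_phenotypes(
    panel: GenotypePanel,
    covariates: pd.DataFrame,
    arch: ArchitectureSpec,
    truth: TraitTruth | None = None,
    seed: int | np.random.Generator | None = None,
) -> tuple[pd.DataFrame, TraitTruth]:
    """Build the quantitative trait from genotypes + environment.

    trait = sqrt(h2) * gamma(sex) * S + sum_c alpha_c E_c
            + sum_c delta_c * sqrt(h2) * S * E_c + sqrt(1 - h2) * eps

    with S the standardized true genetic score, gamma(sex) the female/male
    effect ratio, E_c standardized environment codes and eps standard normal.
    Passing ``truth`` reuses previously drawn causal variants and effects so
    several cohorts share one architecture.  Returns the covariate table with
    a ``trait`` column plus the :class:`TraitTruth` record.
    """
    if len(covariates) != panel.n_individuals:
        raise ValueError("covariate rows must match panel individuals")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(arch.seed if seed is None else seed))
    if truth is None:
        truth = draw_architecture(panel, arch, rng)
    raw = truth.raw_score(panel)
    if arch.h2 > 0 and truth.score_sd == 0:
        raise ValueError("true genetic score is constant; cannot target h2 > 0")
    s = (raw - truth.score_mean) / truth.score_sd if truth.score_sd > 0 else np.zeros_like(raw)

    gamma = np.where(covariates["sex"].to_numpy() == "F", arch.sex_effect_ratio, 1.0)
    h2, sqrt_h2 = arch.h2, np.sqrt(arch.h2)
    y = sqrt_h2 * gamma * s
    for cov, alpha in arch.env_effects.items():
        y = y + alpha * _numeric_env(covariates, cov)
    for cov, delta in arch.gxe_terms:
        y = y + delta * sqrt_h2 * s * _numeric_env(covariates, cov)
    y = y + np.sqrt(1.0 - h2) * rng.standard_normal(panel.n_individuals)

    out = covariates.copy()
    out["trait"] = y
    return out, truth

def draw_architecture(panel: GenotypePanel, arch: ArchitectureSpec,
                      seed: int | np.random.Generator | None = None) -> TraitTruth:
    """Draw causal variants and effect sizes; record score scaling from ``panel``."""
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(arch.seed if seed is None else seed))
    if arch.n_causal > panel.n_variants:
        raise ValueError("n_causal exceeds panel variants")
    idx = np.sort(rng.choice(panel.n_variants, size=arch.n_causal, replace=False))
    betas = arch.beta_sd * rng.standard_normal(arch.n_causal)
    raw = panel.dosages[:, idx].astype(float) @ betas
    return TraitTruth(
        causal_indices=idx,
        causal_ids=[panel.variants["ID"].iloc[i] for i in idx],
        betas=betas,
        h2=arch.h2,
        sex_effect_ratio=arch.sex_effect_ratio,
        gxe_terms=list(arch.gxe_terms),
        score_mean=float(raw.mean()),
        score_sd=float(raw.std()),
    )

def simulate_multistudy(
    specs: Sequence[PopulationSpec],
    arch: ArchitectureSpec,
    shared_causals: bool = True,
    spacing_bp: int = 5_000,
    seed: int | None = None,
) -> list[tuple[GenotypePanel, pd.DataFrame, TraitTruth]]:
    """Simulate several cohorts on one shared variant map.

    All cohorts see the same (chromosome, position, ID, alleles) list; each
    cohort's frequencies diverge from the common ancestral frequencies at its
    own FST and its LD decays at its own scale.  With ``shared_causals`` the
    causal variants and effect sizes are drawn once (anchored on the first
    cohort) and reused everywhere — the generative premise behind
    cross-ancestry meta-analysis and PRS portability experiments.
    """
    if len(specs) < 2:
        raise ValueError("need at least two population specs")
    base_seed = arch.seed if seed is None else seed
    vmap = make_variant_map(arch.n_variants, spacing_bp=spacing_bp,
                            seed=rng_for(base_seed, "synthdata", "variant_map"))
    positions = vmap["POS"].to_numpy()
    ancestral = vmap["ancestral_freq"].to_numpy()

    out = []
    truth: TraitTruth | None = None
    freqs_by_name: dict[str, np.ndarray] = {}
    for i, spec in enumerate(specs):
        if spec.parent is not None:
            if spec.parent not in freqs_by_name:
                raise ValueError(
                    f"parent {spec.parent!r} of {spec.name!r} not simulated yet"
                )
            base = freqs_by_name[spec.parent]
        else:
            base = ancestral
        freqs = draw_subpopulation_frequencies(
            base, spec.fst, rng_for(base_seed, "synthdata", f"freqs:{spec.name}:{i}")
        )
        freqs_by_name[spec.name] = freqs
        panel = simulate_genotypes(
            spec, freqs, positions,
            seed=rng_for(base_seed, "synthdata", f"geno:{spec.name}:{i}"),
            variants=vmap,
        )
        cov = simulate_covariates(spec, rng_for(base_seed, "synthdata", f"cov:{spec.name}:{i}"))
        if truth is None:
            truth = draw_architecture(panel, arch, rng_for(base_seed, "synthdata", "architecture"))
        elif not shared_causals:
            truth = draw_architecture(panel, arch,
                                      rng_for(base_seed, "synthdata", f"architecture:{i}"))
        pheno, truth = simulate_phenotypes(
            panel, cov, arch, truth=truth,
            seed=rng_for(base_seed, "synthdata", f"pheno:{spec.name}:{i}"),
        )
        out.append((panel, pheno, truth))
    return out

def hudson_fst(freq_a, freq_b, n_a: float = np.inf, n_b: float = np.inf) -> float:
    """Hudson FST estimator from allele frequencies (ratio-of-averages form).

    ``n_a``/``n_b`` are the numbers of sampled *alleles* (2 x individuals for
    diploid dosage frequencies); the default (infinity) drops the finite-sample
    correction, appropriate when the inputs are exact population frequencies.
    """
    pa = np.asarray(freq_a, dtype=float)
    pb = np.asarray(freq_b, dtype=float)
    num = (pa - pb) ** 2 - pa * (1 - pa) / (n_a - 1) - pb * (1 - pb) / (n_b - 1)
    den = pa * (1 - pb) + pb * (1 - pa)
    return float(num.sum() / den.sum())
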