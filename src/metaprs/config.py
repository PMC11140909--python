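"""Run configuration: a strict, flat-ish YAML schema mirroring every stage's tunables."""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

SCHEMA_VERSION = "1"

def _check_keys(d: dict, allowed: set[str], where: str) -> None:
    unknown = set(d) - allowed
    if unknown:
        raise ValueError(f"unknown config keys in {where}: {sorted(unknown)}")

@dataclass
class PopulationConfig:
    name: str
    fst: float = 0.05
    ld_decay_bp: float = 50_000.0
    n_individuals: int = 1000
    region: str = "East"
    parent: str | None = None
    env: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, d: dict, where: str) -> "PopulationConfig":
        _check_keys(d, {f for f in cls.__dataclass_fields__}, where)
        return cls(**d)

@dataclass
class RunConfig:
    """Resolved parameters for a full simulate -> interact pipeline run."""

    seed: int = 0
    schema_version: str = SCHEMA_VERSION
    # architecture
    n_variants: int = 20_000
    spacing_bp: int = 2_500
    n_causal: int = 100
    h2: float = 0.3
    beta_sd: float = 1.0
    sex_effect_ratio: float = 1.0
    gxe_terms: list = field(default_factory=list)     # [[covariate, delta], ...]
    env_effects: dict = field(default_factory=dict)   # covariate -> alpha
    # cohorts
    discovery: list = field(default_factory=list)     # PopulationConfig
    targets: list = field(default_factory=list)       # PopulationConfig
    # gwas
    gwas_covariates: list = field(default_factory=lambda: ["age", "age2", "sex"])
    gwas_n_pcs: int = 10
    # meta
    ldsc_intercepts: object = "auto"
    min_k: int = 2
    # finemap
    p_threshold: float = 5e-8
    min_separation: int = 1_000_000
    flank: int = 1_000_000
    coverage: float = 0.99
    # prs
    clump_distance: int = 250_000
    clump_r2: float = 0.8
    p_grid: list = field(default_factory=lambda: [5e-8, 1e-6, 1e-5, 1e-4,
                                                  1e-3, 0.01, 0.05, 0.1, 0.2, 0.5, 1.0])
    frac_validation: float = 0.1
    split_strata: list = field(default_factory=lambda: ["sex", "region"])
    tune_on_combined: bool = False
    # interact
    interaction_modifiers: list = field(
        default_factory=lambda: ["sex", "region", "physical_activity",
                                 "socioeconomic", "smoking", "alcohol"])
    region_n_pcs: int = 5

    def __post_init__(self) -> None:
        self.discovery = [
            p if isinstance(p, PopulationConfig) else PopulationConfig.from_dict(p, "discovery")
            for p in self.discovery
        ]
        self.targets = [
            p if isinstance(p, PopulationConfig) else PopulationConfig.from_dict(p, "targets")
            for p in self.targets
        ]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        _check_keys(d, {f for f in cls.__dataclass_fields__}, "run config")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        return asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def sha256(self) -> str:
        blob = yaml.safe_dump(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

def demo_config(seed: int = 0) -> RunConfig:
    """Desk-scale demo: 3 divergent discovery cohorts, 2 target regions.

    Emulates the shape of a multi-ancestry discovery (one large homogeneous
    cohort, one East-Asian-like, one African-like with faster LD decay)
    feeding a two-region African-like target with region-specific
    environments and a PRS x physical-activity interaction.
    """
    return RunConfig(
        seed=seed,
        n_variants=20_000,
        spacing_bp=2_500,
        n_causal=20,
        h2=0.3,
        sex_effect_ratio=2.0,
        gxe_terms=[["physical_activity", -0.15]],
        env_effects={"physical_activity": -0.1},
        discovery=[
            {"name": "euro_like", "fst": 0.02, "ld_decay_bp": 100_000,
             "n_individuals": 1200, "region": "discovery"},
            {"name": "asian_like", "fst": 0.1, "ld_decay_bp": 100_000,
             "n_individuals": 1200, "region": "discovery"},
            {"name": "african_like", "fst": 0.12, "ld_decay_bp": 50_000,
             "n_individuals": 1200, "region": "discovery"},
        ],
        targets=[
            {"name": "target_west", "fst": 0.005, "parent": "african_like",
             "ld_decay_bp": 50_000, "n_individuals": 900, "region": "West",
             "env": {"physical_activity": [0.5, 1.0]}},
            {"name": "target_south", "fst": 0.005, "parent": "african_like",
             "ld_decay_bp": 50_000, "n_individuals": 900, "region": "South",
             "env": {"physical_activity": [-0.5, 1.0]}},
        ],
        gwas_n_pcs=5,
        frac_validation=0.2,
    )
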