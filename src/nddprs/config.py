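"""Configuration objects for the synthetic cohort generator and the pipeline.

``SimConfig`` fixes every stochastic property of the generated cohort; all
random draws descend from its single ``seed`` through fixed per-stage
sub-streams, so each stage is independently reproducible.  ``RunConfig``
bundles a ``SimConfig`` with the QC / PRS / statistics thresholds used by
the analysis stages; the defaults are the study's operating values
(variant call rate > 0.90, sample genotyping rate >= 0.99, MAF >= 0.01,
HWE exact p >= 1e-5, imputation INFO >= 0.8, clump r^2 0.1 within 200 kb,
score thresholds {0.01, 0.03, 0.05, 1.00}, relatedness cut 0.2, DEG
nominal p < 0.05).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigError

#: fixed offsets deriving per-stage random sub-streams from the run seed
STREAM_GENOTYPES = 11
STREAM_SUMSTATS = 23
STREAM_SUMSTATS_2 = 29
STREAM_CLINICAL = 37
STREAM_COUNTS = 53


@dataclass
class SimConfig:
    """Parameters of the synthetic postmortem-brain cohort.

    The defaults emulate the target study's design: 24 schizophrenia cases
    and 48 non-psychiatric controls genotyped genome-wide, 19 cases with
    antemortem clinical records, a much larger external discovery GWAS,
    a negative rank correlation of -0.5 between polygenic score and
    antipsychotic responsiveness, and bulk prefrontal-cortex RNA-seq
    counts for the clinical cases.  Genome size and gene count are scaled
    to a desk-size panel (LD blocks of 20 variants on autosomes 1-22,
    8,000 genes) so the full pipeline runs in minutes.
    """

    n_cases: int = 24
    n_controls: int = 48
    n_clinical: int = 19

    # genotype panel
    n_variants: int = 6000
    n_blocks: int = 300
    within_block_r: float = 0.7
    ld_model: str = "equicorrelated"  # or "ar1"
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_frac: float = 0.002          # background per-entry missingness
    low_callrate_frac: float = 0.02      # variants with concentrated missingness
    low_callrate_missing: float = 0.25
    ambiguous_frac: float = 0.02
    info_beta: tuple[float, float] = (30.0, 2.0)

    # discovery GWAS / genetic architecture
    n_causal: int = 100
    heritability_liability: float = 0.3
    discovery_n: int = 50_000

    # clinical records
    prs_ars_rho: float = -0.5

    # RNA-seq counts
    n_genes: int = 8000
    n_de_genes: int = 800
    lfc_sd: float = 0.5
    lfc_min: float = 0.0
    dispersion_shape: float = 0.1
    dispersion_df: float = 20.0
    libsize_log_sd: float = 0.2
    mean_libsize: float = 3.0e6
    nonautosomal_gene_frac: float = 0.05

    seed: int = 1

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        counts = {
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "n_variants": self.n_variants,
            "n_blocks": self.n_blocks,
            "n_genes": self.n_genes,
        }
        for name, value in counts.items():
            if int(value) != value or value <= 0:
                raise ConfigError(f"{name} must be a positive integer, got {value!r}")
        for name, value in {
            "n_causal": self.n_causal,
            "n_de_genes": self.n_de_genes,
            "n_clinical": self.n_clinical,
        }.items():
            if int(value) != value or value < 0:
                raise ConfigError(f"{name} must be a non-negative integer, got {value!r}")
        if self.n_causal > self.n_variants:
            raise ConfigError("n_causal must not exceed n_variants")
        if self.n_de_genes > self.n_genes:
            raise ConfigError("n_de_genes must not exceed n_genes")
        if self.n_clinical > self.n_cases:
            raise ConfigError("n_clinical must not exceed n_cases")
        if not (0.0 <= self.within_block_r < 1.0):
            raise ConfigError("within_block_r must lie in [0, 1)")
        if self.ld_model not in ("equicorrelated", "ar1"):
            raise ConfigError("ld_model must be 'equicorrelated' or 'ar1'")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ConfigError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not (0.0 <= self.heritability_liability < 1.0):
            raise ConfigError("heritability_liability must lie in [0, 1)")
        if self.discovery_n < 2:
            raise ConfigError("discovery_n must be at least 2")
        if not (-1.0 < self.prs_ars_rho < 1.0):
            raise ConfigError("prs_ars_rho must lie strictly inside (-1, 1)")
        for name, value in {
            "lfc_sd": self.lfc_sd,
            "missing_frac": self.missing_frac,
            "low_callrate_frac": self.low_callrate_frac,
            "low_callrate_missing": self.low_callrate_missing,
            "ambiguous_frac": self.ambiguous_frac,
            "nonautosomal_gene_frac": self.nonautosomal_gene_frac,
        }.items():
            if value < 0:
                raise ConfigError(f"{name} must be non-negative, got {value!r}")
        for name, value in {
            "dispersion_shape": self.dispersion_shape,
            "dispersion_df": self.dispersion_df,
            "libsize_log_sd": self.libsize_log_sd,
            "mean_libsize": self.mean_libsize,
        }.items():
            if value <= 0:
                raise ConfigError(f"{name} must be positive, got {value!r}")

    def replace(self, **kwargs) -> "SimConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(self.maf_range)
        d["info_beta"] = list(self.info_beta)
        return d


@dataclass
class RunConfig:
    """End-to-end pipeline configuration with the study's default thresholds."""

    sim: SimConfig = field(default_factory=SimConfig)
    out_dir: str = "nddprs_run"
    seed: int = 1

    # variant / sample QC
    variant_call_rate: float = 0.90     # strict >
    sample_call_rate: float = 0.99      # strict >=, exclusion is strict <
    maf_min: float = 0.01               # retain >=
    hwe_p_min: float = 1.0e-5           # retain >=
    hwe_mode: str = "controls"          # or "all"
    relatedness_max: float = 0.2        # strict >

    # PRS
    info_min: float = 0.8               # retain >=
    clump_r2: float = 0.1
    clump_window_bp: int = 200_000
    p_thresholds: tuple[float, ...] = (0.01, 0.03, 0.05, 1.00)

    # statistics
    bh_family: str = "per-prs"          # or "global"
    deg_alpha: float = 0.05

    # DGE
    cpm_min: float = 1.0
    dispersion_prior_df: float = 10.0

    log_level: str = "info"

    def __post_init__(self) -> None:
        if isinstance(self.sim, dict):
            self.sim = SimConfig(**self.sim)
        self.validate()

    def validate(self) -> None:
        if self.bh_family not in ("per-prs", "global"):
            raise ConfigError("bh_family must be 'per-prs' or 'global'")
        if self.hwe_mode not in ("controls", "all"):
            raise ConfigError("hwe_mode must be 'controls' or 'all'")
        for name in ("variant_call_rate", "sample_call_rate", "maf_min",
                     "hwe_p_min", "info_min", "clump_r2", "deg_alpha"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ConfigError(f"{name} must lie in [0, 1], got {v!r}")
        if self.clump_window_bp <= 0:
            raise ConfigError("clump_window_bp must be positive")
        if not self.p_thresholds or any(not (0 < t <= 1) for t in self.p_thresholds):
            raise ConfigError("p_thresholds must be p-values in (0, 1]")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        if "p_thresholds" in raw:
            raw["p_thresholds"] = tuple(raw["p_thresholds"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"] = self.sim.to_dict()
        d["p_thresholds"] = list(self.p_thresholds)
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
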