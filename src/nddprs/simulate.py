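"""Synthetic postmortem-cohort generator.

Every pipeline input — block-LD diploid genotypes, discovery-GWAS summary
statistics with true polygenic effects, clinical records whose
antipsychotic-responsiveness score (ARS) has a tunable rank correlation
with the true genetic score, and negative-binomial RNA-seq counts with
planted group effects — is generated from one :class:`~nddprs.config.SimConfig`.
All draws descend from ``cfg.seed`` through fixed per-stage sub-streams,
so each stage is bit-reproducible on its own.

The genotype model is deliberately simple: within an LD block the two
haplotype copies of each sample are thresholded equicorrelated (or AR(1))
Gaussians, which gives Hardy-Weinberg marginals by construction and a
controllable dosage correlation for clumping tests.  Realistic human LD
mosaics, imputation error and chip artifacts are out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import (STREAM_CLINICAL, STREAM_COUNTS, STREAM_GENOTYPES,
                     STREAM_SUMSTATS, STREAM_SUMSTATS_2, SimConfig)
from .errors import ConfigError, ValidationError
from .genio import VARIANT_META_COLUMNS, GenotypeMatrix

_NONAMBIG_PAIRS = [("A", "C"), ("A", "G"), ("T", "C"), ("T", "G"),
                   ("C", "A"), ("G", "A"), ("C", "T"), ("G", "T")]
_AMBIG_PAIRS = [("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")]

#: bp between adjacent variants in a block; blocks are spaced > 1 Mb apart
VARIANT_SPACING_BP = 10_000
BLOCK_GAP_BP = 1_200_000


def _block_sizes(n_variants: int, n_blocks: int) -> np.ndarray:
    base = n_variants // n_blocks
    sizes = np.full(n_blocks, base, dtype=int)
    sizes[: n_variants - base * n_blocks] += 1
    return sizes


def _latent_haplotype(rng: np.random.Generator, n: int, sizes: np.ndarray,
                      r: float, model: str) -> np.ndarray:
    """One n x m latent Gaussian with the requested within-block correlation."""
    cols = []
    for size in sizes:
        eps = rng.standard_normal((n, size))
        if r == 0.0 or size == 1:
            cols.append(eps)
        elif model == "equicorrelated":
            shared = rng.standard_normal((n, 1))
            cols.append(np.sqrt(r) * shared + np.sqrt(1.0 - r) * eps)
        else:  # ar1
            z = np.empty((n, size))
            z[:, 0] = eps[:, 0]
            for j in range(1, size):
                z[:, j] = r * z[:, j - 1] + np.sqrt(1.0 - r * r) * eps[:, j]
            cols.append(z)
    return np.concatenate(cols, axis=1)


def simulate_genotypes(cfg: SimConfig) -> GenotypeMatrix:
    """Draw the diploid dosage panel for all cases and controls.

    Variants are partitioned into ``cfg.n_blocks`` contiguous blocks laid
    out across autosomes 1..22; within a block the latent liabilities of
    each haplotype share correlation ``cfg.within_block_r`` and are
    thresholded at the variant's drawn MAF, so genotypes are in HWE
    marginally and correlated within blocks.  A ``missing_frac`` of calls
    is knocked out and an ``ambiguous_frac`` of variants is given A/T or
    C/G alleles to exercise QC.
    """
    cfg.validate()
    rng = np.random.default_rng([cfg.seed, STREAM_GENOTYPES])
    n = cfg.n_cases + cfg.n_controls
    m = cfg.n_variants
    sizes = _block_sizes(m, cfg.n_blocks)

    mafs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=m)
    thresh = stats.norm.ppf(mafs)
    hap1 = _latent_haplotype(rng, n, sizes, cfg.within_block_r, cfg.ld_model)
    hap2 = _latent_haplotype(rng, n, sizes, cfg.within_block_r, cfg.ld_model)
    dosage = (hap1 < thresh).astype(float) + (hap2 < thresh).astype(float)

    # missingness is concentrated in a few low-call-rate variants (which the
    # call-rate filter should catch) over a low background rate, as in
    # post-imputation panels
    miss_rate = np.full(m, cfg.missing_frac)
    n_low = int(round(cfg.low_callrate_frac * m))
    if n_low:
        low = rng.choice(m, size=n_low, replace=False)
        miss_rate[low] = cfg.low_callrate_missing
    dosage[rng.random(dosage.shape) < miss_rate[None, :]] = np.nan

    # genomic coordinates: blocks cycle over autosomes, well separated
    chroms = np.empty(m, dtype=object)
    pos = np.empty(m, dtype=int)
    per_chrom_offset = dict.fromkeys(range(1, 23), 0)
    j = 0
    for b, size in enumerate(sizes):
        c = (b % 22) + 1
        start = per_chrom_offset[c] + 1
        per_chrom_offset[c] = start + size * VARIANT_SPACING_BP + BLOCK_GAP_BP
        for k in range(size):
            chroms[j] = str(c)
            pos[j] = start + k * VARIANT_SPACING_BP
            j += 1

    pair_idx = rng.integers(0, len(_NONAMBIG_PAIRS), size=m)
    alleles = np.array([_NONAMBIG_PAIRS[i] for i in pair_idx], dtype=object)
    n_ambig = int(round(cfg.ambiguous_frac * m))
    if n_ambig:
        amb = rng.choice(m, size=n_ambig, replace=False)
        amb_idx = rng.integers(0, len(_AMBIG_PAIRS), size=n_ambig)
        alleles[amb] = [_AMBIG_PAIRS[i] for i in amb_idx]

    a, b = cfg.info_beta
    info = rng.beta(a, b, size=m)

    variant_meta = pd.DataFrame({
        "id": [f"rs{j + 1}" for j in range(m)],
        "chrom": chroms.astype(str),
        "pos": pos,
        "alleleA": [p[0] for p in alleles],
        "alleleB": [p[1] for p in alleles],
        "info": info,
    })[VARIANT_META_COLUMNS]

    sex = np.where(rng.random(n) < 0.65, "M", "F")
    age = np.clip(np.rint(rng.normal(67, 10, size=n)), 40, 95).astype(int)
    sample_meta = pd.DataFrame({
        "id": [f"samp{i + 1:03d}" for i in range(n)],
        "diagnosis": "NA",
        "sex": sex,
        "age": age,
    })
    return GenotypeMatrix(dosage, variant_meta, sample_meta)


# ---------------------------------------------------------------------------
# discovery summary statistics
# ---------------------------------------------------------------------------

def simulate_summary_stats(cfg: SimConfig, genotypes: GenotypeMatrix, *,
                           stream: int = STREAM_SUMSTATS,
                           swap_frac: float = 0.3,
                           strand_flip_frac: float = 0.2) -> pd.DataFrame:
    """Emulate an external discovery GWAS on the same variant panel.

    ``cfg.n_causal`` variants get true per-allele effects with total
    variance ``heritability_liability``; the observed BETA adds noise with
    the standard error implied by ``discovery_n`` unrelated samples, and P
    comes from the Wald statistic.  A fraction of records report the
    effect/other alleles swapped or on the opposite strand, to exercise
    harmonization.  The returned table carries the standard columns
    ``SNP CHR BP A1 A2 BETA P INFO`` plus a ``beta_true`` truth column
    (dropped by :func:`write_summary_stats`).
    """
    if cfg.discovery_n < 2:
        raise ConfigError("discovery_n must be at least 2")
    vm = genotypes.variant_meta
    m = len(vm)
    if cfg.n_causal > m:
        raise ConfigError("n_causal exceeds the variant panel size")
    rng = np.random.default_rng([cfg.seed, stream])

    beta_true = np.zeros(m)
    if cfg.n_causal:
        causal = rng.choice(m, size=cfg.n_causal, replace=False)
        beta_true[causal] = rng.normal(
            0.0, np.sqrt(cfg.heritability_liability / cfg.n_causal), size=cfg.n_causal)

    freq = genotypes.alt_allele_freq()
    freq = np.where(np.isfinite(freq) & (freq > 0) & (freq < 1), freq, 0.5)
    se = 1.0 / np.sqrt(2.0 * freq * (1.0 - freq) * cfg.discovery_n)
    beta_obs = beta_true + rng.normal(0.0, se)
    z = beta_obs / se
    p = np.clip(2.0 * stats.norm.sf(np.abs(z)), 1e-300, 1.0)
    info = rng.beta(*cfg.info_beta, size=m)

    # effect allele is alleleB unless the record is emitted swapped and/or
    # on the opposite strand
    a1 = vm["alleleB"].to_numpy(dtype=object).copy()
    a2 = vm["alleleA"].to_numpy(dtype=object).copy()
    beta_rep = beta_obs.copy()
    swap = rng.random(m) < swap_frac
    a1[swap], a2[swap] = a2[swap].copy(), a1[swap].copy()
    beta_rep[swap] *= -1.0
    comp = {"A": "T", "T": "A", "C": "G", "G": "C"}
    flip = rng.random(m) < strand_flip_frac
    for j in np.flatnonzero(flip):
        a1[j] = comp[a1[j]]
        a2[j] = comp[a2[j]]

    return pd.DataFrame({
        "SNP": vm["id"].to_numpy(),
        "CHR": vm["chrom"].to_numpy(),
        "BP": vm["pos"].to_numpy(),
        "A1": a1,
        "A2": a2,
        "BETA": beta_rep,
        "P": p,
        "INFO": info,
        "beta_true": beta_true,
    })


def write_summary_stats(stats_df: pd.DataFrame, path) -> None:
    cols = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "P", "INFO"]
    stats_df[cols].to_csv(path, sep="\t", index=False)


def read_summary_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    missing = [c for c in ["SNP", "CHR", "BP", "A1", "A2", "BETA", "P"] if c not in df.columns]
    if missing:
        raise ValidationError(f"summary-stat table missing columns {missing}")
    return df


def true_polygenic_score(genotypes: GenotypeMatrix, stats_df: pd.DataFrame) -> pd.Series:
    """Per-sample score under the *true* effects (truth column), mean-imputed."""
    beta = stats_df.set_index("SNP")["beta_true"].reindex(
        genotypes.variant_meta["id"]).fillna(0.0).to_numpy()
    dose = genotypes.dosage
    col_mean = np.nanmean(np.where(np.isnan(dose), np.nan, dose), axis=0)
    filled = np.where(np.isnan(dose), col_mean, dose)
    return pd.Series(filled @ beta, index=genotypes.sample_meta["id"].to_numpy())


# ---------------------------------------------------------------------------
# clinical records
# ---------------------------------------------------------------------------

def _normal_scores(x: np.ndarray) -> np.ndarray:
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf(ranks / (len(x) + 1.0))


def simulate_clinical(cfg: SimConfig, true_score: pd.Series,
                      ) -> tuple[pd.Series, pd.DataFrame]:
    """Assign diagnoses and build antemortem clinical records.

    Case/control labels come from a liability threshold: liability is
    ``sqrt(h2) * z(true_score) + sqrt(1 - h2) * noise`` and the top
    ``cfg.n_cases`` samples are cases.  For ``cfg.n_clinical`` cases, a
    latent responsiveness variable is drawn from a Gaussian copula whose
    rank correlation with the true score targets ``cfg.prs_ars_rho``; the
    positive-subscale DIBS timeline is then back-solved (integer scores,
    CP-eq perturbed on ties) so the resulting ARS-PS reproduces the
    latent's ranks exactly.  Negative and general-psychopathology
    subscales get independent latents, mirroring the null behaviour
    expected of them.

    Returns ``(diagnosis labels per sample, clinical table)``.
    """
    if not (-1.0 < cfg.prs_ars_rho < 1.0):
        raise ConfigError("prs_ars_rho must lie strictly inside (-1, 1)")
    rng = np.random.default_rng([cfg.seed, STREAM_CLINICAL])
    score = np.asarray(true_score, dtype=float)
    ids = np.asarray(true_score.index)
    n_all = score.size
    if n_all < cfg.n_cases:
        raise ValidationError("need one true_score per sample, at least n_cases of them")

    h2 = cfg.heritability_liability
    z = _normal_scores(score)
    liability = np.sqrt(h2) * z + np.sqrt(1.0 - h2) * rng.standard_normal(n_all)
    case_idx = np.argsort(liability)[::-1][: cfg.n_cases]
    diagnosis = pd.Series("CTL", index=ids, name="diagnosis")
    diagnosis.iloc[case_idx] = "SCZ"

    clin_idx = rng.choice(case_idx, size=cfg.n_clinical, replace=False)
    clin_idx = np.sort(clin_idx)
    n = cfg.n_clinical
    if n == 0:
        return diagnosis, pd.DataFrame(columns=[
            "id", "sex", "age", "doi", "cpeq_3mo",
            "dibs_pos_max", "dibs_pos_3mo", "dibs_neg_max", "dibs_neg_3mo",
            "dibs_gen_max", "dibs_gen_3mo"])

    zs = _normal_scores(score[clin_idx])
    rho_g = 2.0 * np.sin(np.pi * cfg.prs_ars_rho / 6.0)  # Spearman -> copula Pearson
    latent_pos = rho_g * zs + np.sqrt(1.0 - rho_g ** 2) * rng.standard_normal(n)
    latent_neg = rng.standard_normal(n)
    latent_gen = rng.standard_normal(n)

    s_max = {
        "pos": 1 + rng.poisson(8.0, size=n),
        "neg": 1 + rng.poisson(2.5, size=n),
        "gen": 1 + rng.poisson(2.2, size=n),
    }
    cpeq = rng.lognormal(mean=np.log(450.0), sigma=0.9, size=n)

    # back-solve the positive subscale so ARS-PS ranks == latent_pos ranks;
    # ties are broken by nudging CP-eq downward (raising the ARS)
    order = np.argsort(latent_pos)
    u = (np.arange(1, n + 1)) / (n + 1.0)
    s_pre = {k: np.empty(n, dtype=int) for k in s_max}
    prev = -np.inf
    for rank_pos, i in enumerate(order):
        smax = s_max["pos"][i]
        k = int(np.clip(np.rint(u[rank_pos] * smax), 0, smax))
        if k == 0 and prev >= 0.0:
            k = 1
        cr = k / smax
        ars = cr / cpeq[i]
        if cr > 0 and ars <= prev:
            cpeq[i] = cr / (prev * 1.05)
            ars = cr / cpeq[i]
        s_pre["pos"][i] = smax - k
        prev = max(prev, ars)

    for name, latent in (("neg", latent_neg), ("gen", latent_gen)):
        ranks = stats.rankdata(latent) / (n + 1.0)
        k = np.clip(np.rint(ranks * s_max[name]), 0, s_max[name]).astype(int)
        s_pre[name] = s_max[name] - k

    sex = np.where(rng.random(n) < 0.68, "M", "F")
    age = np.clip(np.rint(rng.normal(67, 10, size=n)), 40, 95).astype(int)
    doi = np.clip(np.rint(rng.normal(41, 8, size=n)), 5, 70).astype(int)
    clinical = pd.DataFrame({
        "id": ids[clin_idx],
        "sex": sex,
        "age": age,
        "doi": doi,
        "cpeq_3mo": cpeq,
        "dibs_pos_max": s_max["pos"], "dibs_pos_3mo": s_pre["pos"],
        "dibs_neg_max": s_max["neg"], "dibs_neg_3mo": s_pre["neg"],
        "dibs_gen_max": s_max["gen"], "dibs_gen_3mo": s_pre["gen"],
    })
    return diagnosis, clinical


# ---------------------------------------------------------------------------
# RNA-seq counts
# ---------------------------------------------------------------------------

def simulate_counts(cfg: SimConfig, group_labels: pd.Series,
                    ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Negative-binomial bulk counts with planted between-group effects.

    ``group_labels`` maps sample id -> 'high' / 'low'.  Gene-wise
    dispersions come from a scaled inverse-chi-square prior
    (``dispersion_shape * df / chi2(df)``), library sizes are log-normal,
    and ``cfg.n_de_genes`` autosomal genes receive log2 fold changes
    drawn N(0, ``lfc_sd``) (magnitudes floored at ``lfc_min`` when set,
    preserving sign).  A ``nonautosomal_gene_frac`` of genes is placed on
    chrX/chrY to exercise the autosome filter.

    Returns ``(counts genes x samples, gene_meta, truth)`` where truth
    records ``is_de`` and the planted ``lfc`` per gene.
    """
    cfg.validate()
    labels = pd.Series(group_labels)
    if set(labels.unique()) - {"high", "low"}:
        raise ValidationError("group labels must be 'high' or 'low'")
    if (labels == "high").sum() < 2 or (labels == "low").sum() < 2:
        raise ValidationError("need at least 2 samples per group")
    rng = np.random.default_rng([cfg.seed, STREAM_COUNTS])
    G, S = cfg.n_genes, len(labels)

    gene_ids = np.array([f"gene{g + 1:05d}" for g in range(G)], dtype=object)
    chrom = rng.integers(1, 23, size=G).astype(str).astype(object)
    n_nonauto = int(round(cfg.nonautosomal_gene_frac * G))
    if n_nonauto:
        na_idx = rng.choice(G, size=n_nonauto, replace=False)
        chrom[na_idx] = rng.choice(["X", "Y"], size=n_nonauto)
    autosomal = np.array([c.isdigit() for c in chrom])

    log_q = rng.normal(0.0, 1.5, size=G)
    q = np.exp(log_q)
    q /= q.sum()
    lib = rng.lognormal(np.log(cfg.mean_libsize), cfg.libsize_log_sd, size=S)

    lfc = np.zeros(G)
    is_de = np.zeros(G, dtype=bool)
    if cfg.n_de_genes:
        candidates = np.flatnonzero(autosomal)
        if candidates.size < cfg.n_de_genes:
            raise ConfigError("not enough autosomal genes to plant DE effects")
        de_idx = rng.choice(candidates, size=cfg.n_de_genes, replace=False)
        raw = rng.normal(0.0, cfg.lfc_sd, size=cfg.n_de_genes)
        if cfg.lfc_min > 0:
            sign = np.where(raw >= 0, 1.0, -1.0)
            raw = sign * np.maximum(np.abs(raw), cfg.lfc_min)
        lfc[de_idx] = raw
        is_de[de_idx] = True

    x = (labels == "high").to_numpy().astype(float)
    mu = q[:, None] * lib[None, :] * np.exp2(lfc[:, None] * x[None, :])
    phi = cfg.dispersion_shape * cfg.dispersion_df / rng.chisquare(cfg.dispersion_df, size=G)
    n_param = 1.0 / np.maximum(phi, 1e-12)
    counts = rng.negative_binomial(n_param[:, None], n_param[:, None] / (n_param[:, None] + mu))

    counts_df = pd.DataFrame(counts, index=gene_ids, columns=labels.index)
    gene_meta = pd.DataFrame({"id": gene_ids, "chrom": chrom.astype(str)})
    truth = pd.DataFrame({"id": gene_ids, "is_de": is_de, "lfc": lfc,
                          "dispersion": phi})
    return counts_df, gene_meta, truth


# ---------------------------------------------------------------------------
# whole-cohort convenience bundle
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Everything the pipeline consumes, generated from one config."""

    genotypes: GenotypeMatrix
    sumstats_adhd: pd.DataFrame
    sumstats_asd: pd.DataFrame
    clinical: pd.DataFrame
    true_score_adhd: pd.Series
    true_score_asd: pd.Series


def simulate_cohort(cfg: SimConfig) -> SyntheticCohort:
    """Generate genotypes, two discovery GWAS, diagnoses and clinical records.

    The schizophrenia liability (hence the case/control labels) and the
    ARS copula are tied to the first (ADHD-like) true score; the second
    (ASD-like) discovery GWAS shares the panel but has independent causal
    effects.
    """
    g = simulate_genotypes(cfg)
    ss_adhd = simulate_summary_stats(cfg, g, stream=STREAM_SUMSTATS)
    ss_asd = simulate_summary_stats(cfg, g, stream=STREAM_SUMSTATS_2)
    score_adhd = true_polygenic_score(g, ss_adhd)
    score_asd = true_polygenic_score(g, ss_asd)
    diagnosis, clinical = simulate_clinical(cfg, score_adhd)
    sm = g.sample_meta.copy()
    sm["diagnosis"] = diagnosis.to_numpy()
    g = GenotypeMatrix(g.dosage, g.variant_meta, sm)
    return SyntheticCohort(g, ss_adhd, ss_asd, clinical, score_adhd, score_asd)
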