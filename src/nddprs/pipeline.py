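"""End-to-end orchestration: simulate -> QC -> PRS -> ARS -> association
statistics -> differential expression -> over-representation, with one
seeded config, per-stage logging and a machine-readable run manifest.

Every stage writes its table to the output directory in the same
plain-text formats the stage command-line tools read, so any stage can
be re-run standalone on a previous run's outputs.
"""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .ars import build_ars_table
from .config import RunConfig
from .dge import run_dge, volcano_table
from .enrich import ora_all, rank_pathways, write_gmt
from .genio import filter_samples, filter_variants, write_dosage_tsv, write_vcf
from .prs import compute_prs
from .simulate import simulate_cohort, simulate_counts, write_summary_stats
from .stats import demographics_table, median_split, run_association_battery

log = logging.getLogger("nddprs")


@dataclass
class RunReport:
    """Everything a run produced, plus the manifest written to disk."""

    manifest: dict
    correlations: pd.DataFrame
    demographics: pd.DataFrame
    deg_table: pd.DataFrame
    enrichment: pd.DataFrame
    prs_results: dict = field(default_factory=dict)
    groups: pd.Series | None = None


def _toy_gene_sets(gene_ids: list[str], truth: pd.DataFrame,
                   seed: int) -> dict[str, list[str]]:
    """Gene sets for the enrichment stage: two sets enriched in the planted
    DE genes plus random background sets of matched sizes."""
    rng = np.random.default_rng([seed, 97])
    de = truth.loc[truth["is_de"], "id"].tolist()
    pool = list(gene_ids)
    sets: dict[str, list[str]] = {}
    for i, frac in enumerate((0.7, 0.5), start=1):
        n_set = min(60, max(10, len(de) // 4))
        n_de = int(frac * n_set)
        de_part = list(rng.choice(de, size=min(n_de, len(de)), replace=False))
        bg_part = list(rng.choice(pool, size=n_set - len(de_part), replace=False))
        sets[f"planted_set_{i}"] = de_part + bg_part
    for i in range(1, 19):
        size = int(rng.integers(15, 80))
        sets[f"random_set_{i:02d}"] = list(rng.choice(pool, size=size, replace=False))
    return sets


def run_all(config: RunConfig) -> RunReport:
    """Execute the full workflow under one config and seed.

    Stages run in their fixed order; a failure in any stage is re-raised
    with the stage name attached.  Outputs and a JSON manifest land in
    ``config.out_dir``.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    cfg = config.sim.replace(seed=config.seed)
    manifest: dict = {
        "package_version": __version__,
        "python": platform.python_version(),
        "seed": config.seed,
        "parameters": config.to_dict(),
        "stages": {},
    }
    stage = "simulate"
    try:
        cohort = simulate_cohort(cfg)
        write_vcf(cohort.genotypes, out / "genotypes.vcf")
        write_dosage_tsv(cohort.genotypes, out / "genotypes_dosage.tsv")
        write_summary_stats(cohort.sumstats_adhd, out / "sumstats_adhd.tsv")
        write_summary_stats(cohort.sumstats_asd, out / "sumstats_asd.tsv")
        cohort.clinical.to_csv(out / "clinical.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_samples": cohort.genotypes.n_samples,
            "n_variants": cohort.genotypes.n_variants,
            "n_clinical": len(cohort.clinical),
        }
        log.info("simulate: %d samples x %d variants",
                 cohort.genotypes.n_samples, cohort.genotypes.n_variants)

        stage = "qc"
        g, vrep = filter_variants(cohort.genotypes,
                                  call_rate=config.variant_call_rate,
                                  maf_min=config.maf_min,
                                  hwe_p_min=config.hwe_p_min,
                                  hwe_mode=config.hwe_mode)
        g, srep = filter_samples(g, call_rate=config.sample_call_rate,
                                 relatedness_max=config.relatedness_max)
        qc_frame = pd.concat([vrep.to_frame().assign(level="variant"),
                              srep.to_frame().assign(level="sample")])
        qc_frame.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "variants_retained": g.n_variants,
            "samples_retained": g.n_samples,
            "steps": qc_frame.to_dict("records"),
        }
        log.info("qc: %d variants, %d samples retained", g.n_variants, g.n_samples)

        stage = "prs"
        prs_results = {}
        for name, ss in (("ADHD", cohort.sumstats_adhd), ("ASD", cohort.sumstats_asd)):
            res = compute_prs(ss, g, thresholds=config.p_thresholds,
                              info_min=config.info_min,
                              r2_thresh=config.clump_r2,
                              window_bp=config.clump_window_bp)
            res.scores.to_csv(out / f"prs_{name.lower()}_scores.tsv",
                              sep="\t", index=False)
            res.r2_by_threshold.to_csv(out / f"prs_{name.lower()}_thresholds.tsv",
                                       sep="\t", index=False)
            prs_results[name] = res
            manifest["stages"].setdefault(stage, {})[name] = {
                "best_threshold": res.best_threshold,
                "harmonization": res.harmonization_report,
                "r2_by_threshold": res.r2_by_threshold.to_dict("records"),
            }
            log.info("prs %s: best threshold %s", name, res.best_threshold)

        stage = "ars"
        ars_table = build_ars_table(cohort.clinical)
        ars_table.to_csv(out / "ars.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {"n_evaluable": ars_table.attrs["n_evaluable"]}

        stage = "assoc"
        clin_ids = cohort.clinical["id"].tolist()
        best = {name: res.best_scores().reindex(clin_ids)
                for name, res in prs_results.items()}
        correlations = run_association_battery(best, ars_table, cohort.clinical,
                                               family=config.bh_family)
        correlations.to_csv(out / "correlations.tsv", sep="\t", index=False)
        groups = median_split(best["ADHD"])
        demo = demographics_table(cohort.clinical, groups)
        demo.to_csv(out / "demographics.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_correlations": int(correlations["p"].notna().sum()),
            "median_split": groups.value_counts().to_dict(),
        }
        log.info("assoc: median split %s", groups.value_counts().to_dict())

        stage = "dge"
        counts, gene_meta, truth = simulate_counts(cfg, groups)
        counts.to_csv(out / "counts.tsv", sep="\t")
        gene_meta.to_csv(out / "gene_annotation.tsv", sep="\t", index=False)
        truth.to_csv(out / "counts_truth.tsv", sep="\t", index=False)
        samples = cohort.clinical[["id", "sex", "age"]].copy()
        samples["group"] = groups.reindex(samples["id"]).to_numpy()
        deg = run_dge(counts, gene_meta, samples, cpm_min=config.cpm_min,
                      prior_df=config.dispersion_prior_df,
                      alpha=config.deg_alpha)
        deg.to_csv(out / "deg.tsv", sep="\t", index=False)
        volcano_table(deg).to_csv(out / "volcano.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_genes_tested": int((~deg["excluded"]).sum()),
            "n_deg_nominal": int(deg["is_deg"].sum()),
            "n_deg_fdr": int((deg["fdr"] < config.deg_alpha).sum()),
        }
        log.info("dge: %d nominal DEGs", int(deg["is_deg"].sum()))

        stage = "enrich"
        universe = deg.loc[~deg["excluded"], "gene"].tolist()
        gene_sets = _toy_gene_sets(universe, truth, config.seed)
        write_gmt(gene_sets, out / "gene_sets.gmt")
        deg_ids = deg.loc[deg["is_deg"], "gene"].tolist()
        enrichment = ora_all(deg_ids, gene_sets, universe)
        enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
        top = rank_pathways(enrichment)
        top.to_csv(out / "enrichment_top.tsv", sep="\t", index=False)
        manifest["stages"][stage] = {
            "n_sets": len(gene_sets),
            "top_pathway": top["pathway"].iloc[0] if len(top) else None,
        }
    except Exception as err:
        raise type(err)(f"[stage {stage}] {err}") from err

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str, sort_keys=True)
    _write_report(out / "report.txt", manifest, correlations, demo, deg, top)
    return RunReport(manifest, correlations, demo, deg, enrichment,
                     prs_results, groups)


def _write_report(path: Path, manifest: dict, correlations: pd.DataFrame,
                  demo: pd.DataFrame, deg: pd.DataFrame,
                  top: pd.DataFrame) -> None:
    with open(path, "w") as fh:
        fh.write("nddprs run report\n=================\n\n")
        fh.write(f"seed: {manifest['seed']}\n\n")
        fh.write("PRS ~ clinical correlations\n")
        fh.write(correlations.to_string(index=False) + "\n\n")
        fh.write("Subgroup demographics\n")
        fh.write(demo.to_string(index=False) + "\n\n")
        fh.write(f"DEGs (nominal): {int(deg['is_deg'].sum())}; "
                 f"FDR-significant: {int((deg['fdr'] < 0.05).sum())}\n\n")
        fh.write("Top pathways\n")
        fh.write(top.to_string(index=False) + "\n")
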