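"""Negative-binomial GLM differential expression: normalization, fitting,
dispersion estimation and the likelihood-ratio test.

The TMM factors and the fixed-dispersion GLM/LRT are additionally
cross-checked against the reference R implementation (edgeR) on a small
fixture, keeping the two routes independent.
"""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest

from nddprs.config import SimConfig
from nddprs.dge import (build_design, estimate_dispersions, filter_genes,
                        fit_gene, fit_genes, lrt_test, run_dge, tmm_factors,
                        volcano_table)
from nddprs.errors import ValidationError
from nddprs.simulate import simulate_counts


def _counts_fixture(n_genes=120, n_de=20, seed=4, lfc_sd=1.0, n=12):
    cfg = SimConfig(n_genes=n_genes, n_de_genes=n_de, lfc_sd=lfc_sd,
                    nonautosomal_gene_frac=0.0, seed=seed)
    ids = [f"p{i:02d}" for i in range(n)]
    groups = pd.Series(["high"] * (n // 2) + ["low"] * (n - n // 2), index=ids)
    counts, gm, truth = simulate_counts(cfg, groups)
    rng = np.random.default_rng(seed + 1)
    samples = pd.DataFrame({"id": ids, "group": groups.to_numpy(),
                            "sex": rng.choice(["M", "F"], n),
                            "age": rng.integers(40, 80, n)})
    return counts, gm, truth, samples


class TestFilterGenes:
    def test_sex_chromosome_and_allzero_genes_removed(self, nineteen_samples):
        cfg = SimConfig(n_genes=100, n_de_genes=0, nonautosomal_gene_frac=0.2,
                        seed=2)
        groups = nineteen_samples.set_index("id")["group"]
        counts, gm, _ = simulate_counts(cfg, groups)
        counts.iloc[5] = 0  # force one all-zero autosomal gene
        kept = filter_genes(counts, gm, groups)
        kept_chrom = gm.set_index("id").loc[kept.index, "chrom"]
        assert kept_chrom.str.isdigit().all()
        assert counts.index[5] not in kept.index

    def test_high_count_gene_retained(self, nineteen_samples):
        groups = nineteen_samples.set_index("id")["group"]
        counts = pd.DataFrame(
            np.full((3, 19), 500), columns=nineteen_samples["id"],
            index=["g1", "g2", "g3"])
        gm = pd.DataFrame({"id": ["g1", "g2", "g3"], "chrom": ["1", "2", "3"]})
        kept = filter_genes(counts, gm, groups)
        assert len(kept) == 3


class TestTMM:
    def test_identical_columns_give_unit_factors(self):
        y = np.tile(np.arange(1, 101)[:, None], (1, 4))
        np.testing.assert_allclose(tmm_factors(y), np.ones(4), atol=1e-12)

    def test_pure_depth_change_absorbed_by_library_size(self):
        rng = np.random.default_rng(0)
        base = rng.poisson(50, size=(500, 1)).astype(float) + 1
        y = np.hstack([base, base * 2, base, base])
        f = tmm_factors(y)
        np.testing.assert_allclose(f, np.ones(4), atol=1e-6)

    def test_asymmetric_de_shifts_factors_compensatingly(self):
        rng = np.random.default_rng(1)
        base = rng.poisson(100, size=(1000, 2)).astype(float) + 1
        shifted = base.copy()
        shifted[:200, 1] *= 8  # 20% of genes strongly up in sample 2
        f = tmm_factors(shifted)
        # the up-shifted sample's non-DE genes look depressed after
        # library-size scaling, so its factor drops below the other's
        assert f[1] < 1.0 < f[0]

    def test_matches_edgeR_reference(self, tmp_path):
        counts, *_ = _counts_fixture(seed=7)
        mine = tmm_factors(counts)
        counts.to_csv(tmp_path / "c.tsv", sep="\t")
        out = subprocess.run(
            ["Rscript", "-e",
             'suppressMessages(library(edgeR));'
             f'x <- as.matrix(read.delim("{tmp_path}/c.tsv", row.names=1));'
             'cat(paste(calcNormFactors(x, method="TMM"), collapse=","))'],
            capture_output=True, text=True, timeout=120)
        assert out.returncode == 0, out.stderr
        ref = np.array([float(v) for v in out.stdout.strip().split(",")])
        np.testing.assert_allclose(mine, ref, atol=1e-10)

    def test_zero_total_sample_rejected(self):
        y = np.ones((10, 3))
        y[:, 1] = 0
        with pytest.raises(ValidationError):
            tmm_factors(y)


class TestFit:
    def test_poisson_limit_matches_poisson_glm(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(3)
        n = 16
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n)])
        offset = np.log(rng.uniform(0.8e6, 1.2e6, n))
        y = rng.poisson(np.exp(0.5 * X[:, 1] + offset - 10)).astype(float)
        beta, ll = fit_gene(y, X, offset, phi=0.0)
        ref = sm.GLM(y, X, family=sm.families.Poisson(), offset=offset).fit()
        np.testing.assert_allclose(beta, ref.params, atol=1e-6)

    def test_matches_statsmodels_nb_glm(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(5)
        n = 19
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n),
                             rng.integers(0, 2, n)])
        offset = np.full(n, 10.0)
        mu = np.exp(X @ np.array([-4.0, 1.0, -0.5]) + offset)
        phi = 0.2
        y = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu)).astype(float)
        beta, ll = fit_gene(y, X, offset, phi)
        ref = sm.GLM(y, X, family=sm.families.NegativeBinomial(alpha=phi),
                     offset=offset).fit()
        np.testing.assert_allclose(beta, ref.params, atol=1e-5)
        assert ll == pytest.approx(ref.llf, abs=1e-4)

    def test_intercept_only_closed_form(self):
        y = np.full(10, 36.0)
        X = np.ones((10, 1))
        offset = np.full(10, 2.0)
        beta, _ = fit_gene(y, X, offset, phi=0.1)
        assert beta[0] == pytest.approx(np.log(36.0) - 2.0, abs=1e-8)

    def test_lfc_recovery_on_deep_counts(self):
        rng = np.random.default_rng(6)
        n = 40
        X = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], n // 2)])
        offset = np.zeros(n)
        mu = np.exp(5.0 + np.log(2.0) * X[:, 1])  # LFC of 1 on the log2 scale
        phi = 0.05
        y = rng.negative_binomial(1 / phi, 1 / (1 + phi * mu)).astype(float)
        beta, _ = fit_gene(y, X, offset, phi)
        assert beta[1] / np.log(2) == pytest.approx(1.0, abs=0.1)

    def test_matches_edgeR_glmfit_fixed_dispersion(self, tmp_path):
        counts, gm, truth, samples = _counts_fixture(seed=9)
        full, reduced, names = build_design(samples)
        offset = np.log(counts.sum(axis=0).to_numpy(float))
        Y = counts.to_numpy(float)
        bf, llf, _, _ = fit_genes(Y, full, offset, 0.1)
        br, llr, _, _ = fit_genes(Y, reduced, offset, 0.1)
        stat, p, _ = lrt_test(llf, llr)
        counts.to_csv(tmp_path / "c.tsv", sep="\t")
        pd.DataFrame(full, columns=names).to_csv(tmp_path / "X.tsv", sep="\t",
                                                 index=False)
        r = subprocess.run(["Rscript", "-e", f'''
suppressMessages(library(edgeR))
x <- as.matrix(read.delim("{tmp_path}/c.tsv", row.names=1))
X <- as.matrix(read.delim("{tmp_path}/X.tsv"))
fit <- glmFit(x, design=X, dispersion=0.1, offset=log(colSums(x)), prior.count=0)
lrt <- glmLRT(fit, coef=ncol(X))
write.table(cbind(coef(fit)[,ncol(X)], lrt$table$LR),
            "{tmp_path}/ref.tsv", sep="\\t", col.names=FALSE)
'''], capture_output=True, text=True, timeout=120)
        assert r.returncode == 0, r.stderr
        ref = pd.read_csv(tmp_path / "ref.tsv", sep="\t", header=None,
                          index_col=0)
        np.testing.assert_allclose(bf[:, -1], ref[1].to_numpy(), atol=1e-3)
        np.testing.assert_allclose(stat, ref[2].to_numpy(), atol=1e-4)


class TestDispersions:
    def test_poisson_data_gives_small_common_dispersion(self, rng):
        n = 19
        X = np.column_stack([np.ones(n), rng.integers(0, 2, n)])
        offset = np.zeros(n)
        mu = np.exp(rng.uniform(2, 6, size=(400, 1)))
        Y = rng.poisson(np.broadcast_to(mu, (400, n))).astype(float)
        est = estimate_dispersions(Y, X, offset)
        assert est.common <= 0.05

    def test_recovers_planted_common_dispersion(self, rng):
        n = 19
        X = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], [9, 10])])
        offset = np.zeros(n)
        phi = 0.4
        mu = np.exp(rng.uniform(3, 7, size=(2000, 1)))
        Y = rng.negative_binomial(1 / phi,
                                  1 / (1 + phi * np.broadcast_to(mu, (2000, n)))
                                  ).astype(float)
        est = estimate_dispersions(Y, X, offset)
        assert 0.3 <= est.common <= 0.5
        assert abs(np.median(est.genewise) - phi) < 0.15

    def test_single_gene_fully_shrunk_to_common(self, rng):
        n = 12
        X = np.ones((n, 1))
        Y = rng.poisson(50, size=(1, n)).astype(float)
        est = estimate_dispersions(Y, X, np.zeros(n))
        assert est.genewise[0] == pytest.approx(est.common)


class TestLRTAndTable:
    def test_null_gene_has_unit_p(self):
        stat, p, bad = lrt_test(np.array([-100.0]), np.array([-100.0]))
        assert p[0] == pytest.approx(1.0) and not bad[0]

    def test_llfull_below_llreduced_flagged(self):
        stat, p, bad = lrt_test(np.array([-101.0]), np.array([-100.0]))
        assert bad[0]

    def test_label_swap_negates_lfc_keeps_p(self):
        counts, gm, truth, samples = _counts_fixture(seed=11)
        a = run_dge(counts, gm, samples)
        flipped = samples.copy()
        flipped["group"] = np.where(flipped["group"] == "high", "low", "high")
        b = run_dge(counts, gm, flipped)
        merged = a.set_index("gene").join(b.set_index("gene"), rsuffix="_b")
        np.testing.assert_allclose(merged["log2_fc"], -merged["log2_fc_b"],
                                   atol=1e-5)
        np.testing.assert_allclose(merged["p"], merged["p_b"], atol=1e-6)

    def test_dominant_planted_gene_ranks_first(self, nineteen_samples):
        cfg = SimConfig(n_genes=200, n_de_genes=1, lfc_sd=0.1, lfc_min=3.0,
                        dispersion_shape=0.02, nonautosomal_gene_frac=0.0,
                        seed=21)
        groups = nineteen_samples.set_index("id")["group"]
        counts, gm, truth = simulate_counts(cfg, groups)
        out = run_dge(counts, gm, nineteen_samples)
        planted = truth.loc[truth["is_de"], "id"].iloc[0]
        assert out["gene"].iloc[0] == planted

    def test_volcano_pass_through(self):
        counts, gm, truth, samples = _counts_fixture(seed=13)
        deg = run_dge(counts, gm, samples)
        v = volcano_table(deg)
        assert len(v) == len(deg)
        assert (v["is_deg"] == (deg["p"] < 0.05).fillna(False).to_numpy()).all()
        empty = volcano_table(deg.iloc[:0])
        assert empty.empty

    def test_design_collinear_group_rejected(self):
        samples = pd.DataFrame({
            "id": ["a", "b", "c", "d"],
            "group": ["high", "high", "low", "low"],
            "sex": ["M", "M", "F", "F"],  # sex == group here
            "age": [50, 50, 50, 50],
        })
        # sex column enters first, leaving group collinear with it
        with pytest.raises(ValidationError):
            build_design(samples)
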