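"""Generator self-consistency: LD, MAF, heritability, effect sharing,
trait/GWAS structure, and determinism."""

import dataclasses

import numpy as np
import pytest
from scipy import stats

from omixwas import (SimConfig, simulate_covariates, simulate_genotypes,
                     simulate_omics, simulate_trait_and_gwas)
from omixwas.simulate import PROTEIN_LAYER, expression_layer, _Law


def _adjacent_corrs(variants, dosages):
    out = []
    for g in variants.gene_id.unique():
        ids = variants.loc[variants.gene_id == g, "variant_id"].tolist()
        X = dosages[ids].to_numpy()
        out.extend(np.corrcoef(X[:, i], X[:, i + 1])[0, 1]
                   for i in range(len(ids) - 1))
    return np.array(out)


class TestGenotypes:
    def test_independent_variants_when_ld_zero(self):
        cfg = SimConfig(n_train_samples=10_000, n_genes=3,
                        n_variants_per_gene=15, ld_decay=0.0, seed=1)
        variants, dosages = simulate_genotypes(cfg)
        X = dosages.to_numpy()
        C = np.corrcoef(X, rowvar=False)
        off = np.abs(C[np.triu_indices_from(C, 1)])
        assert off.mean() < 0.05

    def test_adjacent_correlation_matches_ld_decay(self):
        cfg = SimConfig(n_train_samples=10_000, n_genes=4,
                        n_variants_per_gene=15, ld_decay=0.9, seed=2)
        variants, dosages = simulate_genotypes(cfg)
        corrs = _adjacent_corrs(variants, dosages)
        assert abs(corrs.mean() - 0.9) < 0.05

    def test_realized_maf_within_range(self):
        cfg = SimConfig(n_train_samples=8000, n_genes=4,
                        n_variants_per_gene=10, maf_range=(0.1, 0.4), seed=3)
        variants, dosages = simulate_genotypes(cfg)
        af = dosages.to_numpy().mean(axis=0) / 2
        maf = np.minimum(af, 1 - af)
        assert np.all(maf > 0.05) and np.all(maf < 0.45)
        assert np.abs(maf - variants.maf.to_numpy()).max() < 0.05

    def test_dosages_bounded_and_positions_in_window(self):
        cfg = SimConfig(n_train_samples=100, n_genes=5,
                        n_variants_per_gene=8, seed=4)
        variants, dosages = simulate_genotypes(cfg)
        assert dosages.to_numpy().min() >= 0
        assert dosages.to_numpy().max() <= 2
        from omixwas import gene_annotations
        anno = gene_annotations(cfg).set_index("gene_id")
        for rec in variants.itertuples(index=False):
            g = anno.loc[rec.gene_id]
            assert g.body_start - cfg.cis_flank <= rec.pos
            assert rec.pos <= g.body_end + cfg.cis_flank

    def test_deterministic_under_fixed_seed(self):
        cfg = SimConfig(n_train_samples=200, n_genes=3,
                        n_variants_per_gene=6, seed=5)
        a = simulate_genotypes(cfg)
        b = simulate_genotypes(cfg)
        assert a[0].equals(b[0]) and a[1].equals(b[1])

    def test_independent_cohorts_differ(self):
        cfg = SimConfig(n_train_samples=200, n_genes=2,
                        n_variants_per_gene=6, seed=5)
        va, da = simulate_genotypes(cfg, cohort=0)
        vb, db_ = simulate_genotypes(cfg, cohort=1)
        assert va[["variant_id", "maf"]].equals(vb[["variant_id", "maf"]])
        assert not np.array_equal(da.to_numpy(), db_.to_numpy())

    @pytest.mark.parametrize("kwargs", [
        {"n_variants_per_gene": 0}, {"maf_range": (0.0, 0.5)},
        {"maf_range": (0.1, 0.6)}, {"ld_decay": 1.0}, {"cis_h2": 1.0},
        {"n_causal_per_gene": 50, "n_variants_per_gene": 10},
        {"cross_layer_effect_corr": 1.5},
    ])
    def test_degenerate_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SimConfig(**kwargs)


class TestOmics:
    def test_cis_h2_target_recovered(self):
        cfg = SimConfig(n_train_samples=900, n_genes=100,
                        n_variants_per_gene=8, cis_h2=0.3, seed=6)
        variants, dosages = simulate_genotypes(cfg)
        cov = simulate_covariates(cfg, dosages.index)
        omics, truth = simulate_omics(cfg, variants, dosages, cov)
        r2 = []
        for g in variants.gene_id.unique():
            m = dosages[truth.causal_ids[g]].to_numpy() \
                @ truth.effects[PROTEIN_LAYER][g]
            y = omics[PROTEIN_LAYER][g].to_numpy()
            r2.append(np.corrcoef(m, y)[0, 1] ** 2)
        assert abs(np.mean(r2) - 0.3) < 0.05

    def test_null_heritability_gives_genotype_independent_omics(self):
        cfg = SimConfig(n_train_samples=2000, n_genes=20,
                        n_variants_per_gene=6, cis_h2=0.0, seed=7)
        variants, dosages = simulate_genotypes(cfg)
        cov = simulate_covariates(cfg, dosages.index)
        omics, truth = simulate_omics(cfg, variants, dosages, cov)
        cors = []
        for g in variants.gene_id.unique():
            y = omics[PROTEIN_LAYER][g].to_numpy()
            X = dosages[variants.loc[variants.gene_id == g,
                                     "variant_id"]].to_numpy()
            cors.extend(abs(np.corrcoef(X[:, j], y)[0, 1])
                        for j in range(X.shape[1]))
            assert np.all(truth.effects[PROTEIN_LAYER][g] == 0)
        assert np.mean(cors) < 0.05

    def test_perfect_cross_layer_sharing(self):
        cfg = SimConfig(n_train_samples=300, n_genes=10,
                        n_variants_per_gene=6, cross_layer_effect_corr=1.0,
                        n_tissues=2, seed=8)
        variants, dosages = simulate_genotypes(cfg)
        cov = simulate_covariates(cfg, dosages.index)
        _, truth = simulate_omics(cfg, variants, dosages, cov)
        for g in variants.gene_id.unique():
            bp = truth.effects[PROTEIN_LAYER][g]
            bt = truth.effects[expression_layer("T00")][g]
            ratio = bt[bp != 0] / bp[bp != 0]
            assert np.allclose(ratio, ratio[0], atol=1e-10)

    def test_cross_layer_effect_correlation_target(self):
        cfg = SimConfig(n_train_samples=50, n_genes=400,
                        n_variants_per_gene=4, n_causal_per_gene=1,
                        cross_layer_effect_corr=0.5, n_tissues=1, seed=9)
        variants, dosages = simulate_genotypes(cfg)
        cov = simulate_covariates(cfg, dosages.index)
        _, truth = simulate_omics(cfg, variants, dosages, cov)
        # raw (unscaled) effect draws share the target correlation; the
        # per-gene variance scaling preserves sign but not magnitude, so
        # compare the sign-agreement rate with its closed form
        # P(sign match) = 1/2 + arcsin(rho)/pi.
        bp = np.array([truth.effects[PROTEIN_LAYER][g][0]
                       for g in variants.gene_id.unique()])
        bt = np.array([truth.effects[expression_layer("T00")][g][0]
                       for g in variants.gene_id.unique()])
        match = np.mean(np.sign(bp) == np.sign(bt))
        expected = 0.5 + np.arcsin(0.5) / np.pi
        assert abs(match - expected) < 0.08


class TestTraitAndGwas:
    def test_global_null_z_scores_standard_normal(self):
        cfg = SimConfig(n_train_samples=50, n_genes=150,
                        n_variants_per_gene=4, ld_decay=0.3,
                        n_mediated_genes=0, n_gwas_samples=2000, seed=10)
        variants, dosages = simulate_genotypes(cfg)
        cov = simulate_covariates(cfg, dosages.index)
        _, truth = simulate_omics(cfg, variants, dosages, cov)
        _, gwas = simulate_trait_and_gwas(cfg, truth, variants)
        z = (gwas.beta / gwas.se).to_numpy()
        assert abs(z.mean()) < 0.1
        assert abs(z.var() - 1.0) < 0.3

    def test_single_causal_variant_matches_closed_form_power(self):
        # one gene, one causal variant explaining `frac` of trait variance:
        # the expected marginal z is sqrt(frac * n_gwas) (trait variance 1)
        frac, n_gwas = 0.01, 20_000
        zs = []
        for stream in range(6):
            cfg = SimConfig(n_train_samples=50, n_genes=1,
                            n_variants_per_gene=1, n_causal_per_gene=1,
                            n_mediated_genes=1, mediated_var_frac=frac,
                            n_gwas_samples=n_gwas, ld_decay=0.0, seed=12)
            variants, dosages = simulate_genotypes(cfg)
            cov = simulate_covariates(cfg, dosages.index)
            _, truth = simulate_omics(cfg, variants, dosages, cov)
            _, gwas = simulate_trait_and_gwas(cfg, truth, variants,
                                              stream=stream)
            zs.append(abs(float(gwas.beta.iloc[0] / gwas.se.iloc[0])))
        expected = np.sqrt(frac * n_gwas)
        assert abs(np.mean(zs) - expected) < 1.5

    def test_mediated_variance_scaling(self, small_chain):
        truth = small_chain["truth"]
        cfg = small_chain["cfg"]
        dosages = small_chain["dosages"]
        tot = 0.0
        for g in truth.mediated_genes:
            m = dosages[truth.causal_ids[g]].to_numpy() \
                @ truth.effects[PROTEIN_LAYER][g]
            tot += truth.alpha[g] ** 2 * m.var()
        assert tot == pytest.approx(
            cfg.n_mediated_genes * cfg.mediated_var_frac, rel=0.25)

    def test_trait_variance_near_one(self, small_chain):
        t = small_chain["trait"].iloc[:, 1].to_numpy()
        assert abs(t.var() - 1.0) < 0.15

    def test_streams_give_independent_gwas_same_law(self, small_cohort):
        cfg = small_cohort["cfg"]
        _, g1 = simulate_trait_and_gwas(cfg, small_cohort["truth"],
                                        small_cohort["variants"], stream=0)
        _, g2 = simulate_trait_and_gwas(cfg, small_cohort["truth"],
                                        small_cohort["variants"], stream=1)
        assert g1.variant_id.equals(g2.variant_id)
        assert not np.allclose(g1.beta, g2.beta)

    def test_streaming_and_reused_cohort_agree_in_law(self, small_cohort):
        # streaming GWAS regenerates blocks deterministically: two calls
        # with the same stream are bit-identical
        cfg = small_cohort["cfg"]
        _, a = simulate_trait_and_gwas(cfg, small_cohort["truth"],
                                       small_cohort["variants"])
        _, b = simulate_trait_and_gwas(cfg, small_cohort["truth"],
                                       small_cohort["variants"])
        assert a.equals(b)


def test_latent_law_thresholds_match_mafs():
    cfg = SimConfig(n_train_samples=10, n_genes=2, n_variants_per_gene=5,
                    seed=13)
    law = _Law(cfg)
    for g, t in law.thresholds.items():
        mafs = law.variants.loc[law.variants.gene_id == g, "maf"].to_numpy()
        assert np.allclose(stats.norm.sf(t), mafs)
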