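"""Shared fixtures: one small synthetic cohort run end-to-end, reused by
the module test files to keep the suite fast."""

import numpy as np
import pytest

from omixwas import (PROTEIN_LAYER, SimConfig, association_scan,
                     gene_annotations, harmonize_gwas, preprocess_layer,
                     simulate_covariates, simulate_genotypes, simulate_omics,
                     simulate_trait_and_gwas, train_layer)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_train_samples=500, n_genes=15, n_variants_per_gene=12,
                     ld_decay=0.6, cis_h2=0.3, n_causal_per_gene=2,
                     n_mediated_genes=8, mediated_var_frac=0.01,
                     n_gwas_samples=4000, n_tissues=1, seed=11)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    """Simulated genotypes, covariates, omics and truth for a small cohort."""
    variants, dosages = simulate_genotypes(small_cfg)
    anno = gene_annotations(small_cfg)
    cov = simulate_covariates(small_cfg, dosages.index)
    omics, truth = simulate_omics(small_cfg, variants, dosages, cov)
    return {"cfg": small_cfg, "variants": variants, "dosages": dosages,
            "anno": anno, "cov": cov, "omics": omics, "truth": truth}


@pytest.fixture(scope="session")
def small_chain(small_cohort):
    """The small cohort taken through preprocessing, GWAS simulation,
    harmonization, model training and the association scan."""
    c = dict(small_cohort)
    cfg = c["cfg"]
    resid, retained, prep_log = preprocess_layer(
        c["omics"][PROTEIN_LAYER], c["cov"], n_pcs=5, n_surrogates=5)
    trait, gwas = simulate_trait_and_gwas(cfg, c["truth"], c["variants"],
                                          dosages=c["dosages"])
    harm, report = harmonize_gwas(c["variants"], gwas)
    db = train_layer(resid, c["variants"], c["dosages"], c["anno"],
                     PROTEIN_LAYER, gwas_variant_ids=harm.index,
                     seed=cfg.seed)
    results = association_scan(db, {"trait": harm}, c["dosages"],
                               reference_variants=c["variants"])
    c.update({"resid": resid, "retained": retained, "prep_log": prep_log,
              "trait": trait, "gwas": gwas, "harm": harm,
              "harm_report": report, "db": db, "results": results})
    return c


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
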