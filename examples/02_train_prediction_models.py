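"""Preprocess an omic layer and train cis elastic-net prediction models.

Runs inverse normalization, PC/surrogate-value scoring, chi-squared
outlier removal and covariate residualization, then fits one
cross-validated elastic net per gene on its cis-window dosages (restricted
to GWAS variants) and reports predictive performance with BH-FDR
annotation.
"""

import numpy as np

from omixwas import (SimConfig, gene_annotations, harmonize_gwas,
                     model_significance, preprocess_layer,
                     simulate_covariates, simulate_genotypes, simulate_omics,
                     simulate_trait_and_gwas, train_layer)
from omixwas.simulate import PROTEIN_LAYER

cfg = SimConfig(n_train_samples=900, n_genes=30, n_variants_per_gene=20,
                cis_h2=0.3, seed=2)
variants, dosages = simulate_genotypes(cfg)
cov = simulate_covariates(cfg, dosages.index)
omics, truth = simulate_omics(cfg, variants, dosages, cov)

resid, retained, log = preprocess_layer(omics[PROTEIN_LAYER], cov)
print(f"preprocess: {log['n_input_samples']} samples in, "
      f"{log['n_removed_union']} removed as score outliers, "
      f"{log['n_retained']} retained")

_, gwas = simulate_trait_and_gwas(cfg, truth, variants)
harm, rep = harmonize_gwas(variants, gwas)
db = train_layer(resid, variants, dosages, gene_annotations(cfg),
                 PROTEIN_LAYER, gwas_variant_ids=harm.index, seed=cfg.seed)
model_significance(db, fdr_level=0.05)

r2 = [m.cv_r2 for m in db.models.values()]
n_sig = sum(db.significant.values())
print(f"trained {len(db)} non-trivial models "
      f"({db.meta['n_trivial']} trivial)")
print(f"mean cross-validated r2 = {np.mean(r2):.3f} "
      f"(simulated cis heritability {cfg.cis_h2})")
print(f"{n_sig} of {len(db)} genes significantly predictable at FDR 0.05")
m = db.get("G0000", PROTEIN_LAYER)
print(f"example model G0000: {len(m.variant_ids)} nonzero cis-SNP weights, "
      f"cv_r2 = {m.cv_r2:.3f}, cv_pval = {m.cv_pval:.2e}")
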