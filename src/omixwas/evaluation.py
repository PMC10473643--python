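"""End-to-end validation runs on synthetic cohorts.

Each function simulates a cohort under fixed study conditions, runs the
full pipeline (preprocess -> train -> summary association), and measures a
calibration or recovery property of the method: agreement between the
summary-statistic z-score and its individual-level oracle, null
calibration, detection power for mediated trait effects, heritability
recovery by cross-validated r2, the decomposition sign identity, and
cross-layer concordance recovery.  The problem sizes are the package's
validation defaults; every function is deterministic given ``seed``.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .assoc import association_scan, ld_covariance
from .concordance import (orient_to_positive_gwas, tissue_concordance,
                          weight_decomposition)
from .io import harmonize_gwas
from .models import train_layer
from .preprocess import preprocess_layer
from .simulate import (PROTEIN_LAYER, SimConfig, gene_annotations,
                       simulate_covariates, simulate_genotypes,
                       simulate_omics, simulate_trait_and_gwas)


def _run_protein_chain(cfg: SimConfig, reuse_cohort_for_gwas: bool,
                       trait_name: str = "trait"):
    """simulate -> preprocess -> harmonize -> train for the protein layer."""
    variants, dosages = simulate_genotypes(cfg)
    anno = gene_annotations(cfg)
    cov = simulate_covariates(cfg, dosages.index)
    omics, truth = simulate_omics(cfg, variants, dosages, cov)
    resid, _, _ = preprocess_layer(omics[PROTEIN_LAYER], cov)
    trait, gwas = simulate_trait_and_gwas(
        cfg, truth, variants,
        dosages=dosages if reuse_cohort_for_gwas else None,
        trait_name=trait_name)
    harm, _ = harmonize_gwas(variants, gwas)
    db = train_layer(resid, variants, dosages, anno, PROTEIN_LAYER,
                     gwas_variant_ids=harm.index, seed=cfg.seed)
    return variants, dosages, anno, cov, omics, truth, resid, trait, harm, db


def _marginal_z(x: np.ndarray, y: np.ndarray) -> float:
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    beta = float(xc @ yc) / sxx
    resid = yc - beta * xc
    se = np.sqrt(float(resid @ resid) / (len(y) - 2) / sxx)
    return beta / se


def summary_individual_agreement(seed: int, n_samples: int = 2000,
                                 n_genes: int = 200,
                                 n_variants_per_gene: int = 30,
                                 cis_h2: float = 0.3) -> dict:
    """Summary-statistic vs individual-level association oracle.

    One cohort is reused as training set, LD reference and GWAS cohort, so
    the gene-level z from summary statistics should match the z-score of
    regressing the trait on the model-predicted omic level, gene by gene.
    Also evaluates the oriented weight-decomposition sign identity
    (sign(WA) == sign(z_g)) on every testable gene of the same run.
    """
    cfg = SimConfig(n_train_samples=n_samples, n_genes=n_genes,
                    n_variants_per_gene=n_variants_per_gene, cis_h2=cis_h2,
                    ld_decay=0.7, n_mediated_genes=n_genes // 2,
                    mediated_var_frac=0.003, n_tissues=1, seed=seed)
    (variants, dosages, _anno, _cov, _omics, _truth, _resid, trait, harm,
     db) = _run_protein_chain(cfg, reuse_cohort_for_gwas=True)
    results = association_scan(db, {"trait": harm}, dosages,
                               reference_variants=variants)
    z_by_gene = results.set_index("gene_id")["z"]
    y = trait.set_index("sample_id")["trait"].loc[dosages.index].to_numpy()
    z_sum, z_ind = [], []
    n_sign_match = n_testable = 0
    for (gene, _layer), model in db.models.items():
        pred = dosages[model.variant_ids].to_numpy() @ model.weights
        if pred.std() == 0 or gene not in z_by_gene.index:
            continue
        z_sum.append(float(z_by_gene[gene]))
        z_ind.append(_marginal_z(pred, y))
        ld = ld_covariance(model, dosages, variants)
        wa = weight_decomposition(orient_to_positive_gwas(model, harm, ld))
        if wa is not None:
            n_testable += 1
            n_sign_match += int(np.sign(wa) == np.sign(z_by_gene[gene]))
    z_sum = np.asarray(z_sum)
    z_ind = np.asarray(z_ind)
    return {"pearson_r": float(np.corrcoef(z_sum, z_ind)[0, 1]),
            "max_abs_dz": float(np.max(np.abs(z_sum - z_ind))),
            "n_genes": int(len(z_sum)),
            "decomposition_sign_match_frac":
                n_sign_match / n_testable if n_testable else np.nan,
            "n_decomposition_testable": int(n_testable)}


def null_calibration(seed: int, n_reps: int = 20, n_genes: int = 25,
                     n_train: int = 400, n_gwas: int = 2000,
                     n_reference: int = 3000,
                     fdr_level: float = 0.05) -> dict:
    """Global-null calibration: traits unlinked to any omic level.

    Models are trained on cohorts with real cis-genetic architecture, but
    every mediation coefficient is zero, so association p-values should be
    uniform (pooled Kolmogorov-Smirnov) and the realized false-positive
    proportion at BH ``fdr_level`` should stay near zero on average.  The
    LD reference is a panel drawn independently of the training cohort:
    with the training panel itself, the fitted weights overfit its realized
    LD, sigma_g is overestimated and the null z-scores deflate (a
    conservative miscalibration that the uniformity test would flag).
    """
    pooled_p = []
    fpp = []
    for rep in range(n_reps):
        cfg = SimConfig(n_train_samples=n_train, n_gwas_samples=n_gwas,
                        n_genes=n_genes, n_variants_per_gene=20,
                        cis_h2=0.3, ld_decay=0.7, n_mediated_genes=0,
                        n_tissues=1, seed=seed + 101 * rep)
        (variants, _dosages, _anno, _cov, _omics, _truth, _resid, _trait,
         harm, db) = _run_protein_chain(cfg, reuse_cohort_for_gwas=False)
        _, reference = simulate_genotypes(cfg, n_samples=n_reference,
                                          cohort=1)
        results = association_scan(db, {"trait": harm}, reference,
                                   reference_variants=variants,
                                   fdr_level=fdr_level)
        if results.empty:
            continue
        pooled_p.extend(results["p"].tolist())
        fpp.append(float(results["significant"].mean()))
    ks = stats.kstest(pooled_p, "uniform")
    return {"ks_pval": float(ks.pvalue), "n_pairs": len(pooled_p),
            "mean_false_positive_prop": float(np.mean(fpp)),
            "n_reps": len(fpp)}


def power_recovery(seed: int, n_mediated: int = 50, n_null: int = 10,
                   mediated_var_frac: float = 0.005, n_gwas: int = 50_000,
                   n_train: int = 900, fdr_level: float = 0.05) -> dict:
    """Detection power for genes whose genetically determined protein level
    explains ``mediated_var_frac`` of the trait variance in a GWAS cohort
    of ``n_gwas``.  Genes whose prediction model is trivial count as
    missed."""
    n_genes = n_mediated + n_null
    cfg = SimConfig(n_train_samples=n_train, n_gwas_samples=n_gwas,
                    n_genes=n_genes, n_variants_per_gene=30, cis_h2=0.3,
                    ld_decay=0.7, n_mediated_genes=n_mediated,
                    mediated_var_frac=mediated_var_frac, n_tissues=1,
                    seed=seed)
    (variants, dosages, _anno, _cov, _omics, truth, _resid, _trait, harm,
     db) = _run_protein_chain(cfg, reuse_cohort_for_gwas=False)
    results = association_scan(db, {"trait": harm}, dosages,
                               reference_variants=variants,
                               fdr_level=fdr_level)
    med = set(truth.mediated_genes)
    detected = results[results["gene_id"].isin(med)
                       & results["significant"]]["gene_id"].nunique()
    return {"power": detected / len(med), "n_mediated": len(med),
            "n_null_flagged": int(results[~results["gene_id"].isin(med)]
                                  ["significant"].sum())}


def heritability_recovery(seed: int, n_genes: int = 100, n_train: int = 900,
                          cis_h2: float = 0.3) -> dict:
    """Mean cross-validated r2 across genes simulated at a common cis
    heritability; shrinkage and CV noise should keep it near ``cis_h2``."""
    cfg = SimConfig(n_train_samples=n_train, n_genes=n_genes,
                    n_variants_per_gene=30, cis_h2=cis_h2, ld_decay=0.7,
                    n_tissues=1, seed=seed)
    (_variants, _dosages, _anno, _cov, _omics, _truth, _resid, _trait,
     _harm, db) = _run_protein_chain(cfg, reuse_cohort_for_gwas=True)
    r2 = [m.cv_r2 for m in db.models.values()]
    return {"mean_cv_r2": float(np.mean(r2)), "n_models": len(r2),
            "n_trivial": cfg.n_genes - len(r2)}


def concordance_recovery(seed: int, cross_layer_corr: float,
                         n_tissues: int = 10, n_genes: int = 40,
                         n_train: int = 600, n_gwas: int = 20_000) -> dict:
    """Protein-vs-expression concordance under a known cross-layer effect
    correlation.

    The trait is mediated through the protein layer; expression effect
    vectors share the causal variants with correlation
    ``cross_layer_corr``.  Reports the fraction of tissues whose Spearman
    correlation of signed log10 p-values with the protein scan is
    positive, and the sign-test p-value."""
    cfg = SimConfig(n_train_samples=n_train, n_gwas_samples=n_gwas,
                    n_genes=n_genes, n_variants_per_gene=20, cis_h2=0.3,
                    ld_decay=0.7, n_mediated_genes=n_genes // 2,
                    mediated_var_frac=0.008,
                    cross_layer_effect_corr=cross_layer_corr,
                    n_tissues=n_tissues, seed=seed)
    variants, dosages = simulate_genotypes(cfg)
    anno = gene_annotations(cfg)
    cov = simulate_covariates(cfg, dosages.index)
    omics, truth = simulate_omics(cfg, variants, dosages, cov)
    _trait, gwas = simulate_trait_and_gwas(cfg, truth, variants)
    harm, _ = harmonize_gwas(variants, gwas)
    merged = None
    for layer, mat in omics.items():
        resid, _, _ = preprocess_layer(mat, cov)
        db = train_layer(resid, variants, dosages, anno, layer,
                         gwas_variant_ids=harm.index, seed=cfg.seed)
        if merged is None:
            merged = db
        else:
            for m in db.models.values():
                merged.add(m)
    results = association_scan(merged, {"trait": harm}, dosages,
                               reference_variants=variants)
    conc = tissue_concordance(results, trait="trait",
                              protein_layer=PROTEIN_LAYER)
    n_pos = int((conc["spearman_rho"] > 0).sum())
    return {"frac_positive": n_pos / len(conc), "n_positive": n_pos,
            "n_tissues": len(conc),
            "binom_pval": float(conc["binom_pval"].iloc[0]),
            "mean_rho": float(conc["spearman_rho"].mean())}
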