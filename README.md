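# omixwas

Imputation-based proteome- and transcriptome-wide association studies
(PWAS/TWAS) for quantitative traits, built around GWAS summary statistics —
with a synthetic multi-omic cohort generator so the whole pipeline can be
exercised, validated and calibrated end to end without any external data.

## Who this is for

Statistical geneticists who want to associate a trait with *genetically
predicted* molecular levels (plasma proteins, tissue gene expression) when
the trait cohort has genotypes-level GWAS results but no omic measurements.
A training cohort with genotypes and omics supplies per-gene prediction
models; the GWAS supplies marginal variant effects; an LD reference panel
glues the two together.

## The method

1. **Preprocessing.** Each omic feature is rank-based inverse-normal
   transformed.  Top-10 principal-component scores and top-10 surrogate
   values (singular directions of the covariate-residualized matrix) are
   computed; samples with chi-squared upper-tail p < 0.001 on either score
   set are removed; features are then residualized on covariates (age,
   sex, medication use, genetic PCs) plus the surrogate values.
2. **cis prediction models.** For every gene, an elastic net
   (l1_ratio = 0.5, penalty chosen by 10-fold cross-validation) predicts
   the residualized omic level from dosages of variants within ±1 Mb of
   the gene body, restricted to variants present in the GWAS.  Models with
   no nonzero weight are *trivial* and dropped; predictive
   r² / p come from out-of-fold predictions, with Benjamini–Hochberg FDR
   across genes.
3. **Summary-statistic association.** With model weights *w*, GWAS
   z-scores *z_l*, and the reference dosage covariance Γ,

       z_g = Σ_l w_l · (σ_l / σ_g) · z_l,     σ_g² = wᵀ Γ w,  σ_l = √Γ_ll

   which equals the z-score of regressing the trait on the predicted omic
   level when the reference matches the GWAS cohort.  Two-sided normal
   p-values, BH q-values per (layer, trait), and signed log10 p-values
   (computed on the log scale, so |z| in the hundreds stays finite).
4. **Concordance.** Protein-vs-expression comparisons: signed log10 p
   Spearman correlations per tissue, an exact binomial sign test on the
   number of positively correlated tissues, nonzero-weight SNP overlap and
   joint-significance direction classes, and a per-gene decomposition
   after orienting every variant so its GWAS effect is positive — the
   weighted average Σ z̃_l σ_l w̃_l / Σ z̃_l σ_l of oriented weights, which
   provably has the sign of z_g.

The synthetic cohort generator produces LD-structured genotypes (latent
Gaussian AR(1) haplotypes thresholded at MAF quantiles, with the latent
correlation calibrated so the *dosage* correlation hits its target), omic
layers with sparse cis effects plus covariate and hidden-factor structure,
a trait mediated through the genetic protein component, and marginal GWAS
statistics from an independent cohort — each piece with known ground truth.

## Worked example

`examples/` holds one short script per capability.  From
`examples/03_summary_association.py` (30 genes, 10 of them mediating 1% of
trait variance each, one 1,000-sample cohort reused as training set, LD
reference and GWAS cohort):

```
5 of 30 genes significantly associated with the trait at FDR 0.05
of these, 5 are truly mediated (simulated: 10)

gene      summary-z   individual-z
G0000      +3.374      +3.376
G0001      -2.052      -2.052
G0002      +2.522      +2.520
G0003      -1.831      -1.830
G0004      -4.389      -4.419

significant associations, printed-table style (|log10 p| rounded, direction in parentheses):
trait       LDL
layer   protein
gene_id
G0000      3(+)
G0004      5(-)
G0005      3(+)
G0007      5(-)
G0008      3(+)
```

The summary-statistic z and the individual-level regression z agree to two
decimals because the LD reference here *is* the GWAS cohort; every
significant gene is a truly mediated one; the final block is the
association table in the conventional printed format (rounded |log10 p|
with the direction of association in parentheses).

A thin CLI wraps the same stages for shell use
(`examples/05_cli_pipeline.sh`):

```bash
omixwas all --config run.yaml --seed 5 --out-dir run/
```

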