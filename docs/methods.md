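# Methods

## Model and scope

`omixwas` implements the imputation-based omics-wide association design:
gene-level prediction models are trained on a cohort with genotypes and
omic measurements, then combined with *marginal* GWAS summary statistics
and an LD reference panel to test whether the genetically determined
component of each omic feature is associated with the trait.  The gene
statistic is

    z_g = Σ_l w_l (σ_l / σ_g) z_l,   σ_g² = wᵀ Γ w,

with `w` the per-dosage elastic-net weights on the model's effect alleles,
`z_l = β_l / se_l` the harmonized GWAS z-scores, `Γ` the reference-panel
dosage covariance over the model's variants and `σ_l = √Γ_ll`.  When the
reference panel is the GWAS cohort itself, `z_g` equals (up to the
t-to-normal map) the z-score of regressing the trait on the
model-predicted omic level — the package's core oracle, asserted in the
test suite at Pearson r ≥ 0.99 and max |Δz| ≤ 0.2 over 200 genes.

Out of scope by design: relatedness inference, conditional/joint
multi-gene analysis, colocalization, Mendelian-randomization-style causal
estimation, imputation of missing gene–tissue pairs, and cross-ancestry
correction.

## Preprocessing

Per layer, in a fixed order: (1) rank-based inverse normal transform per
feature, `Φ⁻¹((r − c)/(n − 2c + 1))` with average ranks for ties; offset
`c = 0.5` by default (Blom's 3/8 available) — the offset variant is a free
choice and is configurable because published pipelines rarely state it.
(2) Top-k PC scores of the centered matrix and top-k surrogate values,
defined here as the top singular directions of the covariate-residualized
matrix, both scaled to unit variance (k = 10 each by default).  This
two-step surrogate construction is a deterministic simplification of
surrogate variable analysis that serves the same two roles — outlier
detection and adjustment for unobserved factors — and is exactly
reproducible.  (3) Outlier removal: with standardized scores the squared
row norm is χ²_k under multivariate normality; samples with upper-tail
p < 0.001 on *either* score set are removed (union).  (4) Scores are
recomputed on the retained samples (configurable, since published
orderings are ambiguous) and features are residualized by OLS on
covariates + surrogate values; residuals are orthogonal to every design
column by construction.  Re-running the filter on retained samples removes
nothing in most runs, but exact idempotence is not guaranteed (scores are
recomputed on a shifted sample) and is not asserted.

## cis prediction models

Candidate predictors for a gene are variants inside the gene body ± 1 Mb
(closed interval, clamped at position 1; strand ignored) that are present
in the harmonized GWAS — the same restriction applied at association time,
so weights transfer.  The elastic net uses l1_ratio 0.5 with the penalty
strength chosen by 10-fold seeded cross-validation (minimum MSE) over an
explicit 40-point geometric grid spanning three decades below the
data-derived `alpha_max`.  Two numerical choices matter:

- the response is standardized internally and weights are back-transformed
  (glmnet convention), because the naive penalty parameterization is not
  scale-equivariant in y — the ridge and lasso terms scale differently;
- the grid is computed once from the full data rather than per fold, so
  every fold is evaluated at identical penalties and the selected penalty
  is deterministic and scale-equivariant.

Dosages enter on the raw (0–2) scale so weights combine directly with
per-allele GWAS effects.  `cv_r2` is the squared correlation between
out-of-fold predictions at the selected penalty and the response;
`cv_pval` is the one-sided (positive) correlation test, since predictive
skill is directional.  Models with no nonzero weight are trivial and
excluded.  BH-FDR runs across the non-trivial models of a layer;
externally supplied model sets can be filtered at predictive p < 0.05
(strict inequality).

## Association and concordance

Harmonization matches variants by chromosome:position and compares allele
pairs: swapped effect/other alleles negate β and z, mismatched pairs are
dropped with a count, and model variants absent from the GWAS are flagged
so training excludes them.  Strand-ambiguous palindromic (A/T, C/G)
variants are kept by default — the synthetic data has no strand errors —
with a flag to drop them on real data.  Variants with zero reference
variance are excluded from both the numerator and Γ (they carry no
information and would poison σ_g); a gene with σ_g = 0 is untestable.
p-values are two-sided normal; signed log10 p is computed from the normal
log-survival function so genome-scale signals (|z| ≫ 38) remain finite.
The printed-table report shows |log10 p| rounded to the nearest integer
with the direction in parentheses, significant cells only.

For the per-gene decomposition, each variant is oriented so its GWAS z is
non-negative (weights and z negated together; z = 0 keeps orientation and
is flagged).  The weighted average uses z̃_l σ_l as weights,

    WA = Σ z̃_l σ_l w̃_l / Σ z̃_l σ_l = z_g σ_g / Σ z̃_l σ_l,

an exact identity making sign(WA) = sign(z_g) whenever the denominator is
positive; plain-z weighting is available as an option, but only the
z̃·σ form yields the stated proportionality exactly.  Tissue-wise
concordance is the Spearman correlation (average-rank ties, two-sided p,
pairwise-complete deletion, ≥ 3 pairs) of signed log10 p-values between
the protein scan and each expression scan, summarized by the exact
one-sided binomial sign test on the number of positive tissues.

## Synthetic cohort generator

The generator *defines* the study conditions for every validation run.

- **Genotypes.** One LD block per gene, no cross-gene LD (gene bodies
  spaced 5 Mb so ±1 Mb windows never overlap).  Each haplotype carries a
  latent Gaussian AR(1) vector; the alternate allele is the latent value
  exceeding the upper-f quantile, making the realized frequency f exact in
  expectation.  Because thresholding attenuates correlation — and binary
  margins bound it — the latent coefficient of every adjacent pair is
  calibrated by inverting the Plackett identity (∂P₁₁/∂ρ = bivariate
  normal density) with Gauss–Legendre quadrature and brentq; MAFs wander
  along the block as a reflected random walk (step sd 0.01) inside
  `maf_range`, which mimics the frequency similarity of tightly linked
  variants and keeps the target dosage correlation attainable.
- **Omics.** y_g = X_cis b_g + Cγ_g + Hδ_g + ε_g with empirical variance
  shares: cis_h2 (default 0.3, a mid-range value for significantly
  predictable plasma proteins), covariates 0.05, shared hidden factors
  0.10, noise the remainder of unit variance.  Effects sit on
  `n_causal_per_gene` (default 3) shared causal variants; expression-layer
  effect vectors are drawn with correlation `cross_layer_effect_corr` to
  the protein vector.
- **Trait and GWAS.** T = Σ α_g m_g + ε with m_g the genetic protein
  component and noise scaled to unit trait variance.  Mediated genes carry
  α either drawn N(0, sd) or fixed so each explains an exact variance
  fraction.  The GWAS cohort is a fresh draw from the same law (streamed
  gene-by-gene in two passes, so n_gwas = 50,000 needs only O(n × 30)
  memory), or optionally the training cohort itself, which makes the
  summary-vs-individual oracle tight.  Summary statistics are per-variant
  marginal OLS β and se with the alternate allele as effect allele.
  Traits are standardized; only z = β/se enters the association, so GWAS
  trait scaling is immaterial downstream.

What the generator does **not** emulate: realistic haplotype/recombination
structure, cross-gene LD, related individuals, strand errors, imputation
uncertainty, assay-specific measurement models, sex chromosomes, or
ancestry heterogeneity.  Green validation runs therefore demonstrate
correctness of the statistical machinery under its own assumptions, not
robustness to those real-data complications.

## Validation runs (`omixwas.evaluation`, `scripts/acceptance.py`)

Problem sizes are the package's standard validation conditions: oracle
agreement on one 2,000-sample cohort with 200 genes × 30 variants at
cis_h2 0.3 (100 genes mediating 0.3% of trait variance each — modest
effects keep the t-to-normal map near-linear); heritability recovery over
100 genes at n = 900; power for 50 genes each mediating 0.5% of trait
variance against a 50,000-sample GWAS (trivial models count as missed);
null calibration over 20 replicates × 25 genes (500 gene–trait pairs) with
n_train 400, n_gwas 2,000; concordance over 10 tissues × 40 genes at
cross-layer correlations 0.5 and 0.

The null-calibration run uses an LD reference panel (n = 3,000) drawn
independently of the training cohort.  With the training panel as
reference the fitted weights overfit its realized LD, σ_g is overestimated
and null z-scores deflate to variance ≈ 0.82 — conservative (false
positives stay controlled) but visibly non-uniform.  With an independent
panel the per-gene null z variance is ≈ 1 and cross-gene correlation ≈ 0.
The pooled Kolmogorov–Smirnov uniformity check retains the intrinsic
false-rejection rate of any finite Monte Carlo test.

## Known limitations

- Surrogate values are SVD-based, not the full iteratively reweighted
  surrogate variable analysis; hidden factors correlated with the primary
  signal are handled less delicately.
- The elastic-net CV selects a single penalty per gene; no model averaging
  across the path.
- Multi-allelic variants are out of scope; only biallelic records are
  handled, and palindromic variants rely on exact allele matching.
- The gene statistic assumes the GWAS and reference cohorts share LD;
  ancestry mismatch between them biases σ_g and is not corrected.
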