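"""Synthetic multi-omic cohort generator.

Produces every input the association pipeline consumes — LD-structured
genotype dosages, protein and multi-tissue expression matrices with sparse
cis-genetic architecture, covariates, hidden technical factors, a trait
mediated through the genetic component of the omic levels, and marginal GWAS
summary statistics from an independent (or reused) cohort — together with
the ground truth needed for parameter-recovery tests.

Model
-----
Genotypes: one LD block per gene.  Each haplotype carries a latent Gaussian
AR(1) vector; the alternate allele is present when the latent value exceeds
the upper-``f`` normal quantile, so the realized alternate-allele frequency
is ``f`` by construction.  Thresholding attenuates correlation, so the
latent AR coefficient for each adjacent pair is calibrated numerically so
that the *dosage* correlation of adjacent variants equals ``ld_decay``.

Omics: for feature (gene) ``g`` in a layer,

    y_g = X_cis b_g + C gamma_g + H delta_g + eps_g

with the genetic component scaled to explain ``cis_h2`` of unit total
variance, known covariates ``C`` explaining ``covariate_var``, shared hidden
factors ``H`` explaining ``hidden_var``, and independent noise filling the
remainder.  Protein-layer and expression-layer effect vectors share the
causal variant set and are drawn with correlation
``cross_layer_effect_corr``.

Trait: ``T = sum_g alpha_g m_g + eps`` where ``m_g = X_cis b_g`` is the
genetically determined protein component in the GWAS cohort; the noise is
scaled so ``var(T) = 1``.  GWAS summary statistics are per-variant marginal
ordinary-least-squares effects with standard errors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy import optimize, stats

PROTEIN_LAYER = "protein"

_ALLELE_PAIRS = [
    ("A", "G"), ("A", "C"), ("C", "T"), ("G", "T"),
    ("G", "A"), ("C", "A"), ("T", "C"), ("T", "G"),
]


def expression_layer(tissue: str) -> str:
    """Layer label for an expression tissue."""
    return f"expression:{tissue}"


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Variance shares (``cis_h2``, ``covariate_var``, ``hidden_var``) refer to
    the unit total variance of each omic feature; their sum must stay below 1
    so independent noise can fill the remainder.
    """

    n_train_samples: int = 900
    n_gwas_samples: int = 5000
    n_genes: int = 100
    n_variants_per_gene: int = 30
    ld_decay: float = 0.7
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_causal_per_gene: int = 3
    cis_h2: float = 0.3
    n_hidden_factors: int = 2
    covariate_var: float = 0.05
    hidden_var: float = 0.10
    n_mediated_genes: int = 0
    mediation_effect_sd: float = 0.1
    mediated_var_frac: float | None = None
    cross_layer_effect_corr: float = 0.5
    n_tissues: int = 1
    gene_body_span: int = 10_000
    gene_spacing: int = 5_000_000
    cis_flank: int = 1_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_train_samples", "n_gwas_samples", "n_genes",
                     "n_variants_per_gene", "n_causal_per_gene", "n_tissues"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1, got {getattr(self, name)}")
        if self.n_hidden_factors < 0 or self.n_mediated_genes < 0:
            raise ValueError("n_hidden_factors and n_mediated_genes must be >= 0")
        if self.n_causal_per_gene > self.n_variants_per_gene:
            raise ValueError("n_causal_per_gene cannot exceed n_variants_per_gene")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must lie within (0, 0.5], got {self.maf_range}")
        if not (0.0 <= self.ld_decay < 1.0):
            raise ValueError("ld_decay must be in [0, 1)")
        if not (0.0 <= self.cis_h2 < 1.0):
            raise ValueError("cis_h2 must be in [0, 1)")
        if not (-1.0 <= self.cross_layer_effect_corr <= 1.0):
            raise ValueError("cross_layer_effect_corr must be in [-1, 1]")
        hidden = self.hidden_var if self.n_hidden_factors > 0 else 0.0
        if self.cis_h2 + self.covariate_var + hidden >= 1.0:
            raise ValueError("cis_h2 + covariate_var + hidden_var must be < 1")
        if self.mediated_var_frac is not None:
            if not (0.0 < self.mediated_var_frac < 1.0):
                raise ValueError("mediated_var_frac must be in (0, 1)")
            if self.n_mediated_genes * self.mediated_var_frac >= 1.0:
                raise ValueError("total mediated trait variance must be < 1")
        if self.n_mediated_genes > self.n_genes:
            raise ValueError("n_mediated_genes cannot exceed n_genes")


@dataclass
class SyntheticTruth:
    """Ground truth of one simulated cohort.

    ``effects[layer][gene]`` is the per-dosage causal effect vector aligned
    with ``causal_ids[gene]``; ``alpha[gene]`` is the trait mediation
    coefficient on the genetically determined protein component (exactly 0
    for null genes).
    """

    causal_ids: dict[str, list[str]] = field(default_factory=dict)
    effects: dict[str, dict[str, np.ndarray]] = field(default_factory=dict)
    alpha: dict[str, float] = field(default_factory=dict)
    mediated_genes: list[str] = field(default_factory=list)

    def to_table(self) -> pd.DataFrame:
        rows = []
        for layer, per_gene in self.effects.items():
            for gene, b in per_gene.items():
                for vid, eff in zip(self.causal_ids[gene], b):
                    rows.append({"gene_id": gene, "layer": layer, "variant_id": vid,
                                 "effect": eff, "alpha": self.alpha.get(gene, 0.0)})
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# latent-AR calibration

_GL_X, _GL_W = leggauss(32)


def _bvn_pdf(t1: float, t2: float, r: np.ndarray) -> np.ndarray:
    det = 1.0 - r * r
    q = (t1 * t1 - 2.0 * r * t1 * t2 + t2 * t2) / det
    return np.exp(-0.5 * q) / (2.0 * np.pi * np.sqrt(det))


def _indicator_cov(t1: float, t2: float, rho: float) -> float:
    # Plackett: d/drho P(Z1>t1, Z2>t2) = bivariate normal pdf at (t1, t2)
    if rho == 0.0:
        return 0.0
    nodes = 0.5 * rho * (_GL_X + 1.0)
    weights = 0.5 * rho * _GL_W
    return float(np.sum(weights * _bvn_pdf(t1, t2, nodes)))


_RHO_CACHE: dict[tuple[float, float, float], float] = {}


def latent_rho_for_dosage_corr(target_r: float, f1: float, f2: float) -> float:
    """Latent Gaussian correlation inducing dosage correlation ``target_r``
    between two thresholded variants with alternate-allele frequencies
    ``f1``, ``f2``.  Clipped at 0.999 when the target is unattainable
    (binary margins bound the achievable correlation)."""
    if target_r == 0.0:
        return 0.0
    target_cov = target_r * np.sqrt(f1 * (1 - f1) * f2 * (1 - f2))
    t1 = stats.norm.isf(f1)
    t2 = stats.norm.isf(f2)
    hi = 0.999
    if _indicator_cov(t1, t2, hi) <= target_cov:
        return hi
    return optimize.brentq(
        lambda r: _indicator_cov(t1, t2, r) - target_cov, 0.0, hi, xtol=1e-6)


# ---------------------------------------------------------------------------
# the generative law (variant frame shared by every cohort drawn from it)

def _rng(config: SimConfig, *stream) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((config.seed, 7919, *stream)))


def gene_annotations(config: SimConfig) -> pd.DataFrame:
    """Gene bodies laid out on one chromosome, spaced so cis windows of
    adjacent genes do not overlap (no cross-gene LD by construction)."""
    rows = []
    for i in range(config.n_genes):
        start = 2_000_000 + i * config.gene_spacing
        rows.append({"gene_id": f"G{i:04d}", "chrom": "1", "body_start": start,
                     "body_end": start + config.gene_body_span,
                     "strand": "+" if i % 2 == 0 else "-"})
    return pd.DataFrame(rows)


class _Law:
    """Frozen variant frame: positions, MAFs, thresholds, calibrated latent
    AR coefficients.  Cohorts of any size are drawn against the same law."""

    def __init__(self, config: SimConfig):
        self.config = config
        rng = _rng(config, 0)
        anno = gene_annotations(config)
        lo, hi = config.maf_range
        m = config.n_variants_per_gene
        rows = []
        self.thresholds: dict[str, np.ndarray] = {}
        self.latent_rho: dict[str, np.ndarray] = {}
        for _, g in anno.iterrows():
            w_lo = max(1, int(g.body_start) - config.cis_flank)
            w_hi = int(g.body_end) + config.cis_flank
            pos = np.sort(rng.choice(w_hi - w_lo, size=m, replace=False) + w_lo)
            # MAFs wander slowly along the block: tightly linked variants sit
            # on shared haplotype backgrounds, so neighbours have similar
            # frequencies — which also keeps the target dosage correlation
            # attainable for thresholded binary variants.
            mafs = np.empty(m)
            mafs[0] = rng.uniform(lo, hi)
            steps = rng.normal(0.0, 0.01, size=max(m - 1, 0))
            for j in range(1, m):
                mafs[j] = float(np.clip(mafs[j - 1] + steps[j - 1], lo, hi))
            pair_idx = rng.integers(0, len(_ALLELE_PAIRS), size=m)
            self.thresholds[g.gene_id] = stats.norm.isf(mafs)
            rho = np.empty(max(m - 1, 0))
            for j in range(m - 1):
                key = (round(mafs[j], 3), round(mafs[j + 1], 3),
                       config.ld_decay)
                if key not in _RHO_CACHE:
                    _RHO_CACHE[key] = latent_rho_for_dosage_corr(
                        config.ld_decay, key[0], key[1])
                rho[j] = _RHO_CACHE[key]
            self.latent_rho[g.gene_id] = rho
            for j in range(m):
                ref, alt = _ALLELE_PAIRS[pair_idx[j]]
                rows.append({"variant_id": f"{g.gene_id}_v{j:03d}",
                             "gene_id": g.gene_id, "chrom": g.chrom,
                             "pos": int(pos[j]), "ref": ref, "alt": alt,
                             "maf": mafs[j]})
        self.variants = pd.DataFrame(rows)

    def draw_gene(self, gene_id: str, n: int,
                  rng: np.random.Generator) -> np.ndarray:
        """Integer dosage block (n x m) for one gene's LD block."""
        t = self.thresholds[gene_id]
        rho = self.latent_rho[gene_id]
        m = len(t)
        dosage = np.zeros((n, m), dtype=np.float64)
        for _hap in range(2):
            z = np.empty((n, m))
            z[:, 0] = rng.standard_normal(n)
            for k in range(1, m):
                innov = rng.standard_normal(n)
                z[:, k] = rho[k - 1] * z[:, k - 1] + np.sqrt(
                    1.0 - rho[k - 1] ** 2) * innov
            dosage += (z > t).astype(np.float64)
        return dosage


def simulate_genotypes(config: SimConfig,
                       n_samples: int | None = None,
                       cohort: int = 0,
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cohort genotypes drawn from the config's generative law.

    Returns ``(variants, dosages)``: the variant table (variant_id, gene_id,
    chrom, pos, ref, alt, maf) and a samples x variants dosage DataFrame
    with entries in {0, 1, 2} counting the alternate allele.  ``cohort``
    selects an independent sample draw against the same variant law
    (cohort 0 is the training cohort; higher values give e.g. an external
    LD reference panel).
    """
    law = _Law(config)
    n = config.n_train_samples if n_samples is None else n_samples
    rng = _rng(config, 1, cohort)
    prefix = "S" if cohort == 0 else f"R{cohort}_"
    sample_ids = [f"{prefix}{i:05d}" for i in range(n)]
    blocks = [law.draw_gene(g, n, rng)
              for g in law.variants.gene_id.unique()]
    dosages = pd.DataFrame(np.hstack(blocks), index=sample_ids,
                           columns=law.variants.variant_id.to_numpy())
    return law.variants.copy(), dosages


def simulate_covariates(config: SimConfig, sample_ids) -> pd.DataFrame:
    """Known covariates: age, sex, lipid-medication use, 4 genetic PCs."""
    rng = _rng(config, 2)
    n = len(sample_ids)
    cov = pd.DataFrame({
        "age": rng.uniform(45, 84, size=n),
        "sex": rng.integers(0, 2, size=n).astype(float),
        "medication": (rng.random(n) < 0.2).astype(float),
    }, index=list(sample_ids))
    for k in range(4):
        cov[f"genetic_pc{k + 1}"] = rng.standard_normal(n)
    return cov


def _scaled(component: np.ndarray, target_var: float) -> np.ndarray:
    sd = component.std()
    if sd == 0:
        return np.zeros_like(component)
    return component * (np.sqrt(target_var) / sd)


def simulate_omics(config: SimConfig, variants: pd.DataFrame,
                   dosages: pd.DataFrame, covariates: pd.DataFrame,
                   ) -> tuple[dict[str, pd.DataFrame], SyntheticTruth]:
    """Omic layers (protein + ``n_tissues`` expression tissues) and truth.

    Each feature is one gene; its genetic component is scaled on the
    training cohort so it explains exactly ``cis_h2`` of unit variance.
    """
    if not dosages.index.equals(covariates.index):
        raise ValueError("genotypes and covariates must share the sample set")
    rng_eff = _rng(config, 3)
    rng_noise = _rng(config, 5)
    n = dosages.shape[0]
    genes = list(variants.gene_id.unique())
    layers = [PROTEIN_LAYER] + [expression_layer(f"T{t:02d}")
                                for t in range(config.n_tissues)]
    C = covariates.to_numpy(dtype=float)
    C = (C - C.mean(axis=0)) / np.where(C.std(axis=0) == 0, 1, C.std(axis=0))

    truth = SyntheticTruth(effects={lay: {} for lay in layers})
    rho = config.cross_layer_effect_corr
    k = config.n_causal_per_gene

    raw_effects: dict[str, dict[str, np.ndarray]] = {lay: {} for lay in layers}
    for g in genes:
        vids = variants.loc[variants.gene_id == g, "variant_id"].to_numpy()
        causal = sorted(rng_eff.choice(len(vids), size=k, replace=False))
        truth.causal_ids[g] = list(vids[causal])
        u0 = rng_eff.standard_normal(k)
        raw_effects[PROTEIN_LAYER][g] = u0
        for lay in layers[1:]:
            w = rng_eff.standard_normal(k)
            raw_effects[lay][g] = rho * u0 + np.sqrt(1.0 - rho ** 2) * w

    mediated = genes[: config.n_mediated_genes]
    truth.mediated_genes = list(mediated)
    for g in genes:
        truth.alpha[g] = 0.0
    for g in mediated:
        if config.mediated_var_frac is not None:
            mag = np.sqrt(config.mediated_var_frac / max(config.cis_h2, 1e-12))
            truth.alpha[g] = float(mag * rng_eff.choice([-1.0, 1.0]))
        else:
            truth.alpha[g] = float(rng_eff.normal(0.0, config.mediation_effect_sd))

    hidden = config.hidden_var if config.n_hidden_factors > 0 else 0.0
    noise_var = 1.0 - config.cis_h2 - config.covariate_var - hidden
    out: dict[str, pd.DataFrame] = {}
    for lay in layers:
        H = rng_noise.standard_normal((n, config.n_hidden_factors))
        Y = np.empty((n, len(genes)))
        for j, g in enumerate(genes):
            vids = truth.causal_ids[g]
            Xc = dosages[vids].to_numpy()
            b_raw = raw_effects[lay][g]
            genet = Xc @ b_raw
            if config.cis_h2 > 0 and genet.std() > 0:
                scale = np.sqrt(config.cis_h2) / genet.std()
            else:
                scale = 0.0
            truth.effects[lay][g] = b_raw * scale
            y = genet * scale
            if config.covariate_var > 0:
                gamma = rng_noise.standard_normal(C.shape[1])
                y = y + _scaled(C @ gamma, config.covariate_var)
            if config.n_hidden_factors > 0 and config.hidden_var > 0:
                delta = rng_noise.standard_normal(config.n_hidden_factors)
                y = y + _scaled(H @ delta, config.hidden_var)
            y = y + rng_noise.normal(0.0, np.sqrt(noise_var), size=n)
            Y[:, j] = y
        out[lay] = pd.DataFrame(Y, index=dosages.index, columns=genes)
    return out, truth


def _marginal_ols(X: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-column marginal OLS of trait on dosage: (beta, se)."""
    n = X.shape[0]
    xc = X - X.mean(axis=0)
    tc = t - t.mean()
    sxx = np.einsum("ij,ij->j", xc, xc)
    sxt = xc.T @ tc
    stt = float(tc @ tc)
    with np.errstate(divide="ignore", invalid="ignore"):
        beta = np.where(sxx > 0, sxt / np.where(sxx > 0, sxx, 1.0), 0.0)
        rss = np.maximum(stt - beta * sxt, 0.0)
        se = np.sqrt(rss / (n - 2) / np.where(sxx > 0, sxx, np.nan))
    return beta, se


def simulate_trait_and_gwas(
    config: SimConfig,
    truth: SyntheticTruth,
    variants: pd.DataFrame,
    dosages: pd.DataFrame | None = None,
    trait_name: str = "trait",
    stream: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Trait values and marginal GWAS summary statistics.

    When ``dosages`` is given, that cohort (typically the training cohort)
    is reused as the GWAS cohort, which makes the summary-statistic and
    individual-level association routes agree exactly up to the t-to-normal
    approximation.  Otherwise a fresh cohort of ``n_gwas_samples`` is drawn
    from the same law, gene block by gene block, so memory stays at
    O(n_gwas x variants-per-gene).

    ``stream`` varies only the trait-noise and GWAS-cohort random draws
    (not the generative law), so several traits can be simulated against
    the same variant frame and truth.

    Returns ``(trait_table, gwas_summary)``; the summary has columns
    variant_id, chrom, pos, effect_allele, other_allele, beta, se, n with
    the alternate allele as effect allele.
    """
    rng_t = _rng(config, 4, stream)
    genes = list(variants.gene_id.unique())

    if dosages is not None:
        n = dosages.shape[0]
        sample_ids = list(dosages.index)

        def gene_block(g):
            vids = variants.loc[variants.gene_id == g, "variant_id"]
            return dosages[vids].to_numpy()
    else:
        n = config.n_gwas_samples
        sample_ids = [f"W{i:06d}" for i in range(n)]
        law = _Law(config)

        def gene_block(g):
            gi = genes.index(g)
            return law.draw_gene(g, n, _rng(config, 6, stream, gi))

    genetic = np.zeros(n)
    for g in genes:
        a = truth.alpha.get(g, 0.0)
        if a == 0.0:
            continue
        b = truth.effects[PROTEIN_LAYER][g]
        vids = truth.causal_ids[g]
        X = gene_block(g)
        cols = list(variants.loc[variants.gene_id == g, "variant_id"])
        idx = [cols.index(v) for v in vids]
        genetic += a * (X[:, idx] @ b)

    var_g = float(np.var(genetic))
    if var_g >= 1.0:
        raise ValueError("mediated trait variance >= 1; reduce alpha effects")
    t = genetic + rng_t.normal(0.0, np.sqrt(1.0 - var_g), size=n)

    betas, ses = [], []
    for g in genes:
        X = gene_block(g)
        b, s = _marginal_ols(X, t)
        betas.append(b)
        ses.append(s)
    gwas = variants[["variant_id", "chrom", "pos"]].copy()
    gwas["effect_allele"] = variants["alt"].to_numpy()
    gwas["other_allele"] = variants["ref"].to_numpy()
    gwas["beta"] = np.concatenate(betas)
    gwas["se"] = np.concatenate(ses)
    gwas["n"] = n
    trait = pd.DataFrame({"sample_id": sample_ids, trait_name: t})
    return trait, gwas
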