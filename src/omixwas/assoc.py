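"""Gene-level association from GWAS summary statistics.

The statistic combines a gene's prediction-model weights w with the GWAS
per-variant z-scores and a reference-panel dosage covariance Gamma:

    z_g = sum_l w_l * (sigma_l / sigma_g) * z_l,   sigma_g^2 = w' Gamma w,

where sigma_l = sqrt(Gamma_ll).  This equals the z-score of regressing the
trait on the model-predicted omic level when the reference panel matches
the GWAS cohort.  p-values are two-sided normal; q-values are
Benjamini-Hochberg within each (layer, trait); signed log10 p-values are
computed on the log scale so genome-scale associations (|z| > 40, p below
double underflow) remain finite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

LOG10 = np.log(10.0)


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (capped at 1)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def signed_log10_p(z) -> np.ndarray:
    """sign(z) * (-log10 of the two-sided normal p), underflow-safe."""
    z = np.asarray(z, dtype=float)
    neg_log10_p = -(np.log(2.0) + stats.norm.logsf(np.abs(z))) / LOG10
    return np.sign(z) * neg_log10_p


@dataclass
class LDBlockCov:
    """Reference-panel dosage covariance over one model's variants."""

    gene_id: str
    variant_ids: list[str]
    gamma: np.ndarray

    def __post_init__(self) -> None:
        self.gamma = np.atleast_2d(np.asarray(self.gamma, dtype=float))
        if self.gamma.shape[0] != self.gamma.shape[1]:
            raise ValueError("Gamma must be square")
        if not np.allclose(self.gamma, self.gamma.T, atol=1e-10):
            raise ValueError("Gamma must be symmetric")
        if np.any(np.diag(self.gamma) < 0):
            raise ValueError("Gamma diagonal must be >= 0")

    @property
    def sigma(self) -> np.ndarray:
        return np.sqrt(np.diag(self.gamma))


def ld_covariance(model, reference_dosages: pd.DataFrame,
                  reference_variants: pd.DataFrame | None = None) -> LDBlockCov:
    """Sample covariance of reference dosages over a model's variants.

    When ``reference_variants`` is given, reference columns whose alt
    allele disagrees with the model's effect allele (but matches its other
    allele) are flipped (dosage -> 2 - dosage) before the covariance is
    taken.  Variants absent from the reference are dropped; no overlap is
    an error.  Zero-variance variants are retained with sigma_l = 0 — the
    association step excludes them.
    """
    present = [v for v in model.variant_ids if v in reference_dosages.columns]
    if not present:
        raise ValueError(f"{model.gene_id}: no model variant found in the "
                         "LD reference")
    X = reference_dosages[present].to_numpy(dtype=float).copy()
    if reference_variants is not None:
        alt = reference_variants.set_index("variant_id")["alt"]
        ref = reference_variants.set_index("variant_id")["ref"]
        ea = dict(zip(model.variant_ids, model.effect_alleles))
        for j, vid in enumerate(present):
            if vid in alt.index and ea.get(vid, alt[vid]) != alt[vid]:
                if ea[vid] == ref[vid]:
                    X[:, j] = 2.0 - X[:, j]
                else:
                    raise ValueError(f"{vid}: effect allele matches neither "
                                     "reference allele")
    gamma = np.cov(X, rowvar=False, ddof=1)
    return LDBlockCov(gene_id=model.gene_id, variant_ids=present,
                      gamma=np.atleast_2d(gamma))


@dataclass
class AssociationResult:
    gene_id: str
    layer: str
    trait: str
    z: float
    p: float
    signed_log10_p: float
    n_snps_used: int
    n_snps_dropped: int

    @property
    def direction(self) -> str:
        return "+" if self.z >= 0 else "-"


def gene_zscore(model, gwas_harmonized: pd.DataFrame, ld: LDBlockCov,
                trait: str = "trait") -> AssociationResult | None:
    """Gene-level z-score from harmonized GWAS z's, model weights and the
    reference covariance.  Model variants missing from the GWAS or with
    zero reference variance are dropped from the sum (counted in the
    result); a gene whose predicted level has zero variance in the
    reference is untestable and returns ``None``."""
    w_by_id = dict(zip(model.variant_ids, model.weights))
    ld_pos = {v: i for i, v in enumerate(ld.variant_ids)}
    sigma_all = ld.sigma
    used, dropped = [], 0
    for vid in model.variant_ids:
        if vid in gwas_harmonized.index and vid in ld_pos \
                and sigma_all[ld_pos[vid]] > 0:
            used.append(vid)
        else:
            dropped += 1
    if not used:
        return None
    idx = [ld_pos[v] for v in used]
    gamma = ld.gamma[np.ix_(idx, idx)]
    w = np.array([w_by_id[v] for v in used])
    sig = sigma_all[idx]
    zl = gwas_harmonized.loc[used, "z"].to_numpy(dtype=float)
    var_g = float(w @ gamma @ w)
    if var_g <= 0:
        return None
    sigma_g = np.sqrt(var_g)
    z_g = float(np.sum(w * sig * zl) / sigma_g)
    p = float(2.0 * stats.norm.sf(abs(z_g)))
    return AssociationResult(
        gene_id=model.gene_id, layer=model.layer, trait=trait, z=z_g, p=p,
        signed_log10_p=float(signed_log10_p(z_g)),
        n_snps_used=len(used), n_snps_dropped=dropped)


def association_scan(db, gwas_by_trait: dict[str, pd.DataFrame],
                     reference_dosages: pd.DataFrame,
                     reference_variants: pd.DataFrame | None = None,
                     fdr_level: float = 0.05) -> pd.DataFrame:
    """One association per (gene, layer, trait) with BH q-values within
    each (layer, trait) block and a significance flag at ``fdr_level``."""
    rows = []
    ld_cache: dict[tuple[str, str], LDBlockCov | None] = {}
    for (gene, layer), model in db.models.items():
        key = (gene, layer)
        if key not in ld_cache:
            try:
                ld_cache[key] = ld_covariance(model, reference_dosages,
                                              reference_variants)
            except ValueError:
                ld_cache[key] = None
        ld = ld_cache[key]
        if ld is None:
            continue
        for trait, gwas in gwas_by_trait.items():
            res = gene_zscore(model, gwas, ld, trait=trait)
            if res is None:
                continue
            rows.append({"gene_id": res.gene_id, "layer": res.layer,
                         "trait": res.trait, "z": res.z, "p": res.p,
                         "signed_log10_p": res.signed_log10_p,
                         "direction": res.direction,
                         "n_snps_used": res.n_snps_used})
    results = pd.DataFrame(rows, columns=[
        "gene_id", "layer", "trait", "z", "p", "signed_log10_p",
        "direction", "n_snps_used"])
    if results.empty:
        results["q"] = pd.Series(dtype=float)
        results["significant"] = pd.Series(dtype=bool)
        return results
    results["q"] = np.nan
    for _, idx in results.groupby(["layer", "trait"]).groups.items():
        results.loc[idx, "q"] = bh_fdr(results.loc[idx, "p"].to_numpy())
    results["significant"] = results["q"] <= fdr_level
    return results


def table1_report(results: pd.DataFrame, layers: list[str] | None = None,
                  ) -> pd.DataFrame:
    """Report in the published-table style: per gene and trait, the rounded
    |log10 p| followed by the direction in parentheses (e.g. "406(+)"),
    shown for significant cells only; genes with no significant association
    are omitted."""
    sig = results[results["significant"]]
    keep_genes = sig["gene_id"].unique()
    sub = results[results["gene_id"].isin(keep_genes)].copy()
    if layers is not None:
        sub = sub[sub["layer"].isin(layers)]

    def cell(row):
        if not row["significant"]:
            return "."
        mag = int(round(abs(row["signed_log10_p"])))
        return f"{mag}({row['direction']})"

    sub["cell"] = sub.apply(cell, axis=1)
    wide = sub.pivot_table(index="gene_id", columns=["trait", "layer"],
                           values="cell", aggfunc="first")
    return wide.fillna(".")
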