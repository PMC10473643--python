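"""Protein-vs-expression association concordance.

Given association results for a protein layer and one or more expression
layers (tissues), this module computes the comparisons used to judge
whether proteome- and transcriptome-level associations tell the same
story: the genes x contexts signed log10 p-value matrix, per-tissue
Spearman rank correlations, the exact binomial test on the number of
tissues with positive correlation, the per-gene oriented weight
decomposition (all GWAS effects turned positive so the weighted average of
model weights has the sign of the gene-level z), nonzero-weight SNP
overlap between layers, and the joint-significance direction
classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def signed_logp_matrix(results: pd.DataFrame, trait: str | None = None,
                       require_significant: bool = False) -> pd.DataFrame:
    """Wide genes x contexts matrix of signed log10 p-values.

    A context is a layer (for a single trait) or "layer|trait".  Missing
    (gene, context) pairs stay NaN.  With ``require_significant``, only
    genes with at least one significant association are displayed."""
    sub = results if trait is None else results[results["trait"] == trait]
    if require_significant:
        keep = sub.loc[sub["significant"], "gene_id"].unique()
        sub = sub[sub["gene_id"].isin(keep)]
    if trait is None and sub["trait"].nunique() > 1:
        sub = sub.assign(context=sub["layer"] + "|" + sub["trait"])
    else:
        sub = sub.assign(context=sub["layer"])
    return sub.pivot_table(index="gene_id", columns="context",
                           values="signed_log10_p", aggfunc="first")


def spearman_concordance(a, b) -> tuple[float, float]:
    """Spearman rank correlation (average-rank ties, two-sided p) over
    pairwise-complete entries; fewer than 3 complete pairs is an error."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ok = np.isfinite(a) & np.isfinite(b)
    if ok.sum() < 3:
        raise ValueError(f"need >= 3 complete pairs, got {int(ok.sum())}")
    rho, p = stats.spearmanr(a[ok], b[ok])
    return float(rho), float(p)


def sign_binomial_test(n_positive: int, n_total: int,
                       alternative: str = "greater") -> float:
    """Exact binomial tail probability of >= ``n_positive`` successes in
    ``n_total`` fair coin flips (one-sided upper tail by default)."""
    if not (0 <= n_positive <= n_total):
        raise ValueError("need 0 <= n_positive <= n_total")
    return float(stats.binomtest(n_positive, n_total, 0.5,
                                 alternative=alternative).pvalue)


@dataclass
class OrientedModelView:
    """One gene's model after orienting every variant so its GWAS z is
    non-negative; variants with z exactly 0 keep their orientation and are
    flagged."""

    gene_id: str
    variant_ids: list[str]
    weights: np.ndarray       # oriented w~
    gwas_z: np.ndarray        # oriented z~ >= 0
    sigma: np.ndarray
    zero_z_ids: list[str]


def orient_to_positive_gwas(model, gwas_harmonized: pd.DataFrame,
                            ld=None) -> OrientedModelView:
    """Swap effect alleles so every variant's GWAS effect is positive,
    negating the model weight and z of flipped variants (an involution)."""
    sigma_map = {}
    if ld is not None:
        sigma_map = dict(zip(ld.variant_ids, ld.sigma))
    vids, ws, zs, sig, zero = [], [], [], [], []
    for vid, w in zip(model.variant_ids, model.weights):
        if vid not in gwas_harmonized.index:
            continue
        z = float(gwas_harmonized.loc[vid, "z"])
        if z < 0:
            w, z = -w, -z
        elif z == 0:
            zero.append(vid)
        vids.append(vid)
        ws.append(float(w))
        zs.append(z)
        sig.append(float(sigma_map.get(vid, 1.0)))
    return OrientedModelView(gene_id=model.gene_id, variant_ids=vids,
                             weights=np.array(ws), gwas_z=np.array(zs),
                             sigma=np.array(sig), zero_z_ids=zero)


def weight_decomposition(view: OrientedModelView,
                         weighting: str = "z_sigma") -> float | None:
    """Weighted average of oriented model weights.

    With the default ``z_sigma`` weighting,

        WA = sum_l z~_l sigma_l w~_l / sum_l z~_l sigma_l,

    which has the same sign as, and is proportional to, the gene-level
    z-score (WA = z_g * sigma_g / sum_l z~_l sigma_l).  ``weighting="z"``
    uses the oriented z alone.  Returns ``None`` (undefined) when the
    denominator is not positive."""
    if weighting == "z_sigma":
        wt = view.gwas_z * view.sigma
    elif weighting == "z":
        wt = view.gwas_z
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    denom = float(wt.sum())
    if denom <= 0:
        return None
    return float(np.sum(wt * view.weights) / denom)


def decomposition_table(view: OrientedModelView) -> pd.DataFrame:
    """Per-variant contributions to the weighted-average decomposition."""
    wt = view.gwas_z * view.sigma
    denom = wt.sum()
    contrib = wt * view.weights / denom if denom > 0 else np.full_like(wt, np.nan)
    return pd.DataFrame({"variant_id": view.variant_ids,
                         "oriented_z": view.gwas_z,
                         "oriented_weight": view.weights,
                         "sigma": view.sigma, "contribution": contrib})


def overlap_and_classify(model_a, model_b, result_a, result_b,
                         fdr_level: float = 0.05) -> dict:
    """Nonzero-weight SNP overlap between two layers' models of one gene,
    plus the joint-significance direction class."""
    if model_a is None or model_b is None or result_a is None or result_b is None:
        return {"n_overlap": 0, "klass": "one-layer-only"}
    overlap = set(model_a.variant_ids) & set(model_b.variant_ids)
    sig_a = bool(result_a["q"] <= fdr_level)
    sig_b = bool(result_b["q"] <= fdr_level)
    if sig_a and sig_b:
        klass = ("both-significant-concordant"
                 if np.sign(result_a["z"]) == np.sign(result_b["z"])
                 else "both-significant-discordant")
    elif sig_a or sig_b:
        klass = "one-significant"
    else:
        klass = "neither"
    return {"n_overlap": len(overlap), "klass": klass}


def tissue_concordance(results: pd.DataFrame, trait: str,
                       protein_layer: str = "protein",
                       only_significant_genes: bool = False) -> pd.DataFrame:
    """Per-tissue Spearman correlation between protein-layer and
    expression-layer signed log10 p-values across genes, with the sign-test
    summary attached to every row."""
    mat = signed_logp_matrix(results, trait=trait,
                             require_significant=only_significant_genes)
    if protein_layer not in mat.columns:
        raise ValueError(f"no {protein_layer!r} column in results")
    rows = []
    for ctx in mat.columns:
        if ctx == protein_layer:
            continue
        rho, p = spearman_concordance(mat[protein_layer], mat[ctx])
        rows.append({"trait": trait, "context": ctx, "spearman_rho": rho,
                     "rho_pval": p,
                     "n_genes": int((mat[protein_layer].notna()
                                     & mat[ctx].notna()).sum())})
    out = pd.DataFrame(rows)
    if not out.empty:
        n_pos = int((out["spearman_rho"] > 0).sum())
        out["n_positive"] = n_pos
        out["n_total"] = len(out)
        out["binom_pval"] = sign_binomial_test(n_pos, len(out))
    return out
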