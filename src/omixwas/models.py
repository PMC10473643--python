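"""Per-gene elastic-net prediction models of omic residuals from cis-window
genotype dosages, evaluated by cross-validation.

A gene's candidate predictors are the variants inside its cis window (gene
body plus a 1 Mb flank on each side by default) that are also present in the
harmonized GWAS, mirroring the restriction applied during training so model
weights transfer to the summary-statistic association.  Fitting is on the
raw dosage scale, so the stored weights combine directly with per-allele
GWAS effects.  A model with no nonzero weight is "trivial" and kept out of
the database.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold
import warnings

from .assoc import bh_fdr


@dataclass
class PredictionModel:
    """Sparse cis-SNP weights for one (gene, layer) with CV performance."""

    gene_id: str
    layer: str
    variant_ids: list[str]
    effect_alleles: list[str]
    weights: np.ndarray
    cv_r2: float
    cv_pval: float
    n_train: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.variant_ids) == 0:
            raise ValueError("a PredictionModel must carry >= 1 nonzero weight")


@dataclass
class ModelDB:
    """Prediction models keyed by (gene_id, layer), plus training metadata."""

    models: dict[tuple[str, str], PredictionModel] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)
    qvalues: dict[tuple[str, str], float] = field(default_factory=dict)
    significant: dict[tuple[str, str], bool] = field(default_factory=dict)

    def add(self, model: PredictionModel) -> None:
        key = (model.gene_id, model.layer)
        if key in self.models:
            raise ValueError(f"duplicate model key {key}")
        self.models[key] = model

    def get(self, gene_id: str, layer: str) -> PredictionModel | None:
        return self.models.get((gene_id, layer))

    def layers(self) -> list[str]:
        return sorted({lay for _, lay in self.models})

    def by_layer(self, layer: str) -> list[PredictionModel]:
        return [m for (_, lay), m in self.models.items() if lay == layer]

    def __len__(self) -> int:
        return len(self.models)

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        wrows, srows = [], []
        for (gene, lay), m in self.models.items():
            for vid, ea, w in zip(m.variant_ids, m.effect_alleles, m.weights):
                wrows.append({"gene_id": gene, "layer": lay, "variant_id": vid,
                              "effect_allele": ea, "weight": w})
            srows.append({"gene_id": gene, "layer": lay, "cv_r2": m.cv_r2,
                          "cv_pval": m.cv_pval,
                          "n_snps_nonzero": len(m.variant_ids),
                          "n_train": m.n_train})
        return pd.DataFrame(wrows), pd.DataFrame(srows)

    @classmethod
    def from_frames(cls, weights: pd.DataFrame,
                    summary: pd.DataFrame) -> "ModelDB":
        db = cls()
        grouped = weights.groupby(["gene_id", "layer"], sort=False)
        for rec in summary.itertuples(index=False):
            grp = grouped.get_group((rec.gene_id, rec.layer))
            db.add(PredictionModel(
                gene_id=rec.gene_id, layer=rec.layer,
                variant_ids=list(grp.variant_id),
                effect_alleles=list(grp.effect_allele),
                weights=grp.weight.to_numpy(),
                cv_r2=float(rec.cv_r2), cv_pval=float(rec.cv_pval),
                n_train=int(rec.n_train)))
        return db


def cis_window(gene, flank: int = 1_000_000) -> tuple[str, int, int]:
    """Closed cis interval: gene body extended by ``flank`` bp on both
    sides, clamped at position 1.  Strand does not alter the window."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    start = max(1, int(gene.body_start) - flank)
    end = int(gene.body_end) + flank
    return str(gene.chrom), start, end


def cis_variants(variants: pd.DataFrame, gene,
                 flank: int = 1_000_000) -> pd.DataFrame:
    chrom, start, end = cis_window(gene, flank)
    mask = ((variants.chrom.astype(str) == chrom)
            & (variants.pos >= start) & (variants.pos <= end))
    return variants[mask]


def fit_elastic_net_cv(X: pd.DataFrame, y: np.ndarray, gene_id: str,
                       layer: str, l1_ratio: float = 0.5, n_folds: int = 10,
                       seed: int = 0, n_alphas: int = 40,
                       ) -> PredictionModel | None:
    """Cross-validated elastic net of an omic residual on cis dosages.

    The penalty strength is chosen by k-fold CV (minimum mean squared
    error); cv_r2 is the squared correlation between out-of-fold
    predictions at the chosen penalty and ``y``, and cv_pval the one-sided
    (positive) correlation-test p-value.  Returns ``None`` for a trivial
    model (no nonzero weight, or no usable predictor).
    """
    y = np.asarray(y, dtype=float)
    if np.ptp(y) == 0:
        raise ValueError(f"{gene_id}/{layer}: constant response")
    keep = X.columns[X.std(axis=0).to_numpy() > 0]
    if len(keep) == 0:
        return None
    Xk = X[keep].to_numpy(dtype=float)
    n = Xk.shape[0]
    if n < n_folds:
        raise ValueError(f"n_train ({n}) < folds ({n_folds})")
    cv = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(cv.split(Xk))
    # fit on the unit-variance response and rescale the weights after
    # (glmnet-style): the naive elastic-net penalty is not
    # scale-equivariant in y because the ridge term scales differently
    # from the lasso term
    y_sd = y.std()
    ys = y / y_sd
    # explicit geometric penalty grid computed once from the full data so
    # every fold is evaluated at identical penalties
    Xc = Xk - Xk.mean(axis=0)
    yc = ys - ys.mean()
    alpha_max = float(np.max(np.abs(Xc.T @ yc))) / (n * l1_ratio)
    if alpha_max <= 0:
        return None
    alphas = np.geomspace(alpha_max, alpha_max * 1e-3, n_alphas)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        enet_cv = ElasticNetCV(l1_ratio=l1_ratio, alphas=alphas,
                               cv=folds, max_iter=5000, tol=1e-6)
        enet_cv.fit(Xk, ys)
        alpha = float(enet_cv.alpha_)
        oof = np.empty(n)
        for train, test in folds:
            fold_fit = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=5000,
                                  tol=1e-6).fit(Xk[train], ys[train])
            oof[test] = fold_fit.predict(Xk[test])
        final = ElasticNet(alpha=alpha, l1_ratio=l1_ratio, max_iter=5000,
                           tol=1e-6).fit(Xk, ys)
    nz = np.flatnonzero(final.coef_)
    if nz.size == 0:
        return None
    if np.ptp(oof) == 0:
        cv_r2, cv_pval = 0.0, 1.0
    else:
        r, cv_pval = stats.pearsonr(oof, y, alternative="greater")
        cv_r2 = float(r * r)
        cv_pval = float(cv_pval)
    return PredictionModel(
        gene_id=gene_id, layer=layer,
        variant_ids=[keep[i] for i in nz],
        effect_alleles=["" for _ in nz],
        weights=final.coef_[nz] * y_sd,
        cv_r2=cv_r2, cv_pval=cv_pval, n_train=n)


def train_layer(residuals: pd.DataFrame, variants: pd.DataFrame,
                dosages: pd.DataFrame, annotations: pd.DataFrame,
                layer: str, gwas_variant_ids=None,
                flank: int = 1_000_000, l1_ratio: float = 0.5,
                n_folds: int = 10, seed: int = 0) -> ModelDB:
    """Train one prediction model per gene of a layer.

    ``gwas_variant_ids``, when given, restricts candidate predictors to
    variants present in the (harmonized) GWAS.  Trivial models are skipped;
    the count is recorded in the database metadata.
    """
    db = ModelDB(meta={"layer": layer, "l1_ratio": l1_ratio,
                       "n_folds": n_folds, "seed": seed, "flank": flank,
                       "n_trivial": 0})
    alt_by_id = variants.set_index("variant_id")["alt"]
    anno = annotations.set_index("gene_id")
    samples = residuals.index
    X_all = dosages.loc[samples]
    for gene_id in residuals.columns:
        if gene_id not in anno.index:
            continue
        cand = cis_variants(variants, anno.loc[gene_id], flank)
        ids = [v for v in cand.variant_id if v in dosages.columns]
        if gwas_variant_ids is not None:
            allowed = set(gwas_variant_ids)
            ids = [v for v in ids if v in allowed]
        if not ids:
            db.meta["n_trivial"] += 1
            continue
        model = fit_elastic_net_cv(
            X_all[ids], residuals[gene_id].to_numpy(), gene_id, layer,
            l1_ratio=l1_ratio, n_folds=n_folds, seed=seed)
        if model is None:
            db.meta["n_trivial"] += 1
            continue
        model.effect_alleles = [alt_by_id[v] for v in model.variant_ids]
        db.add(model)
    return db


def model_significance(db: ModelDB, fdr_level: float = 0.05) -> ModelDB:
    """Benjamini-Hochberg q-values over the non-trivial models of each
    layer; flags models significant at ``fdr_level``."""
    for layer in db.layers():
        keys = [k for k in db.models if k[1] == layer]
        pvals = np.array([db.models[k].cv_pval for k in keys])
        if pvals.size == 0:
            continue
        qvals = bh_fdr(pvals)
        for k, q in zip(keys, qvals):
            db.qvalues[k] = float(q)
            db.significant[k] = bool(q <= fdr_level)
    return db


def filter_models(db: ModelDB, max_cv_pval: float = 0.05) -> ModelDB:
    """Keep models with predictive p-value strictly below ``max_cv_pval``
    (the filter applied to externally trained model sets)."""
    out = ModelDB(meta=dict(db.meta))
    for key, m in db.models.items():
        if m.cv_pval < max_cv_pval:
            out.models[key] = m
            if key in db.qvalues:
                out.qvalues[key] = db.qvalues[key]
                out.significant[key] = db.significant[key]
    return out
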