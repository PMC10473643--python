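"""Readers/writers for the pipeline's external formats and the allele
harmonization contract between GWAS summary statistics and model variants.

Conventions: coordinates are 1-based closed intervals (VCF convention);
dosages count the alternate allele; the model's effect allele is always the
alternate allele of the training VCF.  All tables travel as tab-separated
files.  The prediction-model database is a pair of tables (per-variant
weights, per-gene summary) mirroring the conventional prediction-model
layout so third-party model sets can be imported.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from cyvcf2 import VCF

PALINDROMIC = ({"A", "T"}, {"C", "G"})


class VcfParseError(ValueError):
    pass


# ---------------------------------------------------------------------------
# plain tables

def write_table(df: pd.DataFrame, path, index: bool = False) -> None:
    # 17 significant digits round-trips IEEE doubles exactly
    df.to_csv(path, sep="\t", index=index, float_format="%.17g")


def read_table(path, index_col=None) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col,
                       float_precision="round_trip")


def write_matrix(df: pd.DataFrame, path) -> None:
    """Samples x features matrix with the sample id as first column."""
    df.to_csv(path, sep="\t", index=True, index_label="sample_id",
              float_format="%.17g")


def read_matrix(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="sample_id",
                       float_precision="round_trip")


# ---------------------------------------------------------------------------
# VCF

def write_vcf(variants: pd.DataFrame, dosages: pd.DataFrame, path) -> None:
    """Emit an uncompressed VCF 4.2 with a DS (dosage) FORMAT field."""
    samples = list(dosages.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(variants["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,'
                 'Description="Alternate allele dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(samples) + "\n")
        mat = dosages.to_numpy()
        for i, v in enumerate(variants.itertuples(index=False)):
            row = "\t".join(f"{d:.6g}" for d in mat[:, i])
            fh.write(f"{v.chrom}\t{v.pos}\t{v.variant_id}\t{v.ref}\t{v.alt}"
                     f"\t.\tPASS\t.\tDS\t{row}\n")


def _validate_vcf_text(path) -> None:
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            if len(line.rstrip("\n").split("\t")) < 10:
                raise VcfParseError(
                    f"{path}: malformed VCF record at line {lineno} "
                    "(fewer than 10 tab-separated fields)")


def load_dosages(vcf_path, maf_threshold: float = 0.05,
                 ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Load dosages from a VCF, dropping variants with MAF at or below
    ``maf_threshold`` (the "0.05 or less" rule: the boundary is removed).

    Uses the DS field when present, else converts hard genotypes; missing
    entries are mean-imputed per variant.
    """
    _validate_vcf_text(vcf_path)
    vcf = VCF(str(vcf_path))
    samples = list(vcf.samples)
    rows, cols = [], []
    for var in vcf:
        ds = var.format("DS")
        if ds is not None:
            d = np.asarray(ds, dtype=float).reshape(-1)
        else:
            gt = np.asarray(var.genotype.array())[:, :2].astype(float)
            gt[gt < 0] = np.nan
            d = gt.sum(axis=1)
        d = np.where((d < 0) | ~np.isfinite(d), np.nan, d)
        if np.all(np.isnan(d)):
            continue
        mean = np.nanmean(d)
        d = np.where(np.isnan(d), mean, d)
        af = mean / 2.0
        maf = min(af, 1.0 - af)
        if maf <= maf_threshold:
            continue
        vid = var.ID or f"{var.CHROM}:{var.POS}"
        rows.append({"variant_id": vid, "chrom": str(var.CHROM),
                     "pos": int(var.POS), "ref": var.REF, "alt": var.ALT[0],
                     "maf": maf})
        cols.append(d)
    if not rows:
        raise ValueError(
            f"{vcf_path}: no variants retained after the MAF <= "
            f"{maf_threshold} filter")
    variants = pd.DataFrame(rows)
    dosages = pd.DataFrame(np.column_stack(cols), index=samples,
                           columns=variants.variant_id.to_numpy())
    return variants, dosages


# ---------------------------------------------------------------------------
# omics

def load_omics(table_path, feature_gene_map: pd.DataFrame,
               ) -> tuple[pd.DataFrame, pd.Series, int]:
    """Load a samples x features omic table, dropping features that map to
    zero or multiple genes.

    ``feature_gene_map`` has columns ``feature_id`` and ``gene_id`` (one row
    per mapping; a feature appearing twice maps to multiple genes).  Returns
    the filtered matrix, the retained feature -> gene map, and the number of
    features dropped.
    """
    mat = read_matrix(table_path)
    if mat.index.duplicated().any():
        dups = mat.index[mat.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids in {table_path}: {dups}")
    counts = feature_gene_map.groupby("feature_id")["gene_id"].nunique()
    unique_feats = set(counts[counts == 1].index)
    keep = [f for f in mat.columns if f in unique_feats]
    n_dropped = mat.shape[1] - len(keep)
    gene_map = (feature_gene_map.drop_duplicates("feature_id")
                .set_index("feature_id")["gene_id"].loc[keep])
    return mat[keep], gene_map, n_dropped


# ---------------------------------------------------------------------------
# GWAS harmonization

def _key(chrom, pos):
    return (str(chrom), int(pos))


def harmonize_gwas(model_variants: pd.DataFrame, gwas: pd.DataFrame,
                   drop_palindromic: bool = False,
                   ) -> tuple[pd.DataFrame, dict]:
    """Align GWAS records to the model variants' effect (alt) alleles.

    Matching key is chrom:pos:allele-pair, robust to id differences.  Where
    the GWAS effect/other alleles are swapped relative to the model's
    alt/ref, ``beta`` (and hence z) is negated.  Records with mismatched
    alleles are dropped; model variants absent from the GWAS are flagged in
    the report so training can exclude them.

    Returns ``(harmonized, report)``.  ``harmonized`` is indexed by model
    variant_id with columns effect_allele (= model alt), other_allele, beta,
    se, z, n.  ``report`` counts matches, sign flips, mismatches and misses.
    """
    lut: dict[tuple, list] = {}
    for rec in gwas.itertuples(index=False):
        lut.setdefault(_key(rec.chrom, rec.pos), []).append(rec)
    out_rows = []
    report = {"n_matched": 0, "n_flipped": 0, "n_mismatch": 0,
              "n_missing": 0, "n_palindromic_dropped": 0, "missing_ids": []}
    for mv in model_variants.itertuples(index=False):
        if drop_palindromic and {mv.ref, mv.alt} in PALINDROMIC:
            report["n_palindromic_dropped"] += 1
            report["missing_ids"].append(mv.variant_id)
            continue
        recs = lut.get(_key(mv.chrom, mv.pos))
        if not recs:
            report["n_missing"] += 1
            report["missing_ids"].append(mv.variant_id)
            continue
        rec = sign = None
        for cand in recs:
            if cand.effect_allele == mv.alt and cand.other_allele == mv.ref:
                rec, sign = cand, 1.0
                break
            if cand.effect_allele == mv.ref and cand.other_allele == mv.alt:
                rec, sign = cand, -1.0
        if rec is None:
            report["n_mismatch"] += 1
            report["missing_ids"].append(mv.variant_id)
            continue
        if sign < 0:
            report["n_flipped"] += 1
        beta = sign * float(rec.beta)
        se = float(rec.se)
        if se <= 0 or not np.isfinite(beta / se):
            raise ValueError(f"non-positive se or non-finite z for "
                             f"{mv.variant_id}")
        out_rows.append({"variant_id": mv.variant_id,
                         "effect_allele": mv.alt, "other_allele": mv.ref,
                         "beta": beta, "se": se, "z": beta / se,
                         "n": getattr(rec, "n", np.nan)})
        report["n_matched"] += 1
    harmonized = pd.DataFrame(
        out_rows, columns=["variant_id", "effect_allele", "other_allele",
                           "beta", "se", "z", "n"]).set_index("variant_id")
    return harmonized, report


# ---------------------------------------------------------------------------
# model database tables

def write_model_db(db, weights_path, summary_path) -> None:
    weights, summary = db.to_frames()
    write_table(weights, weights_path)
    write_table(summary, summary_path)


def read_model_db(weights_path, summary_path):
    from .models import ModelDB
    return ModelDB.from_frames(read_table(weights_path),
                               read_table(summary_path))
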