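"""Stage orchestration: simulate -> preprocess -> train -> associate ->
compare, each re-runnable in isolation from persisted tab-separated
intermediates, with a machine-readable JSON run log per stage.

Every tunable threshold lives in :class:`RunConfig` with the analysis
defaults (MAF filter 0.05, outlier alpha 0.001, FDR 0.05, 1 Mb cis flank,
external-model predictive-p filter 0.05); nothing is hard-coded in the
stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as oio
from . import preprocess as prep
from .models import ModelDB, model_significance, train_layer
from .assoc import association_scan, table1_report
from .concordance import tissue_concordance
from .simulate import (PROTEIN_LAYER, SimConfig, gene_annotations,
                       simulate_covariates, simulate_genotypes,
                       simulate_omics, simulate_trait_and_gwas)

STAGES = ("simulate", "preprocess", "train", "associate", "compare")


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    maf_threshold: float = 0.05
    n_pcs: int = 10
    n_surrogates: int = 10
    outlier_alpha: float = 0.001
    int_offset: float = 0.5
    flank: int = 1_000_000
    l1_ratio: float = 0.5
    n_folds: int = 10
    model_filter_p: float = 0.05
    fdr_level: float = 0.05
    trait_names: tuple[str, ...] = ("trait",)
    layer: str | None = None      # restrict preprocess/train to one layer
    out_dir: str = "omixwas_run"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "trait_names" in raw:
            raw["trait_names"] = tuple(raw["trait_names"])
        return cls(sim=sim, **raw)

    def with_seed(self, seed: int) -> "RunConfig":
        cfg = dataclasses.replace(self)
        cfg.sim = dataclasses.replace(self.sim, seed=seed)
        return cfg


def _hash(path: Path) -> str:
    return hashlib.md5(path.read_bytes()).hexdigest()


def _need(out: Path, *names: str) -> None:
    for name in names:
        if not (out / name).exists():
            raise FileNotFoundError(
                f"missing upstream output {out / name}; run the producing "
                "stage first")


def _write_log(out: Path, stage: str, config: RunConfig, inputs: list[str],
               counts: dict) -> None:
    log = {"stage": stage, "seed": config.sim.seed,
           "params": {k: v for k, v in dataclasses.asdict(config).items()
                      if k != "sim"},
           "sim": dataclasses.asdict(config.sim),
           "input_hashes": {n: _hash(out / n) for n in inputs
                            if (out / n).exists()},
           "counts": counts}
    log["params"]["trait_names"] = list(config.trait_names)
    log["sim"]["maf_range"] = list(config.sim.maf_range)
    with open(out / f"log_{stage}.json", "w") as fh:
        json.dump(log, fh, indent=1, default=str)


def stage_simulate(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.sim
    variants, dosages = simulate_genotypes(sim)
    anno = gene_annotations(sim)
    cov = simulate_covariates(sim, dosages.index)
    omics, truth = simulate_omics(sim, variants, dosages, cov)
    oio.write_vcf(variants, dosages, out / "genotypes.vcf")
    oio.write_table(variants, out / "variants.tsv")
    oio.write_table(anno, out / "annotations.tsv")
    oio.write_matrix(cov, out / "covariates.tsv")
    for layer, mat in omics.items():
        oio.write_matrix(mat, out / f"omics_{layer.replace(':', '_')}.tsv")
    with open(out / "layers.json", "w") as fh:
        json.dump(sorted(omics), fh)
    traits = {}
    for i, name in enumerate(config.trait_names):
        trait, gwas = simulate_trait_and_gwas(sim, truth, variants,
                                              trait_name=name, stream=i)
        oio.write_table(trait, out / f"trait_{name}.tsv")
        oio.write_table(gwas, out / f"gwas_{name}.tsv")
        traits[name] = len(gwas)
    oio.write_table(truth.to_table(), out / "truth.tsv")
    counts = {"n_variants": len(variants), "n_samples": len(dosages),
              "n_layers": len(omics), "gwas_variants_per_trait": traits}
    _write_log(out, "simulate", config, [], counts)
    return counts


def stage_preprocess(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    _need(out, "covariates.tsv", "layers.json")
    cov = oio.read_matrix(out / "covariates.tsv")
    layers = json.load(open(out / "layers.json"))
    if config.layer is not None:
        layers = [lay for lay in layers if lay == config.layer]
    counts = {}
    for layer in layers:
        fname = f"omics_{layer.replace(':', '_')}.tsv"
        _need(out, fname)
        mat = oio.read_matrix(out / fname)
        resid, retained, log = prep.preprocess_layer(
            mat, cov, n_pcs=config.n_pcs, n_surrogates=config.n_surrogates,
            outlier_alpha=config.outlier_alpha, int_offset=config.int_offset)
        oio.write_matrix(resid, out / f"residuals_{layer.replace(':', '_')}.tsv")
        pd.Series(retained).to_csv(
            out / f"retained_{layer.replace(':', '_')}.tsv", sep="\t",
            index=False, header=["sample_id"])
        counts[layer] = log
    _write_log(out, "preprocess", config,
               ["covariates.tsv"], counts)
    return counts


def stage_train(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    _need(out, "genotypes.vcf", "annotations.tsv", "layers.json")
    variants, dosages = oio.load_dosages(out / "genotypes.vcf",
                                         config.maf_threshold)
    anno = oio.read_table(out / "annotations.tsv")
    layers = json.load(open(out / "layers.json"))
    first_trait = config.trait_names[0]
    _need(out, f"gwas_{first_trait}.tsv")
    gwas = oio.read_table(out / f"gwas_{first_trait}.tsv")
    harmonized, report = oio.harmonize_gwas(variants, gwas)
    if config.layer is not None:
        layers = [lay for lay in layers if lay == config.layer]
    merged = ModelDB(meta={"seed": config.sim.seed,
                           "harmonization": {k: v for k, v in report.items()
                                             if k != "missing_ids"}})
    counts = {}
    for layer in layers:
        fname = f"residuals_{layer.replace(':', '_')}.tsv"
        _need(out, fname)
        resid = oio.read_matrix(out / fname)
        db = train_layer(resid, variants, dosages, anno, layer,
                         gwas_variant_ids=harmonized.index,
                         flank=config.flank, l1_ratio=config.l1_ratio,
                         n_folds=config.n_folds, seed=config.sim.seed)
        for m in db.models.values():
            merged.add(m)
        counts[layer] = {"n_models": len(db), "n_trivial": db.meta["n_trivial"]}
    model_significance(merged, config.fdr_level)
    oio.write_model_db(merged, out / "model_weights.tsv",
                       out / "model_summary.tsv")
    _write_log(out, "train", config, ["genotypes.vcf"], counts)
    return counts


def stage_associate(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    _need(out, "model_weights.tsv", "model_summary.tsv", "genotypes.vcf")
    db = oio.read_model_db(out / "model_weights.tsv", out / "model_summary.tsv")
    variants, dosages = oio.load_dosages(out / "genotypes.vcf",
                                         config.maf_threshold)
    gwas_by_trait = {}
    for name in config.trait_names:
        _need(out, f"gwas_{name}.tsv")
        gwas = oio.read_table(out / f"gwas_{name}.tsv")
        gwas_by_trait[name], _ = oio.harmonize_gwas(variants, gwas)
    results = association_scan(db, gwas_by_trait, dosages,
                               reference_variants=variants,
                               fdr_level=config.fdr_level)
    oio.write_table(results, out / "associations.tsv")
    report = table1_report(results)
    report.to_csv(out / "association_report.tsv", sep="\t")
    counts = {"n_results": len(results),
              "n_significant": int(results["significant"].sum())}
    _write_log(out, "associate", config, ["model_weights.tsv"], counts)
    return counts


def stage_compare(config: RunConfig) -> dict:
    out = Path(config.out_dir)
    assoc_path = out / "associations.tsv"
    if not assoc_path.exists():
        raise FileNotFoundError(
            f"missing association table {assoc_path}; run the associate "
            "stage first")
    results = oio.read_table(assoc_path)
    counts = {}
    frames = []
    for trait in config.trait_names:
        sub = results[results["trait"] == trait]
        if sub["layer"].nunique() < 2:
            counts[trait] = "skipped (single layer)"
            continue
        conc = tissue_concordance(sub, trait=trait,
                                  protein_layer=PROTEIN_LAYER)
        frames.append(conc)
        counts[trait] = {"n_contexts": len(conc),
                         "n_positive": int(conc["n_positive"].iloc[0])
                         if not conc.empty else 0}
    if frames:
        oio.write_table(pd.concat(frames, ignore_index=True),
                        out / "concordance.tsv")
    from .concordance import signed_logp_matrix
    mat = signed_logp_matrix(results)
    mat.to_csv(out / "signed_logp_wide.tsv", sep="\t")
    _write_log(out, "compare", config, ["associations.tsv"], counts)
    return counts


_STAGE_FN = {"simulate": stage_simulate, "preprocess": stage_preprocess,
             "train": stage_train, "associate": stage_associate,
             "compare": stage_compare}


def run_stage(name: str, config: RunConfig) -> dict:
    if name == "all":
        return {s: _STAGE_FN[s](config) for s in STAGES}
    if name not in _STAGE_FN:
        raise ValueError(f"unknown stage {name!r}; choose from {STAGES}")
    return _STAGE_FN[name](config)
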