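"""Configuration, file formats, and end-to-end pipeline orchestration.

Every stage reads and writes plain-text formats (CSV/TSV/VCF/JSON); a run
directory gains a manifest recording content hashes of every artifact, so a
re-run with the same configuration and seed is verifiably identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cv import cv_summary_table, run_cv_year, whole_dataset_reference
from .genotypes import (GenotypeMatrix, QCReport, grm_vanraden1,
                        impute_naive, ld_r2_window, qc_inbreds)
from .gradient import fit_baseline_blup, qc_phenotypes, scale_gradient
from .gwas import backsolve_snp_effects, select_top_snps, snp_env_effects
from .merit import build_features, fit_merit_model, predict_merit
from .params import gebv_trajectories, genetic_params
from .rnm import ModelSpec, compare_models, fit_rnm
from .simulate import (SimulationConfig, hybrids_from_crosses, make_hybrids,
                       simulate_env_covariates, simulate_parents,
                       simulate_trial)

logger = logging.getLogger("reactnorm")

__all__ = ["PipelineConfig", "run_pipeline", "read_genotypes",
           "write_vcf", "read_vcf"]


@dataclass
class PipelineConfig:
    """Run settings: stage toggles plus per-stage parameters."""

    out_dir: str = "reactnorm_run"
    seed: int = 0
    stages: list = field(default_factory=lambda: [
        "simulate", "qc", "gradient", "fit", "params", "gwas", "merit", "cv"])
    simulation: SimulationConfig | None = None
    # genotype QC
    maf_min: float = 0.01
    miss_max: float = 0.05
    grm_blend: float = 0.01
    ld_window_snps: int = 100
    ld_threshold: float = 0.2
    # phenotype QC
    sd_limit: float = 3.0
    repeatability_min: float = 0.1
    # model
    run_ladder: bool = True
    order: int = 2
    residual: str = "heterogeneous"
    include_be: bool = True
    # gwas
    top_k: int = 5
    # merit model
    merit_trees: tuple = (250, 500, 1000)
    # external inputs (used when the simulate stage is off)
    phenotype_csv: str | None = None
    genotype_tsv: str | None = None
    weather_csv: str | None = None
    soil_csv: str | None = None

    def __post_init__(self):
        if self.simulation is None:
            self.simulation = SimulationConfig(seed=self.seed)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        sim = d.pop("simulation", None)
        cfg = cls(**{k: v for k, v in d.items()
                     if k in {f.name for f in dataclasses.fields(cls)}})
        if sim is not None:
            sim["C_a"] = np.array(sim["C_a"])
            sim["C_be"] = np.array(sim["C_be"])
            sim["merit_range"] = tuple(sim["merit_range"])
            cfg.simulation = SimulationConfig(**sim)
        return cfg


# ---------------------------------------------------------------------------
# genotype file formats
# ---------------------------------------------------------------------------

def read_genotypes(path, fmt: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix from 0/1/2 TSV or VCF."""
    if fmt in ("tsv", "tsv-012"):
        return GenotypeMatrix.from_tsv(path)
    if fmt == "vcf":
        return read_vcf(path)
    raise ValueError(f"unknown genotype format {fmt!r}")


def read_vcf(path) -> GenotypeMatrix:
    """Read GT fields from a VCF; values are counts of the REF allele.

    Multi-allelic sites are kept but flagged non-biallelic so that genotype
    QC removes them.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    ids, chroms, pos, bial, rows = [], [], [], [], []
    for var in vcf:
        ids.append(var.ID or f"S{var.CHROM}_{var.POS}")
        chroms.append(str(var.CHROM))
        pos.append(int(var.POS))
        bial.append(len(var.ALT) <= 1)
        gts = var.genotype.array()[:, :2]
        missing = (gts < 0).any(axis=1)
        ref_count = (gts == 0).sum(axis=1).astype(float)
        ref_count[missing] = np.nan
        rows.append(ref_count)
    snps = pd.DataFrame({"snp_id": ids, "chrom": chroms, "pos": pos,
                         "biallelic": bial})
    return GenotypeMatrix(samples, snps, np.array(rows).T)


def write_vcf(matrix: GenotypeMatrix, path) -> None:
    """Write a minimal VCF 4.2 with the counted allele as REF."""
    gt_code = {2.0: "0/0", 1.0: "0/1", 0.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description='
                 '"Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(matrix.samples) + "\n")
        for k, snp in matrix.snps.iterrows():
            calls = [gt_code.get(v, "./.") for v in matrix.values[:, k]]
            fh.write(f"{snp['chrom']}\t{snp['pos']}\t{snp['snp_id']}\t"
                     f"A\tC\t.\tPASS\t.\tGT\t" + "\t".join(calls) + "\n")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the configured stages in dependency order.

    Returns the manifest: per-stage artifact paths with content hashes.
    Stage failures raise immediately; artifacts of completed stages remain
    on disk.
    """
    cfg = config
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"version": __version__, "seed": cfg.seed, "stages": {}}
    art: dict = {}

    def record(stage: str, name: str, path: Path):
        manifest["stages"].setdefault(stage, {})[name] = {
            "path": str(path), "sha256": _sha256(path)}

    stages = list(cfg.stages)
    if "simulate" not in stages:
        for need, label in ((cfg.phenotype_csv, "phenotype_csv"),
                            (cfg.genotype_tsv, "genotype_tsv")):
            if need is None or not Path(need).exists():
                raise FileNotFoundError(
                    f"{label} required (and must exist) when the simulate "
                    f"stage is off: {need!r}")

    # ---- simulate -------------------------------------------------------
    if "simulate" in stages:
        logger.info("stage simulate")
        sim = cfg.simulation
        parents, _ = simulate_parents(sim.n_parents, sim.n_snps,
                                      seed=sim.seed)
        cross, hybrids = make_hybrids(parents, sim.n_hybrids,
                                      seed=sim.seed + 1)
        pheno, truth = simulate_trial(hybrids, sim)
        weather, soil = simulate_env_covariates(
            truth.true_merit, sim.covariate_noise, seed=sim.seed + 2)
        parents.to_tsv(out / "parents.tsv")
        write_vcf(parents, out / "parents.vcf")
        hybrids.to_tsv(out / "hybrids.tsv")
        cross.to_csv(out / "crosses.csv", index=False)
        pheno.to_csv(out / "phenotypes.csv", index=False)
        weather.to_csv(out / "weather_daily.csv", index=False)
        soil.to_csv(out / "soil.csv", index=False)
        for name in ("parents.tsv", "parents.vcf", "hybrids.tsv",
                     "crosses.csv", "phenotypes.csv", "weather_daily.csv",
                     "soil.csv"):
            record("simulate", name, out / name)
        art.update(pheno=pheno, parents=parents, crosses=cross,
                   hybrids=hybrids, weather=weather, soil=soil, truth=truth)
    else:
        art["pheno"] = pd.read_csv(cfg.phenotype_csv)
        art["hybrids"] = read_genotypes(cfg.genotype_tsv)
        if cfg.weather_csv:
            art["weather"] = pd.read_csv(cfg.weather_csv)
        if cfg.soil_csv:
            art["soil"] = pd.read_csv(cfg.soil_csv)

    # ---- qc -------------------------------------------------------------
    if "qc" in stages:
        logger.info("stage qc")
        pheno_qc, prep = qc_phenotypes(art["pheno"], sd_limit=cfg.sd_limit,
                                       repeatability_min=cfg.repeatability_min)
        if "parents" in art:
            # inbred-panel QC, naive imputation, then hybrid assembly
            par_qc, grep = qc_inbreds(art["parents"], maf_min=cfg.maf_min,
                                      miss_max=cfg.miss_max)
            par_qc = impute_naive(par_qc, inbred=True)
            geno = hybrids_from_crosses(par_qc, art["crosses"])
        else:
            # externally supplied hybrid matrix: assumed already QC'd at the
            # inbred level; orient and complete it
            geno = art["hybrids"].orient_major()
            geno = impute_naive(geno, inbred=False)
            grep = QCReport(n_snps_in=geno.n_snps, n_snps_out=geno.n_snps)
        pheno_qc.to_csv(out / "phenotypes_qc.csv", index=False)
        grep.to_json(out / "genotype_qc.json")
        with open(out / "phenotype_qc.json", "w") as fh:
            json.dump(dataclasses.asdict(prep), fh, indent=2, default=str)
        for name in ("phenotypes_qc.csv", "genotype_qc.json",
                     "phenotype_qc.json"):
            record("qc", name, out / name)
        art.update(pheno_qc=pheno_qc, geno=geno)
    else:
        art.setdefault("pheno_qc", art["pheno"])
        art.setdefault("geno", art["hybrids"])

    grm = grm_vanraden1(art["geno"], blend=cfg.grm_blend)
    ld_table, ld_summary = ld_r2_window(art["geno"],
                                        window_snps=cfg.ld_window_snps)

    # ---- gradient -------------------------------------------------------
    if "gradient" in stages:
        logger.info("stage gradient")
        fit1 = fit_baseline_blup(art["pheno_qc"])
        grad = scale_gradient(fit1.beta)
        grad.to_csv(out / "gradient.csv")
        record("gradient", "gradient.csv", out / "gradient.csv")
        art["gradient"] = grad

    # ---- fit ------------------------------------------------------------
    if "fit" in stages:
        logger.info("stage fit")
        if cfg.run_ladder:
            cmp = compare_models(art["pheno_qc"], art["gradient"], grm)
            cmp.table.to_csv(out / "model_comparison.csv", index=False)
            record("fit", "model_comparison.csv", out / "model_comparison.csv")
            fit = cmp.best_fit
        else:
            fit = fit_rnm(art["pheno_qc"], art["gradient"], grm,
                          ModelSpec(order=cfg.order, residual=cfg.residual,
                                    include_be=cfg.include_be))
        fit.a_hat.to_csv(out / "coefficients_additive.csv")
        pd.DataFrame(fit.C_a).to_csv(out / "C_additive.csv", index=False)
        with open(out / "fit_summary.json", "w") as fh:
            json.dump({"logL": fit.logL, "n_iter": fit.n_iter,
                       "spec": fit.spec.label(),
                       "d0": fit.residual.d0, "d1": fit.residual.d1},
                      fh, indent=2)
        for name in ("coefficients_additive.csv", "C_additive.csv",
                     "fit_summary.json"):
            record("fit", name, out / name)
        art["fit"] = fit

    # ---- params ---------------------------------------------------------
    if "params" in stages:
        logger.info("stage params")
        gp = genetic_params(art["fit"])
        gp.to_frame().to_csv(out / "genetic_params.csv", index=False)
        pd.DataFrame(gp.R, index=gp.env_ids, columns=gp.env_ids).to_csv(
            out / "genetic_correlation.csv")
        gebv = gebv_trajectories(art["fit"].a_hat, T=art["fit"].T,
                                 env_ids=art["fit"].env_ids)
        gebv.to_csv(out / "gebv.csv")
        for name in ("genetic_params.csv", "genetic_correlation.csv",
                     "gebv.csv"):
            record("params", name, out / name)
        art["gp"] = gp

    # ---- gwas -----------------------------------------------------------
    if "gwas" in stages:
        logger.info("stage gwas")
        geno = art["geno"]
        p = geno.allele_freq
        Z = geno.values - 2.0 * p
        u = backsolve_snp_effects(Z, art["fit"].a_hat,
                                  snp_ids=geno.snps["snp_id"])
        eff = snp_env_effects(u, T=art["fit"].T,
                              env_ids=art["fit"].env_ids)
        sel = select_top_snps(eff, k=cfg.top_k, ld_table=ld_table,
                              ld_threshold=cfg.ld_threshold,
                              snp_meta=geno.snps)
        long = eff.stack().rename("effect").reset_index()
        long.columns = ["snp_id", "env_id", "effect"]
        long.to_csv(out / "snp_env_effects.csv", index=False)
        with open(out / "selected_snps.json", "w") as fh:
            json.dump(sel, fh, indent=2)
        for name in ("snp_env_effects.csv", "selected_snps.json"):
            record("gwas", name, out / name)
        art.update(snp_effects=eff, selection=sel)

    # ---- merit ----------------------------------------------------------
    if "merit" in stages and "weather" in art:
        logger.info("stage merit")
        feats = build_features(art["weather"], art["soil"])
        theta = pd.Series(art["gradient"].theta_map())
        common = [e for e in feats.env_ids if e in theta.index]
        mm = fit_merit_model(feats.table.loc[common], theta.loc[common],
                             seed=cfg.seed, n_trees_grid=cfg.merit_trees)
        pred = predict_merit(mm, feats.table)
        pred.to_csv(out / "merit_predictions.csv")
        with open(out / "merit_model.json", "w") as fh:
            json.dump({"best_params": mm.best_params,
                       "cv_rmse": mm.cv_rmse,
                       "cv_correlation": mm.cv_correlation}, fh, indent=2)
        for name in ("merit_predictions.csv", "merit_model.json"):
            record("merit", name, out / name)
        art["merit_model"] = mm

    # ---- cv -------------------------------------------------------------
    if "cv" in stages:
        logger.info("stage cv")
        pheno_qc = art["pheno_qc"]
        whole, _, _ = whole_dataset_reference(
            pheno_qc, grm, ModelSpec(order=cfg.order, residual=cfg.residual))
        results = []
        years = sorted(pheno_qc["year"].unique())
        for year in years:
            for arm in ("RNM", "GBLUP"):
                try:
                    results.extend(run_cv_year(
                        pheno_qc, grm, year, model_arm=arm,
                        schemes=("CV0", "CV00"),
                        references=("single_env_blup", "whole_dataset"),
                        weather=art.get("weather"), soil=art.get("soil"),
                        whole_gebv=whole, seed=cfg.seed,
                        merit_kwargs={"n_trees_grid": cfg.merit_trees}))
                except ValueError as err:
                    logger.warning("cv year skipped (%s %s): %s",
                                   year, arm, err)
        table = cv_summary_table(results)
        table.to_csv(out / "cv_results.csv", index=False)
        record("cv", "cv_results.csv", out / "cv_results.csv")
        art["cv_table"] = table

    cfg.to_yaml(out / "config.yaml")
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return manifest
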