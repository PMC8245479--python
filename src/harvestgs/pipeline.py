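"""End-to-end orchestration: simulate (optional) -> QC -> per-harvest
cross-validation -> selection metrics -> cross-harvest transfer.

Every run writes a manifest (inputs, seed, package version, per-file
SHA-256 checksums) and a human-readable report; rerunning with the same
config and seed reproduces all numeric outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import RunConfig
from .containers import GenotypeMatrix
from .cv import cross_validate
from .io import (
    detect_and_read_genotypes,
    read_phenotypes,
    write_genotype_tsv,
    write_phenotypes,
    write_vcf,
)
from .metrics import build_metrics_report, narrow_and_genomic_h2
from .qc import apply_qc, impute_and_standardize
from .rrblup import build_design, estimate_variance_components
from .simulate import simulate_genotypes, simulate_phenotypes
from .transfer import transfer_accuracy

logger = logging.getLogger("harvestgs")

__all__ = ["run_pipeline"]


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: RunConfig) -> Path:
    """Execute all stages and return the run directory."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stages: list[str] = []
    written: list[Path] = []
    summary: dict = {"seed": config.seed, "version": __version__}

    # -- stage 1: data -----------------------------------------------------
    if config.simulation is not None:
        logger.info("stage simulate: %d progeny x %d markers x %d harvests",
                    config.simulation.n_progeny, config.simulation.n_markers,
                    config.simulation.n_harvests)
        sim = simulate_genotypes(config.simulation)
        pheno, truth = simulate_phenotypes(sim, config.simulation)
        genotypes = sim.genotypes
        write_vcf(genotypes, out / "genotypes.vcf")
        write_genotype_tsv(genotypes, out / "genotypes.tsv")
        write_phenotypes(pheno, out / "phenotypes.csv")
        truth.true_breeding_values.to_csv(out / "true_breeding_values.csv")
        truth.causal_effects.to_csv(out / "true_causal_effects.csv")
        truth.parent_assignments.to_csv(out / "parent_assignments.csv", index=False)
        written += [out / f for f in (
            "genotypes.vcf", "genotypes.tsv", "phenotypes.csv",
            "true_breeding_values.csv", "true_causal_effects.csv", "parent_assignments.csv")]
        stages.append("simulate")
    else:
        logger.info("stage load: %s, %s", config.genotype_path, config.phenotype_path)
        genotypes = detect_and_read_genotypes(config.genotype_path)
        pheno = read_phenotypes(config.phenotype_path)
        stages.append("load")

    harvests = sorted(pheno["harvest"].unique())

    # -- stage 2: QC -------------------------------------------------------
    geno_qc, qc_report = apply_qc(genotypes, config.qc)
    qc_report.per_marker.to_csv(out / "qc_report.csv", index=False)
    written.append(out / "qc_report.csv")
    write_genotype_tsv(geno_qc, out / "genotypes_qc.tsv")
    written.append(out / "genotypes_qc.tsv")
    summary["qc"] = {
        "n_input_markers": qc_report.n_input_markers,
        "n_failed_call_rate": qc_report.n_failed_call_rate,
        "n_failed_maf": qc_report.n_failed_maf,
        "n_retained": qc_report.n_retained,
        "maf_min_applied": qc_report.maf_min,
    }
    logger.info("stage qc: %d -> %d markers", qc_report.n_input_markers, qc_report.n_retained)
    stages.append("qc")

    # -- stage 3: per-harvest CV (plus mean yield) ------------------------
    cv_summaries = {}
    cv_results = {}
    scopes: list[int | None] = list(harvests) + ([None] if len(harvests) > 1 else [])
    for h in scopes:
        label = f"harvest{h}" if h is not None else "mean_yield"
        res = cross_validate(
            geno_qc, pheno, harvest=h, k=config.k_folds, seed=config.seed,
            aggregate=config.aggregate,
        )
        cv_results[h] = res
        res.oof_gebv.to_csv(out / f"cv_gebv_{label}.csv")
        written.append(out / f"cv_gebv_{label}.csv")
        cv_summaries[label] = {
            "r_yg": res.r_yg,
            "k": res.fold_plan.k,
            "mean_h2": float(np.mean([f["h2"] for f in res.per_fold])),
        }
        logger.info("stage cv %s: r_yg = %.3f", label, res.r_yg)
    summary["cross_validation"] = cv_summaries
    stages.append("cv")

    # -- stage 4: metrics --------------------------------------------------
    Z, _ = impute_and_standardize(geno_qc)
    metric_summaries = {}
    for h in scopes:
        label = f"harvest{h}" if h is not None else "mean_yield"
        spec = build_design(pheno, h, geno_qc.individuals, Z, aggregate=config.aggregate)
        vc = estimate_variance_components(spec)
        her = narrow_and_genomic_h2(vc)
        if config.aggregate == "records":
            # r_yg is a correlation with entry-mean phenotypes, so the
            # accuracy denominator uses heritability on the same scale:
            # h2_mean = s2g / (s2g + s2e / n_replicates)
            sub = pheno if h is None else pheno[pheno["harvest"] == h]
            n_rep = len(sub) / sub["individual"].nunique()
            denom = vc.sigma2_g + vc.sigma2_e / n_rep
            h2_mean = min(vc.sigma2_g / denom, 1.0) if denom > 0 else 0.0
            her = narrow_and_genomic_h2(vc, h2_g=h2_mean)
            her.h2_a = h2_mean
        r_yg = cv_results[h].r_yg
        if not np.isfinite(r_yg) or r_yg <= 0:
            logger.warning("metrics %s skipped: predictive ability undefined", label)
            continue
        report = build_metrics_report(
            r_yg=r_yg,
            h=her,
            n_individuals=geno_qc.n_individuals,
            pheno=pheno,
            harvest=h,
            t_phenotypic=config.t_phenotypic,
            t_gws=config.t_gws,
            desired=tuple(config.desired_accuracies),
            scale=config.ni_scale,
        )
        report.ni.to_csv(out / f"ni_table_{label}.csv", index=False)
        written.append(out / f"ni_table_{label}.csv")
        metric_summaries[label] = {**report.to_dict(), "h2_record_scale": vc.h2}
    summary["metrics"] = metric_summaries
    stages.append("metrics")

    # -- stage 5: transfers ------------------------------------------------
    transfer_summaries = {}
    pairs = [(i, j) for i in harvests for j in harvests if i <= j]
    for i, j in pairs:
        res = transfer_accuracy(
            geno_qc, pheno, i, j, k=config.k_folds, seed=config.seed,
            aggregate=config.aggregate, target="ebv",
        )
        key = f"{i}->{j}"
        transfer_summaries[key] = res.transfer_accuracy
        res.scatter.to_csv(out / f"transfer_{i}_{j}.csv", index=False)
        written.append(out / f"transfer_{i}_{j}.csv")
        logger.info("stage transfer %s: r = %.3f", key, res.transfer_accuracy)
    summary["transfer"] = transfer_summaries
    stages.append("transfer")

    # -- manifest + report -------------------------------------------------
    summary_path = out / "summary.json"
    with open(summary_path, "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True, default=_json_default)
    written.append(summary_path)

    manifest = {
        "stages": stages,
        "seed": config.seed,
        "version": __version__,
        "elapsed_seconds": round(time.time() - t0, 2),
        "inputs": {
            "simulated": config.simulation is not None,
            "genotype_path": config.genotype_path,
            "phenotype_path": config.phenotype_path,
        },
        "files": {p.name: _sha256(p) for p in written},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    lines = [
        f"harvestgs run (seed {config.seed})",
        f"markers: {qc_report.n_input_markers} -> {qc_report.n_retained} after QC "
        f"(call rate >= {config.qc.call_rate_min}, MAF > {qc_report.maf_min:.4f})",
        "",
        "predictive ability (tenfold CV):",
    ]
    for label, cvs in cv_summaries.items():
        lines.append(f"  {label}: r_yg = {cvs['r_yg']:.3f}")
    lines.append("")
    lines.append("transfer accuracies (train->test, GEBV vs EBV):")
    for key, acc in transfer_summaries.items():
        lines.append(f"  {key}: r = {acc:.3f}")
    (out / "report.txt").write_text("\n".join(lines) + "\n")
    return out
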