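"""End-to-end pipeline: config-driven staging of simulate/qc/train/cas/map.

A single YAML config names the inputs, the stages to run and their
parameters; one seed drives every source of randomness, so two runs of the
same config produce byte-identical result tables.
"""

from __future__ import annotations

import logging
from dataclasses import replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import expression as eqc
from . import gkm, mapping, pre
from .io import (
    align_samples,
    load_genes,
    load_genotypes,
    load_peaks,
    open_genome,
    read_matrix,
    write_matrix,
)

logger = logging.getLogger("eqtac")

_KNOWN_TOP = {"seed", "outdir", "stages", "inputs", "simulate", "qc", "train", "cas", "map"}
_KNOWN_INPUTS = {"genome", "vcf", "peaks", "counts", "tpm", "covariates", "genes",
                 "exclude_regions"}
_KNOWN_QC = {"outlier_threshold", "exclude_self", "tpm_min", "count_min", "sample_frac"}
_KNOWN_TRAIN = {"l", "k", "d", "folds", "width", "negative_ratio", "pad", "collapse_revcomp"}
_KNOWN_CAS = {"flank", "ld_r2", "min_gap", "maf_min", "radius"}
_KNOWN_MAP = {"n_perm", "fdr", "cis_window", "n_hidden_factors", "nominal_eqtl"}
_ALL_STAGES = ["simulate", "qc", "train", "cas", "map"]


def _check_keys(section: dict, known: set, where: str) -> None:
    for key in section:
        if key not in known:
            raise ValueError(f"unknown config key {key!r} in {where}")


def _validate(cfg: dict) -> dict:
    _check_keys(cfg, _KNOWN_TOP, "top level")
    _check_keys(cfg.get("inputs", {}) or {}, _KNOWN_INPUTS, "inputs")
    _check_keys(cfg.get("qc", {}) or {}, _KNOWN_QC, "qc")
    _check_keys(cfg.get("train", {}) or {}, _KNOWN_TRAIN, "train")
    _check_keys(cfg.get("cas", {}) or {}, _KNOWN_CAS, "cas")
    _check_keys(cfg.get("map", {}) or {}, _KNOWN_MAP, "map")
    return cfg


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return _validate(cfg)


def run_pipeline(config, outdir=None, seed=None) -> dict:
    """Execute the requested stages; returns paths of the written tables.

    ``config`` is a path to a YAML file or an already-loaded dict.
    """
    if not isinstance(config, dict):
        config = load_config(config)
    else:
        _validate(config)
    seed = int(config.get("seed", 0) if seed is None else seed)
    out = Path(outdir or config.get("outdir", "eqtac_out"))
    out.mkdir(parents=True, exist_ok=True)
    stages = config.get("stages", _ALL_STAGES)
    inputs = dict(config.get("inputs", {}) or {})
    written: dict[str, str] = {}

    if "simulate" in stages:
        from .simulate import SimConfig, simulate

        sim_cfg = SimConfig(seed=seed, **(config.get("simulate") or {}))
        sim = simulate(sim_cfg)
        simdir = out / "sim"
        sim.write(simdir)
        logger.info("simulated cohort written to %s", simdir)
        inputs = {
            "genome": simdir / "genome.fa",
            "vcf": simdir / "genotypes.vcf",
            "peaks": simdir / "peaks.narrowPeak",
            "counts": simdir / "counts.tsv",
            "tpm": simdir / "tpm.tsv",
            "covariates": simdir / "covariates.tsv",
            "genes": simdir / "genes.tsv",
        }
        written["sim"] = str(simdir)

    need_data = any(s in stages for s in ("qc", "train", "cas", "map"))
    if not need_data:
        return written
    for key in ("genome", "vcf", "peaks", "counts", "tpm", "genes"):
        if key not in inputs:
            raise ValueError(f"missing required input {key!r}")
        if not Path(inputs[key]).exists():
            raise FileNotFoundError(f"input {key!r} not found: {inputs[key]}")

    cas_cfg = config.get("cas") or {}
    genome = open_genome(inputs["genome"])
    geno = load_genotypes(inputs["vcf"], maf_min=cas_cfg.get("maf_min", 0.05))
    logger.info(
        "loaded %d SNPs (%d excluded, %d below MAF, %d high-missingness)",
        len(geno.variants), len(geno.excluded), geno.n_maf_filtered,
        geno.n_missingness_filtered,
    )
    if "exclude_regions" in inputs and inputs["exclude_regions"]:
        regions = load_peaks(inputs["exclude_regions"])
        before = len(geno.variants)
        geno.variants = [
            v for v in geno.variants
            if not any(r.chrom == v.chrom and r.start <= v.pos < r.end for r in regions)
        ]
        logger.info("excluded-region filter removed %d SNPs", before - len(geno.variants))
    peaks = load_peaks(inputs["peaks"])
    counts = read_matrix(inputs["counts"])
    tpm = read_matrix(inputs["tpm"])
    genes = load_genes(inputs["genes"])
    if inputs.get("covariates"):
        covariates = read_matrix(inputs["covariates"])
    else:
        covariates = pd.DataFrame(columns=counts.columns)  # intercept-only
        logger.info("no covariates supplied; proceeding with intercept only")

    samples = align_samples(geno.samples, list(counts.columns),
                            list(covariates.columns) if covariates.shape[0] else geno.samples)
    counts, tpm = counts.loc[:, samples], tpm.loc[:, samples]
    if covariates.shape[0]:
        covariates = covariates.loc[:, samples]

    qc_cfg = config.get("qc") or {}
    if "qc" in stages:
        log_tpm = np.log2(tpm + 1.0)
        report = eqc.correlation_outlier_stat(
            log_tpm,
            threshold=qc_cfg.get("outlier_threshold", -5.0),
            exclude_self=qc_cfg.get("exclude_self", False),
        )
        qc_path = out / "qc_report.tsv"
        report.table.to_csv(qc_path, sep="\t", index_label="sample_id")
        written["qc_report"] = str(qc_path)
        keep = [s for s in samples if s not in report.outliers]
        logger.info("QC flagged %d outlier samples", len(report.outliers))
        samples = keep
        counts, tpm = counts.loc[:, samples], tpm.loc[:, samples]
        if covariates.shape[0]:
            covariates = covariates.loc[:, samples]
    expr = eqc.prepare_expression(
        counts, tpm,
        tpm_min=qc_cfg.get("tpm_min", 0.1),
        count_min=qc_cfg.get("count_min", 6),
        sample_frac=qc_cfg.get("sample_frac", 0.2),
    )
    logger.info("%d / %d genes pass expression filters", expr.shape[0], counts.shape[0])
    expr_path = out / "expression_int.tsv"
    write_matrix(expr, expr_path, "gene_id")
    written["expression"] = str(expr_path)

    model = None
    if "train" in stages:
        tr = config.get("train") or {}
        base = gkm.GkmParams(
            l=tr.get("l", 10), k=tr.get("k", 6), d=tr.get("d", 3),
            collapse_revcomp=tr.get("collapse_revcomp", True),
        )
        positives = gkm.extract_positive_set(genome, peaks, width=tr.get("width", 100))
        pad = tr.get("pad", 500)
        excluded_regions = [(p.chrom, p.start - pad, p.end + pad) for p in peaks]
        negatives = gkm.build_negative_set(
            genome, positives, excluded_regions,
            n_ratio=tr.get("negative_ratio", 1), seed=seed,
        )
        model = gkm.train_classifier(
            gkm.TrainingSet(positives, negatives),
            params_grid=base, folds=tr.get("folds", 3), seed=seed,
        )
        logger.info("trained model: CV AUC %.4f (C=%g)", model.cv_auc, model.params.C)
        model.save(out / "model_weights.tsv", out / "model.json")
        written["model"] = str(out / "model.json")

    if "cas" in stages or "map" in stages:
        if model is None:
            raise ValueError("cas/map stages require the train stage (or a model)")
        pres = pre.select_pres(
            peaks, geno.variants, geno.excluded,
            ld_r2=cas_cfg.get("ld_r2", 0.3), min_gap=cas_cfg.get("min_gap", 10),
            radius=cas_cfg.get("radius", 250),
        )
        table = pre.pre_table(pres)
        kept = [p for p in pres if p.kept]
        logger.info("PRE selection: %d kept / %d candidates (%s)", len(kept), len(pres),
                    table[table.drop_reason != ""].drop_reason.value_counts().to_dict())
        table.to_csv(out / "pre_table.tsv", sep="\t")
        written["pre_table"] = str(out / "pre_table.tsv")
        cas_df, score_df = pre.cas_matrix(
            pres, model, genome, geno.samples, flank=cas_cfg.get("flank", 9)
        )
        cas_df = cas_df.loc[:, samples]
        write_matrix(cas_df, out / "cas.tsv", "pre_id")
        score_df.to_csv(out / "allele_scores.tsv", sep="\t", index=False)
        written["cas"] = str(out / "cas.tsv")

    if "map" in stages:
        mp = config.get("map") or {}
        n_hidden = mp.get("n_hidden_factors", 0)
        cov_full = covariates
        if n_hidden:
            factors, _ = mapping.hidden_factors(expr, n_hidden)
            cov_full = pd.concat([covariates, factors]) if covariates.shape[0] else factors
        results, fdr_obj = mapping.map_eqtac(
            kept, genes, expr, cas_df, cov_full if cov_full.shape[0] else None,
            cis_window=mp.get("cis_window", 1e6),
            n_perm=mp.get("n_perm", 100), fdr=mp.get("fdr", 0.05), seed=seed,
        )
        logger.info(
            "eQTac mapping: %d pairs, p threshold %.3g, %d significant",
            len(results), fdr_obj.p_threshold, int(results["significant"].sum()),
        )
        results.to_csv(out / "eqtac_results.tsv", sep="\t", index=False,
                       float_format="%.12g")
        written["results"] = str(out / "eqtac_results.tsv")
        if mp.get("nominal_eqtl", False):
            dos = geno.dosage_matrix().loc[:, samples]
            vpos = {v.vid: (v.chrom, v.pos) for v in geno.variants}
            nom = mapping.nominal_cis_eqtl(
                dos, vpos, genes, expr, cov_full if cov_full.shape[0] else None,
                cis_window=mp.get("cis_window", 1e6),
            )
            nom.to_csv(out / "nominal_eqtl.tsv", sep="\t", index=False,
                       float_format="%.12g")
            written["nominal_eqtl"] = str(out / "nominal_eqtl.tsv")
    return written
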