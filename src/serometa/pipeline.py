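"""End-to-end orchestration: simulate -> preprocess -> differential
abundance -> set enrichment -> differential co-abundance.

A run is driven by one YAML config (paths, thresholds, covariates, seed) and
writes every stage's tables plus a manifest (config hash, seed, package
version, table checksums) into a run directory; rerunning with the same
config reproduces every stochastic output byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coabundance import DifferentialCoabundance
from .data_model import (
    AbundanceMatrix,
    read_abundance,
    read_annotation,
    read_metadata,
    validate_cohort,
    write_abundance,
    write_table,
)
from .differential_abundance import ModeratedDifferentialAbundance
from .preprocess import (
    filter_missingness,
    impute_minimum,
    missingness_outliers,
    pca_qc,
    quantile_normalize,
    scale_metabolites,
)
from .set_analysis import RotationSetTest, pc1_group_test
from .synthetic_data import SimConfig, CohortSimulator

log = logging.getLogger("serometa")

DEFAULT_CONFIG: dict = {
    "seed": 1,
    "simulate": False,
    "inputs": {},
    "log2_transform": False,
    "covariates": ["sex", "age", "diabetes", "ethnicity", "bmi", "site"],
    "max_missing": 0.20,
    "correlation_threshold": 0.5,
    "fdr_abundance": 0.05,
    "fdr_coabundance": 0.1,
    "enrichment_alpha": 0.05,
    "n_rotations": 9999,
    "exclude_missingness_outliers": False,
    "subset": None,  # e.g. {"ethnicity": "caucasian"} sensitivity rerun
}


def load_config(path: str | Path | None) -> dict:
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    if path is not None:
        user = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(user) - set(DEFAULT_CONFIG)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg.update(user)
    return cfg


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    for handler in (
        logging.StreamHandler(sys.stderr),
        logging.FileHandler(outdir / "run.log", mode="w"),
    ):
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def load_inputs(cfg: dict, outdir: Path):
    """Load the three inputs from disk or simulate them per the config."""
    if cfg.get("simulate"):
        sim = CohortSimulator(SimConfig())
        matrix, metadata, annotation, truth = sim.generate(int(cfg["seed"]))
        write_abundance(matrix, outdir / "simulated_abundance.tsv")
        metadata.to_csv(outdir / "simulated_metadata.tsv", sep="\t", index=False)
        annotation.to_csv(outdir / "simulated_annotation.tsv", sep="\t", index=False)
        truth.to_json(outdir / "simulated_truth.json")
        log.info("simulated cohort: %d samples x %d metabolites (seed=%s)",
                 matrix.n_samples, matrix.n_metabolites, cfg["seed"])
        return matrix, metadata, annotation
    inputs = cfg.get("inputs") or {}
    for key in ("matrix", "metadata", "annotation"):
        if not inputs.get(key):
            raise ValueError(
                f"config must give inputs.{key} or set simulate: true"
            )
    matrix = read_abundance(inputs["matrix"])
    metadata = read_metadata(inputs["metadata"])
    annotation = read_annotation(inputs["annotation"])
    return matrix, metadata, annotation


def preprocess_stage(matrix: AbundanceMatrix, metadata: pd.DataFrame, cfg: dict,
                     outdir: Path):
    """QC chain; returns (normalized, scaled, qc report dict)."""
    filtered, dropped = filter_missingness(matrix, cfg["max_missing"])
    log.info("missingness filter: dropped %d of %d metabolites",
             len(dropped), matrix.n_metabolites)
    outliers = missingness_outliers(matrix)
    if outliers:
        log.warning("missingness outlier subjects: %s", outliers)
    if cfg.get("exclude_missingness_outliers") and outliers:
        keep = [s for s in filtered.sample_ids if s not in set(outliers)]
        filtered = AbundanceMatrix(
            filtered.values.loc[keep], filtered.missing_mask.loc[keep],
            state=filtered.state, log=list(filtered.log),
        )
    imputed = impute_minimum(filtered)
    if cfg.get("log2_transform"):
        imputed = AbundanceMatrix(
            np.log2(imputed.values), imputed.missing_mask, state="imputed",
            log=list(imputed.log) + ["log2"],
        )
    normalized = quantile_normalize(imputed)
    scaled = scale_metabolites(normalized)
    pca_table = pca_qc(scaled, metadata)
    report = {
        "n_metabolites_in": matrix.n_metabolites,
        "n_dropped": len(dropped),
        "dropped": dropped,
        "n_metabolites_out": scaled.n_metabolites,
        "missingness_outlier_subjects": outliers,
        "mean_subject_missingness": float(
            matrix.missing_fraction_per_sample().mean()
        ),
        "pc_variance_explained": [
            float(v) for v in pca_table.attrs["variance_explained"]
        ],
    }
    write_abundance(normalized, outdir / "normalized_abundance.tsv")
    write_abundance(scaled, outdir / "scaled_abundance.tsv")
    write_table(pca_table, outdir / "pca_qc.tsv")
    per_subject = matrix.missing_fraction_per_sample().rename("missing_fraction")
    per_subject.rename_axis("sample_id").reset_index().to_csv(
        outdir / "subject_missingness.tsv", sep="\t", index=False
    )
    (outdir / "qc_report.json").write_text(json.dumps(report, indent=1))
    return normalized, scaled, report


def _apply_subset(metadata: pd.DataFrame, subset) -> pd.DataFrame:
    if not subset:
        return metadata
    keep = pd.Series(True, index=metadata.index)
    for col, val in subset.items():
        keep &= metadata[col].astype(str) == str(val)
    return metadata.loc[keep]


def diffabund_stage(normalized: AbundanceMatrix, scaled: AbundanceMatrix,
                    metadata: pd.DataFrame, annotation: pd.DataFrame,
                    cfg: dict, outdir: Path) -> pd.DataFrame:
    """Per-metabolite differential abundance.

    Statistics (t, p, q) come from the scaled run, the reported logFC and CI
    from a paired run on the normalized (log2) matrix, so the logFC is in
    log2 units while inference matches the unit-variance analysis; the scaled
    coefficient is emitted alongside, clearly labelled.
    """
    covariates = tuple(cfg["covariates"])
    metadata = _apply_subset(metadata, cfg.get("subset"))
    sample_ids = [s for s in scaled.sample_ids if s in metadata.index]
    est_scaled = ModeratedDifferentialAbundance(
        covariates=covariates, alpha=cfg["fdr_abundance"]
    ).fit(scaled.values.loc[sample_ids], metadata)
    est_log2 = ModeratedDifferentialAbundance(
        covariates=covariates, alpha=cfg["fdr_abundance"]
    ).fit(normalized.values.loc[sample_ids], metadata)
    stats_tbl = est_scaled.results_.set_index("metabolite_id")
    log2_tbl = est_log2.results_.set_index("metabolite_id")
    table = pd.DataFrame(
        {
            "metabolite_id": log2_tbl.index,
            "group": annotation.loc[log2_tbl.index, "group"].to_numpy(),
            "logFC": log2_tbl["logFC"],
            "ci_low": log2_tbl["ci_low"],
            "ci_high": log2_tbl["ci_high"],
            "logFC_scaled": stats_tbl.loc[log2_tbl.index, "logFC"],
            "t_mod": stats_tbl.loc[log2_tbl.index, "t_mod"],
            "p": stats_tbl.loc[log2_tbl.index, "p"],
            "q": stats_tbl.loc[log2_tbl.index, "q"],
        }
    ).reset_index(drop=True)
    table["significant"] = table["q"] < cfg["fdr_abundance"]
    table["direction"] = np.where(table["logFC"] > 0, "up", "down")
    table = table.sort_values("logFC", kind="mergesort").reset_index(drop=True)
    write_table(table, outdir / "differential_abundance.tsv")
    log.info("differential abundance: %d significant of %d (d0=%.3g)",
             int(table["significant"].sum()), len(table),
             est_scaled.prior_.d0)
    return table


def enrich_stage(scaled: AbundanceMatrix, metadata: pd.DataFrame,
                 annotation: pd.DataFrame, cfg: dict, outdir: Path) -> pd.DataFrame:
    covariates = tuple(cfg["covariates"])
    metadata = _apply_subset(metadata, cfg.get("subset"))
    sample_ids = [s for s in scaled.sample_ids if s in metadata.index]
    X = scaled.values.loc[sample_ids]
    groups = annotation.loc[scaled.metabolite_ids, "group"]
    rot = RotationSetTest(
        covariates=covariates, n_rotations=int(cfg["n_rotations"]),
        random_state=int(cfg["seed"]),
    ).fit(X, metadata, groups)
    pc1 = pc1_group_test(X, metadata, groups, covariates).set_index("group")
    table = rot.results_.set_index("group")
    table["pc1_coef"] = pc1["coef"]
    table["pc1_p"] = pc1["p"]
    table["pc1_q"] = pc1["q"]
    table = table.reset_index()
    write_table(table, outdir / "group_enrichment.tsv")
    log.info("set analysis: %d groups tested, %d skipped",
             len(table), len(rot.skipped_))
    return table


def coabund_stage(scaled: AbundanceMatrix, metadata: pd.DataFrame,
                  annotation: pd.DataFrame, cfg: dict, outdir: Path):
    covariates = tuple(cfg["covariates"])
    metadata = _apply_subset(metadata, cfg.get("subset"))
    sample_ids = [s for s in scaled.sample_ids if s in metadata.index]
    est = DifferentialCoabundance(
        covariates=covariates,
        threshold=cfg["correlation_threshold"],
        fdr=cfg["fdr_coabundance"],
        enrichment_alpha=cfg["enrichment_alpha"],
    ).fit(scaled.values.loc[sample_ids], metadata,
          annotation.loc[scaled.metabolite_ids])
    write_table(est.pairs_, outdir / "coabundance_pairs.tsv")
    write_table(est.enrichment_, outdir / "coabundance_enrichment.tsv")
    log.info(
        "co-abundance: %d significant of %d tested pairs (p_parameter=%.4g)",
        est.n_significant_, est.n_tested_,
        est.p_parameter_ if est.n_tested_ else float("nan"),
    )
    return est


def run_all(config_path: str | Path | None, outdir: str | Path) -> dict:
    """Run the whole pipeline; returns the manifest dict."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg = load_config(config_path)
    _setup_logging(outdir)
    matrix, metadata, annotation = load_inputs(cfg, outdir)
    validate_cohort(matrix, metadata, annotation)
    normalized, scaled, qc = preprocess_stage(matrix, metadata, cfg, outdir)
    diff = diffabund_stage(normalized, scaled, metadata, annotation, cfg, outdir)
    enrich = enrich_stage(scaled, metadata, annotation, cfg, outdir)
    coab = coabund_stage(scaled, metadata, annotation, cfg, outdir)
    tables = [
        "differential_abundance.tsv",
        "group_enrichment.tsv",
        "coabundance_pairs.tsv",
        "coabundance_enrichment.tsv",
        "pca_qc.tsv",
    ]
    manifest = {
        "config": cfg,
        "config_hash": _config_hash(cfg),
        "seed": cfg["seed"],
        "version": __version__,
        "n_metabolites_analysed": scaled.n_metabolites,
        "n_significant_metabolites": int(diff["significant"].sum()),
        "n_enriched_groups_rotation": int((enrich["q"] < 0.05).sum()),
        "n_tested_pairs": coab.n_tested_,
        "n_significant_pairs": coab.n_significant_,
        "p_parameter": coab.p_parameter_,
        "table_checksums": {
            t: hashlib.sha256((outdir / t).read_bytes()).hexdigest()
            for t in tables if (outdir / t).exists()
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
    log.info("run complete: %s", outdir)
    return manifest
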