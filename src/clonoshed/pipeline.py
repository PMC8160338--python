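"""End-to-end orchestration: simulate -> classify -> CCF -> cfDNA ->
subset sampling -> ROC, with a manifest recording seed and config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import cfdna, sampling, synthetic, variant_matrix
from .io import RunConfig, write_json, write_sample_sheet, write_segments, write_variants_tsv

logger = logging.getLogger("clonoshed")

__all__ = ["run_pipeline", "classify_patient", "patient_detection_records"]


def classify_patient(
    tissue: pd.DataFrame,
    sample_sheet: pd.DataFrame,
    config: RunConfig,
) -> variant_matrix.PresenceMatrix:
    """Rescue -> power filter -> class assignment for one patient."""
    calls = tissue[tissue["called"]] if "called" in tissue.columns else tissue
    matrix = variant_matrix.rescue_mutations(
        calls,
        tissue,
        min_reads=config.min_rescue_reads,
        min_bq=config.min_base_quality,
        min_mq=config.min_map_quality,
    )
    matrix = variant_matrix.power_filter(
        matrix,
        tissue,
        sample_sheet,
        power_target=config.power_target,
        min_reads=config.min_rescue_reads,
    )
    return variant_matrix.classify_mutations(matrix)


def patient_detection_records(
    matrix: variant_matrix.PresenceMatrix,
    plasma: pd.DataFrame,
    tumor_fraction: float,
    config: RunConfig,
) -> pd.DataFrame:
    rec = cfdna.detect_in_cfdna(
        matrix,
        plasma,
        tumor_fraction,
        min_rescue_reads=config.min_rescue_reads,
        min_denovo_vaf=config.cfdna_min_vaf,
    )
    rec.insert(0, "patient", matrix.patient)
    return rec


def run_pipeline(config: RunConfig) -> dict:
    """Run the full synthetic-cohort analysis and write all outputs.

    Returns the manifest dict; identical config + seed reproduce the
    same manifest hash.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=config.log_level)

    sim = synthetic.SimConfig(**config.simulate)
    cohort = synthetic.simulate_cohort(sim, seed=config.seed)
    write_variants_tsv(cohort.tissue, outdir / "tissue_variants.tsv")
    write_variants_tsv(cohort.plasma, outdir / "plasma_variants.tsv")
    write_segments(cohort.segments, outdir / "segments.tsv")
    write_sample_sheet(cohort.sample_sheet, outdir / "sample_sheet.tsv")
    cohort.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False)

    all_records = []
    class_summary = {}
    for patient, tissue in cohort.tissue.groupby("patient"):
        sheet = cohort.sample_sheet[cohort.sample_sheet["patient"] == patient]
        matrix = classify_patient(tissue, sheet, config)
        counts = matrix.class_counts()
        class_summary[patient] = counts
        logger.info("%s: %s", patient, counts)
        matrix.status.to_csv(outdir / f"presence_{patient}.tsv", sep="\t")

        plasma = cohort.plasma[cohort.plasma["patient"] == patient]
        if plasma.empty:
            continue
        # restrict tissue matrix to on-panel loci for the plasma stage
        tf = float(
            cohort.truth.loc[cohort.truth["patient"] == patient, "tumor_fraction"].iloc[0]
        )
        rec = patient_detection_records(matrix, plasma, tf, config)
        all_records.append(rec)

    records = pd.concat(all_records, ignore_index=True)
    records.to_csv(outdir / "detection_records.tsv", sep="\t", index=False)

    stats = {}
    try:
        stats["branch_vs_private"] = {
            k: v for k, v in cfdna.branch_vs_private_test(records).items()
        }
    except ValueError as exc:
        logger.warning("branch-vs-private test skipped: %s", exc)
    try:
        lin = cfdna.ccf_vs_lesions_model(records)
        stats["ccf_slope"] = {"slope": lin["slope"], "ci": lin["slope_ci"]}
    except ValueError as exc:
        logger.warning("ccf-vs-lesions model skipped: %s", exc)

    tissue_truncal = records["tissue_class"].isin(["truncal"])
    usable = records["ctdna_ccf"].notna() & records["tissue_class"].isin(
        ["truncal", "branch", "private"]
    )
    if usable.any() and tissue_truncal[usable].nunique() == 2:
        roc = sampling.roc_truncal_threshold(
            records.loc[usable, "ctdna_ccf"], tissue_truncal[usable]
        )
        stats["roc"] = {
            "auc": roc.auc,
            "threshold": roc.optimal_threshold,
            "sensitivity": roc.sens_at_opt,
            "specificity": roc.spec_at_opt,
        }

    subset_rows = []
    for patient, truth in cohort.truth.groupby("patient"):
        drv = truth[truth["driver"]]
        if drv.empty:
            continue
        lesions = sorted(
            cohort.sample_sheet.loc[
                cohort.sample_sheet["patient"] == patient, "sample"
            ]
        )
        presence = pd.DataFrame(
            [
                {les: les in row["harboring_lesions"].split(",") for les in lesions}
                for _, row in drv.iterrows()
            ],
            index=drv["gene"].values,
        )
        for s in range(1, min(config.max_subset_size, len(lesions)) + 1):
            summ = sampling.subset_statistics(presence, s, seed=config.seed)
            subset_rows.append(
                {
                    "patient": patient,
                    "subset_size": s,
                    "n_subsets": summ.n_subsets,
                    "mean_detected": summ.mean_detected,
                    "sd_detected": summ.sd_detected,
                    "fraction_complete": summ.fraction_complete,
                    "mean_misclassified_truncal": summ.mean_misclassified_truncal,
                }
            )
    pd.DataFrame(subset_rows).to_csv(
        outdir / "subset_summaries.tsv", sep="\t", index=False
    )

    cfg_dict = dataclasses.asdict(config)
    cfg_hash = hashlib.sha256(
        json.dumps(cfg_dict, sort_keys=True).encode()
    ).hexdigest()
    manifest = {
        "seed": config.seed,
        "config_hash": cfg_hash,
        "class_summary": class_summary,
        "stats": stats,
        "n_detection_records": int(len(records)),
    }
    write_json(manifest, outdir / "manifest.json")
    return manifest
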