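"""End-to-end pipeline driver: simulate -> preprocess -> DE -> selection ->
validation -> scoring -> diagnostics, with every intermediate written to an
artifact directory and a summary JSON at the end."""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as rio
from .datatypes import Compendium
from .diagnostics import batch_diagnostics, kmeans_cluster_eval
from .diffexpr import call_de, cross_tissue_overlap, fit_linear_de, moderate_statistics
from .feature_selection import FSConfig, evaluate_selection, run_feature_selection
from .preprocess import combat_adjust, impute_sex, merge_studies, quantile_normalize
from .scoring import (
    bootstrap_or,
    ra_score,
    random_panel_null,
    score_das28_correlation,
    score_group_effect,
    validate_genes,
)
from .simulate import (
    SimulationConfig,
    generate_clinical_annotations,
    generate_compendium,
    generate_validation_sets,
)

log = logging.getLogger("rascore")


def preprocess_tissue(studies, tissue: str, y_genes=None):
    """Quantile-normalize each study, merge, impute sex, batch-adjust."""
    normalized = [
        type(s)(
            values=quantile_normalize(s.values),
            annotations=s.annotations,
            name=s.name,
        )
        for s in studies
    ]
    merged = merge_studies(normalized, tissue=tissue)
    merged.quantile_normalized = True
    if y_genes:
        sex = impute_sex(merged.values, y_genes, annotated=merged.annotations["sex"])
        merged.annotations = merged.annotations.assign(sex=sex)
    adjusted, model = combat_adjust(merged)
    adjusted.annotations = merged.annotations
    return merged, adjusted, model


def tissue_de(comp: Compendium, fdr: float = 0.05, fc: float = 1.2):
    fits = fit_linear_de(
        comp,
        status=comp.annotations["status"],
        sex=comp.annotations["sex"],
        treatment=comp.annotations["treatment"],
    )
    return call_de(moderate_statistics(fits), fdr=fdr, fc=fc)


def run_pipeline(
    sim_config: SimulationConfig | None = None,
    fs_config: FSConfig | None = None,
    outdir: str | Path = "pipeline_out",
    seed: int = 0,
    n_validation_sets: int = 5,
) -> dict:
    sim_config = sim_config or SimulationConfig(seed=seed)
    fs_config = fs_config or FSConfig(n_iterations=25, base_seed=seed + 1)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": seed, "stages": {}}

    log.info("simulate: seed=%d", sim_config.seed)
    studies, truth = generate_compendium(sim_config)
    rio.write_ground_truth(
        truth, outdir / "truth_genes.tsv", outdir / "truth_samples.tsv"
    )

    tissues = list(sim_config.tissues)
    adjusted = {}
    merged = {}
    for tissue in tissues:
        log.info("preprocess: %s", tissue)
        m, a, _ = preprocess_tissue(studies[tissue], tissue, truth.y_genes)
        merged[tissue], adjusted[tissue] = m, a
        rio.write_matrix(a.values, outdir / f"{tissue}_adjusted.tsv")
        rio.write_annotations(a.annotations, outdir / f"{tissue}_annotations.tsv")
        diag = batch_diagnostics(m.values, a.values, a.batches, seed=seed)
        summary["stages"][f"diagnostics_{tissue}"] = {
            name: {
                "mlogloss": rep["mlogloss"],
                "kruskal_median_p": rep["kruskal_median_p"],
            }
            for name, rep in diag.items()
        }

    log.info("differential expression")
    de = {t: tissue_de(adjusted[t]) for t in tissues}
    for t in tissues:
        rio.write_de_table(de[t], outdir / f"{t}_de.tsv")
    common = adjusted[tissues[0]].genes.intersection(adjusted[tissues[1]].genes)
    overlap = cross_tissue_overlap(de[tissues[0]], de[tissues[1]], len(common))
    summary["stages"]["overlap"] = {
        "concordant_up": len(overlap.concordant_up),
        "concordant_down": len(overlap.concordant_down),
        "discordant": len(overlap.discordant),
        "p_up": overlap.p_up,
        "p_down": overlap.p_down,
    }
    concordant = overlap.concordant_up + overlap.concordant_down
    if concordant:
        for t in tissues:
            comp = adjusted[t]
            summary["stages"][f"kmeans_{t}"] = {
                k: v
                for k, v in kmeans_cluster_eval(
                    comp.values, comp.annotations["status"], concordant, seed=seed
                ).items()
                if k != "confusion"
            }

    log.info("feature selection: %d iterations", fs_config.n_iterations)
    report = run_feature_selection(adjusted[tissues[0]], adjusted[tissues[1]], fs_config)
    report.auc_summary.to_csv(outdir / "fs_summary.tsv", sep="\t")
    summary["stages"]["feature_selection"] = {
        "n_in_all_iterations": len(report.genes_in_all),
        "final_genes": report.final_genes,
        **evaluate_selection(report, truth),
    }

    log.info("validation and scoring")
    validation = generate_validation_sets(
        truth, n_sets=n_validation_sets, seed=seed + 50_000
    )
    panel = validate_genes(
        adjusted["blood"], validation, report.final_genes, auc_min=0.8
    )
    rio.write_panel(panel, outdir / "panel.tsv")
    summary["stages"]["validation"] = {
        "n_candidates": len(report.final_genes),
        "panel_up": panel.up_genes,
        "panel_down": panel.down_genes,
    }

    if panel.up_genes and panel.down_genes:
        clin = generate_clinical_annotations(truth)
        score_blocks = {}
        for t in tissues:
            comp = adjusted[t]
            scores = ra_score(comp.values, panel)
            score_blocks[t] = score_group_effect(
                scores, comp.annotations["status"]
            )
        summary["stages"]["ra_score_effect"] = score_blocks

        blood = adjusted["blood"]
        scores = ra_score(blood.values, panel)
        das28 = clin.table["das28"].reindex(scores.index)
        if das28.notna().sum() >= 10:
            assoc = score_das28_correlation(
                scores, das28, blood.batches, seed=seed + 7
            )
            summary["stages"]["das28"] = {
                "pooled_r": assoc["pooled_r"],
                "ci95": assoc["ci95"],
                "combined_p": assoc["combined_p"],
            }
            null = random_panel_null(
                blood.values, panel, das28, n_iter=100, seed=seed + 8
            )
            summary["stages"]["random_panel_null"] = {
                k: v for k, v in null.items() if k != "null_rs"
            }
        orr = bootstrap_or(
            scores,
            blood.annotations["status"],
            contrast=("case", "control"),
            dataset_labels=blood.batches,
            seed=seed + 9,
        )
        summary["stages"]["bootstrap_or"] = orr

        pair = clin.treatment_pairs
        pscores = ra_score(pair.values, panel)
        summary["stages"]["treatment_effect"] = score_group_effect(
            pscores,
            pair.annotations["timepoint"],
            paired=pair.annotations["pair_id"],
        )

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=_jsonable)
    return summary


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.ndarray, pd.Index)):
        return list(obj)
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
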