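# rascore

Cross-tissue transcriptomic biomarker discovery for rheumatoid arthritis
(RA), built as a reusable, fully tested pipeline. The package is aimed at
computational biologists who want to find disease genes that behave
consistently in two tissues — inflamed synovium and whole blood — from
merged multi-study expression compendia, and to summarize a validated gene
panel as a single per-sample disease score.

## What it computes

Starting from several gene × sample log2 expression matrices per tissue
(each with per-sample annotations: dataset of origin, case/control status,
sex, treatment, disease activity), the pipeline:

1. **Preprocesses** each study (intra-study quantile normalization), merges
   studies on their common genes, imputes missing sex labels from mean
   Y-chromosome gene expression, and removes dataset (batch) effects with
   parametric empirical-Bayes location/scale adjustment (ComBat): per gene
   the standardized batch location γ<sub>ig</sub> and scale δ²<sub>ig</sub>
   are shrunk toward normal / inverse-gamma priors and divided out.
2. **Tests differential expression** per gene with an OLS model
   (status + sex + treatment covariates) and empirical-Bayes moderated
   t-statistics: the posterior variance
   s̃²<sub>g</sub> = (d₀s₀² + d s²<sub>g</sub>)/(d₀ + d) shrinks per-gene
   variances toward a prior (d₀, s₀²) estimated by moment matching on the
   log-variances; calls use BH FDR < 0.05 and fold change > 1.2, and
   cross-tissue overlaps are tested with upper-tail hypergeometric
   probabilities.
3. **Selects features** by an iterative resampling loop: per iteration and
   tissue, an 80:20 stratified split; moderated-t significance (FDR < 0.05)
   on the training split; a |Pearson r| ≥ 0.25 filter against case/control
   status; greedy redundancy pruning of gene pairs with |r| > 0.8 (keeping
   the smaller DE p-value); a cross-tissue intersection that drops genes
   changing in opposite directions; and a per-gene test-set AUROC from a
   univariate logistic model. Genes present in every iteration's
   intersection whose mean test AUROC exceeds 2/3 in both tissues form the
   feature-selected set.
4. **Validates and scores**: per-gene logistic models fit once on discovery
   blood and evaluated by AUROC on independent cohorts (panel threshold:
   mean validation AUROC > 0.8); the **RA Score** of a sample is the
   geometric mean of its up-regulated panel genes minus the geometric mean
   of its down-regulated panel genes on the linear intensity scale,
   GM(up) − GM(down) with GM = 2^(mean log2). The clinical battery reports
   DAS28 correlations per dataset with Fisher-combined p-values, bootstrap
   odds ratios per SD of score, paired pre/post-treatment contrasts, and a
   random-panel null comparison.
5. **Diagnoses batch mixing** by the multinomial log loss of a random
   forest predicting dataset-of-origin from the first 20 principal
   components (higher loss = better mixing) and per-PC Kruskal–Wallis tests
   against batch.

Because the original public compendia are not bundled, the package ships a
first-class synthetic compendium generator (`rascore.simulate`) that
emulates their statistical structure — multi-dataset batch effects, a
planted co-directional disease signal that is stronger in synovium than in
blood, correlated gene blocks, Y-gene sex signal, treatment attenuation,
blood class imbalance, and a DAS28 variable tied to a latent disease
burden — together with a ground-truth record so every stage is testable.

## Worked example

```python
from rascore import (
    SimulationConfig, FSConfig, generate_compendium,
    run_feature_selection, hypergeom_overlap_test, ra_score, ScorePanel,
)
from rascore.pipeline import preprocess_tissue
from rascore.feature_selection import evaluate_selection

cfg = SimulationConfig(n_genes=1000, seed=7)
studies, truth = generate_compendium(cfg)

adjusted = {}
for tissue in cfg.tissues:
    merged, adj, model = preprocess_tissue(studies[tissue], tissue, truth.y_genes)
    adjusted[tissue] = adj

report = run_feature_selection(
    adjusted["synovium"], adjusted["blood"], FSConfig(n_iterations=10, base_seed=8)
)
print(f"genes selected in every iteration: {len(report.genes_in_all)}")
print(f"final panel (mean test AUROC > 2/3 in both tissues): {len(report.final_genes)}")
ev = evaluate_selection(report, truth)
print(f"sensitivity vs planted truth: {ev['sensitivity']:.2f}, precision: {ev['precision']:.2f}")

panel = ScorePanel(up_genes=truth.planted_up[:10], down_genes=truth.planted_down[:3])
scores = ra_score(adjusted["blood"].values, panel)
case = adjusted["blood"].annotations["status"] == "case"
print(f"mean RA Score  cases: {scores[case].mean():.1f}   controls: {scores[~case].mean():.1f}")
print(f"up-regulated overlap test: p = {hypergeom_overlap_test(10071, 789, 110, 29):.2g}")
```

Output:

```
genes selected in every iteration: 45
final panel (mean test AUROC > 2/3 in both tissues): 45
sensitivity vs planted truth: 0.73, precision: 1.00
mean RA Score  cases: 35.3   controls: -127.6
up-regulated overlap test: p = 3.4e-09
```

The selection loop recovers 73% of the planted disease genes with no false
positives at this reduced problem size. Cases score far above controls;
the absolute level (and even the sign) of the score depends on the
baseline expression of the chosen panel genes — only the case/control
difference is meaningful. The overlap test is the exact upper-tail
hypergeometric probability of observing 29 shared up-regulated genes
between a 789-gene and a 110-gene DE set over a 10,071-gene common
background.

A command-line interface mirrors the library
(`rascore simulate | preprocess | de | select | score | diagnose | run`);
`rascore run --seed 0 --outdir out/` executes the whole pipeline on a
synthetic compendium and writes every intermediate table plus a summary
JSON.

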