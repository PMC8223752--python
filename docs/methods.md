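# Methods

## The pipeline in brief

The package implements a cross-tissue biomarker-discovery computation for
rheumatoid arthritis: merged multi-study expression compendia from synovium
and whole blood are batch-adjusted, screened by covariate-adjusted
moderated-t differential expression, narrowed by an iterative resampling
feature-selection loop with a co-directionality constraint, validated
per-gene on independent cohorts, and summarized as the RA Score — the
difference of geometric means of up- and down-regulated panel genes — whose
clinical associations (disease activity, treatment response, subgroup
contrasts) are then quantified. Because the real compendium is external,
all development and testing runs on a synthetic generator that reproduces
the compendium's statistical structure with a known ground truth.

## Synthetic compendium: generative model

Per gene g, baseline log2 expression is Normal(μ_g, σ_g) with
μ_g ~ N(7, 1.5) (log2 intensity units, the familiar microarray range) and
residual variances σ²_g drawn from a scaled inverse-chi-square with prior
df d₀ = 4 and scale s₀² = 0.25. The inverse-chi-square family makes
empirical-Bayes variance moderation meaningful (it is the conjugate model
the moderated t assumes); the scale 0.25 (typical per-gene sd ≈ 0.55) was
chosen so that the planted effects below give per-gene AUROCs around
0.80 in blood and 0.90 in synovium — the range reported for real
single-gene RA classifiers — and so that disease genes are informative
without becoming mutually collinear.

Disease signal. Each case sample carries a latent disease burden
b ~ N(1, 0.3); each planted gene has a signed log2 effect β_g drawn
uniformly from (1.0, 2.0) in synovium and (0.6, 1.2) in blood (same sign in
both tissues — co-directionality holds by construction), and the expression
shift of gene g in case j is β_g(b_j + η_gj) with a gene-specific response
jitter η ~ N(0, 0.3). The jitter reflects that real markers track
partially distinct aspects of disease; without it all strong markers would
be near-deterministic functions of the single burden axis and pairwise
correlations among them would exceed any redundancy threshold, which real
DE genes do not. Treated cases (half of cases, two drug-class categories)
have |β| attenuated by 0.25 log2 units.

Structure. Five blocks of five genes each share a latent factor
(within-block Pearson r ≈ 0.9) whose mean also shifts co-directionally with
disease, so block genes are genuine but mutually redundant signal — the
construction the redundancy-pruning step exists for. Eight Y-chromosome
genes are shifted +4 log2 units in males; 40% of samples are emitted with a
blank sex annotation so that sex imputation has work to do. Each dataset
applies an additive per-gene batch shift ~ N(0, 1) and a multiplicative
residual-scale factor exp(N(0, 0.1)), the location/scale structure ComBat
models. Blood is imbalanced (300 cases : 90 controls over four datasets,
~3.4:1, mirroring a discovery compendium dominated by patient series);
synovium has 90 : 30 over three datasets.

Clinical layer. DAS28 (disease-activity score, continuous) is generated
for cases of the first half of datasets as 2.0 + 2.5·b + N(0, 1.7),
giving a latent burden–DAS28 correlation of ≈ 0.40, inside the 0.25–0.43
per-dataset range reported for score–activity correlations in this
setting. Rheumatoid-factor status is assigned independently of burden (so
any expression score is RF-agnostic by construction). A paired cohort
draws 30 patients twice (pre/post treatment, shared burden and per-person
offsets); an osteoarthritis cohort expresses a configurable fraction
(default 0.5) of the planted genes at half magnitude; a polyJIA cohort
expresses the full blood signal.

What the generator does **not** emulate: probe-level intensities and
platform-specific background correction (data are generated
post-normalization), count noise of RNA-seq, correlated batch × biology
confounding, age structure, and cell-type composition shifts. Passing
tests therefore demonstrate correctness of the computation and its
behavior under the modeled structure, not performance on any real cohort.

## Numerical and design choices

- **Quantile normalization**: reference = row-wise mean of the per-column
  sorted values; ties within a column receive the mean of the reference
  values their ranks span; a single-column matrix is returned unchanged
  with a warning.
- **ComBat**: parametric priors; batch design plus optional numeric
  covariates (default none — protecting biological covariates under heavy
  class imbalance can inflate effects, so the conservative default is
  unprotected); EB updates iterate until the relative change of (γ*, δ*)
  falls below 1e-4 (max 100 iterations). The implementation was verified
  against the canonical R implementation (agreement ~1e-14 on a fixed
  instance) and is cross-checked in the test suite against an independent
  straight-line implementation of the published equations (< 1e-6). With a
  homogeneous constant shift the EB prior deliberately shrinks per-gene
  batch locations toward the common mean, leaving per-gene remnants of the
  sampling noise; only the systematic (gene-averaged) difference is
  removed exactly — the tests assert exactly that, matching the canonical
  behavior. A single batch with the guard disabled is an explicit
  pass-through.
- **Sex imputation**: 2-means on the 1-D vector of per-sample Y-gene means,
  centers initialized deterministically at the min and max; the higher
  cluster is male; a center separation below 0.5 log2 units is treated as
  unimodal (no imputation, warning). Annotated sexes are never overwritten.
- **Moderated t**: (d₀, s₀²) by moment matching of log s²_g using
  digamma/trigamma identities, with a Newton inversion of the trigamma
  function; a non-positive excess variance selects the d₀ = ∞ branch. An
  ensemble with literally zero spread returns the common variance as s₀².
  Verified against the reference R implementation to ~1e-14.
- **DE calling**: FDR < 0.05 and fold change > 1.2 interpreted on the
  ratio scale, i.e. |log2FC| > log2 1.2 ≈ 0.263.
- **Status-correlation filter**: |r| ≥ 0.25. The absolute value is
  essential — a signed reading would delete every down-regulated gene.
- **Redundancy pruning**: greedy in ascending DE p-value (ties broken by
  gene id), keeping a gene iff |r| ≤ 0.8 against every kept gene, so the
  statistically strongest member of a correlated block survives.
- **Per-gene classifier**: univariate logistic regression (unpenalized
  Newton solver, tol 1e-8, max 25 iterations). Under complete separation
  the fitted probabilities saturate; since AUROC is invariant to monotone
  transforms, the sign-oriented raw expression is used as the score in
  that case.
- **Feature selection loop**: DE is refit on every training split (never
  reused from a global fit) so test AUROCs are honest; per-iteration seeds
  are base_seed + iteration for auditability; "selected" means membership
  in the post-intersection set of every iteration. AUCPR is computed
  alongside AUROC and their correlation over surviving genes is reported
  as a robustness check.
- **RA Score**: geometric means are computed on the linear (2^x) scale and
  never on z-scaled data (z-scores are signed; geometric means require
  positivity). Missing panel genes are dropped per matrix with a warning —
  the score degrades gracefully. In simulation the *sign* of a control
  sample's score depends on the arbitrary baselines of the panel genes, so
  group contrasts should be read as differences/AUROCs rather than raw
  ratios when control means are near zero; the ratio is reported with a
  warning when its denominator is non-positive.
- **Odds ratios**: logistic regression of class on the score standardized
  within dataset, reported per +1 SD; percentile CIs from a bootstrap
  stratified within dataset × class; complete separation caps |log OR| at
  log 50 with a flag.
- **Pooled DAS28 correlation**: sample-size-weighted mean of per-dataset
  Pearson r, bootstrap 95% CI, Fisher-combined p across datasets
  (X = −2Σ ln pᵢ ~ χ² on 2k df; p = 0 is rejected so callers floor
  explicitly).
- **Batch diagnostics**: PCA by SVD of the gene-centered matrix with a
  deterministic sign convention (largest-|loading| gene positive); random
  forest (500 trees) on the first 20 PCs, 2:1 stratified split, predicted
  probabilities clipped to [1e-15, 1−1e-15]. The Kruskal–Wallis median
  over the first 10 PCs is evaluated on blood, where four datasets put
  three batch components among the leading PCs; with fewer batches the
  median over ten PCs is dominated by non-batch components and is not a
  reliable direction indicator (the mLogLoss direction is, and is checked
  in both tissues).
- **k-means cluster evaluation**: k = 2 with 25 seeded restarts on the
  first two PCs of the restricted matrix; the cluster with the higher case
  fraction is mapped to "case" after clustering (label-free), metrics use
  case as the positive class.

## Problem sizes

Unit tests run on a 400-gene, two-datasets-per-tissue compendium; the
end-to-end checks run the full default compendium (2,000 genes, 510
samples across 7 datasets) with 25 selection iterations, which the package
completes in well under a minute per run. These sizes were chosen to make
the statistical claims testable with comfortable margins while keeping the
suite quick; all scale linearly in genes and samples.

## Known limitations

- The selection loop's "present in all iterations" rule is strict: genes
  whose population status-correlation sits near the 0.25 filter boundary
  drop out stochastically, so sensitivity to weak planted genes falls with
  the iteration count. This mirrors the intended conservatism of the
  original procedure.
- Redundant-block genes rarely survive aggregation because different block
  members win the pruning step in different iterations — at most one can
  survive, and often none does. The block's signal is then represented by
  no gene rather than one; a representative-stabilizing prune (fixed
  priority across iterations) would change this but is not what the
  procedure specifies.
- The bootstrap OR and the effect-size ratio are parametrization-dependent
  (per-SD standardization, within-dataset); numbers are comparable only
  under the same convention.
- ComBat assumes batch effects independent of biology; the generator obeys
  this. Under batch–status confounding (not simulated), adjusted estimates
  would be biased, a known property of the method.
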