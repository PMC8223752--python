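"""Independent-cohort validation, the RA Score, and clinical associations.

The RA Score of a sample is the geometric mean of its up-regulated panel
genes minus the geometric mean of its down-regulated panel genes, both on
the linear intensity scale (2^x for log2 input).  The clinical battery
provides disease-activity (DAS28) correlations with Fisher-combined
p-values, bootstrap odds ratios per standard deviation of score, grouped
effect sizes as ratios of means, and a random-panel null comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import Compendium, ExpressionStudy
from .feature_selection import _logistic_scores, auroc
from .preprocess import zscale_genes


@dataclass
class ScorePanel:
    up_genes: list
    down_genes: list
    validation_auc: dict = field(default_factory=dict)  # gene -> mean AUC
    discovery_log2fc: dict = field(default_factory=dict)
    auc_min: float = 0.8

    def __post_init__(self) -> None:
        if set(self.up_genes) & set(self.down_genes):
            raise ValueError("up and down panel lists overlap")

    @property
    def genes(self) -> list:
        return list(self.up_genes) + list(self.down_genes)


def _case_control(ann: pd.DataFrame) -> pd.Series:
    status = ann["status"]
    return status[status.isin(["case", "control"])]


def validate_genes(
    discovery: Compendium,
    validation_sets: list[ExpressionStudy | Compendium],
    candidate_genes,
    auc_min: float = 0.8,
    zscale: bool = True,
) -> ScorePanel:
    """Per-gene univariate validation on independent cohorts.

    Each candidate is fit once (univariate logistic model) on the z-scaled
    discovery data and evaluated by AUROC on every validation set; genes
    absent from any validation set are dropped from candidacy with a
    warning, mirroring the reduce-to-shared-genes rule.  Genes whose mean
    validation AUROC exceeds ``auc_min`` form the panel, split into up and
    down lists by the sign of the discovery case-control difference.
    """
    candidates = list(candidate_genes)
    shared = [
        g
        for g in candidates
        if all(g in v.values.index for v in validation_sets)
    ]
    dropped = sorted(set(candidates) - set(shared))
    if dropped:
        warnings.warn(
            f"validate_genes: {len(dropped)} candidate(s) missing from some "
            f"validation set(s), excluded: {dropped[:5]}..."
        )
    disc_status = _case_control(discovery.annotations)
    disc_values = discovery.values[disc_status.index]
    if zscale:
        disc_values = zscale_genes(disc_values)
    y_disc = (disc_status == "case").astype(float).to_numpy()

    val_data = []
    for v in validation_sets:
        status = _case_control(v.annotations)
        vals = v.values[status.index]
        if zscale:
            vals = zscale_genes(vals)
        val_data.append((vals, (status == "case").astype(float).to_numpy()))

    mean_auc = {}
    log2fc = {}
    for g in shared:
        x_disc = disc_values.loc[g].to_numpy(dtype=float)
        aucs = []
        for vals, y in val_data:
            if len(np.unique(y)) != 2:
                warnings.warn("validation set with a single class skipped")
                continue
            scores = _logistic_scores(x_disc, y_disc, vals.loc[g].to_numpy(float))
            aucs.append(auroc(scores, y))
        if not aucs:
            continue
        mean_auc[g] = float(np.mean(aucs))
        raw = discovery.values.loc[g, disc_status.index].to_numpy(dtype=float)
        log2fc[g] = float(raw[y_disc == 1].mean() - raw[y_disc == 0].mean())

    kept = [g for g in shared if mean_auc.get(g, 0.0) > auc_min]
    up = [g for g in kept if log2fc[g] > 0]
    down = [g for g in kept if log2fc[g] <= 0]
    return ScorePanel(
        up_genes=up,
        down_genes=down,
        validation_auc={g: mean_auc[g] for g in kept},
        discovery_log2fc=log2fc,
        auc_min=auc_min,
    )


def compare_gene_sets(
    discovery: Compendium,
    validation_sets: list,
    gene_sets: dict[str, list],
    models: tuple = ("logistic", "elastic_net", "random_forest"),
    seed: int = 0,
    zscale: bool = True,
) -> pd.DataFrame:
    """Multivariate gene-set classifiers trained once on discovery.

    Each model is fit on the discovery cohort and applied unchanged to
    every validation set; reports per-set AUROC plus mean and standard
    error across sets.  Overlapping sample ids between discovery and any
    validation set are rejected (leakage guard).
    """
    from sklearn.ensemble import RandomForestClassifier
    from sklearn.linear_model import LogisticRegression, LogisticRegressionCV

    disc_status = _case_control(discovery.annotations)
    disc_samples = set(disc_status.index)
    for v in validation_sets:
        overlap = disc_samples & set(v.values.columns)
        if overlap:
            raise ValueError(
                f"train/validation sample overlap: {sorted(overlap)[:5]}"
            )

    disc_values = discovery.values[disc_status.index]
    if zscale:
        disc_values = zscale_genes(disc_values)
    y_disc = (disc_status == "case").astype(int).to_numpy()

    rows = []
    for set_name, genes in gene_sets.items():
        genes = list(dict.fromkeys(genes))  # dedupe, keep order
        if len(genes) < len(list(gene_sets[set_name])):
            warnings.warn(f"gene set {set_name!r}: duplicates removed")
        shared = [
            g
            for g in genes
            if all(g in v.values.index for v in validation_sets)
            and g in disc_values.index
        ]
        if not shared:
            raise ValueError(f"gene set {set_name!r} empty after reduction")
        X_disc = disc_values.loc[shared].T.to_numpy(dtype=float)
        for model_name in models:
            if model_name == "logistic":
                model = LogisticRegression(C=np.inf, max_iter=1000)
            elif model_name == "elastic_net":
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", FutureWarning)
                    model = LogisticRegressionCV(
                        penalty="elasticnet",
                        solver="saga",
                        l1_ratios=[0.5],
                        cv=5,
                        max_iter=5000,
                        random_state=seed,
                    )
            elif model_name == "random_forest":
                model = RandomForestClassifier(n_estimators=500, random_state=seed)
            else:
                raise ValueError(f"unknown model {model_name!r}")
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model.fit(X_disc, y_disc)
            aucs = []
            for v in validation_sets:
                status = _case_control(v.annotations)
                vals = v.values[status.index]
                if zscale:
                    vals = zscale_genes(vals)
                y = (status == "case").astype(int).to_numpy()
                prob = model.predict_proba(vals.loc[shared].T.to_numpy(float))[:, 1]
                aucs.append(auroc(prob, y))
            aucs = np.array(aucs)
            rows.append(
                {
                    "gene_set": set_name,
                    "model": model_name,
                    "n_genes": len(shared),
                    "mean_auc": aucs.mean(),
                    "se_auc": aucs.std(ddof=1) / np.sqrt(len(aucs))
                    if len(aucs) > 1
                    else 0.0,
                    "per_set_auc": list(aucs),
                }
            )
    return pd.DataFrame(rows)


def ra_score(matrix_log2: pd.DataFrame, panel: ScorePanel) -> pd.Series:
    """GM(up) - GM(down) per sample on the linear (2^x) scale.

    Panel genes missing from the matrix are dropped with a warning — the
    score degrades gracefully when a gene is unavailable.
    """
    up = [g for g in panel.up_genes if g in matrix_log2.index]
    down = [g for g in panel.down_genes if g in matrix_log2.index]
    missing = (set(panel.up_genes) - set(up)) | (set(panel.down_genes) - set(down))
    if missing:
        warnings.warn(f"ra_score: panel genes missing from matrix: {sorted(missing)}")
    if not up or not down:
        raise ValueError("need at least one up and one down panel gene present")
    gm_up = np.exp2(matrix_log2.loc[up].mean(axis=0))
    gm_down = np.exp2(matrix_log2.loc[down].mean(axis=0))
    return (gm_up - gm_down).rename("ra_score")


def score_group_effect(
    scores: pd.Series,
    groups: pd.Series,
    paired: pd.Series | None = None,
) -> dict:
    """Ratio-of-means effect size between two groups with a t-test p.

    Welch's t by default; a paired t-test when pair ids are supplied (the
    first-listed group is the numerator, e.g. pre vs post treatment).
    """
    groups = groups.loc[scores.index]
    names = list(pd.unique(groups))
    if len(names) != 2:
        raise ValueError("score_group_effect expects exactly 2 groups")
    a = scores[groups == names[0]]
    b = scores[groups == names[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs >= 2 samples")
    if paired is not None:
        paired = paired.loc[scores.index]
        wide = pd.DataFrame({"score": scores, "group": groups, "pair": paired})
        piv = wide.pivot(index="pair", columns="group", values="score").dropna()
        t, p = stats.ttest_rel(piv[names[0]], piv[names[1]])
    else:
        t, p = stats.ttest_ind(a, b, equal_var=False)
    ratio = np.nan
    if b.mean() > 0:
        ratio = float(a.mean() / b.mean())
    else:
        warnings.warn("score_group_effect: non-positive denominator mean; ratio NA")
    return {
        "groups": names,
        "means": {names[0]: float(a.mean()), names[1]: float(b.mean())},
        "ratio": ratio,
        "t": float(t),
        "p": float(p),
        "paired": paired is not None,
    }


def score_das28_correlation(
    scores: pd.Series,
    das28: pd.Series,
    dataset_labels: pd.Series,
    n_boot: int = 1000,
    seed: int = 0,
) -> dict:
    """Per-dataset Pearson r with DAS28 plus a pooled weighted mean r.

    Pooling is by sample-size weighting; the 95% CI of the pooled r comes
    from a stratified bootstrap over samples within datasets.
    """
    rng = np.random.default_rng(seed)
    df = pd.DataFrame(
        {"score": scores, "das28": das28.loc[scores.index], "ds": dataset_labels.loc[scores.index]}
    ).dropna()
    per_dataset = {}
    groups = {}
    for ds, sub in df.groupby("ds"):
        if len(sub) < 3:
            continue
        if sub["das28"].std() == 0 or sub["score"].std() == 0:
            warnings.warn(f"dataset {ds}: constant values, skipped")
            continue
        r, p = stats.pearsonr(sub["score"], sub["das28"])
        per_dataset[ds] = {"r": float(r), "p": float(p), "n": int(len(sub))}
        groups[ds] = sub
    if not per_dataset:
        raise ValueError("no dataset with enough annotated DAS28 samples")
    weights = np.array([v["n"] for v in per_dataset.values()], dtype=float)
    rs = np.array([v["r"] for v in per_dataset.values()])
    pooled = float((weights * rs).sum() / weights.sum())

    boot = np.empty(n_boot)
    for i in range(n_boot):
        num = den = 0.0
        for ds, sub in groups.items():
            idx = rng.integers(0, len(sub), len(sub))
            s = sub.iloc[idx]
            if s["score"].std() == 0 or s["das28"].std() == 0:
                continue
            r = stats.pearsonr(s["score"], s["das28"])[0]
            num += len(s) * r
            den += len(s)
        boot[i] = num / den if den else np.nan
    ci = np.nanpercentile(boot, [2.5, 97.5])
    return {
        "per_dataset": per_dataset,
        "pooled_r": pooled,
        "ci95": (float(ci[0]), float(ci[1])),
        "combined_p": fisher_combine(
            [max(v["p"], np.finfo(float).tiny) for v in per_dataset.values()]
        ),
    }


def fisher_combine(pvals) -> float:
    """Fisher's method: X = -2 sum(ln p) ~ chi-square on 2k df."""
    p = np.asarray(list(pvals), dtype=float)
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]; floor zeros explicitly")
    x = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(x, 2 * len(p)))


def bootstrap_or(
    scores: pd.Series,
    labels: pd.Series,
    contrast: tuple,
    dataset_labels: pd.Series | None = None,
    n_boot: int = 1000,
    seed: int = 0,
    cap: float = 50.0,
) -> dict:
    """Odds ratio per +1 SD of (per-dataset standardized) score.

    Logistic regression of class on the standardized score gives the point
    OR and Wald p; a bootstrap stratified within dataset x class gives the
    percentile 95% CI.  Complete separation caps the OR magnitude.
    """
    import statsmodels.api as sm

    rng = np.random.default_rng(seed)
    labels = labels.loc[scores.index]
    mask = labels.isin(contrast)
    scores, labels = scores[mask], labels[mask]
    if dataset_labels is None:
        dataset_labels = pd.Series("all", index=scores.index)
    else:
        dataset_labels = dataset_labels.loc[scores.index]
    counts = labels.value_counts()
    if len(counts) < 2 or (counts < 5).any():
        raise ValueError("each contrast class needs >= 5 samples")

    z = scores.groupby(dataset_labels).transform(
        lambda s: (s - s.mean()) / (s.std(ddof=1) or 1.0)
    )
    y = (labels == contrast[0]).astype(float)

    def _fit_or(zv: np.ndarray, yv: np.ndarray) -> tuple[float, float, bool]:
        X = sm.add_constant(zv)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                res = sm.Logit(yv, X).fit(disp=0, maxiter=100)
            beta = float(res.params[1])
            pv = float(res.pvalues[1])
            if abs(beta) > np.log(cap):
                return float(np.sign(beta) * np.log(cap)), pv, True
            return beta, pv, False
        except Exception:
            return float(np.log(cap)), np.nan, True

    beta, p, capped = _fit_or(z.to_numpy(), y.to_numpy())

    strata = [
        np.where((dataset_labels == ds).to_numpy() & (labels == c).to_numpy())[0]
        for ds in pd.unique(dataset_labels)
        for c in contrast
    ]
    strata = [s for s in strata if len(s)]
    boot = np.empty(n_boot)
    zv, yv = z.to_numpy(), y.to_numpy()
    for i in range(n_boot):
        idx = np.concatenate([s[rng.integers(0, len(s), len(s))] for s in strata])
        boot[i] = _fit_or(zv[idx], yv[idx])[0]
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return {
        "or": float(np.exp(beta)),
        "ci95": (float(np.exp(lo)), float(np.exp(hi))),
        "p": p,
        "capped": capped,
        "contrast": tuple(contrast),
    }


def random_panel_null(
    matrix_log2: pd.DataFrame,
    panel: ScorePanel,
    outcome: pd.Series,
    n_iter: int = 100,
    seed: int = 0,
) -> dict:
    """Correlation of the outcome with scores from random same-shape panels.

    Random panels match the true panel's up/down split sizes, are sampled
    without replacement excluding the true panel genes, and each panel's
    score-outcome Pearson r forms the null; a one-sample two-sided t-test
    compares the null correlations with the true panel's correlation.
    """
    rng = np.random.default_rng(seed)
    n_up, n_down = len(panel.up_genes), len(panel.down_genes)
    pool = matrix_log2.index.difference(panel.genes)
    if len(pool) < n_up + n_down:
        raise ValueError("not enough genes outside the panel")
    samples = matrix_log2.columns.intersection(outcome.dropna().index)
    out = outcome.loc[samples].astype(float)
    true_r = float(
        stats.pearsonr(ra_score(matrix_log2[samples], panel), out)[0]
    )
    null_rs = np.empty(n_iter)
    for i in range(n_iter):
        picks = rng.choice(pool, n_up + n_down, replace=False)
        rand_panel = ScorePanel(
            up_genes=list(picks[:n_up]), down_genes=list(picks[n_up:])
        )
        null_rs[i] = stats.pearsonr(
            ra_score(matrix_log2[samples], rand_panel), out
        )[0]
    t, p = stats.ttest_1samp(null_rs, true_r)
    return {
        "true_r": true_r,
        "null_mean_r": float(null_rs.mean()),
        "null_sd_r": float(null_rs.std(ddof=1)),
        "t": float(t),
        "p": float(p),
        "null_rs": null_rs,
    }
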