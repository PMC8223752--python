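"""Iterative cross-tissue resampling feature selection.

Each iteration draws stratified 80:20 train/test splits independently in
both tissues, finds significant genes on the training split (moderated-t
FDR), filters them by absolute point-biserial correlation with status,
prunes redundant genes (pairwise |r| above a cutoff, keeping the smallest
DE p-value per correlated block), intersects the two tissues' survivors
requiring the same direction of change, and measures each surviving gene's
test-set AUROC from a univariate logistic model.  Genes present in the
intersected set of every iteration whose mean test AUROC clears a
threshold in both tissues form the final feature-selected set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import average_precision_score, roc_auc_score

from .datatypes import Compendium
from .diffexpr import (
    bh_adjust,
    fit_linear_de,
    hypergeom_overlap_test,
    moderate_statistics,
)


@dataclass
class FSConfig:
    n_iterations: int = 100
    split_ratio: float = 0.8
    de_fdr: float = 0.05
    status_corr_min: float = 0.25
    pairwise_corr_max: float = 0.8
    auc_threshold: float = 2.0 / 3.0
    base_seed: int = 0
    use_covariates: bool = True

    def validate(self) -> None:
        if not 0 < self.split_ratio < 1:
            raise ValueError("split_ratio must be in (0,1)")
        for f in ("de_fdr", "status_corr_min", "pairwise_corr_max", "auc_threshold"):
            if not 0 < getattr(self, f) < 1:
                raise ValueError(f"{f} must be in (0,1)")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


@dataclass
class IterationRecord:
    seed: int
    selected: list
    directions: dict  # gene -> +1 / -1 (training log2FC sign, both tissues)
    discordant: list
    overlap_p: float
    per_tissue_selected: dict
    auroc: dict  # tissue -> {gene: auc}
    aucpr: dict


@dataclass
class FSReport:
    iterations: list
    genes_in_all: list
    auc_summary: pd.DataFrame
    final_genes: list
    directions: dict
    tissues: tuple
    config: FSConfig
    auroc_aucpr_corr: dict = field(default_factory=dict)


def stratified_split(
    labels: pd.Series, ratio: float = 0.8, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Class-preserving random split; returns (train, test) index arrays."""
    labels = pd.Series(labels)
    rng = np.random.default_rng(seed)
    train, test = [], []
    for cls, idx in labels.groupby(labels).groups.items():
        idx = np.asarray(idx)
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        perm = rng.permutation(idx)
        n_train = int(round(ratio * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        train.append(perm[:n_train])
        test.append(perm[n_train:])
    return np.concatenate(train), np.concatenate(test)


def correlation_filter(
    matrix: pd.DataFrame,
    status: np.ndarray,
    genes,
    r_min: float = 0.25,
) -> list:
    """Keep genes whose |Pearson r| with binary status reaches r_min."""
    status = np.asarray(status, dtype=float)
    if set(np.unique(status)) - {0.0, 1.0}:
        raise ValueError("status must be coded {0,1}")
    sub = matrix.loc[list(genes)].to_numpy(dtype=float)
    x = sub - sub.mean(axis=1, keepdims=True)
    y = status - status.mean()
    sx = np.sqrt((x**2).sum(axis=1))
    sy = np.sqrt((y**2).sum())
    flat = sx == 0
    if flat.any():
        warnings.warn(
            f"correlation_filter: dropping {int(flat.sum())} constant gene(s)"
        )
    with np.errstate(invalid="ignore"):
        r = (x @ y) / (sx * sy)
    keep = np.abs(r) >= r_min
    keep &= ~flat
    return [g for g, k in zip(genes, keep) if k]


def redundancy_prune(
    matrix: pd.DataFrame,
    genes,
    r_max: float = 0.8,
    priority: pd.Series | None = None,
) -> list:
    """Greedy pruning of correlated genes in priority order.

    A gene is kept iff its |Pearson r| with every already-kept gene is
    <= r_max.  Default priority is the given order; pass ascending DE
    p-values to keep the statistically strongest block representative.
    """
    genes = list(genes)
    if not genes:
        return []
    if priority is not None:
        order = sorted(genes, key=lambda g: (priority.loc[g], g))
    else:
        order = genes
    sub = matrix.loc[order].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        corr = np.corrcoef(sub)
    corr = np.nan_to_num(np.atleast_2d(corr))
    kept_idx: list[int] = []
    for i in range(len(order)):
        if all(abs(corr[i, j]) <= r_max for j in kept_idx):
            kept_idx.append(i)
    return [order[i] for i in kept_idx]


def auroc(scores, labels) -> float:
    """Tie-corrected AUROC (rank / Mann-Whitney form)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("AUROC needs both classes present")
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def aucpr(scores, labels) -> float:
    """Area under the precision-recall step curve (recall-increment sum)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) != 2:
        raise ValueError("AUCPR needs both classes present")
    return float(average_precision_score(labels, np.asarray(scores, dtype=float)))


def _logistic_scores(
    x_train: np.ndarray, y_train: np.ndarray, x_test: np.ndarray
) -> np.ndarray:
    """Univariate logistic model scores; separation falls back to raw x.

    AUROC is invariant to monotone transforms, so when the Newton fit
    saturates (complete separation) the sign-oriented raw expression is an
    equivalent, numerically safe score.
    """
    model = LogisticRegression(
        C=np.inf, solver="newton-cholesky", max_iter=25, tol=1e-8
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model.fit(x_train.reshape(-1, 1), y_train)
    coef = float(model.coef_[0, 0])
    if abs(coef) * (x_train.std() + 1e-12) > 30:  # saturated fit
        return np.sign(coef) * x_test
    return model.predict_proba(x_test.reshape(-1, 1))[:, 1]


def per_gene_auc(
    train_matrix: pd.DataFrame,
    train_labels: np.ndarray,
    test_matrix: pd.DataFrame,
    test_labels: np.ndarray,
    gene: str,
    metric: str = "auroc",
) -> float:
    """Test-set AUROC (or AUCPR) of a univariate logistic model for a gene."""
    y_train = np.asarray(train_labels, dtype=float)
    y_test = np.asarray(test_labels, dtype=float)
    if len(np.unique(y_test)) != 2:
        raise ValueError("test set must contain both classes")
    scores = _logistic_scores(
        train_matrix.loc[gene].to_numpy(dtype=float),
        y_train,
        test_matrix.loc[gene].to_numpy(dtype=float),
    )
    return auroc(scores, y_test) if metric == "auroc" else aucpr(scores, y_test)


def _iteration_tissue_selection(
    comp: Compendium, common: pd.Index, cfg: FSConfig, seed: int
):
    """One tissue's split + DE + filters; returns per-tissue artifacts."""
    ann = comp.annotations
    status = ann["status"]
    keep = status.isin(["case", "control"])
    samples = ann.index[keep]
    values = comp.values.loc[common, samples]
    status = status.loc[samples]

    pos = np.arange(len(samples))
    train_pos, test_pos = stratified_split(
        pd.Series(status.to_numpy(), index=pos), cfg.split_ratio, seed
    )
    train_ids = samples[train_pos]
    test_ids = samples[test_pos]

    sex = ann["sex"] if cfg.use_covariates and "sex" in ann else None
    treatment = (
        ann["treatment"] if cfg.use_covariates and "treatment" in ann else None
    )
    fits = fit_linear_de(
        values[train_ids],
        status=status.loc[train_ids],
        sex=None if sex is None else sex.loc[train_ids],
        treatment=None if treatment is None else treatment.loc[train_ids],
    )
    de = moderate_statistics(fits)
    sig = de.table.index[de.table["p_adj"] < cfg.de_fdr]

    y_train = (status.loc[train_ids] == "case").astype(float).to_numpy()
    train_values = values[train_ids]
    kept = correlation_filter(train_values, y_train, sig, cfg.status_corr_min)
    kept = redundancy_prune(
        train_values, kept, cfg.pairwise_corr_max, priority=de.table["p"]
    )
    signs = np.sign(de.table.loc[kept, "log2fc"]).astype(int)
    y_test = (status.loc[test_ids] == "case").astype(float).to_numpy()
    return {
        "selected": kept,
        "signs": signs,
        "train_values": train_values,
        "test_values": values[test_ids],
        "y_train": y_train,
        "y_test": y_test,
    }


def run_feature_selection(
    tissue_a: Compendium, tissue_b: Compendium, cfg: FSConfig | None = None
) -> FSReport:
    """Run the full resampling loop on two tissue compendia."""
    cfg = cfg or FSConfig()
    cfg.validate()
    common = tissue_a.genes.intersection(tissue_b.genes).sort_values()
    if len(common) < 100:
        raise ValueError("tissues share fewer than 100 genes")
    tissues = (tissue_a.tissue or "tissueA", tissue_b.tissue or "tissueB")
    comps = dict(zip(tissues, (tissue_a, tissue_b)))

    records: list[IterationRecord] = []
    auc_values: dict[str, dict[str, dict[str, list]]] = {
        t: {"auroc": {}, "aucpr": {}} for t in tissues
    }
    for i in range(cfg.n_iterations):
        seed = cfg.base_seed + i
        parts = {
            t: _iteration_tissue_selection(comps[t], common, cfg, seed)
            for t in tissues
        }
        ta, tb = tissues
        set_a = dict(parts[ta]["signs"])
        set_b = dict(parts[tb]["signs"])
        concordant = {
            g: set_a[g] for g in set_a.keys() & set_b.keys() if set_a[g] == set_b[g]
        }
        discordant = sorted(
            g for g in set_a.keys() & set_b.keys() if set_a[g] != set_b[g]
        )
        k = len(concordant) + len(discordant)
        overlap_p = hypergeom_overlap_test(
            len(common), len(set_a), len(set_b), min(k, min(len(set_a), len(set_b)))
        )
        selected = sorted(concordant)
        rec = IterationRecord(
            seed=seed,
            selected=selected,
            directions={g: int(concordant[g]) for g in selected},
            discordant=discordant,
            overlap_p=overlap_p,
            per_tissue_selected={t: list(parts[t]["selected"]) for t in tissues},
            auroc={t: {} for t in tissues},
            aucpr={t: {} for t in tissues},
        )
        for t in tissues:
            p = parts[t]
            for g in selected:
                scores = _logistic_scores(
                    p["train_values"].loc[g].to_numpy(),
                    p["y_train"],
                    p["test_values"].loc[g].to_numpy(),
                )
                a = auroc(scores, p["y_test"])
                pr = aucpr(scores, p["y_test"])
                rec.auroc[t][g] = a
                rec.aucpr[t][g] = pr
                auc_values[t]["auroc"].setdefault(g, []).append(a)
                auc_values[t]["aucpr"].setdefault(g, []).append(pr)
        records.append(rec)

    in_all = set(records[0].selected)
    for rec in records[1:]:
        in_all &= set(rec.selected)
    in_all = sorted(in_all)

    rows = {}
    for g in in_all:
        row = {}
        for t in tissues:
            vals = np.array(auc_values[t]["auroc"][g])
            prs = np.array(auc_values[t]["aucpr"][g])
            row[f"mean_auroc_{t}"] = vals.mean()
            row[f"sd_auroc_{t}"] = vals.std(ddof=1) if len(vals) > 1 else 0.0
            row[f"mean_aucpr_{t}"] = prs.mean()
        rows[g] = row
    summary = pd.DataFrame.from_dict(rows, orient="index")
    summary.index.name = "gene_id"

    if in_all:
        final = [
            g
            for g in in_all
            if all(summary.loc[g, f"mean_auroc_{t}"] > cfg.auc_threshold for t in tissues)
        ]
    else:
        final = []

    corr = {}
    for t in tissues:
        if len(in_all) >= 3:
            x = summary[f"mean_auroc_{t}"]
            y = summary[f"mean_aucpr_{t}"]
            if x.std() > 0 and y.std() > 0:
                r, p = stats.pearsonr(x, y)
                corr[t] = {"r": float(r), "p": float(p)}

    directions = {}
    for g in final:
        directions[g] = records[0].directions[g]
    return FSReport(
        iterations=records,
        genes_in_all=in_all,
        auc_summary=summary,
        final_genes=final,
        directions=directions,
        tissues=tissues,
        config=cfg,
        auroc_aucpr_corr=corr,
    )


def evaluate_selection(report: FSReport, truth) -> dict:
    """Score a feature-selection run against simulation ground truth.

    Sensitivity is over the independently planted genes (block genes are
    deliberately redundant, so at most one per block can survive);
    precision counts any true-signal gene (planted or block) as correct.
    """
    final = set(report.final_genes)
    planted = set(truth.planted_up) | set(truth.planted_down)
    signal = set(truth.signal_genes)
    sensitivity = len(final & planted) / len(planted) if planted else float("nan")
    precision = len(final & signal) / len(final) if final else float("nan")
    n_discordant = 0
    for g in final:
        fc = truth.true_log2fc.loc[g]
        nz = fc[fc != 0]
        if len(nz) == 2 and np.sign(nz.iloc[0]) != np.sign(nz.iloc[1]):
            n_discordant += 1
    per_block: dict[int, int] = {}
    for g in final:
        b = truth.block_membership.get(g)
        if b is not None:
            per_block[b] = per_block.get(b, 0) + 1
    return {
        "sensitivity": sensitivity,
        "precision": precision,
        "n_discordant": n_discordant,
        "max_genes_per_block": max(per_block.values(), default=0),
        "n_final": len(final),
    }
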