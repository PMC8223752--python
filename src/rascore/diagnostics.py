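"""Batch-effect diagnostics and label-free cluster evaluation.

Batch mixing is quantified by how *badly* a random-forest classifier can
recover the dataset of origin from the leading principal components: the
multinomial log loss of its predictions is low when batches are cleanly
separated and rises toward ln(C) (the uniform-predictor loss for C
batches) as batch structure is removed.  A per-component Kruskal-Wallis
test against the batch grouping gives a complementary, threshold-free
view of the same question.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.cluster import KMeans
from sklearn.ensemble import RandomForestClassifier

from .feature_selection import stratified_split

PROB_CLIP = 1e-15


def pca_scores(matrix: pd.DataFrame, k: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample scores on the first k PCs of the gene-centered matrix.

    Sign convention: the gene loading with the largest magnitude on each
    component is made positive, so scores are deterministic.
    """
    if k > min(matrix.shape):
        raise ValueError(f"k={k} exceeds matrix rank bound {min(matrix.shape)}")
    X = matrix.to_numpy(dtype=float)
    X = X - X.mean(axis=1, keepdims=True)
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    for j in range(k):
        lead = np.argmax(np.abs(U[:, j]))
        if U[lead, j] < 0:
            U[:, j] *= -1
            Vt[j, :] *= -1
    scores = (Vt[:k, :].T * s[:k])  # samples x k
    var_explained = s**2 / (s**2).sum()
    return (
        pd.DataFrame(
            scores,
            index=matrix.columns,
            columns=[f"PC{j+1}" for j in range(k)],
        ),
        var_explained[:k],
    )


def batch_predictability(
    matrix: pd.DataFrame,
    batch_labels: pd.Series,
    n_pc: int = 20,
    train_fraction: float = 2.0 / 3.0,
    seed: int = 0,
    n_estimators: int = 500,
) -> float:
    """Multinomial log loss of batch prediction from the first PCs.

    Higher loss means the batch is less predictable, i.e. better mixed.
    """
    batch_labels = batch_labels.loc[matrix.columns]
    classes = pd.unique(batch_labels)
    if len(classes) < 2:
        raise ValueError("need >= 2 batches")
    n_pc = min(n_pc, min(matrix.shape))
    scores, _ = pca_scores(matrix, n_pc)
    y = batch_labels.to_numpy()
    pos = pd.Series(y, index=np.arange(len(y)))
    for attempt in range(10):
        train, test = stratified_split(pos, train_fraction, seed + attempt)
        if set(y[train]) == set(classes) and set(y[test]) == set(classes):
            break
    else:
        raise ValueError("could not produce a split covering every batch")
    rf = RandomForestClassifier(n_estimators=n_estimators, random_state=seed)
    rf.fit(scores.to_numpy()[train], y[train])
    prob = rf.predict_proba(scores.to_numpy()[test])
    prob = np.clip(prob, PROB_CLIP, 1 - PROB_CLIP)
    class_index = {c: i for i, c in enumerate(rf.classes_)}
    true_idx = np.array([class_index[c] for c in y[test]])
    return float(-np.log(prob[np.arange(len(test)), true_idx]).mean())


def pc_batch_kruskal(
    matrix: pd.DataFrame, batch_labels: pd.Series, n_pc: int = 10
) -> pd.DataFrame:
    """Tie-corrected Kruskal-Wallis H of each leading PC against batch."""
    batch_labels = batch_labels.loc[matrix.columns]
    counts = batch_labels.value_counts()
    if len(counts) < 2 or (counts < 2).any():
        raise ValueError("need >= 2 batches with >= 2 samples each")
    n_pc = min(n_pc, min(matrix.shape))
    scores, var = pca_scores(matrix, n_pc)
    rows = []
    for j, pc in enumerate(scores.columns):
        groups = [
            scores[pc][batch_labels == b].to_numpy() for b in counts.index
        ]
        col = scores[pc].to_numpy()
        if np.allclose(col, col[0]):
            warnings.warn(f"{pc}: all values tied; p = 1")
            h, p = 0.0, 1.0
        else:
            h, p = stats.kruskal(*groups)
        rows.append({"pc": pc, "H": float(h), "p": float(p), "var_explained": var[j]})
    return pd.DataFrame(rows).set_index("pc")


def kmeans_cluster_eval(
    matrix: pd.DataFrame,
    status_labels: pd.Series,
    gene_subset,
    seed: int = 0,
) -> dict:
    """Unsupervised 2-means on the first two PCs of a gene subset.

    Clustering never sees the labels; afterwards the cluster with the
    higher case fraction is mapped to "case" and confusion-matrix metrics
    are computed with case as the positive class.
    """
    gene_subset = [g for g in gene_subset if g in matrix.index]
    if not gene_subset:
        raise ValueError("empty gene subset")
    status_labels = status_labels.loc[matrix.columns]
    if set(pd.unique(status_labels)) != {"case", "control"}:
        raise ValueError("status labels must be case/control")
    scores, _ = pca_scores(matrix.loc[gene_subset], k=min(2, len(gene_subset)))
    km = KMeans(n_clusters=2, n_init=25, random_state=seed)
    assignment = km.fit_predict(scores.to_numpy())
    if len(set(assignment)) < 2:
        raise ValueError("degenerate k-means solution (empty cluster)")
    is_case = (status_labels == "case").to_numpy()
    frac = [is_case[assignment == c].mean() for c in (0, 1)]
    case_cluster = int(np.argmax(frac))
    pred_case = assignment == case_cluster
    tp = int((pred_case & is_case).sum())
    fp = int((pred_case & ~is_case).sum())
    fn = int((~pred_case & is_case).sum())
    tn = int((~pred_case & ~is_case).sum())
    return {
        "sensitivity": tp / (tp + fn) if tp + fn else np.nan,
        "specificity": tn / (tn + fp) if tn + fp else np.nan,
        "precision": tp / (tp + fp) if tp + fp else np.nan,
        "recall": tp / (tp + fn) if tp + fn else np.nan,
        "confusion": {"tp": tp, "fp": fp, "fn": fn, "tn": tn},
    }


def batch_diagnostics(
    before: pd.DataFrame,
    after: pd.DataFrame,
    batch_labels: pd.Series,
    n_pc_rf: int = 20,
    n_pc_kw: int = 10,
    seed: int = 0,
) -> dict:
    """Paired before/after batch-adjustment diagnostic report."""
    report = {}
    for name, mat in (("uncorrected", before), ("corrected", after)):
        kw = pc_batch_kruskal(mat, batch_labels, n_pc_kw)
        report[name] = {
            "mlogloss": batch_predictability(mat, batch_labels, n_pc_rf, seed=seed),
            "kruskal_median_p": float(kw["p"].median()),
            "kruskal": kw,
        }
    return report
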