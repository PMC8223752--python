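"""Per-study normalization, cross-study merging, and batch adjustment.

The batch-adjustment step is the parametric empirical-Bayes location/scale
model popularized for merged expression compendia (ComBat): per gene the
data are standardized against a covariate-aware grand mean and pooled
variance, per-batch location (gamma) and scale (delta^2) parameters are
estimated and shrunk toward normal / inverse-gamma priors by an iterative
EB update, and the standardized data are back-transformed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.vq import kmeans2

from .datatypes import Compendium, ExpressionStudy


def log2_transform(matrix: pd.DataFrame, offset: float = 0.0) -> pd.DataFrame:
    """Elementwise log2(x + offset); input must be non-negative."""
    arr = matrix.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("log2_transform requires non-negative input")
    if offset < 0:
        raise ValueError("offset must be non-negative")
    with np.errstate(divide="ignore"):
        out = np.log2(arr + offset)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def quantile_normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Force every sample column onto the common (row-mean) quantile profile.

    Ties within a column receive the mean of the reference values their
    ranks span; with a single column the input is returned unchanged.
    """
    if matrix.shape[1] < 2:
        warnings.warn("quantile_normalize: single column, returned unchanged")
        return matrix.copy()
    arr = matrix.to_numpy(dtype=float)
    reference = np.sort(arr, axis=0).mean(axis=1)
    csum = np.concatenate([[0.0], np.cumsum(reference)])
    out = np.empty_like(arr)
    for j in range(arr.shape[1]):
        col = arr[:, j]
        order = np.argsort(col, kind="mergesort")
        sv = col[order]
        starts = np.concatenate([[0], np.nonzero(np.diff(sv))[0] + 1])
        ends = np.concatenate([starts[1:], [len(sv)]])
        # each tie group receives the mean of the reference values it spans
        group_means = (csum[ends] - csum[starts]) / (ends - starts)
        out[order, j] = np.repeat(group_means, ends - starts)
    return pd.DataFrame(out, index=matrix.index, columns=matrix.columns)


def fpkm_to_log_tpm(fpkm: pd.DataFrame, offset: float = 0.1) -> pd.DataFrame:
    """Column-normalize FPKM to TPM (each column sums to 1e6), then log2."""
    arr = fpkm.to_numpy(dtype=float)
    if (arr < 0).any():
        raise ValueError("FPKM values must be non-negative")
    colsum = arr.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        bad = list(fpkm.columns[zero])
        raise ValueError(f"all-zero FPKM column(s): {bad}")
    tpm = arr / colsum * 1e6
    return pd.DataFrame(
        np.log2(tpm + offset), index=fpkm.index, columns=fpkm.columns
    )


def merge_studies(studies: list[ExpressionStudy], tissue: str = "") -> Compendium:
    """Restrict to the gene intersection and concatenate sample columns."""
    if len(studies) < 2:
        raise ValueError("merge_studies needs at least two studies")
    common = studies[0].genes
    for s in studies[1:]:
        common = common.intersection(s.genes)
    if len(common) == 0:
        raise ValueError("no genes common to all studies")
    common = common.sort_values()
    values = pd.concat([s.values.loc[common] for s in studies], axis=1)
    annotations = pd.concat([s.annotations for s in studies])
    if values.columns.duplicated().any():
        raise ValueError("duplicate sample ids across studies")
    return Compendium(values=values, annotations=annotations, tissue=tissue)


@dataclass
class BatchModel:
    """Fitted empirical-Bayes batch model; transform() re-applies it exactly."""

    batches: list
    gamma_star: pd.DataFrame  # batch x gene shrunken locations
    delta_star: pd.DataFrame  # batch x gene shrunken scales (variances)
    gamma_bar: pd.Series
    tau2: pd.Series
    a_prior: pd.Series
    b_prior: pd.Series
    grand_mean: pd.Series
    var_pooled: pd.Series
    design_coefs: pd.DataFrame | None  # covariate coefficients (gene x cov)
    n_iterations: dict | None = None

    def transform(
        self,
        values: pd.DataFrame,
        batch_labels: pd.Series,
        covariates: pd.DataFrame | None = None,
    ) -> pd.DataFrame:
        genes = values.index
        stand_mean = np.tile(
            self.grand_mean.loc[genes].to_numpy()[:, None], (1, values.shape[1])
        )
        if self.design_coefs is not None:
            cov = covariates.loc[values.columns].to_numpy(dtype=float)
            stand_mean = stand_mean + self.design_coefs.loc[genes].to_numpy() @ cov.T
        sd = np.sqrt(self.var_pooled.loc[genes].to_numpy())[:, None]
        z = (values.to_numpy(dtype=float) - stand_mean) / sd
        out = np.empty_like(z)
        labels = np.asarray(batch_labels.loc[values.columns])
        for b in self.batches:
            cols = labels == b
            g = self.gamma_star.loc[b, genes].to_numpy()[:, None]
            d = np.sqrt(self.delta_star.loc[b, genes].to_numpy())[:, None]
            out[:, cols] = (z[:, cols] - g) / d
        out = out * sd + stand_mean
        return pd.DataFrame(out, index=genes, columns=values.columns)


def _eb_iterate(
    gamma_hat: np.ndarray,
    delta_hat: np.ndarray,
    sdat: np.ndarray,
    g_bar: float,
    t2: float,
    a: float,
    b: float,
    conv: float = 1e-4,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Iterative posterior update for one batch's (gamma*, delta*)."""
    n = sdat.shape[1]
    g_old = gamma_hat.copy()
    d_old = delta_hat.copy()
    for it in range(1, max_iter + 1):
        g_new = (t2 * n * gamma_hat + d_old * g_bar) / (t2 * n + d_old)
        sum2 = ((sdat - g_new[:, None]) ** 2).sum(axis=1)
        d_new = (0.5 * sum2 + b) / (n / 2.0 + a - 1.0)
        change = max(
            np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
            np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
        )
        g_old, d_old = g_new, d_new
        if change < conv:
            break
    return g_old, d_old, it


def combat_adjust(
    compendium: Compendium,
    batch_labels: pd.Series | None = None,
    covariates: pd.DataFrame | None = None,
    allow_single_batch: bool = False,
) -> tuple[Compendium, BatchModel]:
    """Parametric empirical-Bayes batch adjustment of a merged compendium.

    ``covariates``, when given, is a numeric sample x covariate design
    (without intercept or batch columns) whose effects are preserved in the
    standardization step.
    """
    values = compendium.values
    if batch_labels is None:
        batch_labels = compendium.batches
    batch_labels = batch_labels.loc[values.columns]
    batches = list(pd.unique(batch_labels))
    counts = batch_labels.value_counts()
    if len(batches) < 2:
        if not allow_single_batch:
            raise ValueError("combat_adjust requires >= 2 batches")
        # one batch: nothing to adjust
        model = BatchModel(
            batches=batches,
            gamma_star=pd.DataFrame(0.0, index=batches, columns=values.index),
            delta_star=pd.DataFrame(1.0, index=batches, columns=values.index),
            gamma_bar=pd.Series(0.0, index=batches),
            tau2=pd.Series(0.0, index=batches),
            a_prior=pd.Series(np.nan, index=batches),
            b_prior=pd.Series(np.nan, index=batches),
            grand_mean=values.mean(axis=1),
            var_pooled=values.var(axis=1, ddof=0),
            design_coefs=None,
        )
        return compendium.copy_with(values.copy(), batch_adjusted=True), model
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"batches with a single sample: {bad}")

    n_array = values.shape[1]
    batch_design = pd.get_dummies(batch_labels, dtype=float)[batches]
    design = batch_design
    if covariates is not None:
        cov = covariates.loc[values.columns].astype(float)
        design = pd.concat([batch_design, cov], axis=1)
        full = design.to_numpy()
        if np.linalg.matrix_rank(full) < full.shape[1]:
            raise ValueError(
                "covariate design confounded with batch: "
                f"columns {list(design.columns)} are not full rank"
            )

    X = values.to_numpy(dtype=float)  # genes x samples
    D = design.to_numpy(dtype=float)  # samples x p
    B_hat, *_ = np.linalg.lstsq(D, X.T, rcond=None)  # p x genes
    n_batches = np.array([counts[b] for b in batches], dtype=float)
    grand_mean = (n_batches / n_array) @ B_hat[: len(batches), :]

    fitted = (D @ B_hat).T
    var_pooled = ((X - fitted) ** 2).mean(axis=1)
    if (var_pooled <= 0).any():
        raise ValueError("genes with zero pooled variance; drop constant genes")

    stand_mean = np.tile(grand_mean[:, None], (1, n_array))
    design_coefs = None
    if covariates is not None:
        cov_coefs = B_hat[len(batches):, :].T  # genes x cov
        stand_mean = stand_mean + cov_coefs @ cov.to_numpy().T
        design_coefs = pd.DataFrame(
            cov_coefs, index=values.index, columns=cov.columns
        )

    sd = np.sqrt(var_pooled)[:, None]
    s_data = (X - stand_mean) / sd

    gamma_star = {}
    delta_star = {}
    gamma_bar = {}
    tau2 = {}
    a_prior = {}
    b_prior = {}
    n_iterations = {}
    labels = np.asarray(batch_labels)
    adjusted = np.empty_like(s_data)
    for b, nb in zip(batches, n_batches):
        cols = labels == b
        sdat = s_data[:, cols]
        gamma_hat = sdat.mean(axis=1)
        delta_hat = sdat.var(axis=1, ddof=1)
        g_bar = gamma_hat.mean()
        t2 = gamma_hat.var(ddof=1)
        m, v = delta_hat.mean(), delta_hat.var(ddof=1)
        a = (2 * v + m**2) / v
        bp = (m * v + m**3) / v
        g_star, d_star, iters = _eb_iterate(
            gamma_hat, delta_hat, sdat, g_bar, t2, a, bp
        )
        adjusted[:, cols] = (sdat - g_star[:, None]) / np.sqrt(d_star)[:, None]
        gamma_star[b] = g_star
        delta_star[b] = d_star
        gamma_bar[b] = g_bar
        tau2[b] = t2
        a_prior[b] = a
        b_prior[b] = bp
        n_iterations[b] = iters

    adjusted = adjusted * sd + stand_mean
    model = BatchModel(
        batches=batches,
        gamma_star=pd.DataFrame(gamma_star, index=values.index).T,
        delta_star=pd.DataFrame(delta_star, index=values.index).T,
        gamma_bar=pd.Series(gamma_bar),
        tau2=pd.Series(tau2),
        a_prior=pd.Series(a_prior),
        b_prior=pd.Series(b_prior),
        grand_mean=pd.Series(grand_mean, index=values.index),
        var_pooled=pd.Series(var_pooled, index=values.index),
        design_coefs=design_coefs,
        n_iterations=n_iterations,
    )
    out = pd.DataFrame(adjusted, index=values.index, columns=values.columns)
    return compendium.copy_with(out, batch_adjusted=True), model


def impute_sex(
    matrix: pd.DataFrame,
    y_gene_ids: list[str],
    annotated: pd.Series | None = None,
    min_separation: float = 0.5,
) -> pd.Series:
    """Fill blank sex labels from mean Y-chromosome gene expression.

    The per-sample Y-gene means are split by 2-means clustering in one
    dimension (centers initialized at the min and max); the higher cluster
    is labeled male.  Pre-annotated sexes are never overwritten.
    """
    present = [g for g in y_gene_ids if g in matrix.index]
    if not present:
        raise ValueError("none of the Y genes are present in the matrix")
    y_mean = matrix.loc[present].mean(axis=0)
    init = np.array([[y_mean.min()], [y_mean.max()]])
    centers, assignment = kmeans2(
        y_mean.to_numpy()[:, None], init, minit="matrix"
    )
    if abs(centers[1, 0] - centers[0, 0]) < min_separation:
        warnings.warn(
            "impute_sex: Y-gene means unimodal (cluster separation "
            f"{abs(centers[1,0]-centers[0,0]):.3f} < {min_separation}); "
            "no sex imputed"
        )
        imputed = pd.Series("", index=matrix.columns)
    else:
        male_cluster = int(np.argmax(centers[:, 0]))
        imputed = pd.Series(
            np.where(assignment == male_cluster, "male", "female"),
            index=matrix.columns,
        )
    if annotated is not None:
        annotated = annotated.reindex(matrix.columns).fillna("")
        keep = annotated != ""
        imputed[keep] = annotated[keep]
    return imputed


def zscale_genes(
    matrix: pd.DataFrame, grouping: pd.Series | None = None
) -> pd.DataFrame:
    """Per-gene z-scaling, optionally within sample groups (e.g. datasets).

    Zero-variance genes map to all-zeros (kept, with a warning) so that
    panel gene lists retain their length downstream.
    """
    def _z(block: pd.DataFrame) -> pd.DataFrame:
        arr = block.to_numpy(dtype=float)
        mu = arr.mean(axis=1, keepdims=True)
        sd = arr.std(axis=1, ddof=1, keepdims=True)
        flat = sd[:, 0] == 0
        if flat.any():
            warnings.warn(
                f"zscale_genes: {int(flat.sum())} zero-variance gene(s) set to 0"
            )
        sd[flat] = 1.0
        out = (arr - mu) / sd
        out[flat[:, 0] if flat.ndim > 1 else flat, :] = 0.0
        return pd.DataFrame(out, index=block.index, columns=block.columns)

    if grouping is None:
        return _z(matrix)
    grouping = grouping.loc[matrix.columns]
    pieces = []
    for _, cols in grouping.groupby(grouping).groups.items():
        if len(cols) < 2:
            raise ValueError("zscale_genes needs >= 2 samples per group")
        pieces.append(_z(matrix[list(cols)]))
    return pd.concat(pieces, axis=1)[matrix.columns]
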