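"""Covariate-adjusted differential expression with moderated statistics.

Per-gene ordinary least squares on a shared design (intercept + case
status + optional sex / treatment-category covariates), followed by the
empirical-Bayes variance moderation classically used for expression
arrays: per-gene variances s_g^2 are shrunk toward a prior (d0, s0^2)
estimated from the ensemble of log-variances by closed-form moment
matching, and the moderated t is referred to a t distribution on
d0 + d_g degrees of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .datatypes import Compendium


@dataclass
class LinearFits:
    """Per-gene OLS results for the status contrast."""

    coef: pd.Series  # log2FC, case - control
    stdev_unscaled: float  # sqrt((X'X)^-1 diagonal) for the status column
    sigma2: pd.Series  # residual variance per gene
    df_residual: float
    design_columns: list = field(default_factory=list)
    zero_variance: pd.Index = None


@dataclass
class DEResult:
    table: pd.DataFrame  # gene_id x [log2fc, se, t_mod, p, p_adj, direction]
    d0: float
    s0_2: float
    covariates: list = field(default_factory=list)

    @property
    def up(self) -> pd.Index:
        return self.table.index[self.table["direction"] == "up"]

    @property
    def down(self) -> pd.Index:
        return self.table.index[self.table["direction"] == "down"]


def build_design(
    status: pd.Series,
    sex: pd.Series | None = None,
    treatment: pd.Series | None = None,
) -> pd.DataFrame:
    """Intercept + status indicator + optional covariate indicators.

    Treatment is one indicator per category with untreated (empty string)
    as the reference; sex is a single male indicator (blank sex treated as
    the female reference — impute first for better).
    """
    idx = status.index
    cols = {"intercept": np.ones(len(idx)), "status": (status == "case").astype(float)}
    if sex is not None:
        cols["sex_male"] = (sex.loc[idx] == "male").astype(float).to_numpy()
    design = pd.DataFrame(cols, index=idx)
    if treatment is not None:
        t = treatment.loc[idx].fillna("")
        for cat in sorted(c for c in t.unique() if c != ""):
            design[f"treat_{cat}"] = (t == cat).astype(float).to_numpy()
    return design


def fit_linear_de(
    compendium: Compendium | pd.DataFrame,
    status: pd.Series | None = None,
    sex: pd.Series | None = None,
    treatment: pd.Series | None = None,
    design: pd.DataFrame | None = None,
) -> LinearFits:
    """Vectorized per-gene OLS; the contrast is the ``status`` coefficient."""
    values = compendium.values if isinstance(compendium, Compendium) else compendium
    if design is None:
        if status is None:
            raise ValueError("either status labels or a design are required")
        design = build_design(status, sex=sex, treatment=treatment)
    design = design.loc[values.columns]
    X = design.to_numpy(dtype=float)
    n, p = X.shape
    if np.linalg.matrix_rank(X) < p:
        # name the aliased columns for the caller
        _, r = np.linalg.qr(X)
        aliased = [
            design.columns[j] for j in range(p) if abs(r[j, j]) < 1e-8
        ]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")
    counts = (design["status"] > 0).sum(), (design["status"] == 0).sum()
    if min(counts) < 2:
        raise ValueError("need >= 2 samples in each status class")

    Y = values.to_numpy(dtype=float).T  # samples x genes
    xtx_inv = np.linalg.inv(X.T @ X)
    coefs = xtx_inv @ X.T @ Y  # p x genes
    resid = Y - X @ coefs
    df = n - p
    sigma2 = (resid**2).sum(axis=0) / df
    j = list(design.columns).index("status")
    stdev_unscaled = float(np.sqrt(xtx_inv[j, j]))
    zero = values.index[sigma2 <= 0]
    return LinearFits(
        coef=pd.Series(coefs[j], index=values.index, name="log2fc"),
        stdev_unscaled=stdev_unscaled,
        sigma2=pd.Series(sigma2, index=values.index),
        df_residual=float(df),
        design_columns=list(design.columns),
        zero_variance=zero,
    )


def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration (monotone, convex)."""
    if x <= 0:
        return np.inf
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if -dif / y < 1e-8:
            break
    return float(y)


def estimate_variance_prior(
    sigma2: np.ndarray, df: float
) -> tuple[float, float]:
    """Moment-match (d0, s0^2) from log sample variances.

    Fits the scaled-F model for s_g^2 by matching the mean and variance of
    z = log s^2 against digamma/trigamma expressions; a non-positive excess
    variance selects the d0 = inf branch (all variances equal s0^2).
    """
    sigma2 = np.asarray(sigma2, dtype=float)
    if not np.isfinite(sigma2).all():
        raise ValueError("non-finite residual variances")
    ok = sigma2 > 0
    z = np.log(sigma2[ok])
    if np.ptp(z) == 0:
        # zero ensemble spread: the prior is the common variance itself
        return np.inf, float(np.exp(z[0]))
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    e_bar = e.mean()
    n = len(e)
    excess = ((e - e_bar) ** 2).mean() * n / (n - 1) - special.polygamma(1, df / 2.0)
    if excess <= 0:
        d0 = np.inf
        s0_2 = float(np.exp(e_bar))
    else:
        d0 = 2.0 * trigamma_inverse(excess)
        s0_2 = float(np.exp(e_bar + special.digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    return float(d0), s0_2


def moderate_statistics(
    fits: LinearFits, d0: float | None = None, s0_2: float | None = None
) -> DEResult:
    """Empirical-Bayes moderated t-statistics and BH-adjusted p-values."""
    sigma2 = fits.sigma2.to_numpy()
    if len(sigma2) < 10:
        raise ValueError("need >= 10 genes to estimate the variance prior")
    d = fits.df_residual
    if d0 is None or s0_2 is None:
        d0_est, s0_est = estimate_variance_prior(sigma2, d)
        d0 = d0_est if d0 is None else d0
        s0_2 = s0_est if s0_2 is None else s0_2
    if np.isinf(d0):
        s2_post = np.full_like(sigma2, s0_2)
        df_total = np.inf
    else:
        s2_post = (d0 * s0_2 + d * sigma2) / (d0 + d)
        df_total = d0 + d
    coef = fits.coef.to_numpy()
    t_mod = coef / (fits.stdev_unscaled * np.sqrt(s2_post))
    if np.isinf(df_total):
        p = 2 * stats.norm.sf(np.abs(t_mod))
    else:
        p = 2 * stats.t.sf(np.abs(t_mod), df_total)
    p_adj = bh_adjust(p)
    table = pd.DataFrame(
        {
            "log2fc": coef,
            "se": fits.stdev_unscaled * np.sqrt(sigma2),
            "t_mod": t_mod,
            "p": p,
            "p_adj": p_adj,
            "direction": "ns",
        },
        index=fits.coef.index,
    )
    return DEResult(
        table=table,
        d0=float(d0),
        s0_2=float(s0_2),
        covariates=[c for c in fits.design_columns if c not in ("intercept", "status")],
    )


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment (cumulative-min enforced)."""
    p = np.asarray(pvals, dtype=float)
    if ((p < 0) | (p > 1)).any() or not np.isfinite(p).all():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_de(de: DEResult, fdr: float = 0.05, fc: float = 1.2) -> DEResult:
    """Apply the FDR + fold-change gate and set direction calls.

    The fold-change cutoff is on the ratio scale: |log2FC| > log2(fc).
    """
    if fc <= 1:
        raise ValueError("fold-change cutoff must exceed 1")
    lfc = np.log2(fc)
    t = de.table
    sig = t["p_adj"] < fdr
    t["direction"] = np.where(
        sig & (t["log2fc"] > lfc),
        "up",
        np.where(sig & (t["log2fc"] < -lfc), "down", "ns"),
    )
    return de


@dataclass
class OverlapResult:
    concordant_up: list
    concordant_down: list
    discordant: list
    p_up: float
    p_down: float
    params_up: tuple  # (N, K, n, k)
    params_down: tuple


def hypergeom_overlap_test(N: int, K: int, n: int, k: int) -> float:
    """Upper-tail P(X >= k) under Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent counts N={N}, K={K}, n={n}, k={k}")
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def cross_tissue_overlap(
    de_a: DEResult, de_b: DEResult, background_n: int
) -> OverlapResult:
    """Concordant / discordant DE sets between two tissues with overlap p."""
    up_a, down_a = set(de_a.up), set(de_a.down)
    up_b, down_b = set(de_b.up), set(de_b.down)
    union = up_a | down_a | up_b | down_b
    if background_n < len(union):
        raise ValueError("background smaller than the union of DE sets")
    con_up = sorted(up_a & up_b)
    con_down = sorted(down_a & down_b)
    disc = sorted((up_a & down_b) | (down_a & up_b))
    params_up = (background_n, len(up_a), len(up_b), len(con_up))
    params_down = (background_n, len(down_a), len(down_b), len(con_down))
    return OverlapResult(
        concordant_up=con_up,
        concordant_down=con_down,
        discordant=disc,
        p_up=hypergeom_overlap_test(*params_up),
        p_down=hypergeom_overlap_test(*params_down),
        params_up=params_up,
        params_down=params_down,
    )


def ora(
    query_set, collections: dict[str, list], background
) -> pd.DataFrame:
    """Hypergeometric over-representation of a query set in collections."""
    background = set(background)
    if not background:
        raise ValueError("empty background")
    if not collections:
        raise ValueError("no collections supplied")
    query = set(query_set) & background
    if set(query_set) - background:
        raise ValueError("query set contains genes outside the background")
    rows = []
    for name, members in collections.items():
        members = set(members) & background
        k = len(query & members)
        N, K, n = len(background), len(members), len(query)
        rows.append(
            {
                "collection": name,
                "N": N,
                "K": K,
                "n": n,
                "k": k,
                "p": hypergeom_overlap_test(N, K, n, k),
            }
        )
    out = pd.DataFrame(rows).set_index("collection")
    out["p_adj"] = bh_adjust(out["p"].to_numpy())
    return out
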