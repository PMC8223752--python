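"""Independent, deliberately naive reference implementations used only to
cross-check the package.  Everything here is written as straight-line or
brute-force code, separate from the library's vectorized paths."""

import itertools
import math

import numpy as np


def auroc_by_pair_counting(scores, labels) -> float:
    """AUROC as the fraction of (positive, negative) pairs ranked correctly,
    ties counting one half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                wins += 1.0
            elif p == q:
                wins += 0.5
    return wins / (len(pos) * len(neg))


def hypergeom_upper_tail_enumeration(N, K, n, k) -> float:
    """P(X >= k) by direct summation of the hypergeometric pmf."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += (
            math.comb(K, x) * math.comb(N - K, n - x) / math.comb(N, n)
        )
    return total


def bh_stepup(p) -> np.ndarray:
    """Benjamini-Hochberg by the literal step-up definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    prev = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        rank = m - rank_from_top
        val = min(prev, p[idx] * m / rank)
        adj[idx] = val
        prev = val
    return adj


def combat_reference(X, batches, conv=1e-4, max_iter=100):
    """Straight-line parametric empirical-Bayes batch adjustment.

    Follows the published location/scale model step by step with explicit
    per-gene loops, no covariates: standardize against the weighted grand
    mean and pooled variance, estimate per-batch location gamma_hat and
    scale delta_hat, shrink via the iterative posterior-mean updates under
    the normal / inverse-gamma priors, and back-transform.
    """
    X = np.asarray(X, dtype=float)
    batches = np.asarray(batches)
    levels = list(dict.fromkeys(batches))
    G, n = X.shape
    n_i = {b: int((batches == b).sum()) for b in levels}

    batch_mean = {b: X[:, batches == b].mean(axis=1) for b in levels}
    alpha = np.zeros(G)
    for b in levels:
        alpha += n_i[b] / n * batch_mean[b]
    var_pooled = np.zeros(G)
    for g in range(G):
        s = 0.0
        for j in range(n):
            s += (X[g, j] - batch_mean[batches[j]][g]) ** 2
        var_pooled[g] = s / n
    Z = (X - alpha[:, None]) / np.sqrt(var_pooled)[:, None]

    out = np.empty_like(Z)
    for b in levels:
        cols = batches == b
        zb = Z[:, cols]
        nb = n_i[b]
        gamma_hat = zb.mean(axis=1)
        delta_hat = zb.var(axis=1, ddof=1)
        g_bar = gamma_hat.mean()
        t2 = gamma_hat.var(ddof=1)
        m_d = delta_hat.mean()
        v_d = delta_hat.var(ddof=1)
        a_prior = (2 * v_d + m_d**2) / v_d
        b_prior = (m_d * v_d + m_d**3) / v_d

        g_old = gamma_hat.copy()
        d_old = delta_hat.copy()
        for _ in range(max_iter):
            g_new = np.empty(G)
            d_new = np.empty(G)
            for g in range(G):
                g_new[g] = (t2 * nb * gamma_hat[g] + d_old[g] * g_bar) / (
                    t2 * nb + d_old[g]
                )
                ss = float(((zb[g] - g_new[g]) ** 2).sum())
                d_new[g] = (0.5 * ss + b_prior) / (nb / 2 + a_prior - 1)
            change = max(
                np.max(np.abs(g_new - g_old) / np.maximum(np.abs(g_old), 1e-12)),
                np.max(np.abs(d_new - d_old) / np.maximum(np.abs(d_old), 1e-12)),
            )
            g_old, d_old = g_new, d_new
            if change < conv:
                break
        out[:, cols] = (zb - g_old[:, None]) / np.sqrt(d_old)[:, None]
    return out * np.sqrt(var_pooled)[:, None] + alpha[:, None]


def ora_enumeration_p(N, K, n, k) -> float:
    """Exact overlap tail by enumerating over the overlap count support."""
    return hypergeom_upper_tail_enumeration(N, K, n, k)


def aucpr_by_step_curve(scores, labels) -> float:
    """Average precision: sum of precision x recall increments over the
    ranked list, ties processed as one block."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = labels.sum()
    order = np.argsort(-scores, kind="mergesort")
    s, y = scores[order], labels[order]
    ap = 0.0
    tp = fp = 0
    i = 0
    prev_recall = 0.0
    while i < len(s):
        j = i
        while j < len(s) and s[j] == s[i]:
            j += 1
        tp += int(y[i:j].sum())
        fp += int((1 - y[i:j]).sum())
        recall = tp / n_pos
        precision = tp / (tp + fp)
        ap += (recall - prev_recall) * precision
        prev_recall = recall
        i = j
    return ap
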