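"""Independent brute-force oracles used to pin the implementations.

Everything here is written from the definitions, deliberately naive, and
shares no code path with the package.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def ssgsea_running_sum(expr_df: pd.DataFrame, set_genes, alpha: float) -> np.ndarray:
    """Literal running-sum single-sample enrichment score, one sample at a time.

    Genes are ordered by expression descending with ties broken by ascending
    gene id; rank weight is G - position + 1; the score is the sum over
    positions of (weighted in-set CDF - uniform out-of-set CDF).
    """
    genes = list(expr_df.index)
    set_genes = set(set_genes) & set(genes)
    G = len(genes)
    m = len(set_genes)
    assert 0 < m < G
    out = []
    for sample in expr_df.columns:
        col = expr_df[sample]
        ordered = sorted(genes, key=lambda g: (-col[g], g))
        weights = {g: float(G - pos) for pos, g in enumerate(ordered)}  # G..1
        denom_in = sum(weights[g] ** alpha for g in set_genes)
        es = 0.0
        cum_in = 0.0
        cum_out = 0
        for g in ordered:
            if g in set_genes:
                cum_in += weights[g] ** alpha
            else:
                cum_out += 1
            es += cum_in / denom_in - cum_out / (G - m)
        out.append(es)
    return np.array(out)


def spearman_rank_pearson(x, y) -> float:
    """Spearman rho as average ranks followed by a product-moment correlation."""

    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        ranks = np.empty(len(v))
        for i, vi in enumerate(v):
            less = np.sum(v < vi)
            equal = np.sum(v == vi)
            ranks[i] = less + (equal + 1) / 2.0
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx @ ry) / np.sqrt((rx @ rx) * (ry @ ry)))


def ranksum_exact_two_sided(x, y) -> float:
    """Exact two-sided rank-sum p by enumeration of all group assignments."""
    from itertools import combinations

    pooled = np.concatenate([x, y])
    n1 = len(x)
    ranks = pd.Series(pooled).rank().to_numpy()
    obs = ranks[:n1].sum()
    stats = [sum(ranks[list(idx)]) for idx in combinations(range(len(pooled)), n1)]
    stats = np.array(stats)
    mean = stats.mean()
    p = np.mean(np.abs(stats - mean) >= np.abs(obs - mean) - 1e-12)
    return float(p)


def pair_count_auc(scores, labels) -> float:
    """AUC as the literal probability a positive outscores a negative."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for a in pos:
        for b in neg:
            total += 1.0 if a > b else 0.5 if a == b else 0.0
    return total / (len(pos) * len(neg))


def td_auc_no_censoring(scores, time, t) -> float:
    """Cumulative/dynamic AUC(t) by exhaustive pair enumeration, no censoring."""
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    cases = scores[time <= t]
    ctrls = scores[time > t]
    total = 0.0
    for a in cases:
        for b in ctrls:
            total += 1.0 if a > b else 0.5 if a == b else 0.0
    return total / (len(cases) * len(ctrls))


def power_iteration_first_right_singular(M: np.ndarray, iters: int = 5000) -> np.ndarray:
    """First right singular vector of M via power iteration on M^T M."""
    A = M.T @ M
    v = np.ones(A.shape[0]) / np.sqrt(A.shape[0])
    for _ in range(iters):
        v_new = A @ v
        v_new /= np.linalg.norm(v_new)
        if np.allclose(v_new, v, atol=1e-14):
            v = v_new
            break
        v = v_new
    return v


def logrank_by_hand(time, event, group) -> float:
    """Log-rank chi-square from the 2x2 tables at each distinct event time."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    group = np.asarray(group)
    levels = sorted(set(group))
    o_a = e_a = var = 0.0
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        n = at_risk.sum()
        n_a = (at_risk & (group == levels[0])).sum()
        d = ((time == t) & (event == 1)).sum()
        d_a = ((time == t) & (event == 1) & (group == levels[0])).sum()
        o_a += d_a
        e_a += d * n_a / n
        if n > 1:
            var += d * (n - d) * n_a * (n - n_a) / (n**2 * (n - 1))
    return float((o_a - e_a) ** 2 / var)
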