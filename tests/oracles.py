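"""Independent naive reference implementations used only to check the package.

Everything here is written as directly from the definitions as possible —
explicit double loops, exhaustive enumeration — and shares no code with the
implementation under test.
"""

from fractions import Fraction
from itertools import combinations

import numpy as np


def naive_ssgsea(ordered_genes, rank_values, members, alpha):
    """Double-loop running-sum ssGSEA score, straight from the definition."""
    n = len(ordered_genes)
    in_set = [g in members for g in ordered_genes]
    sum_w = sum(rank_values[j] ** alpha for j in range(n) if in_set[j])
    n_out = n - sum(in_set)
    es = 0.0
    for i in range(n):
        p_in = sum(rank_values[j] ** alpha for j in range(i + 1) if in_set[j]) / sum_w
        p_out = sum(1 for j in range(i + 1) if not in_set[j]) / n_out
        es += p_in - p_out
    return es


def naive_gsea_es(ordered_genes, weights, members, exponent):
    """Naive weighted-KS walk; returns the signed extreme deviation."""
    n = len(ordered_genes)
    in_set = [g in members for g in ordered_genes]
    w = [abs(weights[j]) ** exponent for j in range(n)]
    denom = sum(w[j] for j in range(n) if in_set[j])
    n_out = n - sum(in_set)
    running = 0.0
    best = 0.0
    for i in range(n):
        if in_set[i]:
            running += (w[i] / denom) if denom > 0 else 1.0 / sum(in_set)
        else:
            running -= 1.0 / n_out
        if abs(running) > abs(best):
            best = running
    return best


def enumerate_ranksum_p(a, b):
    """Exact two-sided Wilcoxon rank-sum p by enumerating all label assignments.

    Two-sided p doubles the smaller tail probability of the rank-sum statistic
    (capped at 1), matching the exact Mann-Whitney distribution for untied data.
    """
    pooled = np.concatenate([a, b])
    ranks = np.argsort(np.argsort(pooled)) + 1
    n_a = len(a)
    obs = ranks[:n_a].sum()
    sums = np.array([sum(ranks[list(idx)]) for idx in combinations(range(len(pooled)), n_a)])
    total = len(sums)
    ge = int((sums >= obs).sum())
    le = int((sums <= obs).sum())
    return min(Fraction(1), 2 * Fraction(min(ge, le), total))


def brute_spearman(x, y):
    """Spearman rho from average ranks, computed with the plain product-moment formula."""

    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sorted_v[j] == sorted_v[i]:
                j += 1
            ranks[order[i:j]] = (i + j + 1) / 2.0
            i = j
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))
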