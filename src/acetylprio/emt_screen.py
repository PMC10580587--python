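"""Spearman correlation screen of candidate genes against per-sample EMT scores.

A gene passes the screen when its tie-aware Spearman correlation with the EMT
scores satisfies both |SCC| >= scc_min and p <= p_max, with inclusive
boundaries.  The two-sided p-value uses the t-distribution approximation with
n-2 degrees of freedom; an exact permutation p is available for very small n.
"""

from __future__ import annotations

from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats

from acetylprio.errors import AlignmentError, DegenerateInputError, ValidationError
from acetylprio.io_formats import ExpressionMatrix
from acetylprio.de_ranking import P_FLOOR, ScreenThresholds


def _t_pvalue(r: np.ndarray, n: int) -> np.ndarray:
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    return np.clip(p, P_FLOOR, 1.0)


def spearman(x, y, exact: bool = False) -> tuple[float, float]:
    """Tie-aware Spearman correlation with a two-sided p-value.

    ``exact=True`` enumerates all rank permutations (only sensible for n < 10).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("x and y must be 1-D of equal length")
    n = x.size
    if n < 4:
        raise ValidationError(f"need at least 4 observations, got {n}")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input vector")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    scc = float(np.corrcoef(rx, ry)[0, 1])
    if exact:
        if n > 9:
            raise ValidationError("exact permutation p only supported for n <= 9")
        obs = abs(scc)
        count = 0
        total = 0
        for perm in permutations(ry):
            total += 1
            if abs(np.corrcoef(rx, np.asarray(perm))[0, 1]) >= obs - 1e-12:
                count += 1
        return scc, count / total
    return scc, float(_t_pvalue(np.asarray(scc), n))


def passes_filter(scc: float, p: float, thresholds: ScreenThresholds | None = None) -> bool:
    """Joint pass/fail rule with inclusive boundaries: |SCC| >= scc_min and p <= p_max."""
    thresholds = thresholds or ScreenThresholds()
    return bool(p <= thresholds.p_max and abs(scc) >= thresholds.scc_min)


def screen(
    matrix: ExpressionMatrix,
    emt_scores: pd.Series,
    gene_list: list[str],
    thresholds: ScreenThresholds | None = None,
) -> pd.DataFrame:
    """Correlate each listed gene with the EMT scores and apply the joint filter.

    Samples are aligned by id (mismatch is an error listing the offenders).
    Listed genes absent from the matrix are reported with ``missing=True`` and
    direction 'none' rather than dropped.
    """
    thresholds = thresholds or ScreenThresholds()
    matrix_ids = set(matrix.sample_ids)
    score_ids = set(emt_scores.index)
    if matrix_ids != score_ids:
        offenders = sorted(matrix_ids.symmetric_difference(score_ids))
        raise AlignmentError(f"sample ids differ between matrix and EMT scores: {offenders[:10]}")

    present = [g for g in gene_list if g in set(matrix.gene_ids)]
    missing = [g for g in gene_list if g not in set(matrix.gene_ids)]

    y = emt_scores.loc[matrix.sample_ids].to_numpy()
    n = y.size
    ry = stats.rankdata(y)
    sub = matrix.data.loc[present].to_numpy()
    rx = stats.rankdata(sub, axis=1)
    rx_c = rx - rx.mean(axis=1, keepdims=True)
    ry_c = ry - ry.mean()
    denom = np.sqrt((rx_c**2).sum(axis=1) * (ry_c**2).sum())
    if np.any(denom == 0):
        bad = [present[i] for i in np.nonzero(denom == 0)[0]]
        raise DegenerateInputError(f"constant expression for genes: {bad[:10]}")
    scc = rx_c @ ry_c / denom
    p = _t_pvalue(scc, n)
    passes = (p <= thresholds.p_max) & (np.abs(scc) >= thresholds.scc_min)
    direction = np.where(passes & (scc > 0), "positive", np.where(passes & (scc < 0), "negative", "none"))

    out = pd.DataFrame(
        {
            "gene_id": present + missing,
            "scc": np.concatenate([scc, np.full(len(missing), np.nan)]),
            "p": np.concatenate([p, np.full(len(missing), np.nan)]),
            "passes": np.concatenate([passes, np.zeros(len(missing), dtype=bool)]),
            "direction": np.concatenate([direction, np.full(len(missing), "none", dtype=object)]),
            "missing": [False] * len(present) + [True] * len(missing),
        }
    )
    return out
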