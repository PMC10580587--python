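"""Two-group Wilcoxon differential expression and the composite rank score R.

For each gene the cancer-vs-normal contrast yields a two-sided rank-sum
p-value and a fold change computed on the log2 scale
(log2FC = mean_cancer - mean_normal).  The two are combined into the
composite rank score

    R = -log10(p) * log2(FC)

whose sign follows the regulation direction; genes are ranked by R and the
top fraction (default 30%) is carried into the prioritization overlap.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from acetylprio.errors import DomainError, InsufficientSamplesError, ValidationError
from acetylprio.io_formats import ExpressionMatrix, SampleAnnotation

P_FLOOR = 1e-300  # prevents infinite R for vanishing p-values


@dataclass(frozen=True)
class ScreenThresholds:
    """Cutoffs for the DE and correlation screens; boundaries are inclusive."""

    p_max: float = 0.05
    scc_min: float = 0.3
    top_fraction: float = 0.30

    def __post_init__(self) -> None:
        problems = []
        if not (0 < self.p_max <= 1):
            problems.append(f"p_max={self.p_max} not in (0, 1]")
        if not (0 <= self.scc_min <= 1):
            problems.append(f"scc_min={self.scc_min} not in [0, 1]")
        if not (0 < self.top_fraction <= 1):
            problems.append(f"top_fraction={self.top_fraction} not in (0, 1]")
        if problems:
            raise ValidationError("; ".join(problems))


def _group_values(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    group_a: str,
    group_b: str,
    min_size: int,
) -> tuple[np.ndarray, np.ndarray]:
    ids_a = annotation.samples_in_state(group_a) or annotation.samples_in_stage(group_a)
    ids_b = annotation.samples_in_state(group_b) or annotation.samples_in_stage(group_b)
    for name, ids in ((group_a, ids_a), (group_b, ids_b)):
        if len(ids) < min_size:
            raise InsufficientSamplesError(
                f"group {name!r} has {len(ids)} samples, needs >= {min_size}"
            )
    return matrix.data[ids_a].to_numpy(), matrix.data[ids_b].to_numpy()


def wilcoxon_de(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    group_a: str = "cancer",
    group_b: str = "normal",
) -> pd.Series:
    """Two-sided Wilcoxon rank-sum p-value per gene for group_a vs group_b.

    Uses the exact null distribution when the smaller group has <= 8 samples
    and the gene's values are untied, and the normal approximation with tie
    and continuity correction otherwise.  p is clamped to [1e-300, 1].
    """
    a, b = _group_values(matrix, annotation, group_a, group_b, min_size=2)
    small = min(a.shape[1], b.shape[1]) <= 8
    if not small:
        res = stats.mannwhitneyu(a, b, axis=1, method="asymptotic", use_continuity=True)
        p = np.asarray(res.pvalue, dtype=float)
        # fully tied rows make the tie-corrected variance vanish -> no evidence
        tied = np.ptp(np.concatenate([a, b], axis=1), axis=1) == 0
        p[tied] = 1.0
    else:
        p = np.empty(a.shape[0])
        for i in range(a.shape[0]):
            row = np.concatenate([a[i], b[i]])
            if np.ptp(row) == 0:
                p[i] = 1.0
                continue
            has_ties = len(np.unique(row)) < len(row)
            method = "asymptotic" if has_ties else "exact"
            p[i] = stats.mannwhitneyu(
                a[i], b[i], method=method, use_continuity=True
            ).pvalue
    p = np.clip(p, P_FLOOR, 1.0)
    return pd.Series(p, index=matrix.gene_ids, name="p")


def fold_change(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    group_a: str = "cancer",
    group_b: str = "normal",
) -> pd.DataFrame:
    """Per-gene fold change of group_a over group_b on the log2 scale."""
    a, b = _group_values(matrix, annotation, group_a, group_b, min_size=1)
    log2fc = a.mean(axis=1) - b.mean(axis=1)
    return pd.DataFrame(
        {"fc": np.exp2(log2fc), "log2fc": log2fc}, index=matrix.gene_ids
    )


def rank_score(p, fc):
    """Composite rank score R = -log10(p) * log2(fc); vectorized."""
    p = np.asarray(p, dtype=float)
    fc = np.asarray(fc, dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise DomainError("p must lie in (0, 1]")
    if np.any(fc <= 0):
        raise DomainError("fold change must be positive")
    r = -np.log10(p) * np.log2(fc)
    return float(r) if r.ndim == 0 else r


def differential_rank(
    matrix: ExpressionMatrix,
    annotation: SampleAnnotation,
    genes: list[str] | None = None,
    thresholds: ScreenThresholds | None = None,
    group_a: str = "cancer",
    group_b: str = "normal",
) -> pd.DataFrame:
    """Full differential table: p, BH-adjusted p, fc, log2fc, R and DE class.

    ``genes`` restricts the table to a candidate collection (ids absent from
    the matrix are ignored).  The BH column is informational only; the DE
    class uses the raw p-value cutoff.
    """
    thresholds = thresholds or ScreenThresholds()
    if genes is not None:
        present = [g for g in genes if g in set(matrix.gene_ids)]
        matrix = ExpressionMatrix(matrix.data.loc[present])
    p = wilcoxon_de(matrix, annotation, group_a, group_b)
    fcs = fold_change(matrix, annotation, group_a, group_b)
    r = rank_score(p.to_numpy(), fcs["fc"].to_numpy())
    de_class = np.where(
        (p.to_numpy() <= thresholds.p_max) & (fcs["log2fc"].to_numpy() > 0),
        "up",
        np.where(
            (p.to_numpy() <= thresholds.p_max) & (fcs["log2fc"].to_numpy() < 0),
            "down",
            "not_de",
        ),
    )
    out = pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "p": p.to_numpy(),
            "p_bh": _benjamini_hochberg(p.to_numpy()),
            "fc": fcs["fc"].to_numpy(),
            "log2fc": fcs["log2fc"].to_numpy(),
            "r_score": r,
            "de_class": de_class,
        }
    )
    return out


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    n = p.size
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    adj[order] = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
    return np.clip(adj, 0.0, 1.0)


def select_top(results: pd.DataFrame, thresholds: ScreenThresholds | None = None) -> pd.DataFrame:
    """Top fraction of genes by descending R score (ties broken by gene id).

    Returns the first floor(top_fraction * n) rows, at least one.
    """
    thresholds = thresholds or ScreenThresholds()
    if results.empty:
        raise ValidationError("empty differential table")
    ordered = results.sort_values(
        ["r_score", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    k = max(1, math.floor(thresholds.top_fraction * len(ordered)))
    top = ordered.head(k).copy()
    top.insert(1, "r_rank", np.arange(1, k + 1))
    return top
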