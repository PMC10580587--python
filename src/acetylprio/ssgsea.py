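"""Single-sample gene-set enrichment (ssGSEA) for per-sample EMT activity.

Each sample's genes are ranked by decreasing expression (rank value N for the
highest-expressed gene, ties broken lexicographically by gene id).  Walking the
ranked list, the enrichment score accumulates the difference between the
weighted in-set cumulative distribution (weights ``rank**alpha``) and the
uniform out-of-set cumulative distribution:

    ES = sum_i [ P_in(i) - P_out(i) ]

With ``normalize=True`` the raw per-sample scores are divided by the
(max - min) spread across the cohort, which fixes the score range without
changing the sample ordering.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from acetylprio.errors import DegenerateComplementError, EmptySetError, ValidationError
from acetylprio.io_formats import ExpressionMatrix, GeneSet


@dataclass(frozen=True)
class SsgseaParams:
    """Rank-weight exponent and cross-sample normalization switch."""

    alpha: float = 0.25
    normalize: bool = True

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ValidationError(f"alpha must be >= 0, got {self.alpha}")


def rank_genes_in_sample(column: pd.Series) -> tuple[list[str], np.ndarray]:
    """Order genes by decreasing expression; return (ordered ids, rank weights N..1).

    Ties are broken by gene-id lexicographic order so the ranking is
    deterministic regardless of input order.
    """
    if len(column) < 2:
        raise ValidationError("ranking needs at least 2 genes")
    frame = pd.DataFrame({"expr": column})
    frame = frame.sort_index().sort_values("expr", ascending=False, kind="stable")
    n = len(frame)
    return list(frame.index), np.arange(n, 0, -1, dtype=float)


def ssgsea_score(
    ordered_genes: list[str], weights: np.ndarray, gene_set: GeneSet | set[str], alpha: float = 0.25
) -> float:
    """Running-sum enrichment score of one ranked sample against one gene set."""
    members = set(gene_set.members) if isinstance(gene_set, GeneSet) else set(gene_set)
    hit = np.fromiter((g in members for g in ordered_genes), dtype=bool, count=len(ordered_genes))
    n = hit.size
    n_hit = int(hit.sum())
    if n_hit == 0:
        raise EmptySetError("gene set does not intersect the ranked genes")
    if n_hit == n:
        raise DegenerateComplementError("gene set covers all ranked genes")
    w = np.asarray(weights, dtype=float) ** alpha
    p_in = np.cumsum(np.where(hit, w, 0.0)) / np.sum(w[hit])
    p_out = np.cumsum(~hit) / float(n - n_hit)
    return float(np.sum(p_in - p_out))


def emt_scores(
    matrix: ExpressionMatrix, emt_set: GeneSet, params: SsgseaParams | None = None
) -> pd.Series:
    """Per-sample ssGSEA enrichment score for one gene set (the "EMT score").

    Set members absent from the matrix are dropped with a logged count.
    """
    params = params or SsgseaParams()
    present = emt_set.intersect(matrix.gene_ids)
    members = set(present.members)

    # Vectorized equivalent of scoring each sample column independently:
    # argsort each column by (-expression, gene id).
    data = matrix.data.sort_index()
    values = data.to_numpy()
    n_genes, n_samples = values.shape
    is_member = data.index.isin(members)
    order = np.argsort(-values, axis=0, kind="stable")  # index ties resolved by sorted gene ids
    rank_w = np.arange(n_genes, 0, -1, dtype=float)[:, None] ** params.alpha
    hit = is_member[order]
    n_hit = int(is_member.sum())
    if n_hit == n_genes:
        raise DegenerateComplementError("gene set covers all measured genes")
    w_hit = np.where(hit, rank_w, 0.0)
    p_in = np.cumsum(w_hit, axis=0) / w_hit.sum(axis=0)
    p_out = np.cumsum(~hit, axis=0) / float(n_genes - n_hit)
    raw = (p_in - p_out).sum(axis=0)

    scores = pd.Series(raw, index=matrix.sample_ids, name="emt_score")
    if params.normalize:
        spread = scores.max() - scores.min()
        if spread > 0:
            scores = scores / spread
    return scores
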