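"""Intersection of the top-R-ranked genes with the EMT-correlated genes.

The candidate list keeps the genes that (a) sit in the top fraction of the R
ranking, (b) pass the correlation screen (positively, by default) and (c) are
up-regulated in cancer.  Ordering is by descending R score; provenance columns
carry each candidate's rank, correlation and pass flags.
"""

from __future__ import annotations

import logging

import pandas as pd

from acetylprio.errors import ValidationError

logger = logging.getLogger(__name__)


def overlap(
    top_ranked: pd.DataFrame,
    screen_results: pd.DataFrame,
    require_positive: bool = True,
    require_up: bool = True,
) -> pd.DataFrame:
    """Candidate set: top-ranked genes whose correlation screen passes.

    ``top_ranked`` is the output of :func:`acetylprio.de_ranking.select_top`
    (gene_id, r_rank, r_score, de_class, ...); ``screen_results`` comes from
    :func:`acetylprio.emt_screen.screen`.  An empty intersection is a valid,
    logged outcome.
    """
    if top_ranked.empty or screen_results.empty:
        raise ValidationError("overlap inputs must be non-empty tables")
    passers = screen_results[screen_results["passes"]]
    if require_positive:
        passers = passers[passers["direction"] == "positive"]
    merged = top_ranked.merge(
        passers[["gene_id", "scc", "p"]].rename(columns={"p": "scc_p"}),
        on="gene_id",
        how="inner",
    )
    if require_up and "de_class" in merged.columns:
        merged = merged[merged["de_class"] == "up"]
    merged = merged.sort_values(
        ["r_score", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    if merged.empty:
        logger.warning("candidate overlap is empty")
    return merged
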