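"""End-to-end orchestration: EMT scoring -> DE ranking -> correlation screen
-> candidate overlap -> per-candidate GSEA, with a machine-readable report.

The same computation is exposed twice: :func:`run_analysis` works on in-memory
objects (what tests and the analysis scripts use) and :func:`run_pipeline`
reads a YAML-configured set of files, writes every stage's table and a JSON
report.  Reports contain only data and parameters, never timestamps, so a
rerun with the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from acetylprio.de_ranking import ScreenThresholds, differential_rank, select_top
from acetylprio.emt_screen import screen
from acetylprio.errors import ValidationError
from acetylprio.gsea import correlation_profile, permutation_p
from acetylprio.io_formats import (
    ExpressionMatrix,
    GeneSet,
    SampleAnnotation,
    read_annotation,
    read_expression,
    read_gmt,
    write_results_table,
)
from acetylprio.prioritize import overlap
from acetylprio.ssgsea import SsgseaParams, emt_scores

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    expr_path: str
    ann_path: str
    gmt_path: str
    outdir: str
    emt_set_name: str = "EMT"
    acetyl_set_name: str = "ACETYLTRANSFERASE_ACTIVITY"
    log2_transform: bool = False
    alpha: float = 0.25
    normalize: bool = True
    p_max: float = 0.05
    scc_min: float = 0.3
    top_fraction: float = 0.30
    require_positive: bool = True
    require_up: bool = True
    gsea_exponent: float = 1.0
    n_perm: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        missing = [p for p in (self.expr_path, self.ann_path, self.gmt_path) if not Path(p).exists()]
        if missing:
            raise ValidationError(f"missing input files: {missing}")
        ScreenThresholds(self.p_max, self.scc_min, self.top_fraction)
        SsgseaParams(self.alpha, self.normalize)


@dataclass
class AnalysisResult:
    emt: pd.Series
    de: pd.DataFrame
    top: pd.DataFrame
    screen: pd.DataFrame
    candidates: pd.DataFrame
    gsea: pd.DataFrame
    report: dict = field(default_factory=dict)


def run_analysis(
    expression: ExpressionMatrix,
    annotation: SampleAnnotation,
    emt_set: GeneSet,
    acetyl_genes: list[str],
    ssgsea_params: SsgseaParams | None = None,
    thresholds: ScreenThresholds | None = None,
    require_positive: bool = True,
    require_up: bool = True,
    gsea_exponent: float = 1.0,
    n_perm: int = 1000,
    seed: int = 0,
    run_gsea: bool = True,
) -> AnalysisResult:
    """Run every analysis stage on in-memory inputs and assemble the report."""
    ssgsea_params = ssgsea_params or SsgseaParams()
    thresholds = thresholds or ScreenThresholds()
    annotation.validate_against(expression)

    emt = emt_scores(expression, emt_set, ssgsea_params)
    de = differential_rank(expression, annotation, genes=acetyl_genes, thresholds=thresholds)
    top = select_top(de, thresholds)
    scr = screen(expression, emt, acetyl_genes, thresholds)
    cand = overlap(top, scr, require_positive=require_positive, require_up=require_up)

    gsea_rows = []
    if run_gsea:
        for i, gene in enumerate(cand["gene_id"]):
            profile = correlation_profile(expression, gene)
            res = permutation_p(
                profile, emt_set, n_perm=n_perm, seed=seed + i, exponent=gsea_exponent
            )
            gsea_rows.append(
                {
                    "gene_id": gene,
                    "es": res.es,
                    "p_perm": res.p_perm,
                    "n_perm": res.n_perm,
                    "n_leading_edge": len(res.leading_edge),
                    "leading_edge": ",".join(res.leading_edge),
                    "seed": res.seed,
                }
            )
    gsea_df = pd.DataFrame(
        gsea_rows,
        columns=["gene_id", "es", "p_perm", "n_perm", "n_leading_edge", "leading_edge", "seed"],
    )

    report = {
        "n_genes": expression.shape[0],
        "n_samples": expression.shape[1],
        "n_acetyl_genes": int(len(de)),
        "n_up": int((de["de_class"] == "up").sum()),
        "n_down": int((de["de_class"] == "down").sum()),
        "n_top_ranked": int(len(top)),
        "n_positive_correlated": int((scr["direction"] == "positive").sum()),
        "n_negative_correlated": int((scr["direction"] == "negative").sum()),
        "n_candidates": int(len(cand)),
        "candidates": list(cand["gene_id"]),
        "empty_overlap": bool(cand.empty),
        "params": {
            "alpha": ssgsea_params.alpha,
            "normalize": ssgsea_params.normalize,
            "p_max": thresholds.p_max,
            "scc_min": thresholds.scc_min,
            "top_fraction": thresholds.top_fraction,
            "require_positive": require_positive,
            "require_up": require_up,
            "gsea_exponent": gsea_exponent,
            "n_perm": n_perm,
            "seed": seed,
        },
    }
    return AnalysisResult(emt=emt, de=de, top=top, screen=scr, candidates=cand, gsea=gsea_df, report=report)


def run_pipeline(config: PipelineConfig) -> dict:
    """File-based pipeline: read inputs, run all stages, write tables + report."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    expression = read_expression(config.expr_path, log2_transform=config.log2_transform)
    annotation = read_annotation(config.ann_path)
    sets = read_gmt(config.gmt_path)
    emt_set = sets[config.emt_set_name]
    acetyl_genes = list(sets[config.acetyl_set_name].members)

    result = run_analysis(
        expression,
        annotation,
        emt_set,
        acetyl_genes,
        ssgsea_params=SsgseaParams(config.alpha, config.normalize),
        thresholds=ScreenThresholds(config.p_max, config.scc_min, config.top_fraction),
        require_positive=config.require_positive,
        require_up=config.require_up,
        gsea_exponent=config.gsea_exponent,
        n_perm=config.n_perm,
        seed=config.seed,
    )

    emt_table = result.emt.rename("emt_score").rename_axis("sample_id").reset_index()
    write_results_table(emt_table, outdir / "emt_scores.tsv")
    write_results_table(result.de, outdir / "de_rank.tsv")
    write_results_table(result.screen, outdir / "screen.tsv")
    write_results_table(result.candidates, outdir / "candidates.tsv")
    write_results_table(result.gsea, outdir / "gsea.tsv")
    report_path = outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(result.report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline report written to %s", report_path)
    return result.report
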