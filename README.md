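# acetylprio

Prioritization of histone-acetylation genes coupled to epithelial–mesenchymal
transition (EMT) activity in staged expression cohorts.

Histone acetyltransferases (HATs) are recurrent regulators of the EMT program
that drives carcinoma invasion and metastasis. Given a bulk expression cohort
spanning normal tissue, premalignant lesions (CIN1–CIN3) and invasive cervical
cancer, this package asks: *which acetyltransferase genes are both
over-expressed in cancer and correlated with EMT pathway activity?* It is
aimed at computational biologists who want a reproducible, testable version of
this integrative screen — including a synthetic cohort generator with ground
truth, so every stage can be validated without downloading anything.

## The method

1. **EMT score per sample (ssGSEA).** Genes in each sample are ranked by
   decreasing expression; the EMT set's enrichment is the summed deviation
   between the weighted in-set and uniform out-of-set cumulative
   distributions, with rank weights `rank^alpha` (default `alpha = 0.25`),
   optionally normalized by the cohort-wide score spread.
2. **Differential-expression rank score.** Per gene, a two-sided Wilcoxon
   rank-sum test of cancer vs normal and a fold change computed on the log2
   scale combine into the composite rank score

   `R = -log10(p) * log2(FC)`

   whose sign follows the regulation direction. Genes are ranked by `R` and
   the top 30% are retained.
3. **Correlation screen.** Each acetyltransferase gene's expression is
   correlated (Spearman) with the per-sample EMT scores; genes pass with
   `p <= 0.05` and `|SCC| >= 0.3` (boundaries inclusive).
4. **Candidate overlap.** Candidates are the genes in the top-`R` cut that
   are up-regulated and positively correlated with the EMT scores.
5. **GSEA validation.** For each candidate, all other genes are ranked by
   their Spearman correlation with the candidate, and the weighted
   Kolmogorov–Smirnov enrichment score of the EMT set along that ranking is
   tested against a gene-label permutation null
   (`p = (1 + exceedances) / (n_perm + 1)`).

The synthetic generator (`acetylprio.synthetic_data`) draws cohorts with the
structure this analysis assumes: 128 samples across five stages, a latent EMT
activity rising with stage, a 200-gene EMT program loading on it, and an
88-gene acetyltransferase collection of which 7 planted genes are shifted in
cancer (`delta = 1` log2 unit) and coupled to the activity (`gamma = 0.6`).
See `docs/methods.md` for the generative model and all defaults.

## Worked example

The numbered scripts under `analysis/` run the screen end-to-end on the
default synthetic cohort (seed 7) and write their tables under `results/`:

```sh
python analysis/01_simulate_cohort.py
python analysis/05_prioritize_candidates.py
```

prints

```
cohort: 5288 genes x 128 samples (seed 7)
planted candidates (7): HAT027, HAT029, HAT033, HAT050, HAT075, HAT081, HAT087
...
candidate overlap: 7 genes (top 26 by R intersected with positive screen passers)
gene_id  r_rank  r_score   scc de_class
 HAT075       1     24.8 0.646       up
 HAT081       2       19 0.655       up
 HAT029       3     18.6 0.551       up
 HAT050       4     16.1 0.671       up
 HAT027       5     15.5 0.597       up
 HAT033       6     14.3  0.56       up
 HAT087       7       12 0.485       up
recovered planted candidates: 7/7; spurious: 0
```

i.e. on this draw the pipeline recovers exactly the seven genes the generator
planted: each sits in the top 30% of the `R` ranking (`r_rank`, `r_score`),
is up-regulated at `p <= 0.05` (`de_class`), and correlates positively with
the EMT scores (`scc`). `analysis/06_gsea_validation.py` then confirms each
candidate's correlation profile is enriched for the EMT set (ES 0.94–0.98,
permutation `p = 2e-4` at 5000 draws), and
`analysis/07_calibration_and_recovery.py` reports sensitivity 1.00 with 0
spurious candidates over 25 cohorts and a null-cohort DE rate of 0.049 at the
nominal 0.05.

The same pipeline is scriptable over files — `acetylprio run --config
pipeline.yaml` — with subcommands for each stage (`simulate`, `emt-score`,
`rank`, `screen`, `prioritize`, `gsea`, `score-ihc`); see `acetylprio --help`.

## Layout

- `src/acetylprio/` — the library: `io_formats` (TSV/GCT/GMT), `ssgsea`,
  `de_ranking`, `emt_screen`, `prioritize`, `gsea`, `synthetic_data`,
  `study_metrics` (IHC staining index, tumour volume, 2^(−ΔΔCt)),
  `pipeline`/`cli`, `evaluation`.
- `analysis/` — numbered narrative scripts writing `results/`.
- `tests/` — unit, property (hypothesis) and acceptance tests with
  independent naive oracles in `tests/oracles.py`.
- `docs/methods.md` — model, parameter and design documentation.
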