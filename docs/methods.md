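# Methods

## The screen

The pipeline prioritizes acetyltransferase genes in a staged expression
cohort by intersecting two one-dimensional screens and validating the
survivors:

1. per-sample EMT activity via single-sample gene-set enrichment (ssGSEA);
2. cancer-vs-normal differential expression summarized by the composite rank
   score `R = -log10(p) * log2(FC)`;
3. a Spearman correlation screen of each acetyl gene against the EMT scores;
4. the candidate overlap (top-`R`, up-regulated, positively correlated);
5. weighted-KS GSEA of each candidate's genome-wide correlation profile
   against the EMT set, with a permutation p-value.

All inputs are genes × samples matrices on a log2 scale. Values are assumed
log2 already; `log2_transform: true` applies `log2(x + 1)` on load for
raw-scale data. Rows with missing values are dropped at load (logged);
duplicate gene ids collapse to the row with the highest mean expression, the
standard probe-collapse convention for microarrays.

## ssGSEA (EMT score)

For sample *j*, genes are ordered by decreasing expression; the top gene gets
rank value *N*. Ties are broken lexicographically by gene id, which makes the
ranking — and everything downstream — independent of input row order and of
platform-specific sort stability. With hit weights `w = rank^alpha`,

    ES_j = sum_{i=1..N} [ P_in(i) − P_out(i) ],
    P_in(i)  = sum_{k<=i, g_k in S} w_k / sum_{g in S} w_g,
    P_out(i) = #{k<=i : g_k not in S} / (N − |S|).

This is the summed-deviation (not extreme-deviation) running-sum statistic,
the form standard for single-sample scoring. Defaults: `alpha = 0.25` and
cross-sample normalization by `max − min` of the raw scores — the dominant
convention among common implementations; both are configurable because
different published variants differ exactly here. Normalization divides all
scores by one positive constant, so it never changes the sample ordering, and
each sample's raw score depends only on that sample's within-sample ranks
(both properties are tested). Set members missing from the matrix are dropped
with a logged count; an empty intersection or an empty complement is an
error, not a silent zero.

A note on a tempting monotonicity claim: promoting a set member one rank
upward past a non-member does *not* always increase ES when `alpha > 0`,
because the promoted member's larger weight also inflates the in-set
normalizer `sum_S w`, shrinking every other member's cumulative contribution;
a 21-gene counterexample is easy to find by random search. The property holds
for the unweighted `alpha = 0` statistic, and the test suite asserts it
there.

## Differential expression and the R score

The two-group contrast is cancer vs normal; premalignant (CIN1–CIN3) samples
stay in the cohort for EMT scoring and correlation but are excluded from the
two-group test, since the fold change is defined between cancer and normal.

The Wilcoxon rank-sum p-value is exact (full null distribution) when the
smaller group has ≤ 8 samples and the gene's values are untied, and otherwise
uses the normal approximation with tie correction and continuity correction.
Fully tied genes get `p = 1` (no evidence). p-values are clamped to
`[1e-300, 1]` so `R` stays finite.

Fold change is the difference of group means on the log2 scale,
exponentiated: `log2FC = mean_cancer − mean_normal`, `FC = 2^log2FC`. This
makes `sign(R) = sign(log2FC)` whenever `p < 1`, so the `R` ranking puts
strongly up-regulated genes first and strongly down-regulated genes last.

The "top 30%" cut is `floor(0.30 × n)` genes (minimum 1) of the full acetyl
collection ranked by signed `R`, ties broken by gene id. The candidate
overlap additionally requires `de_class == up`, so down-regulated genes that
sneak into the top cut cannot become candidates; a config switch
(`require_up=False`) removes that restriction. A Benjamini–Hochberg column is
emitted for information only — the screen's decision rule is the raw
`p <= 0.05`, by design.

## Correlation screen

Spearman correlation from average ranks (tie-aware), two-sided p from the
t-approximation with `n − 2` degrees of freedom — adequate at n ≈ 128, and
consistent with `scipy.stats.spearmanr` (cross-checked in tests); an exact
permutation p is available for n < 10. The joint filter is inclusive at both
boundaries: `p <= 0.05` **and** `|SCC| >= 0.3` pass. At n = 128 the `|SCC|`
threshold is the binding constraint — under independence
P(|SCC| ≥ 0.3) ≈ 6 × 10⁻⁴ — which is why the null pass rate of the joint
filter sits far below 0.05. Correlations use all samples (normal through
cancer); restricting to a sample subset is a caller-level choice of the
matrix passed in. Genes in the list but absent from the matrix are reported
with a `missing` flag rather than dropped.

## GSEA of a candidate's correlation profile

All other genes are ranked by their Spearman correlation with the candidate
(candidate excluded, ties by gene id). Along that ranking, hits increment the
running sum by `|SCC|^exponent` normalized by the in-set total, misses
decrement by `1/(N − |S|)`; the enrichment score is the signed
maximum-magnitude deviation, bounded in [−1, 1]. `exponent = 1`
(Subramanian-style weighting) is the default; `exponent = 0` gives the
classic KS statistic. If every in-set weight is zero (possible at
`exponent > 0` when all members have SCC exactly 0), hits fall back to equal
steps `1/|S|`.

Because the input is a single ranked profile rather than a phenotype-labelled
matrix, the permutation null draws random same-size gene-label sets without
replacement — a deliberate deviation from phenotype-permutation GSEA, which
is not defined here. The p-value uses the `(1 + exceedances)/(n_perm + 1)`
estimator, so `p >= 1/(n_perm + 1)` always. The null is evaluated
vectorized: between hits the running sum decreases monotonically, so its
extrema can only occur at hit positions or immediately before them, and
evaluating those `2|S|` points per permutation reproduces the full walk's
|ES| exactly (asserted against the explicit walk in tests). The leading edge
is the set members at or before the extreme deviation (at or after it, for
negative ES).

## Synthetic cohorts

The generator draws the structure the analysis assumes:

    a_j    ~ Normal(mu_stage[s(j)], sigma_activity²)      latent EMT activity
    EMT    x_ij = b_i + lambda_i a_j + eps_ij
    planted x_ij = b_i + delta·1[s(j)=cancer] + gamma·a_j + eps_ij
    null   x_ij = b_i + eps_ij

with `b_i ~ Normal(7, 2²)` log2 baselines and `eps ~ Normal(0, sigma_noise²)`
(a Student-t option exists for robustness checks). Defaults: 128 samples
split 24/14/22/40/28 across normal/CIN1/CIN2/CIN3/cancer — the composition of
the public cervical cohort this design emulates (GEO GSE63514; only the total
of 128 is fixed by the design, the split is configurable); stage activity
means 0, 0.5, 1.0, 1.5, 2.0 (`sigma_activity = 0.5`); 200 EMT genes with
loadings uniform in [0.5, 1.5]; 88 acetyl genes with 7 planted
(`delta = 1.0` log2 units, `gamma = 0.6`); 5000 background genes;
`sigma_noise = 1.0`.

The truth table records each gene's class and its model-implied expected
cancer-vs-normal log2FC. For a planted gene that expectation is
`delta + gamma·(mu_cancer − mu_normal) = 1.0 + 0.6·2.0 = 2.2`, **not**
`delta` alone: the planted genes ride the activity gradient as well as the
cancer-specific shift. Estimator-bias checks therefore compare the fitted
log2FC against this expectation — the quantity the estimator actually
targets under the model — rather than against the `delta` parameter.
`null_cohort()` zeroes `delta`, `gamma` and all `lambda_i`, giving pure
noise for calibration runs. By default the set used for EMT scoring is the
same set that generated the signal; `set_overlap_fraction < 1` swaps part of
it for background genes to emulate a misspecified signature.

What the simulation does *not* emulate: probe-level effects, batch
structure, gene–gene correlation beyond the single latent factor,
stage-dependent variance, and non-Gaussian marginals (unless t-noise is
enabled). Passing tests therefore demonstrate correctness and calibration of
the procedure under its own assumptions, not performance on real microarray
data — for that, the optional networked script fetches the real cohort.

## Clinical-assay scores

The IHC staining index multiplies intensity (0–3) by proportion of positive
cells (0–4) — the usual immunoreactive-score convention; with these scales no
product equals 5, so the published cutoffs (index ≥ 6 high, ≤ 4 low) classify
every reachable value. The proportion binning from raw percentages is not
modelled; inputs are pre-binned integers. Tumour volume is
`length × width²/2` (mm³, length ≥ width), and qPCR fold change is
`2^(−ΔΔCt)`.

## Numerical and design choices

- Determinism: every stochastic step takes an explicit seed
  (`numpy.random.default_rng`); pipeline reports contain parameters and
  results only (no timestamps), so identical config + seed gives
  byte-identical outputs. Per-candidate GSEA seeds are `seed + rank index`.
- Ties: broken lexicographically by gene id everywhere a total order is
  needed (expression ranking, R ranking, profile ranking).
- Problem sizes used by tests and the acceptance script — full 5288 × 128
  cohorts, 25-seed recovery runs, 500-set × 1000-permutation GSEA
  calibration — were chosen to keep the whole suite comfortably inside a few
  minutes on a single CPU while leaving Monte-Carlo error well below the
  margins being asserted.
- The DE null-rate check aggregates three independent null cohorts
  (≈ 15 900 null genes): the continuity-corrected normal approximation is
  slightly conservative (empirical rate ≈ 0.048 at the 24-vs-28 design), and
  the larger aggregate keeps sampling noise small relative to the
  3-standard-error band around 0.05.
- Limitations: no moderated-variance statistics, no covariate adjustment, no
  multi-set ssGSEA projection, no NES/FDR machinery across gene sets, no
  survival modelling. These are out of scope, not missing features.
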