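"""Synthetic staged expression cohorts with a latent EMT activity.

The generator emulates the statistical structure the pipeline assumes in a
staged cervical cohort: 128 samples across normal / CIN1-3 / cancer stages, a
latent per-sample EMT activity whose mean increases with stage severity, an
EMT gene program loading on that activity, an 88-gene acetyltransferase
collection of which a small planted subset is both shifted upward in cancer
and coupled to the activity, and independent Gaussian noise on the log2 scale:

    activity           a_j ~ Normal(mu_stage[s(j)], sigma_activity^2)
    EMT program gene   x_ij = b_i + lambda_i * a_j + eps_ij
    planted candidate  x_ij = b_i + delta * 1[s(j)=cancer] + gamma * a_j + eps_ij
    null / background  x_ij = b_i + eps_ij

with baselines b_i ~ Normal(baseline_mean, baseline_sd^2) and
eps_ij ~ Normal(0, sigma_noise^2).  A ground-truth table records each gene's
class and its model-implied expected cancer-vs-normal log2 fold change, which
for a planted gene is delta + gamma * (mu_cancer - mu_normal).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from acetylprio.errors import ValidationError
from acetylprio.io_formats import (
    STAGES,
    ExpressionMatrix,
    GeneSet,
    GeneSetCollection,
    SampleAnnotation,
)

#: per-stage sample counts of the cohort design being emulated (total 128)
DEFAULT_STAGE_SIZES = {"normal": 24, "CIN1": 14, "CIN2": 22, "CIN3": 40, "cancer": 28}


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of the generative model; defaults are the study conditions."""

    stage_sizes: dict = field(default_factory=lambda: dict(DEFAULT_STAGE_SIZES))
    n_background_genes: int = 5000
    emt_set_size: int = 200
    n_acetyl_genes: int = 88
    n_planted: int = 7
    delta: float = 1.0  # cancer-vs-normal mean shift of planted genes, log2 units
    gamma: float = 0.6  # loading of planted genes on the EMT activity
    lambda_range: tuple[float, float] = (0.5, 1.5)  # EMT-gene loadings
    mu_stage: tuple[float, ...] = (0.0, 0.5, 1.0, 1.5, 2.0)  # activity mean per stage
    sigma_activity: float = 0.5
    sigma_noise: float = 1.0
    baseline_mean: float = 7.0
    baseline_sd: float = 2.0
    noise_df: float | None = None  # Student-t degrees of freedom; None = Gaussian
    set_overlap_fraction: float = 1.0  # fraction of the scoring EMT set drawn from the true program
    seed: int = 0

    def validate(self) -> None:
        problems = []
        if set(self.stage_sizes) != set(STAGES):
            problems.append(f"stage_sizes keys must be {STAGES}")
        elif any(v < 2 for v in self.stage_sizes.values()):
            problems.append("stage_sizes: every stage needs >= 2 samples")
        if self.n_planted > self.n_acetyl_genes:
            problems.append("n_planted exceeds n_acetyl_genes")
        if len(self.mu_stage) != len(STAGES):
            problems.append("mu_stage needs one value per stage")
        elif any(b < a for a, b in zip(self.mu_stage, self.mu_stage[1:])):
            problems.append("mu_stage must be non-decreasing with stage severity")
        if self.sigma_activity < 0 or self.sigma_noise < 0:
            problems.append("sigma_activity and sigma_noise must be >= 0")
        if not (0 < self.set_overlap_fraction <= 1):
            problems.append("set_overlap_fraction must be in (0, 1]")
        if problems:
            raise ValidationError("; ".join(problems))

    @property
    def n_samples(self) -> int:
        return sum(self.stage_sizes.values())


@dataclass
class Cohort:
    """Everything :func:`generate` emits, bundled."""

    expression: ExpressionMatrix
    annotation: SampleAnnotation
    gene_sets: GeneSetCollection
    truth: pd.DataFrame
    activity: pd.Series  # latent per-sample EMT activity (the simulation truth)


def generate(spec: SyntheticSpec | None = None) -> Cohort:
    """Draw one cohort from the generative model; reproducible for fixed seed."""
    spec = spec or SyntheticSpec()
    spec.validate()
    rng = np.random.default_rng(spec.seed)

    stages = [s for s in STAGES for _ in range(spec.stage_sizes[s])]
    n_samples = len(stages)
    sample_ids = [f"S{i + 1:03d}" for i in range(n_samples)]
    mu = dict(zip(STAGES, spec.mu_stage))
    activity = rng.normal([mu[s] for s in stages], spec.sigma_activity)
    is_cancer = np.array([s == "cancer" for s in stages])

    n_emt = spec.emt_set_size
    n_acetyl = spec.n_acetyl_genes
    n_bg = spec.n_background_genes
    emt_ids = [f"EMT{i + 1:04d}" for i in range(n_emt)]
    acetyl_ids = [f"HAT{i + 1:03d}" for i in range(n_acetyl)]
    bg_ids = [f"BG{i + 1:05d}" for i in range(n_bg)]
    gene_ids = emt_ids + acetyl_ids + bg_ids
    n_genes = len(gene_ids)

    planted_idx = rng.choice(n_acetyl, size=spec.n_planted, replace=False)
    planted = np.zeros(n_acetyl, dtype=bool)
    planted[planted_idx] = True

    baseline = rng.normal(spec.baseline_mean, spec.baseline_sd, size=n_genes)
    lam = rng.uniform(*spec.lambda_range, size=n_emt)
    if spec.noise_df is None:
        noise = rng.normal(0.0, spec.sigma_noise, size=(n_genes, n_samples))
    else:
        noise = rng.standard_t(spec.noise_df, size=(n_genes, n_samples)) * spec.sigma_noise

    x = baseline[:, None] + noise
    x[:n_emt] += lam[:, None] * activity[None, :]
    acetyl_rows = slice(n_emt, n_emt + n_acetyl)
    planted_rows = np.nonzero(planted)[0] + n_emt
    x[planted_rows] += spec.delta * is_cancer[None, :] + spec.gamma * activity[None, :]

    expression = ExpressionMatrix(
        pd.DataFrame(x, index=gene_ids, columns=sample_ids)
    )
    annotation = SampleAnnotation(pd.DataFrame({"stage": stages}, index=sample_ids))

    # the EMT set used for scoring; < 1 overlap fraction swaps in background
    # genes to stress-test misspecification
    n_true = int(round(spec.set_overlap_fraction * n_emt))
    scored_emt = list(emt_ids[:n_true])
    if n_true < n_emt:
        fillers = rng.choice(bg_ids, size=n_emt - n_true, replace=False)
        scored_emt += list(fillers)
    gene_sets = GeneSetCollection(
        [
            GeneSet("EMT", "EMT program gene set", tuple(scored_emt)),
            GeneSet("ACETYLTRANSFERASE_ACTIVITY", "acetyltransferase collection", tuple(acetyl_ids)),
        ]
    )

    gene_class = np.array(
        ["emt_program"] * n_emt
        + ["acetyl_null"] * n_acetyl
        + ["background"] * n_bg,
        dtype=object,
    )
    gene_class[planted_rows] = "planted_candidate"
    delta_mu = mu["cancer"] - mu["normal"]
    expected_log2fc = np.zeros(n_genes)
    expected_log2fc[:n_emt] = lam * delta_mu
    expected_log2fc[planted_rows] = spec.delta + spec.gamma * delta_mu
    true_gamma = np.zeros(n_genes)
    true_gamma[planted_rows] = spec.gamma
    true_lambda = np.zeros(n_genes)
    true_lambda[:n_emt] = lam
    true_delta = np.zeros(n_genes)
    true_delta[planted_rows] = spec.delta
    truth = pd.DataFrame(
        {
            "gene_id": gene_ids,
            "gene_class": gene_class,
            "delta": true_delta,
            "gamma": true_gamma,
            "lambda_": true_lambda,
            "expected_log2fc": expected_log2fc,
        }
    )
    return Cohort(
        expression=expression,
        annotation=annotation,
        gene_sets=gene_sets,
        truth=truth,
        activity=pd.Series(activity, index=sample_ids, name="activity"),
    )


def null_cohort(spec: SyntheticSpec | None = None) -> Cohort:
    """Cohort with all effects zeroed (delta = gamma = 0, lambda = 0): pure noise."""
    spec = spec or SyntheticSpec()
    return generate(replace(spec, delta=0.0, gamma=0.0, lambda_range=(0.0, 0.0)))
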