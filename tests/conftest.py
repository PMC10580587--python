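import numpy as np
import pandas as pd
import pytest

from acetylprio.io_formats import ExpressionMatrix, GeneSet, SampleAnnotation
from acetylprio.synthetic_data import SyntheticSpec, generate, null_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One draw from the generative model at the study conditions."""
    return generate(SyntheticSpec(seed=7))


@pytest.fixture(scope="session")
def small_null_cohort():
    """Null cohort kept small for unit-level checks (acceptance uses full size)."""
    spec = SyntheticSpec(n_background_genes=500, seed=11)
    return null_cohort(spec)


@pytest.fixture
def tiny_matrix():
    """5 genes x 6 samples with a clean cancer-vs-normal split."""
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.normal(7, 1, size=(5, 6)),
        index=[f"G{i}" for i in range(5)],
        columns=[f"S{i}" for i in range(6)],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def tiny_annotation():
    frame = pd.DataFrame(
        {"stage": ["normal"] * 3 + ["cancer"] * 3},
        index=[f"S{i}" for i in range(6)],
    )
    return SampleAnnotation(frame)


@pytest.fixture
def emt_set():
    return GeneSet("EMT", "test set", ("G0", "G1"))
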