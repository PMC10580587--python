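import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acetylprio.de_ranking import (
    ScreenThresholds,
    differential_rank,
    fold_change,
    rank_score,
    select_top,
    wilcoxon_de,
)
from acetylprio.errors import DomainError, InsufficientSamplesError, ValidationError
from acetylprio.io_formats import ExpressionMatrix, SampleAnnotation
from tests.oracles import enumerate_ranksum_p


def _two_group(values_a, values_b):
    """Matrix + annotation with one gene split into normal/cancer groups."""
    n_a, n_b = len(values_a), len(values_b)
    samples = [f"n{i}" for i in range(n_a)] + [f"c{i}" for i in range(n_b)]
    data = pd.DataFrame([list(values_a) + list(values_b)], index=["G"], columns=samples)
    ann = SampleAnnotation(
        pd.DataFrame({"stage": ["normal"] * n_a + ["cancer"] * n_b}, index=samples)
    )
    return ExpressionMatrix(data), ann


class TestWilcoxon:
    def test_separated_triples_give_exact_tenth(self):
        m, ann = _two_group([1, 2, 3], [4, 5, 6])
        p = wilcoxon_de(m, ann)
        assert p["G"] == pytest.approx(0.1, abs=1e-12)

    def test_fully_tied_gene_gives_p_one(self):
        m, ann = _two_group([5, 5, 5], [5, 5, 5])
        assert wilcoxon_de(m, ann)["G"] == 1.0

    def test_label_swap_symmetry(self):
        m, ann = _two_group([1.2, 3.4, 2.2, 5.0], [4.1, 0.3, 6.6, 2.9])
        assert wilcoxon_de(m, ann, "cancer", "normal")["G"] == pytest.approx(
            wilcoxon_de(m, ann, "normal", "cancer")["G"], abs=1e-12
        )

    def test_single_sample_group_rejected(self):
        m, ann = _two_group([1, 2], [3])
        with pytest.raises(InsufficientSamplesError):
            wilcoxon_de(m, ann)

    @given(st.integers(0, 100_000))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_small_untied_groups_match_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n_a = int(rng.integers(2, 7))
        n_b = int(rng.integers(2, 7))
        values = rng.permutation(np.arange(n_a + n_b, dtype=float))
        a, b = values[:n_a], values[n_a:]
        m, ann = _two_group(a, b)
        p = wilcoxon_de(m, ann, "cancer", "normal")["G"]
        expect = float(enumerate_ranksum_p(b, a))
        assert p == pytest.approx(expect, abs=1e-12)

    def test_large_group_null_rate_close_to_alpha(self, small_null_cohort):
        p = wilcoxon_de(small_null_cohort.expression, small_null_cohort.annotation)
        rate = (p <= 0.05).mean()
        se = np.sqrt(0.05 * 0.95 / p.size)
        assert abs(rate - 0.05) < 4 * se  # loose unit-level guard; acceptance is stricter


class TestFoldChange:
    def test_log2_difference_of_means(self):
        m, ann = _two_group([5.0, 5.0], [6.0, 6.0])
        out = fold_change(m, ann)
        assert out.loc["G", "log2fc"] == pytest.approx(1.0)
        assert out.loc["G", "fc"] == pytest.approx(2.0)

    def test_equal_means_unity(self):
        m, ann = _two_group([4.0, 6.0], [5.0, 5.0])
        out = fold_change(m, ann)
        assert out.loc["G", "fc"] == pytest.approx(1.0)
        assert out.loc["G", "log2fc"] == pytest.approx(0.0)

    def test_group_swap_inverts(self):
        m, ann = _two_group([3.0, 4.0], [6.5, 7.5])
        fwd = fold_change(m, ann, "cancer", "normal").loc["G", "fc"]
        rev = fold_change(m, ann, "normal", "cancer").loc["G", "fc"]
        assert fwd == pytest.approx(1.0 / rev, abs=1e-12)


class TestRankScore:
    @pytest.mark.parametrize(
        "p,fc,expected",
        [
            (0.05, 2.0, 1.3010299956639813),
            (1.0, 8.0, 0.0),
            (0.01, 0.5, -2.0),
        ],
    )
    def test_closed_form(self, p, fc, expected):
        assert rank_score(p, fc) == pytest.approx(expected, abs=1e-12)

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            rank_score(0.0, 2.0)
        with pytest.raises(DomainError):
            rank_score(0.5, -1.0)

    @given(
        st.floats(1e-10, 1.0, exclude_min=False),
        st.floats(1e-3, 1e3),
    )
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_antisymmetry_in_fold_change(self, p, fc):
        assert rank_score(p, 1.0 / fc) == pytest.approx(-rank_score(p, fc), abs=1e-9)

    def test_strictly_decreasing_in_p_for_up_genes(self):
        ps = np.linspace(0.001, 1.0, 50)
        rs = rank_score(ps, np.full_like(ps, 2.0))
        assert np.all(np.diff(rs) < 0)


class TestSelectTop:
    def _table(self, n, r=None):
        return pd.DataFrame(
            {
                "gene_id": [f"G{i:03d}" for i in range(n)],
                "r_score": r if r is not None else np.arange(n, dtype=float),
                "de_class": ["up"] * n,
            }
        )

    def test_floor_of_fraction(self):
        assert len(select_top(self._table(10), ScreenThresholds(top_fraction=0.30))) == 3

    def test_collection_of_88_yields_26(self):
        assert len(select_top(self._table(88), ScreenThresholds(top_fraction=0.30))) == 26

    def test_minimum_one_gene(self):
        assert len(select_top(self._table(2), ScreenThresholds(top_fraction=0.1))) == 1

    def test_ties_resolved_by_gene_id(self):
        top = select_top(self._table(10, r=[1.0] * 10), ScreenThresholds(top_fraction=0.30))
        assert list(top["gene_id"]) == ["G000", "G001", "G002"]

    def test_ordering_is_descending_r(self):
        top = select_top(self._table(10), ScreenThresholds(top_fraction=0.5))
        assert list(top["r_score"]) == sorted(top["r_score"], reverse=True)
        assert list(top["r_rank"]) == [1, 2, 3, 4, 5]


class TestDifferentialRank:
    def test_table_is_internally_consistent(self, default_cohort):
        acetyl = list(default_cohort.gene_sets["ACETYLTRANSFERASE_ACTIVITY"].members)
        de = differential_rank(default_cohort.expression, default_cohort.annotation, genes=acetyl)
        assert len(de) == 88
        np.testing.assert_allclose(
            de["r_score"], -np.log10(de["p"]) * np.log2(de["fc"]), atol=1e-12
        )
        np.testing.assert_allclose(de["fc"], np.exp2(de["log2fc"]), atol=1e-12)
        up = de["de_class"] == "up"
        assert ((de.loc[up, "p"] <= 0.05) & (de.loc[up, "log2fc"] > 0)).all()
        down = de["de_class"] == "down"
        assert ((de.loc[down, "p"] <= 0.05) & (de.loc[down, "log2fc"] < 0)).all()
        assert set(de["de_class"]) <= {"up", "down", "not_de"}
        assert de["p_bh"].between(0, 1).all()
        assert (de["p_bh"] >= de["p"] - 1e-15).all()

    def test_planted_genes_score_high(self, default_cohort):
        truth = default_cohort.truth.set_index("gene_id")
        acetyl = list(default_cohort.gene_sets["ACETYLTRANSFERASE_ACTIVITY"].members)
        de = differential_rank(default_cohort.expression, default_cohort.annotation, genes=acetyl)
        top = select_top(de)
        planted = set(truth.index[truth["gene_class"] == "planted_candidate"])
        assert planted <= set(top["gene_id"])

    def test_thresholds_validation(self):
        with pytest.raises(ValidationError):
            ScreenThresholds(p_max=0.0)
        with pytest.raises(ValidationError):
            ScreenThresholds(top_fraction=1.5)
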