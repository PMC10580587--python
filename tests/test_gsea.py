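import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from acetylprio.errors import EmptySetError, ValidationError
from acetylprio.gsea import (
    RankedProfile,
    _null_es_magnitudes,
    correlation_profile,
    gsea_es,
    leading_edge,
    permutation_p,
)
from acetylprio.io_formats import ExpressionMatrix
from tests.oracles import brute_spearman, naive_gsea_es


def _profile(genes, weights):
    frame = pd.DataFrame({"gene_id": genes, "scc": weights})
    return RankedProfile("CAND", frame)


def _random_profile(rng, n):
    genes = [f"g{i:03d}" for i in range(n)]
    weights = np.sort(rng.uniform(-1, 1, size=n))[::-1]
    return _profile(genes, weights)


class TestCorrelationProfile:
    def _matrix(self, rng, n_genes=6, n_samples=12):
        genes = ["CAND"] + [f"G{i}" for i in range(n_genes - 1)]
        data = pd.DataFrame(
            rng.normal(size=(n_genes, n_samples)),
            index=genes,
            columns=[f"s{i}" for i in range(n_samples)],
        )
        return ExpressionMatrix(data)

    def test_duplicate_of_candidate_ranks_first(self):
        rng = np.random.default_rng(1)
        m = self._matrix(rng)
        data = m.data.copy()
        data.loc["G0"] = data.loc["CAND"]
        data.loc["G1"] = -data.loc["CAND"]
        profile = correlation_profile(ExpressionMatrix(data), "CAND")
        assert profile.gene_ids[0] == "G0"
        assert profile.frame.iloc[0]["scc"] == pytest.approx(1.0, abs=1e-12)
        assert profile.gene_ids[-1] == "G1"
        assert profile.frame.iloc[-1]["scc"] == pytest.approx(-1.0, abs=1e-12)

    def test_matches_pairwise_brute_force(self):
        rng = np.random.default_rng(2)
        m = self._matrix(rng)
        profile = correlation_profile(m, "CAND")
        cand = m.data.loc["CAND"].to_numpy()
        for _, row in profile.frame.iterrows():
            expect = brute_spearman(m.data.loc[row["gene_id"]].to_numpy(), cand)
            assert row["scc"] == pytest.approx(expect, abs=1e-12)

    def test_candidate_excluded_and_order_descending(self):
        rng = np.random.default_rng(3)
        profile = correlation_profile(self._matrix(rng), "CAND")
        assert "CAND" not in profile.gene_ids
        w = profile.weights
        assert np.all(np.diff(w) <= 1e-15)

    def test_absent_candidate_raises(self):
        rng = np.random.default_rng(4)
        with pytest.raises(KeyError, match="NOPE"):
            correlation_profile(self._matrix(rng), "NOPE")


class TestEnrichmentScore:
    def test_front_loaded_set_is_positive(self):
        rng = np.random.default_rng(5)
        profile = _random_profile(rng, 30)
        es, _ = gsea_es(profile, set(profile.gene_ids[:5]))
        assert es > 0

    def test_unweighted_statistic_negates_under_reversal(self):
        rng = np.random.default_rng(6)
        profile = _random_profile(rng, 25)
        members = set(rng.choice(profile.gene_ids, size=6, replace=False))
        es, _ = gsea_es(profile, members, exponent=0)
        reversed_profile = _profile(profile.gene_ids[::-1], profile.weights[::-1])
        es_rev, _ = gsea_es(reversed_profile, members, exponent=0)
        assert es_rev == pytest.approx(-es, abs=1e-12)

    def test_six_gene_walk_matches_hand_computation(self):
        profile = _profile(list("ABCDEF"), [0.9, 0.6, 0.3, -0.2, -0.5, -0.8])
        es, running = gsea_es(profile, {"A", "B"}, exponent=1)
        # hits A (0.9) and B (0.6): denom 1.5; misses step 1/4
        expect = np.array([0.6, 1.0, 0.75, 0.5, 0.25, 0.0])
        np.testing.assert_allclose(running, expect, atol=1e-12)
        assert es == pytest.approx(1.0, abs=1e-12)

    @given(st.integers(0, 10_000))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_naive_walk(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 60))
        profile = _random_profile(rng, n)
        k = int(rng.integers(1, n))
        members = set(rng.choice(profile.gene_ids, size=k, replace=False))
        exponent = float(rng.choice([0.0, 1.0, 2.0]))
        es, running = gsea_es(profile, members, exponent=exponent)
        expect = naive_gsea_es(profile.gene_ids, profile.weights, members, exponent)
        assert es == pytest.approx(expect, abs=1e-12)
        assert -1.0 - 1e-12 <= es <= 1.0 + 1e-12
        assert np.max(np.abs(running)) == pytest.approx(abs(es), abs=1e-12)

    def test_empty_intersection_raises(self):
        rng = np.random.default_rng(7)
        with pytest.raises(EmptySetError):
            gsea_es(_random_profile(rng, 10), {"nope"})

    def test_leading_edge_members_precede_extreme(self):
        rng = np.random.default_rng(8)
        profile = _random_profile(rng, 40)
        members = set(profile.gene_ids[:4]) | {profile.gene_ids[-1]}
        es, running = gsea_es(profile, members)
        assert es > 0
        edge = leading_edge(profile, members)
        i_ext = int(np.argmax(np.abs(running)))
        positions = [profile.gene_ids.index(g) for g in edge]
        assert set(edge) <= members
        assert all(p <= i_ext for p in positions)
        assert set(edge) == {g for p, g in enumerate(profile.gene_ids) if g in members and p <= i_ext}


class TestPermutationNull:
    @given(st.integers(0, 5_000))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_vectorized_null_agrees_with_direct_walk(self, seed):
        """The hit-position null evaluator must reproduce |ES| of explicit walks."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 50))
        profile = _random_profile(rng, n)
        k = int(rng.integers(1, max(2, n // 2)))
        w = np.abs(profile.weights)
        mags = _null_es_magnitudes(n, k, w, 20, np.random.default_rng(seed))
        pos_rng = np.random.default_rng(seed)
        u = pos_rng.random((20, n))
        pos = np.argpartition(u, k - 1, axis=1)[:, :k]
        pos.sort(axis=1)
        for row, mag in zip(pos, mags):
            members = set(profile.gene_ids[i] for i in row)
            es, _ = gsea_es(profile, members)
            assert mag == pytest.approx(abs(es), abs=1e-12)

    def test_same_seed_reproduces_result(self):
        rng = np.random.default_rng(9)
        profile = _random_profile(rng, 80)
        members = set(rng.choice(profile.gene_ids, size=10, replace=False))
        a = permutation_p(profile, members, n_perm=200, seed=123)
        b = permutation_p(profile, members, n_perm=200, seed=123)
        assert a.es == b.es
        assert a.p_perm == b.p_perm
        assert a.leading_edge == b.leading_edge

    def test_maximally_enriched_set_hits_p_floor(self):
        # distinct positive weights, set = top genes: no random relabelling
        # of a 200-gene profile reaches |ES| = 1
        genes = [f"g{i:03d}" for i in range(200)]
        weights = np.linspace(0.99, 0.01, 200)
        profile = _profile(genes, weights)
        res = permutation_p(profile, set(genes[:5]), n_perm=100, seed=4)
        assert res.es == pytest.approx(1.0, abs=1e-12)
        assert res.p_perm == pytest.approx(1 / 101, abs=1e-12)

    def test_n_perm_floor_enforced(self):
        rng = np.random.default_rng(10)
        profile = _random_profile(rng, 20)
        with pytest.raises(ValidationError):
            permutation_p(profile, set(profile.gene_ids[:3]), n_perm=50)

    def test_oversized_set_warns_but_computes(self):
        rng = np.random.default_rng(11)
        profile = _random_profile(rng, 20)
        members = set(profile.gene_ids[:15])
        with pytest.warns(UserWarning, match="half"):
            res = permutation_p(profile, members, n_perm=100, seed=0)
        assert np.isfinite(res.es)

    def test_null_pvalues_roughly_uniform_smoke(self):
        """Small-scale calibration: random sets yield dispersed p-values."""
        from scipy import stats

        rng = np.random.default_rng(12)
        profile = _random_profile(rng, 300)
        pvals = []
        for i in range(60):
            members = set(rng.choice(profile.gene_ids, size=15, replace=False))
            pvals.append(permutation_p(profile, members, n_perm=200, seed=1000 + i).p_perm)
        assert stats.kstest(pvals, "uniform").pvalue > 0.001
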