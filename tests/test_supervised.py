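"""Supervised SNP-set association layer: subsets, M statistic, permutation
null, empirical p-values, BH adjustment."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scpca.cpca import FitConfig
from scpca.setio import GenotypeMatrix, Phenotype, SnpSet
from scpca.supervised import (
    bh_adjust,
    candidate_subsets,
    empirical_pvalue,
    m_statistic,
    permutation_null,
    results_frame,
    run_snpset_analysis,
    subset_t,
)
from tests.conftest import genotype_matrix

PIPE_CFG = FitConfig(latent_dim=1, max_iterations=50, tolerance=3e-4, n_restarts=1, seed=0)


def _pheno(y):
    y = np.asarray(y, dtype=np.int8)
    return Phenotype(y=y, sample_ids=[f"s{i}" for i in range(y.size)])


class TestCandidateSubsets:
    def test_distinct_pvalues_give_sizes_one_through_v(self, rng):
        p = rng.permutation(20) / 40 + 0.01
        cs = candidate_subsets(p, v=20)
        assert [len(s) for s in cs.subsets] == list(range(1, 21))

    def test_all_equal_pvalues_collapse_to_one_subset(self):
        cs = candidate_subsets(np.full(7, 0.3), v=20)
        uniq = cs.unique()
        assert len(uniq) == 1 and len(uniq[0]) == 7

    def test_single_snp_collapses(self):
        cs = candidate_subsets(np.array([0.2]), v=20)
        assert len(cs.unique()) == 1

    def test_last_subset_is_full_set(self, rng):
        p = rng.random(13)
        cs = candidate_subsets(p, v=20)
        assert len(cs.subsets[-1]) == 13

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=40))
    def test_subsets_are_nested(self, pvals):
        cs = candidate_subsets(np.array(pvals), v=20)
        for a, b in zip(cs.subsets, cs.subsets[1:]):
            assert set(a) <= set(b)


class TestSubsetAndMStatistic:
    def test_negating_scores_negates_t(self, rng):
        G = genotype_matrix(rng.integers(0, 3, (60, 5)))
        y = rng.integers(0, 2, 60)
        y[:2] = [0, 1]
        t = subset_t(SnpSet("s", np.arange(5)), G, _pheno(y), method="pca")
        from scpca.baselines import fit_pca_scores
        from scpca.glm import logistic_wald
        scores = fit_pca_scores(G).scores
        _, _, t_neg, _ = logistic_wald(-scores, y.astype(float))
        assert t == pytest.approx(-t_neg, abs=1e-8)

    def test_empty_subset_rejected(self, rng):
        G = genotype_matrix(rng.integers(0, 3, (10, 3)))
        with pytest.raises(ValueError):
            subset_t(np.array([], dtype=int), G, np.zeros(10), method="pca")

    def test_m_is_signed_max_absolute_t(self):
        # the M definition on a fixed t collection: {2.1, -3.4, 0.5} -> -3.4
        ts = np.array([2.1, -3.4, 0.5])
        best = ts[np.argmax(np.abs(ts))]
        assert best == -3.4

    def test_m_dominates_full_set_t(self, rng):
        G = genotype_matrix(rng.integers(0, 3, (80, 8)))
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        S = SnpSet("g", np.arange(8))
        M, opt = m_statistic(S, G, _pheno(y), method="pca")
        t_full = subset_t(S, G, _pheno(y), method="pca")
        assert abs(M) >= abs(t_full) - 1e-10
        assert set(opt).issubset(set(S.snp_indices))

    def test_single_unique_subset_returns_its_t(self, rng):
        G = genotype_matrix(rng.integers(0, 3, (40, 1)))
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        S = SnpSet("g", np.array([0]))
        M, opt = m_statistic(S, G, _pheno(y), method="cpca", config=PIPE_CFG)
        t = subset_t(S, G, _pheno(y), method="cpca", config=PIPE_CFG)
        assert M == pytest.approx(t, abs=1e-8)


class TestPermutationNull:
    def test_fixed_seed_reproducible(self, rng):
        G = genotype_matrix(rng.integers(0, 3, (50, 6)))
        S = SnpSet("g", np.arange(6))
        a = permutation_null(S, G, 0.5, 20, method="pca", seed=11)
        b = permutation_null(S, G, 0.5, 20, method="pca", seed=11)
        assert np.array_equal(a, b)

    def test_null_symmetric_about_zero(self, rng):
        G = genotype_matrix(rng.integers(0, 3, (120, 6)))
        S = SnpSet("g", np.arange(6))
        null = permutation_null(S, G, 0.5, 200, method="pca", seed=3)
        se = null.std() / np.sqrt(null.size)
        assert abs(null.mean()) < 2.5 * se + 0.05

    def test_b_zero_rejected(self, rng):
        G = genotype_matrix(rng.integers(0, 3, (10, 3)))
        with pytest.raises(ValueError):
            permutation_null(SnpSet("g", np.arange(3)), G, 0.5, 0, method="pca")

    def test_early_stop_truncates_but_keeps_decision(self, rng):
        G = genotype_matrix(rng.integers(0, 3, (60, 6)))
        S = SnpSet("g", np.arange(6))
        full = permutation_null(S, G, 0.5, 50, method="pca", seed=5)
        stopped = permutation_null(
            S, G, 0.5, 50, method="pca", seed=5, m_obs=0.0, early_stop_count=2
        )
        # |null| >= 0 always, so stopping fires at the second round
        assert stopped.size == 2
        assert np.array_equal(stopped, full[:2])


class TestEmpiricalPvalue:
    def test_add_one_formula(self):
        null = np.arange(1, 100) * 0.01  # 99 nulls, all smaller than 5
        assert empirical_pvalue(5.0, null) == pytest.approx(0.01)

    def test_all_ties_give_one(self):
        assert empirical_pvalue(1.0, np.ones(42)) == 1.0

    def test_bounds_and_antimonotonicity(self, rng):
        null = rng.standard_normal(37)
        ps = [empirical_pvalue(m, null) for m in np.linspace(0, 5, 20)]
        assert all(0 < p <= 1 for p in ps)
        assert all(a >= b for a, b in zip(ps, ps[1:]))


class TestBhAdjust:
    def test_hand_worked_stepup(self):
        adj = bh_adjust(np.array([0.01, 0.02, 0.03, 0.04]))
        assert np.allclose(adj, 0.04)

    def test_single_p_unchanged(self):
        assert bh_adjust(np.array([0.2]))[0] == pytest.approx(0.2)

    def test_adjusted_never_below_raw(self, rng):
        p = rng.random(50)
        assert np.all(bh_adjust(p) >= p - 1e-15)

    def test_matches_independent_stepup_implementation(self, rng):
        def stepup(p):
            p = np.asarray(p, float)
            m = p.size
            order = np.argsort(p)
            adj = np.empty(m)
            running = 1.0
            for rank in range(m, 0, -1):
                i = order[rank - 1]
                running = min(running, p[i] * m / rank)
                adj[i] = running
            return adj

        for _ in range(100):
            p = rng.random(rng.integers(1, 40))
            assert np.abs(bh_adjust(p) - stepup(p)).max() < 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.2]))


class TestRunSnpsetAnalysis:
    def test_duplicate_sets_get_identical_results(self, rng):
        G = genotype_matrix(rng.integers(0, 3, (50, 6)))
        y = _pheno(rng.integers(0, 2, 50) | np.r_[1, np.zeros(49, int)])
        sets = [SnpSet("dup", np.arange(6)), SnpSet("dup", np.arange(6))]
        res = run_snpset_analysis(G, y, sets, method="pca", B=19, seed=7)
        assert res[0].M == res[1].M
        assert np.array_equal(res[0].null_M, res[1].null_M)

    def test_results_frame_columns_and_bh(self, rng):
        G = genotype_matrix(rng.integers(0, 3, (50, 8)))
        y = _pheno(rng.integers(0, 2, 50) | np.r_[1, np.zeros(49, int)])
        sets = [SnpSet("a", np.arange(4)), SnpSet("b", np.arange(4, 8))]
        res = run_snpset_analysis(G, y, sets, method="pca", B=19, seed=1)
        df = results_frame(res)
        assert list(df.columns) == [
            "set_id", "n_snps", "n_snps_optimal", "M", "p_value", "p_adjusted"
        ]
        assert (df.p_adjusted >= df.p_value - 1e-15).all()
        assert len(df) == 2

    def test_pooled_null_changes_reference_sample(self, rng):
        G = genotype_matrix(rng.integers(0, 3, (50, 8)))
        y = _pheno(rng.integers(0, 2, 50) | np.r_[1, np.zeros(49, int)])
        sets = [SnpSet("a", np.arange(4)), SnpSet("b", np.arange(4, 8))]
        pooled = run_snpset_analysis(G, y, sets, method="pca", B=19, seed=1, pool_null=True)
        for r in pooled:
            assert 0 < r.p_value <= 1

    def test_cpca_end_to_end_small(self, rng):
        G = genotype_matrix(rng.integers(0, 3, (60, 6)))
        y = _pheno(rng.integers(0, 2, 60) | np.r_[1, np.zeros(59, int)])
        res = run_snpset_analysis(
            G, y, [SnpSet("g", np.arange(6))], method="cpca", B=19, seed=2,
            config=PIPE_CFG,
        )
        assert len(res) == 1 and 0 < res[0].p_value <= 1
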