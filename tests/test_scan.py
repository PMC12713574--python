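import numpy as np
import pytest

from gwadl import geno
from gwadl.scan import (SelectionSet, bonferroni_threshold,
                        intersection_counts, multilocus_scan, pca_covariates,
                        reported_threshold, select_by_pvalue, select_spaced,
                        single_marker_scan)
from gwadl.simulate import SimConfig, simulate_dataset
from tests.conftest import genotype_mean_trait


class TestPCACovariates:
    def test_pc1_separates_demes(self):
        cfg = SimConfig(n_individuals=200, n_snps=800, seed=21)
        g, p, truth = simulate_dataset(cfg)
        gi = geno.impute_mean(g)
        c = pca_covariates(gi, 2)
        pc1 = c.values[:, 1]
        corr = np.corrcoef(pc1, truth.deme)[0, 1]
        assert abs(corr) > 0.9

    def test_scores_orthogonal(self, imputed_dataset):
        _, gi, _, _ = imputed_dataset
        c = pca_covariates(gi, 4)
        scores = c.values[:, 1:]
        gram = scores.T @ scores
        off = gram - np.diag(np.diag(gram))
        assert np.max(np.abs(off)) < 1e-8 * np.max(np.diag(gram))

    def test_k_zero_intercept_only(self, imputed_dataset):
        _, gi, _, _ = imputed_dataset
        c = pca_covariates(gi, 0)
        assert c.values.shape == (gi.n_samples, 1)
        np.testing.assert_array_equal(c.values[:, 0], 1.0)

    def test_k_too_large_error(self, imputed_dataset):
        _, gi, _, _ = imputed_dataset
        with pytest.raises(ValueError):
            pca_covariates(gi, gi.n_samples)


class TestSingleMarkerScan:
    def test_matches_normal_equation_ols(self, rng):
        """Exact agreement with per-marker OLS computed independently via
        statsmodels on a tiny instance."""
        import statsmodels.api as sm

        n, m = 10, 5
        D = rng.binomial(2, 0.4, (n, m)).astype(float)
        y = rng.normal(0, 1, n)
        C = np.column_stack([np.ones(n), rng.normal(0, 1, n)])
        p, b = single_marker_scan(D, y, C)
        for j in range(m):
            X = np.column_stack([C, D[:, j]])
            fit = sm.OLS(y, X).fit()
            assert p[j] == pytest.approx(fit.pvalues[-1], abs=1e-8)
            assert b[j] == pytest.approx(fit.params[-1], abs=1e-8)

    def test_extra_fixed_matches_ols(self, rng):
        import statsmodels.api as sm

        n, m = 12, 6
        D = rng.binomial(2, 0.5, (n, m)).astype(float)
        y = rng.normal(0, 1, n)
        C = np.ones((n, 1))
        p, b = single_marker_scan(D, y, C, extra_fixed=[0])
        X = np.column_stack([C, D[:, 0], D[:, 3]])
        fit = sm.OLS(y, X).fit()
        assert p[3] == pytest.approx(fit.pvalues[-1], abs=1e-8)
        assert p[0] == 1.0  # the fixed marker itself is not tested

    def test_planted_effect_recovered(self, rng):
        n, m = 100, 50
        D = rng.binomial(2, 0.5, (n, m)).astype(float)
        y = 2.0 * D[:, 7] + rng.normal(0, 0.01, n)
        p, b = single_marker_scan(D, y, np.ones((n, 1)))
        assert np.argmin(p) == 7
        assert b[7] == pytest.approx(2.0, abs=0.01)

    def test_collinear_marker_gets_p_one(self, rng):
        n = 30
        D = rng.binomial(2, 0.5, (n, 3)).astype(float)
        D[:, 2] = D[:, 0]  # identical to a fixed marker
        y = rng.normal(0, 1, n)
        p, b = single_marker_scan(D, y, np.ones((n, 1)), extra_fixed=[0])
        assert p[2] == 1.0
        assert b[2] == 0.0

    def test_null_pvalues_uniform(self):
        r = np.random.default_rng(77)
        n, m = 200, 800
        D = r.binomial(2, r.uniform(0.1, 0.9, m), (n, m)).astype(float)
        y = r.normal(0, 1, n)
        p, _ = single_marker_scan(D, y, np.ones((n, 1)))
        frac = np.mean(p < 0.05)
        assert abs(frac - 0.05) < 0.02

    def test_rank_deficient_covariates_error(self, rng):
        n = 20
        D = rng.binomial(2, 0.5, (n, 2)).astype(float)
        C = np.column_stack([np.ones(n), np.ones(n)])
        with pytest.raises(ValueError, match="rank"):
            single_marker_scan(D, rng.normal(0, 1, n), C)


class TestBonferroni:
    def test_panel_size_threshold_prints_as_published_convention(self):
        assert reported_threshold(5_641_729) == pytest.approx(8.8e-9)

    def test_simple_values(self):
        assert bonferroni_threshold(1) == 0.05
        assert bonferroni_threshold(100) == pytest.approx(5e-4)
        with pytest.raises(ValueError):
            bonferroni_threshold(0)


class TestSelection:
    def test_select_by_pvalue_counts(self, rng):
        p = np.full(300, 0.5)
        hot = rng.choice(300, 17, replace=False)
        p[hot] = 1e-6
        s = type("S", (), {"p_values": p})
        sel = select_by_pvalue(s, 1e-4)
        assert set(sel.indices) == set(hot)
        assert select_by_pvalue(s, 1.0).indices.size == 300
        s.p_values = np.full(300, 0.5)
        assert select_by_pvalue(s, 1e-4).indices.size == 0

    def test_select_spaced_stride(self):
        np.testing.assert_array_equal(select_spaced(10, 5).indices,
                                      [0, 2, 4, 6, 8])
        assert select_spaced(7, 7).indices.size == 7
        np.testing.assert_array_equal(select_spaced(9, 1).indices, [0])
        with pytest.raises(ValueError):
            select_spaced(5, 6)

    def test_intersection_counts_enumeration(self):
        sets = {"A": SelectionSet("A", "r", np.array([1, 2])),
                "B": SelectionSet("B", "r", np.array([2, 3]))}
        df = intersection_counts(sets)
        counts = dict(zip(df.combination, df["count"]))
        assert counts == {"A": 1, "B": 1, "A&B": 1}

    def test_disjoint_sets_no_overlap_rows(self):
        sets = {"A": SelectionSet("A", "r", np.array([1])),
                "B": SelectionSet("B", "r", np.array([2]))}
        df = intersection_counts(sets)
        assert df[df.degree > 1].empty

    def test_counts_sum_to_union(self, rng):
        sets = {f"t{i}": SelectionSet(f"t{i}", "r",
                                      rng.choice(5000, 400, replace=False))
                for i in range(12)}
        df = intersection_counts(sets)
        union = set()
        for s in sets.values():
            union |= set(s.indices.tolist())
        assert df["count"].sum() == len(union)


class TestMultilocusScan:
    def test_recovers_planted_qtn(self):
        cfg = SimConfig(n_individuals=250, n_snps=1500, n_qtns=1,
                        polygenic_fraction=0.0, ld_block_len=1,
                        h2_indiv=0.12, seed=5)
        g, p, truth = simulate_dataset(cfg)
        gi = geno.impute_mean(g)
        y = genotype_mean_trait(gi, p)
        res = multilocus_scan(gi, y, pca_covariates(gi, 2))
        q = truth.qtn_indices[0]
        assert np.argmin(res.p_values) == q
        assert q in res.pseudo_qtns

    def test_identical_columns_one_pseudo_qtn(self):
        cfg = SimConfig(n_individuals=200, n_snps=800, n_qtns=1,
                        polygenic_fraction=0.0, ld_block_len=1,
                        h2_indiv=0.3, seed=9)
        g, p, truth = simulate_dataset(cfg)
        gi = geno.impute_mean(g)
        q = truth.qtn_indices[0]
        twin = (q + 123) % gi.n_variants
        gi.dosages[:, twin] = gi.dosages[:, q]
        y = genotype_mean_trait(gi, p)
        res = multilocus_scan(gi, y, pca_covariates(gi, 2))
        assert len({q, twin} & set(res.pseudo_qtns)) == 1

    def test_pseudo_qtn_pairwise_r2_capped(self):
        cfg = SimConfig(n_individuals=200, n_snps=1000, n_qtns=5,
                        polygenic_fraction=0.0, h2_indiv=0.5, seed=13)
        g, p, _ = simulate_dataset(cfg)
        gi = geno.impute_mean(g)
        y = genotype_mean_trait(gi, p)
        res = multilocus_scan(gi, y, pca_covariates(gi, 2))
        qs = res.pseudo_qtns
        for a in range(len(qs)):
            for b in range(a + 1, len(qs)):
                r = np.corrcoef(gi.dosages[:, qs[a]], gi.dosages[:, qs[b]])[0, 1]
                assert r * r <= 0.7 + 1e-9

    def test_null_trait_no_bonferroni_hits(self):
        cfg = SimConfig(n_individuals=200, n_snps=1000, n_qtns=0,
                        polygenic_fraction=0.0, seed=31)
        g, p, _ = simulate_dataset(cfg)
        gi = geno.impute_mean(g)
        y = genotype_mean_trait(gi, p)
        res = multilocus_scan(gi, y, pca_covariates(gi, 2))
        assert (res.p_values < bonferroni_threshold(gi.n_variants)).sum() == 0
        assert res.converged

    def test_pvalues_in_unit_interval(self, imputed_dataset):
        _, gi, p, _ = imputed_dataset
        y = genotype_mean_trait(gi, p)
        res = multilocus_scan(gi, y, pca_covariates(gi, 2))
        assert np.all(res.p_values > 0)
        assert np.all(res.p_values <= 1)
        assert res.p_values.size == gi.n_variants
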