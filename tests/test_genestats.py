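import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

import gwaspath as gp
from gwaspath.genestats import _simulate_null_stats


class TestRawStatistics:
    def test_min_p_singleton(self):
        assert gp.gene_stat_min_p([0.5]) == 0.5

    def test_min_p(self):
        assert gp.gene_stat_min_p([0.2, 0.01, 0.7]) == 0.01

    def test_min_p_matches_sorting_oracle(self, rng):
        p = rng.uniform(size=100)
        assert gp.gene_stat_min_p(p) == sorted(p)[0]

    def test_fisher_of_one_is_zero(self):
        assert gp.gene_stat_fisher([1.0]) == 0.0

    def test_fisher_hand_computation(self):
        assert gp.gene_stat_fisher([0.1, 0.01]) == pytest.approx(13.8155, abs=1e-4)

    def test_fisher_matches_term_by_term_summation(self, rng):
        import math
        p = rng.uniform(0.001, 1, size=200)
        expected = -2 * math.fsum(math.log(x) for x in p)
        assert gp.gene_stat_fisher(p) == pytest.approx(expected, rel=1e-12)

    @pytest.mark.parametrize("fn", [gp.gene_stat_min_p, gp.gene_stat_fisher])
    def test_invalid_inputs_rejected(self, fn):
        with pytest.raises(ValueError):
            fn([])
        with pytest.raises(ValueError):
            fn([0.5, 0.0])


class TestAdjustByPermutation:
    def test_floor_when_observed_most_extreme(self):
        nulls = np.linspace(0.1, 1.0, 999)
        assert gp.adjust_by_permutation(0.05, nulls, "smaller_is_extreme") == \
            pytest.approx(1 / 1000)

    def test_median_observation_near_half(self, rng):
        nulls = rng.normal(size=999)
        p = gp.adjust_by_permutation(np.median(nulls), nulls, "larger_is_extreme")
        assert abs(p - 0.5) < 0.05

    def test_hand_count(self):
        assert gp.adjust_by_permutation(2.5, [1, 2, 3, 4], "larger_is_extreme") == \
            pytest.approx(3 / 5)

    def test_unsmoothed_option(self):
        assert gp.adjust_by_permutation(2.5, [1, 2, 3, 4], "larger_is_extreme",
                                        smoothed=False) == pytest.approx(2 / 4)

    def test_never_zero(self, rng):
        nulls = rng.uniform(size=50)
        p = gp.adjust_by_permutation(1e-20, nulls, "smaller_is_extreme")
        assert p == pytest.approx(1 / 51)


class TestEstimateLd:
    def test_perfectly_correlated_columns(self, tiny_panel):
        ld = gp.estimate_ld(tiny_panel, ["rs1", "rs4"])
        assert ld.corr[0, 1] == pytest.approx(1.0)
        assert np.all(np.diag(ld.corr) == 1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(5)
        n = 10_000
        d = rng.integers(0, 3, size=(n, 3)).astype(float)
        panel = gp.GenotypePanel([f"s{i}" for i in range(n)], ["a", "b", "c"], d)
        ld = gp.estimate_ld(panel, ["a", "b", "c"])
        off = ld.corr[np.triu_indices(3, 1)]
        assert np.all(np.abs(off) < 0.05)

    def test_rank_deficient_repair(self, tiny_panel):
        # rs4 copies rs1: sample matrix is singular
        ld = gp.estimate_ld(tiny_panel, ["rs1", "rs2", "rs4"])
        assert ld.repair_log["repaired"]
        w = np.linalg.eigvalsh(ld.corr)
        assert w.min() >= gp.genestats.PSD_FLOOR * 0.99
        assert np.allclose(np.diag(ld.corr), 1.0)
        ld.cholesky()  # must not raise

    def test_monomorphic_column_zeroed(self):
        d = np.column_stack([np.ones(30), np.arange(30) % 3]).astype(float)
        panel = gp.GenotypePanel([f"s{i}" for i in range(30)], ["mono", "ok"], d)
        ld = gp.estimate_ld(panel, ["mono", "ok"])
        assert ld.corr[0, 1] == 0.0

    def test_pairwise_complete_with_missing(self, tiny_panel):
        d = tiny_panel.dosages.copy()
        d[:10, 2] = np.nan
        panel = gp.GenotypePanel(tiny_panel.samples, tiny_panel.snp_ids, d)
        ld = gp.estimate_ld(panel, ["rs1", "rs3"])
        assert np.isfinite(ld.corr).all()


class TestAdjustBySimulation:
    def test_single_snp_identity(self):
        ld = gp.LdMatrix(["rs1"], np.array([[1.0]]))
        adj_min, _ = gp.adjust_by_simulation([0.05], ld, n_sim=10_000, seed=1)
        se = np.sqrt(0.05 * 0.95 / 10_000)
        assert abs(adj_min - 0.05) < 3 * se

    @pytest.mark.parametrize("m,minp", [(3, 0.02), (8, 0.1)])
    def test_identity_ld_matches_sidak_closed_form(self, m, minp):
        ld = gp.LdMatrix([f"rs{i}" for i in range(m)], np.eye(m))
        p = np.full(m, 0.9)
        p[0] = minp
        adj_min, _ = gp.adjust_by_simulation(p, ld, n_sim=20_000, seed=2)
        expected = 1 - (1 - minp) ** m
        se = np.sqrt(expected * (1 - expected) / 20_000)
        assert abs(adj_min - expected) < 3 * se + 1e-4

    def test_snp_order_invariance(self, tiny_panel):
        ld_a = gp.estimate_ld(tiny_panel, ["rs1", "rs2", "rs3"])
        ld_b = gp.estimate_ld(tiny_panel, ["rs3", "rs1", "rs2"])
        p = {"rs1": 0.02, "rs2": 0.4, "rs3": 0.15}
        a = gp.adjust_by_simulation([p[s] for s in ld_a.snp_ids], ld_a, n_sim=5_000, seed=3)
        b = gp.adjust_by_simulation([p[s] for s in ld_b.snp_ids], ld_b, n_sim=5_000, seed=3)
        assert a[0] == pytest.approx(b[0], abs=0.02)
        assert a[1] == pytest.approx(b[1], abs=0.02)

    def test_dimension_mismatch_rejected(self):
        ld = gp.LdMatrix(["rs1", "rs2"], np.eye(2))
        with pytest.raises(ValueError):
            gp.adjust_by_simulation([0.5], ld, n_sim=1000)

    def test_adjusted_p_lower_bound(self):
        ld = gp.LdMatrix(["rs1"], np.array([[1.0]]))
        adj_min, adj_f = gp.adjust_by_simulation([1e-300], ld, n_sim=500, seed=4)
        assert adj_min == pytest.approx(1 / 501)
        assert adj_f == pytest.approx(1 / 501)

    def test_null_stats_extreme_precision(self):
        # Fisher statistics from the log-scale path stay finite for huge Z
        chol = np.eye(2) * 1.0
        rng = np.random.default_rng(0)
        null_min, null_fisher = _simulate_null_stats(chol, 1000, rng)
        assert np.isfinite(null_fisher).all()
        assert (null_min > 0).all()


class TestTrendTest:
    def test_strong_association_detected(self, rng):
        n = 400
        g = rng.integers(0, 3, n).astype(float)
        y = (g + rng.normal(0, 0.5, n) > 1).astype(float)
        p = gp.trend_test_pvalues(g[:, None], y)
        assert p[0] < 1e-10

    def test_constant_column_p_one(self, rng):
        g = np.column_stack([np.full(100, 2.0), rng.integers(0, 3, 100).astype(float)])
        y = rng.integers(0, 2, 100).astype(float)
        p = gp.trend_test_pvalues(g, y)
        assert p[0] == 1.0
        assert 0 < p[1] <= 1

    def test_matches_chi2_contingency_trend(self, rng):
        # oracle: Armitage trend = n * r^2 against chi2(1)
        n = 300
        g = rng.integers(0, 3, n).astype(float)
        y = rng.integers(0, 2, n).astype(float)
        r = np.corrcoef(g, y)[0, 1]
        expected = sps.chi2.sf(n * r**2, 1)
        assert gp.trend_test_pvalues(g[:, None], y)[0] == pytest.approx(expected)


@pytest.fixture(scope="module")
def null_cohort():
    cfg = gp.SimulationConfig(n_genes=300, n_cases=300, n_controls=300, ld_rho=0.5,
                              seed=77)
    cohort = gp.simulate_cohort(cfg)
    return cohort, gp.assignment_from_panel(cohort)


class TestPhenotypePermutation:
    def test_deterministic_under_seed(self, null_cohort):
        cohort, asn = null_cohort
        a = gp.run_phenotype_permutation(cohort, asn, B=2, seed=9)
        b = gp.run_phenotype_permutation(cohort, asn, B=2, seed=9)
        np.testing.assert_array_equal(a["null_min"], b["null_min"])
        np.testing.assert_array_equal(a["null_fisher"], b["null_fisher"])

    def test_null_adjusted_pvalues_uniform(self, null_cohort):
        cohort, asn = null_cohort
        res = gp.adjust_genes_by_permutation(cohort, asn, B=200, seed=10)
        for col in ("adj_p_min", "adj_p_fisher"):
            ks = sps.kstest(res[col], "uniform")
            assert ks.pvalue > 0.01, f"{col} not uniform (KS P={ks.pvalue:.3g})"

    def test_single_snp_gene_equals_raw_p(self, null_cohort):
        cohort, asn = null_cohort
        res = gp.adjust_genes_by_permutation(cohort, asn, B=400, seed=11)
        single = res[res["n_snps"] == 1]
        assert len(single) > 10
        # Monte-Carlo error of the counting estimator at B=400
        err = (single["adj_p_min"] - single["stat_min_p"]).abs()
        tol = 3 * np.sqrt(single["stat_min_p"] * (1 - single["stat_min_p"]) / 400) + 1 / 400
        assert (err <= tol).mean() > 0.95

    def test_cache_round_trip(self, null_cohort, tmp_path):
        cohort, asn = null_cohort
        a = gp.adjust_genes_by_permutation(cohort, asn, B=50, seed=12,
                                           cache_dir=tmp_path)
        assert len(list(tmp_path.glob("permnull_*.npz"))) == 1
        b = gp.adjust_genes_by_permutation(cohort, asn, B=50, seed=12,
                                           cache_dir=tmp_path)
        pd.testing.assert_frame_equal(a, b)


class TestBulkSimulationAdjustment:
    def test_null_adjusted_pvalues_uniform(self):
        cfg = gp.SimulationConfig(n_genes=400, n_samples=400, ld_rho=0.5, seed=13)
        res = gp.universe_by_simulation(cfg, n_sim=400, seed=14)
        for col in ("adj_p_min", "adj_p_fisher"):
            ks = sps.kstest(res[col], "uniform")
            assert ks.pvalue > 0.01, f"{col} not uniform (KS P={ks.pvalue:.3g})"

    def test_gene_with_no_shared_snps_dropped(self, tiny_panel):
        asn = gp.GeneAssignment({"gA": ["rs1", "rs2"], "gB": ["rs_absent"]})
        res = gp.adjust_genes_by_simulation(
            {"rs1": 0.1, "rs2": 0.5, "rs_absent": 0.2}, asn, tiny_panel,
            n_sim=200, seed=15)
        assert res["gene_id"].tolist() == ["gA"]
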