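"""Association tests, kinship, mixed model and genomic control."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from strat_spectrum import (
    armitage_trend,
    build_variant_table,
    cmh_scan,
    cmh_test,
    eigenstrat_adjusted,
    eigenstrat_scan,
    emmax_reml,
    emmax_scan,
    grm,
    lambda_gc,
    scan_and_summarize,
    trend_scan,
)
from tests.conftest import make_gm


class TestArmitageTrend:
    def test_perfect_correlation(self):
        stat, p = armitage_trend(np.array([2, 2, 0, 0]),
                                 np.array([1, 1, 0, 0]))
        assert stat == pytest.approx(4.0, rel=1e-12)

    def test_constant_genotype_zero(self):
        stat, p = armitage_trend(np.array([1, 1, 1, 1]),
                                 np.array([1, 0, 1, 0]))
        assert (stat, p) == (0.0, 1.0)

    def test_null_calibration_chi2(self, rng):
        n = 400
        y = np.array([0, 1] * (n // 2))
        stats_ = []
        for _ in range(400):
            g = rng.binomial(2, 0.3, size=n)
            s, _ = armitage_trend(g, rng.permutation(y))
            stats_.append(s)
        # mean of chi2_1 is 1, sd of the mean ~ sqrt(2/400)
        assert abs(np.mean(stats_) - 1.0) < 3 * np.sqrt(2 / 400)

    def test_scan_matches_single(self, rng):
        d = rng.binomial(2, 0.3, size=(100, 30)).astype(np.int8)
        d[rng.random(d.shape) < 0.05] = -1
        y = rng.integers(0, 2, size=100)
        stats_ = trend_scan(d, y)
        for j in [0, 13, 29]:
            s, _ = armitage_trend(d[:, j], y)
            assert stats_[j] == pytest.approx(s, rel=1e-10)

    def test_plink_phenotype_coding_accepted(self, rng):
        g = rng.binomial(2, 0.4, size=60)
        y01 = rng.integers(0, 2, size=60)
        s1, _ = armitage_trend(g, y01)
        s2, _ = armitage_trend(g, y01 + 1)  # PLINK 1/2 coding
        assert s1 == pytest.approx(s2, rel=1e-12)


class TestEigenstratAdjusted:
    def test_k0_relation_to_trend(self, rng):
        g = rng.binomial(2, 0.4, size=80)
        y = rng.integers(0, 2, size=80)
        raw, _ = armitage_trend(g, y)
        adj, _ = eigenstrat_adjusted(g, y, np.empty((80, 0)))
        # documented exact relation: (N-1)/N times the trend statistic
        assert adj == pytest.approx(raw * 79 / 80, rel=1e-10)

    def test_invariant_to_pc_component_of_genotype(self, rng):
        # adding any PC-span component to the dosage vector must not move
        # the adjusted statistic: only the residual is tested
        n = 50
        pc = rng.normal(size=(n, 2))
        g = rng.binomial(2, 0.4, size=n).astype(float)
        y = rng.integers(0, 2, size=n)
        stat, _ = eigenstrat_adjusted(g, y, pc)
        shifted = g + 3.0 * pc[:, 0] - 1.2 * pc[:, 1] + 0.5
        stat2, _ = eigenstrat_adjusted(shifted, y, pc)
        assert stat2 == pytest.approx(stat, rel=1e-8)

    def test_structure_captured_by_pc_restores_null(self):
        from strat_spectrum import SimulationConfig, simulate_cohort
        from strat_spectrum.pca import eigen_pca

        config = SimulationConfig(
            n_regions=2, samples_per_region=100,
            n_variants_by_stratum={"common": 2000},
            ancestral_maf_spectrum={"common": ("uniform", 0.1, 0.5)},
            fst=0.1, private_rare_fraction=0.0,
            missing_rate=0.0, genotype_error_rate=0.0, seed=31)
        cohort = simulate_cohort(config)
        gm = cohort.genotypes
        y = (cohort.regions == "R2").astype(int)  # fully confounded phenotype
        pcs = eigen_pca(gm, k=2).scores
        raw = trend_scan(gm, y)
        adj = eigenstrat_scan(gm, y, pcs[:, :1])
        lam_raw = lambda_gc(statistics=raw)
        lam_adj = lambda_gc(statistics=adj)
        assert lam_raw > 2.0
        assert 0.8 < lam_adj < 1.2

    def test_collinear_pcs_warn(self, rng):
        g = rng.binomial(2, 0.4, size=60).astype(float)
        y = rng.integers(0, 2, size=60)
        pc = rng.normal(size=(60, 1))
        with pytest.warns(UserWarning, match="collinear"):
            eigenstrat_adjusted(g, y, np.hstack([pc, pc]))


class TestCMH:
    def test_single_stratum_equals_statsmodels(self, rng):
        from statsmodels.stats.contingency_tables import StratifiedTable

        g = rng.binomial(2, 0.3, size=120)
        y = rng.integers(0, 2, size=120)
        strata = np.array(["s"] * 120)
        stat, p, _ = cmh_test(g, y, strata)
        a = g[y == 1].sum()
        table = np.array([[a, 2 * (y == 1).sum() - a],
                          [g[y == 0].sum(), 2 * (y == 0).sum() - g[y == 0].sum()]])
        st = StratifiedTable([table.T.tolist()])
        res = st.test_null_odds(correction=False)
        assert stat == pytest.approx(res.statistic, abs=1e-10)

    def test_combines_consistent_strata(self):
        # same-direction association in both strata: CMH beats each alone
        g = np.array([2, 2, 1, 0, 0, 0, 2, 2, 2, 1, 0, 0])
        y = np.array([1, 1, 1, 0, 0, 0, 1, 1, 1, 0, 0, 0])
        strata = np.array(["a"] * 6 + ["b"] * 6)
        full, _, _ = cmh_test(g, y, strata)
        sa, _, _ = cmh_test(g[:6], y[:6], strata[:6])
        sb, _, _ = cmh_test(g[6:], y[6:], strata[6:])
        assert full > max(sa, sb)

    def test_permutation_p_uniform_under_confounding(self, rng):
        # phenotype determined by stratum only: within-stratum shuffles are
        # the correct null, so permutation p is calibrated
        pvals = []
        for i in range(60):
            rng_i = np.random.default_rng(1000 + i)
            g = np.concatenate([rng_i.binomial(2, 0.1, 40),
                                rng_i.binomial(2, 0.5, 40)])
            y = np.array([0] * 20 + [1] * 20 + [0] * 20 + [1] * 20)
            strata = np.array(["a"] * 40 + ["b"] * 40)
            _, _, pp = cmh_test(g, y, strata, n_perm=200, seed=i)
            pvals.append(pp)
        assert 0.3 < np.mean(pvals) < 0.7

    def test_no_informative_stratum_warns(self):
        g = np.zeros(10)
        y = np.array([0, 1] * 5)
        with pytest.warns(UserWarning, match="informative"):
            stat, p, _ = cmh_test(g, y, np.array(["s"] * 10))
        assert p == 1.0

    def test_scan_matches_single(self, rng):
        d = rng.binomial(2, 0.3, size=(90, 25)).astype(np.int8)
        d[rng.random(d.shape) < 0.04] = -1
        y = rng.integers(0, 2, size=90)
        strata = np.array(["a", "b", "c"] * 30)
        stats_ = cmh_scan(d, y, strata)
        for j in [0, 11, 24]:
            s, _, _ = cmh_test(d[:, j], y, strata)
            assert stats_[j] == pytest.approx(s, rel=1e-10)


class TestGRM:
    def test_duplicated_individuals(self, rng):
        d = rng.binomial(2, rng.uniform(0.1, 0.5, 200), size=(30, 200)).astype(np.int8)
        d2 = np.vstack([d, d[:1]])  # sample 30 duplicates sample 0
        k = grm(d2)
        assert k[0, 30] == pytest.approx(k[0, 0], rel=1e-10)
        assert k[30, 30] == pytest.approx(k[0, 0], rel=1e-10)

    def test_unrelated_off_diagonal_near_zero(self, rng):
        d = rng.binomial(2, rng.uniform(0.2, 0.5, 500), size=(40, 500)).astype(np.int8)
        k = grm(d)
        off = k[~np.eye(40, dtype=bool)]
        assert abs(off.mean()) < 0.05

    def test_permutation_equivariance(self, rng):
        d = rng.binomial(2, 0.3, size=(20, 100)).astype(np.int8)
        k = grm(d)
        perm = rng.permutation(20)
        k2 = grm(d[perm])
        np.testing.assert_allclose(k2, k[np.ix_(perm, perm)], atol=1e-12)


class TestEMMAX:
    def test_identity_kinship_equals_ols(self, rng):
        n = 80
        d = rng.binomial(2, rng.uniform(0.1, 0.5, 40), size=(n, 40)).astype(np.int8)
        y = rng.integers(0, 2, size=n).astype(float)
        pvals = emmax_scan(y, np.eye(n), d)
        for j in range(0, 40, 7):
            res = stats.linregress(d[:, j].astype(float), y)
            assert pvals[j] == pytest.approx(res.pvalue, rel=1e-6)

    def test_reml_optimum_beats_bracket_endpoints(self, rng):
        n = 60
        d = rng.binomial(2, 0.3, size=(n, 300)).astype(np.int8)
        k = grm(d)
        y = rng.normal(size=n)
        fit = emmax_reml(y, k)
        neg = fit["_neg_rll"]
        assert -neg(np.log(fit["delta"])) >= -neg(np.log(1e-5)) - 1e-9
        assert -neg(np.log(fit["delta"])) >= -neg(np.log(1e5)) - 1e-9

    def test_structured_confounding_reduced(self):
        from strat_spectrum import SimulationConfig, simulate_cohort

        config = SimulationConfig(
            n_regions=2, samples_per_region=100,
            n_variants_by_stratum={"common": 3000},
            ancestral_maf_spectrum={"common": ("uniform", 0.1, 0.5)},
            fst=0.1, private_rare_fraction=0.0,
            missing_rate=0.0, genotype_error_rate=0.0, seed=41)
        cohort = simulate_cohort(config)
        gm = cohort.genotypes
        y = (cohort.regions == "R2").astype(float)
        kin = grm(gm)
        lam_raw = lambda_gc(statistics=trend_scan(gm, y))
        lam_mm = lambda_gc(pvalues=emmax_scan(y, kin, gm))
        assert lam_mm < lam_raw
        assert lam_mm < 1.3


class TestLambdaGC:
    def test_analytic_median(self):
        from scipy.stats import chi2

        med = chi2.ppf(0.5, 1)
        assert lambda_gc(statistics=np.full(101, med)) == pytest.approx(1.0)
        assert lambda_gc(statistics=np.full(101, 2 * med)) == pytest.approx(2.0)

    def test_scale_equivariance(self, rng):
        s = rng.chisquare(1, size=999)
        assert lambda_gc(statistics=3 * s) == pytest.approx(
            3 * lambda_gc(statistics=s), rel=1e-12)

    def test_chi2_draws_calibrate(self, rng):
        s = rng.chisquare(1, size=100_000)
        assert lambda_gc(statistics=s) == pytest.approx(1.0, abs=0.02)

    def test_pvalue_route_matches_statistic_route(self, rng):
        from scipy.stats import chi2

        s = rng.chisquare(1, size=500)
        p = chi2.sf(s, 1)
        assert lambda_gc(pvalues=p) == pytest.approx(
            lambda_gc(statistics=s), rel=1e-9)


class TestScanAndSummarize:
    def test_grid_shape_and_labels(self, two_pop_cohort):
        gm = two_pop_cohort.genotypes
        y = np.tile([1, 2], gm.n_samples // 2)
        table = build_variant_table(gm, two_pop_cohort.regions)
        from strat_spectrum.pca import eigen_pca

        pcs = eigen_pca(gm, k=3).scores
        grid = scan_and_summarize(
            gm, y, two_pop_cohort.regions, table,
            pc_sets={"common": pcs}, pc_counts=(2,))
        assert list(grid.index) == ["CMH", "Raw", "common.2"]
        assert list(grid.columns) == ["common", "lowfreq", "rare",
                                      "rare_maf<=0.005", "rare_maf>0.005"]
        # this cohort has only common variants: rare cells are NA
        assert np.isnan(grid.loc["Raw", "rare"])
        assert np.isfinite(grid.loc["Raw", "common"])
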