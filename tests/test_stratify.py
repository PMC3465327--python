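"""MAF categories, burden, regional sharing and homogeneity statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import chi2

from strat_spectrum import (
    build_variant_table,
    categorize_variants,
    expected_sharing_proportion,
    heterogeneity_scan,
    lambda_r,
    mantel_extension_test,
    rare_allele_burden,
    region_heterogeneity_test,
    region_sharing,
    unique_region_concordance,
    variant_region_presence,
)
from tests.conftest import make_gm


class TestCategorize:
    @pytest.mark.parametrize("maf,copies,expected", [
        (0.3, 1000, "common"),
        (0.05, 300, "common"),      # boundary MAF 0.05 -> common
        (0.01, 60, "lowfreq"),      # boundary 0.01 -> lowfreq
        (0.008, 3, "rare"),
        (0.0003, 2, "others"),
        (0.004, 5, "rare"),
    ])
    def test_category_rules(self, maf, copies, expected):
        cat, _ = categorize_variants(np.array([maf]), np.array([copies]))
        assert cat[0] == expected

    def test_rare_subdivision(self):
        cat, sub = categorize_variants(np.array([0.004, 0.008, 0.3]),
                                       np.array([5, 9, 100]))
        assert list(sub) == ["very_rare", "less_rare", "n/a"]

    def test_categories_partition(self, rng):
        maf = rng.uniform(0, 0.5, 500)
        copies = np.maximum((maf * 1000).astype(int), 1)
        cat, _ = categorize_variants(maf, copies)
        assert (cat != "").all()


class TestBurden:
    def test_burden_arithmetic(self):
        gm = make_gm(np.array([[1, 2, 0], [0, 0, 0]]))
        table = build_variant_table(gm)
        table["category"] = "rare"  # force: all columns count
        regions = np.array(["a", "b"])
        burden, _, _ = rare_allele_burden(gm, table, regions)
        assert burden[0] == 3
        assert burden[1] == 0

    def test_burden_counts_minor_allele_not_allele2(self):
        # allele2 is the major allele here (freq 5/6): burden counts allele1
        gm = make_gm(np.array([[2], [2], [1]]))
        table = build_variant_table(gm)
        table["category"] = "rare"
        burden, _, _ = rare_allele_burden(gm, table, np.array(["a", "a", "b"]))
        np.testing.assert_array_equal(burden, [0, 0, 1])

    def test_kruskal_matches_rank_oracle(self):
        # burdens {1,2,3} vs {11,12,13}: no ties, H has a closed rank form;
        # burden i is realized as i singleton-carrier columns
        n = np.array([1, 2, 3, 11, 12, 13])
        d = np.zeros((6, 13), dtype=np.int8)
        for i, c in enumerate(n):
            d[i, :c] = 1
        gm = make_gm(d)
        table = build_variant_table(gm)
        table["category"] = "rare"
        regions = np.array(["x"] * 3 + ["y"] * 3)
        burden, stat, p = rare_allele_burden(gm, table, regions)
        np.testing.assert_array_equal(burden, n)
        ranks = np.array([1, 2, 3, 4, 5, 6])
        h = 12 / (6 * 7) * (3 * (ranks[:3].mean() - 3.5) ** 2
                            + 3 * (ranks[3:].mean() - 3.5) ** 2)
        assert stat == pytest.approx(h, rel=1e-12)

    def test_single_region_returns_nan_test(self):
        gm = make_gm(np.array([[1], [0]]))
        table = build_variant_table(gm)
        table["category"] = "rare"
        _, stat, p = rare_allele_burden(gm, table, np.array(["a", "a"]))
        assert np.isnan(stat) and np.isnan(p)


class TestSharing:
    def test_known_carrier_placement(self):
        # v0 carried only in region 1; v1 in regions 1 and 3; v2 everywhere
        d = np.array([
            [1, 1, 1],   # region 1
            [0, 0, 1],   # region 2
            [0, 1, 1],   # region 3
        ])
        gm = make_gm(d)
        regions = np.array(["r1", "r2", "r3"])
        table = build_variant_table(gm, regions)
        table["category"] = "rare"
        summary = region_sharing(gm, regions, table, "rare")
        np.testing.assert_array_equal(summary.histogram, [1, 1, 1])
        assert summary.prop_all_regions == pytest.approx(1 / 3)

    def test_common_variant_shared_everywhere(self):
        from strat_spectrum import SimulationConfig, simulate_cohort

        config = SimulationConfig(
            n_regions=2, samples_per_region=50,
            n_variants_by_stratum={"common": 400},
            ancestral_maf_spectrum={"common": ("uniform", 0.2, 0.5)},
            fst=0.0, private_rare_fraction=0.0,
            missing_rate=0.0, genotype_error_rate=0.0, seed=21)
        gm = simulate_cohort(config).genotypes
        regions = simulate_cohort(config).regions
        table = build_variant_table(gm, regions)
        common = table[table["category"] == "common"]
        assert (common["n_regions_polymorphic"] == 2).mean() > 0.99


class TestExpectedSharing:
    def test_pigeonhole_zero(self):
        assert expected_sharing_proportion([1], [10] * 12) == 0.0

    def test_saturation_limit(self):
        assert expected_sharing_proportion([29], [10, 10, 10]) == pytest.approx(1.0)

    def test_exact_matches_montecarlo(self):
        sizes = [10, 10, 10]
        exact = expected_sharing_proportion([4], sizes, method="exact")
        n_mc = 100_000
        mc = expected_sharing_proportion([4], sizes, method="montecarlo",
                                         n_mc=n_mc, seed=42)
        se = np.sqrt(exact * (1 - exact) / n_mc)
        assert abs(exact - mc) < 3 * se

    def test_exact_matches_brute_force_enumeration(self):
        # 2 regions of 3 and 2 individuals, c = 2 carriers:
        # P(both regions hit) = 3*2 / C(5,2) = 0.6
        assert expected_sharing_proportion([2], [3, 2]) == pytest.approx(0.6)


class TestHeterogeneity:
    def test_two_region_textbook_statistic(self):
        # allele table (10,90 | 90,10): chi2 = sum (O-E)^2/E with E = 50
        d = np.concatenate([np.repeat(0, 5), np.repeat(2, 45),
                            np.repeat(2, 5), np.repeat(0, 45)]).astype(np.int8)
        regions = np.array(["a"] * 50 + ["b"] * 50)
        stat, df, p, _ = region_heterogeneity_test(d, regions, n_perm=0)
        expected = 4 * (40 ** 2) / 50
        assert stat == pytest.approx(expected, rel=1e-12)
        assert df == 1

    def test_null_statistic_near_df(self, rng):
        stats = []
        for _ in range(200):
            d = rng.binomial(2, 0.3, size=120).astype(np.int8)
            regions = np.array(["a", "b", "c"] * 40)
            s, df, p, _ = region_heterogeneity_test(d, regions, n_perm=0)
            stats.append(s)
        assert abs(np.mean(stats) - 2) < 0.4  # E[chi2_2] = 2

    def test_permutation_p_reproducible_and_near_asymptotic(self, rng):
        # two independent permutation runs must agree within binomial error;
        # the asymptotic p agrees only up to the sample's HWE-departure
        # dispersion factor, hence the looser second bound
        d = rng.binomial(2, 0.4, size=2000).astype(np.int8)
        regions = np.array(["a", "b"] * 1000)
        n_perm = 1500
        stat, df, p_asymp, p_perm = region_heterogeneity_test(
            d, regions, n_perm=n_perm, seed=11)
        _, _, _, p_perm2 = region_heterogeneity_test(
            d, regions, n_perm=n_perm, seed=99)
        se = np.sqrt(p_perm * (1 - p_perm) / n_perm)
        assert abs(p_perm - p_perm2) < 3 * np.sqrt(2) * se + 2 / n_perm
        assert abs(p_perm - p_asymp) < 0.1

    def test_degenerate_table_p_one(self):
        d = np.zeros(40, dtype=np.int8)
        regions = np.array(["a", "b"] * 20)
        with pytest.warns(UserWarning, match="degenerate"):
            stat, df, p, _ = region_heterogeneity_test(d, regions, n_perm=0)
        assert p == 1.0

    def test_scan_matches_single_variant(self, rng):
        d = rng.binomial(2, 0.3, size=(90, 20)).astype(np.int8)
        d[rng.random(d.shape) < 0.05] = -1
        regions = np.array(["a", "b", "c"] * 30)
        gm = make_gm(d)
        stats, pvals = heterogeneity_scan(gm, regions)
        for j in [0, 7, 19]:
            s, df, p, _ = region_heterogeneity_test(d[:, j], regions, n_perm=0)
            assert stats[j] == pytest.approx(s, rel=1e-10)
            assert pvals[j] == pytest.approx(p, rel=1e-10)


class TestMantelExtension:
    def test_identical_cohorts_give_zero(self):
        copies = np.array([10.0, 20.0])
        alleles = np.array([100.0, 200.0])
        stat, p = mantel_extension_test(copies, alleles, copies, alleles)
        assert stat == pytest.approx(0.0, abs=1e-12)

    def test_single_stratum_reduces_to_allelic_chisq(self):
        # 2x2 table: cohortA 30/70, cohortB 10/90 (alleles)
        a, na, b, nb = 30.0, 100.0, 10.0, 100.0
        stat, p = mantel_extension_test([a], [na], [b], [nb])
        # Pearson chi-square on the 2x2 (equals CMH * N/(N-1))
        table = np.array([[a, na - a], [b, nb - b]])
        n = table.sum()
        e = np.outer(table.sum(1), table.sum(0)) / n
        pearson = ((table - e) ** 2 / e).sum()
        assert stat == pytest.approx(pearson * (n - 1) / n, rel=1e-12)

    def test_two_stratum_hand_formula(self):
        ca, na = np.array([12.0, 5.0]), np.array([60.0, 40.0])
        cb, nb = np.array([6.0, 9.0]), np.array([60.0, 40.0])
        stat, _ = mantel_extension_test(ca, na, cb, nb)
        num, var = 0.0, 0.0
        for k in range(2):
            n = na[k] + nb[k]
            col1 = ca[k] + cb[k]
            col2 = n - col1
            e = na[k] * col1 / n
            v = na[k] * nb[k] * col1 * col2 / (n ** 2 * (n - 1))
            num += ca[k] - e
            var += v
        assert stat == pytest.approx(num ** 2 / var, rel=1e-12)


class TestLambdaR:
    def test_analytic_values(self):
        assert lambda_r(np.full(11, 0.5)) == pytest.approx(1.0, abs=1e-12)
        assert lambda_r(np.full(11, 0.25)) == pytest.approx(2.0, abs=1e-12)

    def test_uniform_null_calibrates(self, rng):
        p = rng.uniform(0, 1, 100_000)
        assert lambda_r(p) == pytest.approx(1.0, abs=0.02)

    def test_zero_p_clipped_with_warning(self):
        with pytest.warns(UserWarning, match="clipped"):
            val = lambda_r(np.array([0.0, 0.5, 0.5]))
        assert np.isfinite(val)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            lambda_r(np.array([]))


class TestUniqueRegionConcordance:
    def test_identical_cohorts_full_concordance(self):
        pres = np.array([[1, 0, 0], [0, 1, 0], [1, 1, 0]], dtype=bool)
        n_both, n_same = unique_region_concordance(pres, pres)
        assert (n_both, n_same) == (2, 2)

    def test_disjoint_private_regions(self):
        a = np.array([[1, 0, 0], [0, 1, 0]], dtype=bool)
        b = np.array([[0, 1, 0], [0, 0, 1]], dtype=bool)
        assert unique_region_concordance(a, b) == (2, 0)

    def test_random_fixture_matches_brute_force(self, rng):
        a = rng.random((200, 5)) < 0.3
        b = rng.random((200, 5)) < 0.3
        a[a.sum(1) == 0, 0] = True
        b[b.sum(1) == 0, 0] = True
        n_both, n_same = unique_region_concordance(a, b)
        exp_both = exp_same = 0
        for i in range(200):
            ra = np.flatnonzero(a[i])
            rb = np.flatnonzero(b[i])
            if len(ra) == 1 and len(rb) == 1:
                exp_both += 1
                exp_same += int(ra[0] == rb[0])
        assert (n_both, n_same) == (exp_both, exp_same)
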