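"""MAF categorization, rare-variant regional sharing, and homogeneity tests.

Variants are binned by minor allele frequency in the pooled controls:
common (MAF >= 0.05), low-frequency (0.01 <= MAF < 0.05), rare
(MAF < 0.01 with the minor allele seen in more than 2 copies) and "others"
(<= 2 copies, artifact-prone, excluded downstream). Rare variants are
further split at MAF 0.005 into very-rare and less-rare.

The module also provides the regional-sharing spectrum of a category (in
how many regions is each variant polymorphic), the expected
all-region-sharing proportion under homogeneous allocation of carriers
(multivariate hypergeometric, by inclusion-exclusion or Monte Carlo), a
per-variant region-homogeneity chi-square with permutation p-values, a
Mantel-extension (stratified CMH) test of cohort differences, and the
lambda_r overdispersion coefficient: the median of -2*ln(p) over a set of
homogeneity-test p-values divided by the chi-square(2df) median 2*ln(2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import chi2, kruskal

from strat_spectrum.plinkio import MISSING, GenotypeMatrix, compute_maf

CHI2_2DF_MEDIAN = 2.0 * math.log(2.0)

CATEGORIES = ("common", "lowfreq", "rare", "others")


@dataclass
class SharingSummary:
    """Distribution of the number of regions in which variants are polymorphic."""

    histogram: np.ndarray  # index r-1 -> variants polymorphic in exactly r regions
    n_variants: int
    prop_all_regions: float
    expected_prop_all_regions: float | None = None

    def __post_init__(self) -> None:
        if self.histogram.sum() > self.n_variants:
            raise ValueError("sharing histogram exceeds variant count")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "n_regions": np.arange(1, len(self.histogram) + 1),
            "n_variants": self.histogram,
        })


def categorize_variants(maf: np.ndarray, copies: np.ndarray,
                        copy_threshold: int = 2):
    """Assign MAF categories; returns (category, rare_subcategory) arrays.

    Boundaries follow the chip-study convention: MAF >= 0.05 -> common;
    0.01 <= MAF < 0.05 -> lowfreq; MAF < 0.01 with minor-allele copies
    above ``copy_threshold`` -> rare, otherwise -> others. Rare variants
    split at MAF 0.005 into very_rare (<= 0.005) and less_rare (> 0.005).
    Undefined MAF (NaN) yields an empty category label.
    """
    maf = np.asarray(maf, dtype=float)
    copies = np.asarray(copies)
    category = np.full(maf.shape, "", dtype=object)
    defined = ~np.isnan(maf)
    category[defined & (maf >= 0.05)] = "common"
    category[defined & (maf >= 0.01) & (maf < 0.05)] = "lowfreq"
    low = defined & (maf < 0.01)
    category[low & (copies > copy_threshold)] = "rare"
    category[low & (copies <= copy_threshold)] = "others"
    rare_sub = np.full(maf.shape, "n/a", dtype=object)
    rare = category == "rare"
    rare_sub[rare & (maf <= 0.005)] = "very_rare"
    rare_sub[rare & (maf > 0.005)] = "less_rare"
    return category, rare_sub


def build_variant_table(gm: GenotypeMatrix, regions: np.ndarray | None = None,
                        copy_threshold: int = 2) -> pd.DataFrame:
    """Per-variant table: MAF, copy count, category, rare subcategory and
    (when region labels are given) the number of regions where polymorphic."""
    table = compute_maf(gm)
    table.insert(0, "variant_id", gm.variant_ids)
    category, rare_sub = categorize_variants(
        table["maf"].to_numpy(), table["mac"].to_numpy(), copy_threshold)
    table["category"] = category
    table["rare_subcategory"] = rare_sub
    if regions is not None:
        presence = variant_region_presence(gm, regions)
        table["n_regions_polymorphic"] = presence.sum(axis=1)
    return table


def _minor_dosages(gm: GenotypeMatrix, minor_is_allele2: np.ndarray) -> np.ndarray:
    """Dosages counting the minor allele, missing mapped to 0 copies."""
    d = gm.dosages
    called = d != MISSING
    d2 = np.where(called, d, 0)
    return np.where(minor_is_allele2[None, :], d2, np.where(called, 2 - d2, 0))


def rare_allele_burden(gm: GenotypeMatrix, variant_table: pd.DataFrame,
                       regions: np.ndarray, category: str = "rare"):
    """Per-individual minor-allele count in a category + Kruskal-Wallis test.

    The burden is the sum of minor-allele dosages over the category's
    variants; missing genotypes contribute 0 copies (a burden is a carrier
    count, and imputing would manufacture rare alleles). The Kruskal-Wallis
    test (tie-corrected) compares burden distributions across regions;
    with a single region the test is undefined and (nan, nan) is returned.
    """
    mask = (variant_table["category"] == category).to_numpy()
    sub = gm.take_variants(np.flatnonzero(mask))
    minor2 = variant_table.loc[mask, "minor_is_allele2"].to_numpy()
    burden = _minor_dosages(sub, minor2).sum(axis=1)
    labels = pd.unique(regions)
    if len(labels) < 2:
        return burden, float("nan"), float("nan")
    groups = [burden[regions == r] for r in labels]
    stat, p = kruskal(*groups)
    return burden, float(stat), float(p)


def variant_region_presence(gm: GenotypeMatrix, regions: np.ndarray,
                            variant_table: pd.DataFrame | None = None) -> np.ndarray:
    """Boolean (variants x regions) matrix: >=1 minor-allele copy among the
    region's non-missing genotypes. Region columns follow label-sorted order
    of ``np.unique``."""
    if variant_table is None:
        variant_table = compute_maf(gm)
    minor2 = variant_table["minor_is_allele2"].to_numpy()
    minor = _minor_dosages(gm, minor2)
    labels = np.unique(regions)
    out = np.empty((gm.n_variants, len(labels)), dtype=bool)
    for k, r in enumerate(labels):
        out[:, k] = (minor[regions == r] > 0).any(axis=0)
    return out


def region_sharing(gm: GenotypeMatrix, regions: np.ndarray,
                   variant_table: pd.DataFrame, category: str,
                   expected: bool = False) -> SharingSummary:
    """Sharing spectrum of one category: histogram over 1..n_regions of the
    number of regions in which each variant is polymorphic.

    With ``expected=True`` the homogeneous-allocation expectation of the
    all-region sharing proportion is attached (exact inclusion-exclusion
    over the category's minor-allele copy counts).
    """
    mask = (variant_table["category"] == category).to_numpy()
    sub = gm.take_variants(np.flatnonzero(mask))
    sub_table = variant_table.loc[mask].reset_index(drop=True)
    presence = variant_region_presence(sub, regions, sub_table)
    n_regions = presence.shape[1]
    counts = presence.sum(axis=1)
    hist = np.bincount(counts, minlength=n_regions + 1)[1:n_regions + 1]
    n = int(mask.sum())
    prop_all = float(hist[-1] / n) if n else float("nan")
    exp_prop = None
    if expected and n:
        region_sizes = np.array([(regions == r).sum() for r in np.unique(regions)])
        exp_prop = expected_sharing_proportion(
            sub_table["mac"].to_numpy(), region_sizes, method="exact")
    return SharingSummary(histogram=hist, n_variants=n,
                         prop_all_regions=prop_all,
                         expected_prop_all_regions=exp_prop)


def expected_sharing_proportion(copy_counts: np.ndarray,
                                region_sizes: np.ndarray,
                                method: str = "exact",
                                n_mc: int = 100_000,
                                seed: int | None = None) -> float:
    """Expected proportion of variants present in every region when carriers
    are allocated homogeneously over individuals.

    For a variant with c minor-allele copies, carriers are dropped at random
    without replacement over the N individuals (multivariate hypergeometric
    over region sizes); the probability that every region receives at least
    one carrier is computed by inclusion-exclusion over region subsets
    (``exact``) or estimated by simulation (``montecarlo``). Returns the
    mean of these probabilities over variants. c below the number of
    regions gives probability 0 by pigeonhole.
    """
    copy_counts = np.asarray(copy_counts, dtype=int)
    region_sizes = np.asarray(region_sizes, dtype=int)
    if (region_sizes < 1).any():
        raise ValueError("region sizes must be >= 1")
    if (copy_counts < 1).any():
        raise ValueError("copy counts must be >= 1")
    n_total = int(region_sizes.sum())
    copy_counts = np.minimum(copy_counts, n_total)
    if method == "exact":
        # signed counts over subset-size totals: for each subset S of regions,
        # a term (-1)^|S| * C(N - sum(sizes in S), c); group equal totals
        signed: dict[int, int] = {}
        r = len(region_sizes)
        for k in range(r + 1):
            sign = -1 if k % 2 else 1
            for subset in combinations(region_sizes.tolist(), k):
                t = sum(subset)
                signed[t] = signed.get(t, 0) + sign
        cache: dict[int, float] = {}

        def prob_all(c: int) -> float:
            if c < r:
                return 0.0
            if c not in cache:
                denom = math.comb(n_total, c)
                num = sum(cnt * math.comb(n_total - t, c)
                          for t, cnt in signed.items() if n_total - t >= c)
                cache[c] = num / denom
            return cache[c]

        return float(np.mean([prob_all(int(c)) for c in copy_counts]))
    if method == "montecarlo":
        rng = np.random.default_rng(seed)
        probs = []
        for c in np.unique(copy_counts):
            draws = rng.multivariate_hypergeometric(
                region_sizes, int(c), size=n_mc)
            probs.append((int(c), (draws > 0).all(axis=1).mean()))
        lookup = dict(probs)
        return float(np.mean([lookup[int(c)] for c in copy_counts]))
    raise ValueError(f"unknown method {method!r}")


def _allele_table(dosages: np.ndarray, regions: np.ndarray) -> np.ndarray:
    """2 x n_regions allele-count table (allele2 copies / other copies)."""
    labels = np.unique(regions)
    table = np.zeros((2, len(labels)))
    for k, r in enumerate(labels):
        d = dosages[regions == r]
        d = d[d != MISSING]
        table[0, k] = d.sum()
        table[1, k] = 2 * len(d) - d.sum()
    return table


def _pearson_chi2(table: np.ndarray) -> float:
    rowsum = table.sum(axis=1, keepdims=True)
    colsum = table.sum(axis=0, keepdims=True)
    total = table.sum()
    expected = rowsum * colsum / total
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(expected > 0, (table - expected) ** 2 / expected, 0.0)
    return float(terms.sum())


def region_heterogeneity_test(dosages: np.ndarray, regions: np.ndarray,
                              n_perm: int = 10_000, seed: int | None = None):
    """(n_regions - 1)-df chi-square homogeneity test of allele counts
    across regions for one variant, with a permutation p-value.

    Returns (statistic, df, asymptotic p, permutation p). Permutations
    shuffle region labels over individuals; the p-value carries the add-one
    correction (b + 1) / (n_perm + 1). ``n_perm=0`` skips permutation
    (returns NaN). A degenerate table (zero allele margin) returns p = 1.
    """
    dosages = np.asarray(dosages)
    labels = np.unique(regions)
    df = len(labels) - 1
    table = _allele_table(dosages, regions)
    if (table.sum(axis=1) == 0).any() or (table.sum(axis=0) == 0).any():
        warnings.warn("degenerate allele table; homogeneity p set to 1")
        return 0.0, df, 1.0, 1.0 if n_perm else float("nan")
    stat = _pearson_chi2(table)
    p_asymp = float(chi2.sf(stat, df=df))
    p_perm = float("nan")
    if n_perm:
        rng = np.random.default_rng(seed)
        called = dosages != MISSING
        b = 0
        for _ in range(n_perm):
            perm = rng.permutation(regions)
            t = _allele_table(dosages, perm)
            if _pearson_chi2(t) >= stat - 1e-12:
                b += 1
        p_perm = (b + 1) / (n_perm + 1)
        del called
    return stat, df, p_asymp, p_perm


def heterogeneity_scan(gm: GenotypeMatrix, regions: np.ndarray):
    """Vectorized region-homogeneity chi-square over all variants.

    Returns (statistics, asymptotic p-values); degenerate variants
    (monomorphic over called genotypes, or an empty region) get p = 1.
    Feeds :func:`lambda_r` for per-category overdispersion.
    """
    d = gm.dosages
    labels = np.unique(regions)
    r = len(labels)
    df = r - 1
    ind = np.stack([(regions == lab).astype(float) for lab in labels])  # (r, n)
    called = (d != MISSING).astype(float)
    dz = np.where(d != MISSING, d, 0).astype(float)
    copies2 = ind @ dz                    # (r, m) allele2 copies per region
    alleles = 2.0 * (ind @ called)        # (r, m) called alleles per region
    copies1 = alleles - copies2
    tot2 = copies2.sum(axis=0)
    tot1 = copies1.sum(axis=0)
    total = alleles.sum(axis=0)
    stats = np.zeros(gm.n_variants)
    ok = (tot1 > 0) & (tot2 > 0) & (alleles > 0).all(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        e2 = alleles * (tot2 / total)[None, :]
        e1 = alleles * (tot1 / total)[None, :]
        terms = np.where(e2 > 0, (copies2 - e2) ** 2 / e2, 0.0) \
            + np.where(e1 > 0, (copies1 - e1) ** 2 / e1, 0.0)
    stats[ok] = terms.sum(axis=0)[ok]
    pvals = np.ones(gm.n_variants)
    pvals[ok] = chi2.sf(stats[ok], df=df)
    return stats, pvals


def _cmh_2x2xk(tables: np.ndarray):
    """CMH statistic for stacked 2x2 tables, shape (K, 2, 2), no continuity
    correction. Returns (statistic, p); strata with margin 0 drop out."""
    a = tables[:, 0, 0]
    row1 = tables[:, 0, :].sum(axis=1)
    row2 = tables[:, 1, :].sum(axis=1)
    col1 = tables[:, :, 0].sum(axis=1)
    col2 = tables[:, :, 1].sum(axis=1)
    n = tables.sum(axis=(1, 2))
    ok = n > 1
    if not ok.any():
        return float("nan"), float("nan")
    e = row1[ok] * col1[ok] / n[ok]
    v = row1[ok] * row2[ok] * col1[ok] * col2[ok] / (n[ok] ** 2 * (n[ok] - 1))
    vsum = v.sum()
    if vsum <= 0:
        return float("nan"), float("nan")
    stat = float((a[ok] - e).sum() ** 2 / vsum)
    return stat, float(chi2.sf(stat, df=1))


def mantel_extension_test(copies_a: np.ndarray, alleles_a: np.ndarray,
                          copies_b: np.ndarray, alleles_b: np.ndarray):
    """1-df Mantel-extension test of an allele-frequency difference between
    two cohorts, stratified by region.

    Inputs are per-stratum allele2 copy counts and total called allele
    counts for each cohort (length K vectors). Implemented as the
    Cochran-Mantel-Haenszel 2x2xK statistic (cohort x allele), continuity
    correction off. Returns (statistic, p); all-degenerate strata yield
    (nan, nan).
    """
    copies_a = np.asarray(copies_a, dtype=float)
    copies_b = np.asarray(copies_b, dtype=float)
    alleles_a = np.asarray(alleles_a, dtype=float)
    alleles_b = np.asarray(alleles_b, dtype=float)
    tables = np.stack([
        np.stack([copies_a, alleles_a - copies_a], axis=1),
        np.stack([copies_b, alleles_b - copies_b], axis=1),
    ], axis=1)  # (K, 2, 2)
    return _cmh_2x2xk(tables)


def lambda_r(pvalues: np.ndarray) -> float:
    """Overdispersion coefficient of homogeneity-test p-values.

    Under the null the p-values are uniform and -2*ln(p) is chi-square with
    2 df, so lambda_r = median(-2*ln(p)) / (2*ln(2)) equals 1; values above
    1 indicate region-heterogeneity beyond chance. p = 0 inputs are clipped
    to the smallest positive float with a warning.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("lambda_r undefined for empty input")
    if (p > 1).any() or (p < 0).any():
        raise ValueError("p-values must lie in [0, 1]")
    if (p == 0).any():
        warnings.warn("p-values of 0 clipped to the smallest positive float")
        p = np.clip(p, np.finfo(float).tiny, 1.0)
    return float(np.median(-2.0 * np.log(p)) / CHI2_2DF_MEDIAN)


def unique_region_concordance(presence_a: np.ndarray, presence_b: np.ndarray):
    """Among variants private to one region in both cohorts, how many are
    private to the *same* region.

    ``presence_a`` / ``presence_b`` are boolean (variants x regions)
    matrices over a shared variant space and region order (see
    :func:`variant_region_presence`). Returns
    (n_unique_in_both, n_same_region).
    """
    if presence_a.shape != presence_b.shape:
        raise ValueError("presence matrices must share variant and region space")
    ca = presence_a.sum(axis=1)
    cb = presence_b.sum(axis=1)
    both = (ca == 1) & (cb == 1)
    same = both & (presence_a.argmax(axis=1) == presence_b.argmax(axis=1))
    return int(both.sum()), int(same.sum())
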