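"""Case-control association tests and genomic-control summaries.

Implements the correction strategies whose calibration is compared across
MAF categories:

* ``armitage_trend`` / ``trend_scan`` -- the uncorrected ("raw") 1-df trend
  test, N * r^2 between dosage and phenotype.
* ``eigenstrat_adjusted`` / ``eigenstrat_scan`` -- the EIGENSTRAT
  correction: residualize dosage and phenotype on k principal components
  (plus intercept) and test the residual correlation with (N - k - 1) df.
* ``cmh_test`` / ``cmh_scan`` -- the Cochran-Mantel-Haenszel 2x2xK allelic
  test stratified on region, optionally with within-stratum permutation
  p-values; the gold standard when the confounding strata are known.
* ``grm`` + ``emmax_scan`` -- mixed-model association: variance components
  fitted once under the null by REML after an eigendecomposition of the
  kinship matrix, then per-variant generalized-least-squares F tests with
  the variance ratio held fixed (the binary phenotype treated as
  quantitative 0/1, as the mixed-model convention goes).
* ``lambda_gc`` -- median observed 1-df chi-square over the theoretical
  chi-square(1) median (~0.4549); ``scan_and_summarize`` assembles the
  lambda grid over methods x MAF categories, including the rare-variant
  subdivision at MAF 0.005.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar
from scipy.stats import chi2
from scipy.stats import f as f_dist

from strat_spectrum.plinkio import MISSING, GenotypeMatrix

CHI2_1DF_MEDIAN = float(chi2.ppf(0.5, df=1))  # ~0.454936

_CHUNK = 8192  # scan block size, keeps float64 temporaries modest


def _as_dosages(g) -> np.ndarray:
    return g.dosages if isinstance(g, GenotypeMatrix) else np.asarray(g)


def _check_phenotype(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    vals = np.unique(y)
    if not np.isin(vals, [0, 1]).all():
        # accept PLINK coding too
        if np.isin(vals, [1, 2]).all():
            return (y == 2).astype(float)
        raise ValueError("phenotype must be binary (0/1 or PLINK 1/2)")
    return y.astype(float)


# ---------------------------------------------------------------------------
# Trend test
# ---------------------------------------------------------------------------

def armitage_trend(g: np.ndarray, y: np.ndarray):
    """Armitage trend test for one variant: statistic = N * corr(g, y)^2.

    Missing dosages are dropped pairwise; a constant dosage or phenotype
    gives (0, 1). Returns (statistic, p) with p from the chi-square(1)
    upper tail.
    """
    g = np.asarray(g, dtype=float)
    yb = _check_phenotype(y)
    ok = g != MISSING
    g, yb = g[ok], yb[ok]
    n = len(g)
    if n < 3:
        raise ValueError("trend test needs >= 3 called samples")
    if np.ptp(g) == 0 or np.ptp(yb) == 0:
        return 0.0, 1.0
    r = np.corrcoef(g, yb)[0, 1]
    stat = n * r * r
    return float(stat), float(chi2.sf(stat, df=1))


def trend_scan(gm, y: np.ndarray) -> np.ndarray:
    """Vectorized trend statistics over all variants (pairwise deletion)."""
    d = _as_dosages(gm)
    yb = _check_phenotype(y)
    m = d.shape[1]
    stats = np.zeros(m)
    for lo in range(0, m, _CHUNK):
        block = d[:, lo:lo + _CHUNK].astype(float)
        called = block != MISSING
        gz = np.where(called, block, 0.0)
        n = called.sum(axis=0)
        sy = called.T @ yb
        syy = called.T @ (yb * yb)
        sg = gz.sum(axis=0)
        sgg = (gz * gz).sum(axis=0)
        sgy = gz.T @ yb
        num = n * sgy - sg * sy
        var_g = n * sgg - sg ** 2
        var_y = n * syy - sy ** 2
        denom = var_g * var_y
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(denom > 0, num ** 2 / denom, 0.0)
        stats[lo:lo + block.shape[1]] = n * r2
    return stats


# ---------------------------------------------------------------------------
# PC adjustment (EIGENSTRAT)
# ---------------------------------------------------------------------------

def eigenstrat_adjusted(g: np.ndarray, y: np.ndarray, pcs: np.ndarray):
    """PC-adjusted 1-df test for one variant.

    Residualizes dosage and phenotype on the k PC score vectors (plus an
    intercept) by least squares and tests the residual correlation:
    statistic = (N - k - 1) * corr(resid_g, resid_y)^2. With k = 0 this is
    (N - 1) * r^2, i.e. the trend statistic scaled by (N - 1)/N. Missing
    dosages are dropped pairwise. Collinear PCs are reduced via the
    pseudo-inverse.
    """
    g = np.asarray(g, dtype=float)
    yb = _check_phenotype(y)
    pcs = np.atleast_2d(np.asarray(pcs, dtype=float))
    if pcs.shape[0] != len(g) and pcs.size:
        pcs = pcs.T
    k = pcs.shape[1] if pcs.size else 0
    ok = g != MISSING
    g, yb = g[ok], yb[ok]
    n = len(g)
    if k >= n - 1:
        raise ValueError("need k < N - 1")
    design = np.column_stack([np.ones(n)] + ([pcs[ok]] if k else []))
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        warnings.warn("collinear PCs; effective k reduced")
        k = rank - 1
    proj = design @ np.linalg.pinv(design)
    rg = g - proj @ g
    ry = yb - proj @ yb
    denom = (rg @ rg) * (ry @ ry)
    if denom <= 0:
        return 0.0, 1.0
    r2 = (rg @ ry) ** 2 / denom
    stat = (n - k - 1) * r2
    return float(stat), float(chi2.sf(stat, df=1))


def eigenstrat_scan(gm, y: np.ndarray, pcs: np.ndarray) -> np.ndarray:
    """Vectorized PC-adjusted statistics (missing dosages mean-imputed)."""
    d = _as_dosages(gm)
    yb = _check_phenotype(y)
    pcs = np.atleast_2d(np.asarray(pcs, dtype=float))
    if pcs.shape[0] != d.shape[0]:
        pcs = pcs.T
    n = d.shape[0]
    k = pcs.shape[1]
    design = np.column_stack([np.ones(n), pcs])
    pinv = np.linalg.pinv(design)
    ry = yb - design @ (pinv @ yb)
    syy = ry @ ry
    m = d.shape[1]
    stats = np.zeros(m)
    for lo in range(0, m, _CHUNK):
        block = d[:, lo:lo + _CHUNK].astype(float)
        called = block != MISSING
        mean = np.where(called, block, 0).sum(axis=0) / np.maximum(
            called.sum(axis=0), 1)
        block = np.where(called, block, mean[None, :])
        rg = block - design @ (pinv @ block)
        sgg = (rg * rg).sum(axis=0)
        sgy = rg.T @ ry
        denom = sgg * syy
        with np.errstate(divide="ignore", invalid="ignore"):
            r2 = np.where(denom > 0, sgy ** 2 / denom, 0.0)
        stats[lo:lo + block.shape[1]] = (n - k - 1) * r2
    return stats


# ---------------------------------------------------------------------------
# CMH
# ---------------------------------------------------------------------------

def _cmh_components(d_block: np.ndarray, yb: np.ndarray, strata: np.ndarray):
    """Per-stratum CMH pieces for a block of variants.

    Returns (sum(a - E), sum(V)) arrays over variants, where a is the
    case allele2 copy count per stratum.
    """
    labels = np.unique(strata)
    num = np.zeros(d_block.shape[1])
    var = np.zeros(d_block.shape[1])
    for lab in labels:
        rows = strata == lab
        block = d_block[rows]
        ys = yb[rows]
        called = block != MISSING
        gz = np.where(called, block, 0.0)
        a = gz.T @ ys                          # case allele2 copies
        row1 = 2.0 * (called.T @ ys)           # case alleles
        n_tot = 2.0 * called.sum(axis=0)       # all alleles
        row2 = n_tot - row1
        col1 = gz.sum(axis=0)                  # allele2 copies
        col2 = n_tot - col1
        ok = n_tot > 1
        with np.errstate(divide="ignore", invalid="ignore"):
            e = np.where(ok, row1 * col1 / n_tot, 0.0)
            v = np.where(ok, row1 * row2 * col1 * col2
                         / (n_tot ** 2 * (n_tot - 1)), 0.0)
        num += np.where(ok, a - e, 0.0)
        var += v
    return num, var


def cmh_test(g: np.ndarray, y: np.ndarray, strata: np.ndarray,
             n_perm: int = 0, seed: int | None = None):
    """CMH 2x2xK allelic test for one variant, strata = region labels.

    Returns (statistic, asymptotic p, permutation p). The permutation p
    shuffles phenotypes within each stratum and carries the add-one
    correction; ``n_perm=0`` skips it (NaN). With no informative stratum
    the test returns (0, 1, 1) with a warning.
    """
    g = np.asarray(g, dtype=float)[:, None]
    yb = _check_phenotype(y)
    strata = np.asarray(strata)
    num, var = _cmh_components(g, yb, strata)
    if var[0] <= 0:
        warnings.warn("no informative stratum; CMH p set to 1")
        return 0.0, 1.0, 1.0 if n_perm else float("nan")
    stat = float(num[0] ** 2 / var[0])
    p_asymp = float(chi2.sf(stat, df=1))
    p_perm = float("nan")
    if n_perm:
        rng = np.random.default_rng(seed)
        labels = np.unique(strata)
        members = [np.flatnonzero(strata == lab) for lab in labels]
        b = 0
        yp = yb.copy()
        for _ in range(n_perm):
            for rows in members:
                yp[rows] = yb[rows][rng.permutation(len(rows))]
            nperm, vperm = _cmh_components(g, yp, strata)
            if vperm[0] > 0 and nperm[0] ** 2 / vperm[0] >= stat - 1e-12:
                b += 1
        p_perm = (b + 1) / (n_perm + 1)
    return stat, p_asymp, p_perm


def cmh_scan(gm, y: np.ndarray, strata: np.ndarray) -> np.ndarray:
    """Vectorized CMH statistics over all variants."""
    d = _as_dosages(gm)
    yb = _check_phenotype(y)
    strata = np.asarray(strata)
    m = d.shape[1]
    stats = np.zeros(m)
    for lo in range(0, m, _CHUNK):
        block = d[:, lo:lo + _CHUNK].astype(float)
        num, var = _cmh_components(block, yb, strata)
        with np.errstate(divide="ignore", invalid="ignore"):
            stats[lo:lo + block.shape[1]] = np.where(var > 0, num ** 2 / var, 0.0)
    return stats


# ---------------------------------------------------------------------------
# Mixed model (EMMAX-style)
# ---------------------------------------------------------------------------

def grm(gm) -> np.ndarray:
    """Genetic relatedness matrix K = Z Z^T / m over standardized dosages.

    Columns are mean-centered and scaled to unit standard deviation
    (missing dosages mean-imputed, i.e. contributing 0); monomorphic
    variants are dropped. Symmetric with positive diagonal.
    """
    d = _as_dosages(gm)
    if d.shape[1] < 2:
        raise ValueError("GRM needs >= 2 variants")
    called = d != MISSING
    mean = np.where(called, d, 0).sum(axis=0) / np.maximum(called.sum(axis=0), 1)
    z = np.where(called, d, mean[None, :]).astype(float) - mean[None, :]
    sd = z.std(axis=0)
    keep = sd > 0
    z = z[:, keep] / sd[keep][None, :]
    k = z @ z.T / keep.sum()
    return (k + k.T) / 2.0


def emmax_reml(y: np.ndarray, kinship: np.ndarray,
               lo: float = 1e-5, hi: float = 1e5, tol: float = 1e-6):
    """Null-model REML fit of y = mu + u + e, u ~ N(0, sg2 K), e ~ N(0, se2 I).

    One-dimensional optimization of the variance ratio delta = se2/sg2 on a
    log scale over [lo, hi], after eigendecomposition of the kinship
    restricted to the space orthogonal to the intercept. Returns a dict
    with delta, sg2, se2, the restricted log-likelihood, and an
    ``ols_boundary`` flag (True when delta hits the upper bound, i.e. the
    genetic variance is effectively 0 and the model reduces to ordinary
    regression).
    """
    yb = np.asarray(y, dtype=float)
    n = len(yb)
    k = np.asarray(kinship, dtype=float)
    if k.shape != (n, n):
        raise ValueError("kinship shape mismatch")
    # restrict to the orthogonal complement of the intercept
    yc = yb - yb.mean()
    ones = np.ones((n, 1)) / np.sqrt(n)
    s = np.eye(n) - ones @ ones.T
    evals, evecs = np.linalg.eigh(s @ k @ s)
    xi = evals[1:]          # n-1 informative eigenvalues
    u = evecs[:, 1:]
    eta = u.T @ yc
    eta2 = eta ** 2
    nq = n - 1

    def neg_restricted_ll(log_delta: float) -> float:
        delta = np.exp(log_delta)
        w = xi + delta
        if (w <= 0).any():
            return np.inf
        rss = (eta2 / w).sum()
        return 0.5 * (nq * np.log(rss) + np.log(w).sum())

    res = minimize_scalar(neg_restricted_ll, bounds=(np.log(lo), np.log(hi)),
                          method="bounded", options={"xatol": tol})
    if not res.success:
        raise RuntimeError(f"REML bracketing failed: {res.message}")
    delta = float(np.exp(res.x))
    w = xi + delta
    sg2 = float((eta2 / w).sum() / nq)
    se2 = sg2 * delta
    boundary = res.x > np.log(hi) - 10 * tol
    return {
        "delta": delta,
        "sg2": sg2,
        "se2": se2,
        "restricted_ll": float(-neg_restricted_ll(res.x)),
        "ols_boundary": bool(boundary),
        "_neg_rll": neg_restricted_ll,  # exposed for optimality checks
    }


def emmax_scan(y: np.ndarray, kinship: np.ndarray, gm,
               reml: dict | None = None) -> np.ndarray:
    """Mixed-model association p-values for every variant.

    Fits the variance ratio once under the null (see :func:`emmax_reml`),
    rotates phenotype and genotypes into the kinship eigenbasis, and runs a
    per-variant weighted-least-squares F test of the dosage term with
    fixed variance components; p from F(1, n - 2). Missing dosages are
    mean-imputed. With K = I the weights are constant and the p-values
    coincide with ordinary linear regression.
    """
    yb = _check_phenotype(y)
    n = len(yb)
    if reml is None:
        reml = emmax_reml(yb, kinship)
    if reml["ols_boundary"]:
        warnings.warn("genetic variance at 0 boundary; EMMAX reduces to OLS")
    evals, evecs = np.linalg.eigh(np.asarray(kinship, dtype=float))
    w = 1.0 / (evals + reml["delta"])
    sqw = np.sqrt(np.maximum(w, 0))
    ut = evecs.T
    a = sqw * (ut @ np.ones(n))
    yt = sqw * (ut @ yb)
    saa = a @ a
    say = a @ yt
    syy = yt @ yt
    rss0 = syy - say ** 2 / saa

    d = _as_dosages(gm)
    m = d.shape[1]
    pvals = np.ones(m)
    for lo_ix in range(0, m, _CHUNK):
        block = d[:, lo_ix:lo_ix + _CHUNK].astype(float)
        called = block != MISSING
        mean = np.where(called, block, 0).sum(axis=0) / np.maximum(
            called.sum(axis=0), 1)
        block = np.where(called, block, mean[None, :])
        gt = sqw[:, None] * (ut @ block)
        sag = a @ gt
        sgg = (gt * gt).sum(axis=0)
        sgy = gt.T @ yt
        det = saa * sgg - sag ** 2
        ok = det > 1e-12 * saa * np.maximum(sgg, 1e-300)
        with np.errstate(divide="ignore", invalid="ignore"):
            beta_g = (saa * sgy - sag * say) / det
            beta_0 = (sgg * say - sag * sgy) / det
            rss1 = syy - (beta_0 * say + beta_g * sgy)
            rss1 = np.maximum(rss1, 0.0)
            fstat = np.where(ok & (rss1 > 0),
                             (rss0 - rss1) * (n - 2) / rss1, 0.0)
        fstat = np.maximum(fstat, 0.0)
        pvals[lo_ix:lo_ix + block.shape[1]] = f_dist.sf(fstat, 1, n - 2)
    return pvals


# ---------------------------------------------------------------------------
# Genomic control
# ---------------------------------------------------------------------------

def lambda_gc(statistics: np.ndarray | None = None,
              pvalues: np.ndarray | None = None, df: int = 1) -> float:
    """Genomic-control lambda: median observed chi-square over the
    chi-square(df) median. P-value input is converted through the
    upper-tail inverse chi-square(df) transform first."""
    if (statistics is None) == (pvalues is None):
        raise ValueError("pass exactly one of statistics / pvalues")
    if pvalues is not None:
        p = np.asarray(pvalues, dtype=float)
        if p.size == 0:
            raise ValueError("lambda_gc undefined for empty input")
        statistics = chi2.isf(np.clip(p, np.finfo(float).tiny, 1.0), df=df)
    stats = np.asarray(statistics, dtype=float)
    if stats.size == 0:
        raise ValueError("lambda_gc undefined for empty input")
    return float(np.median(stats) / chi2.ppf(0.5, df=df))


def scan_and_summarize(gm, y: np.ndarray, regions: np.ndarray,
                       variant_table: pd.DataFrame,
                       pc_sets: dict[str, np.ndarray] | None = None,
                       pc_counts: tuple[int, ...] = (2, 3, 4, 10),
                       kinship_sets: dict[str, np.ndarray] | None = None,
                       include_raw: bool = True,
                       include_cmh: bool = True) -> pd.DataFrame:
    """Genomic-control lambda grid over methods x MAF categories.

    Rows: ``CMH``, ``Raw``, ``<set>.<k>`` for each PC source set and each k
    in ``pc_counts``, and ``EMMAX.<set>`` for each kinship set. Columns:
    common, lowfreq, rare, plus the rare subdivision at MAF 0.005. Raw,
    CMH and PC-adjusted lambdas use the observed statistics directly; the
    EMMAX lambda converts p-values through the inverse chi-square(1)
    transform. Empty categories yield NaN cells.
    """
    d = _as_dosages(gm)
    category = variant_table["category"].to_numpy()
    rare_sub = variant_table["rare_subcategory"].to_numpy()
    # variants with no dosage variation among called genotypes in *this*
    # cohort carry no test (e.g. rare variants private to unsampled
    # regions); they are excluded from the lambda medians, as an analysis
    # tool would report them NA
    testable = np.zeros(d.shape[1], dtype=bool)
    for lo in range(0, d.shape[1], _CHUNK):
        block = d[:, lo:lo + _CHUNK]
        called = block != MISSING
        gz = np.where(called, block, 0)
        n = called.sum(axis=0)
        s = gz.sum(axis=0)
        ss_ = (gz.astype(float) ** 2).sum(axis=0)
        testable[lo:lo + block.shape[1]] = (n > 0) & (n * ss_ > s ** 2)
    masks = {
        "common": (category == "common") & testable,
        "lowfreq": (category == "lowfreq") & testable,
        "rare": (category == "rare") & testable,
        "rare_maf<=0.005": (category == "rare") & (rare_sub == "very_rare")
        & testable,
        "rare_maf>0.005": (category == "rare") & (rare_sub == "less_rare")
        & testable,
    }

    rows: dict[str, dict[str, float]] = {}

    def add_row(name: str, stats: np.ndarray | None = None,
                pvals: np.ndarray | None = None) -> None:
        cells = {}
        for cat, mask in masks.items():
            if not mask.any():
                cells[cat] = float("nan")
            elif stats is not None:
                cells[cat] = lambda_gc(statistics=stats[mask])
            else:
                cells[cat] = lambda_gc(pvalues=pvals[mask])
        rows[name] = cells

    if include_cmh:
        add_row("CMH", stats=cmh_scan(d, y, regions))
    if include_raw:
        add_row("Raw", stats=trend_scan(d, y))
    for set_name, scores in (pc_sets or {}).items():
        scores = np.asarray(scores, dtype=float)
        for k in pc_counts:
            if k > scores.shape[1]:
                warnings.warn(f"{set_name}: only {scores.shape[1]} PCs; skip k={k}")
                continue
            add_row(f"{set_name}.{k}",
                    stats=eigenstrat_scan(d, y, scores[:, :k]))
    for set_name, kin in (kinship_sets or {}).items():
        add_row(f"EMMAX.{set_name}", pvals=emmax_scan(y, kin, d))
    return pd.DataFrame(rows).T[list(masks)]
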